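"""Chromosomal mapping, spacing statistics and duplication-class assignment.

Duplication classes follow the duplicate-gene-classifier convention: a gene in
any collinear block of homolog pairs is WGD/segmental; otherwise a
same-chromosome pair within the tandem rank window makes it tandem, within the
proximal window proximal; any remaining pair makes it dispersed; no pair makes
it singleton.  Rank gaps are counted over ALL genes on the chromosome, not
only family members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import gffutils

from ringminer.util import percent

DUP_CLASSES = ("singleton", "dispersed", "proximal", "tandem", "WGD_segmental")


@dataclass(frozen=True)
class GeneLocus:
    gene_id: str
    chromosome: str
    start: int  # 1-based bp
    end: int
    strand: str = "+"
    rank: int = 0  # order along chromosome among all genes, 1-based
    excluded: bool = False  # unassembled scaffold


@dataclass(frozen=True)
class DupParams:
    """Windows (in gene-rank units) and collinearity-chaining parameters."""

    tandem_max_rank_gap: int = 1
    proximal_max_rank_gap: int = 10
    min_anchors: int = 5
    max_anchor_rank_gap: int = 25

    def __post_init__(self) -> None:
        if self.tandem_max_rank_gap >= self.proximal_max_rank_gap:
            raise ValueError("tandem window must be smaller than proximal window")
        if self.min_anchors < 2:
            raise ValueError("min_anchors must be >= 2")


@dataclass(frozen=True)
class DuplicationCall:
    gene_id: str
    dup_class: str
    evidence: tuple[str, ...] = ()


@dataclass(frozen=True)
class CollinearBlock:
    block_id: str
    anchors: tuple[tuple[str, str], ...]  # ordered (gene_a, gene_b) pairs


DEFAULT_UNPLACED_MARKERS = ("un", "scaffold", "contig")


def _is_unplaced(chrom: str, markers: Sequence[str]) -> bool:
    low = chrom.lower()
    return any(m in low for m in markers)


def load_gene_loci(gff3, unplaced_markers: Sequence[str] = DEFAULT_UNPLACED_MARKERS
                   ) -> list[GeneLocus]:
    """Read gene features from GFF3 (path or text) and assign per-chromosome ranks.

    Genes on unassembled scaffolds (chromosome name containing an unplaced
    marker, e.g. 'ChrUn') are flagged ``excluded`` and receive no rank.
    """
    text = str(gff3)
    from_string = "\n" in text or not text.strip() or text.lstrip().startswith("##")
    if not from_string:
        text = open(text).read()
    if not any(line.strip() and not line.startswith("#")
               for line in text.splitlines()):
        return []
    db = gffutils.create_db(text, ":memory:", from_string=True,
                            merge_strategy="create_unique", force=True)
    raw: list[GeneLocus] = []
    for i, feat in enumerate(db.features_of_type("gene")):
        if feat.start is None or feat.end is None:
            raise ValueError(f"gene record {i + 1} ({feat.id}): missing coordinates")
        gid = feat.attributes.get("ID", [feat.id])[0]
        raw.append(GeneLocus(gene_id=gid, chromosome=feat.seqid,
                             start=feat.start, end=feat.end,
                             strand=feat.strand if feat.strand in "+-" else "+",
                             excluded=_is_unplaced(feat.seqid, unplaced_markers)))
    out: list[GeneLocus] = []
    by_chrom: dict[str, list[GeneLocus]] = {}
    for g in raw:
        if g.excluded:
            out.append(g)
        else:
            by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda g: (g.start, g.gene_id))
        for rank, g in enumerate(genes, start=1):
            out.append(GeneLocus(g.gene_id, g.chromosome, g.start, g.end,
                                 g.strand, rank=rank))
    out.sort(key=lambda g: (g.chromosome, g.start, g.gene_id))
    return out


def chrom_distribution(loci: Sequence[GeneLocus],
                       family: Optional[set[str]] = None) -> dict[str, dict]:
    """Per-chromosome gene counts and percentages (1-decimal, half-up)."""
    kept = [g for g in loci if not g.excluded
            and (family is None or g.gene_id in family)]
    if not kept:
        raise ValueError("no mapped genes to summarize")
    total = len(kept)
    counts: dict[str, int] = {}
    for g in kept:
        counts[g.chromosome] = counts.get(g.chromosome, 0) + 1
    return {c: {"count": n, "percent": percent(n, total, 1)}
            for c, n in sorted(counts.items())}


def mean_adjacent_distance(loci: Sequence[GeneLocus],
                           family: Optional[set[str]] = None
                           ) -> dict[str, Optional[float]]:
    """Mean start-to-start distance (Mb, 1 decimal) between consecutive family
    genes, per chromosome; NA (None) where fewer than two genes map."""
    by_chrom: dict[str, list[int]] = {}
    for g in loci:
        if g.excluded or (family is not None and g.gene_id not in family):
            continue
        by_chrom.setdefault(g.chromosome, []).append(g.start)
    out: dict[str, Optional[float]] = {}
    for chrom, starts in sorted(by_chrom.items()):
        starts.sort()
        if len(starts) < 2:
            out[chrom] = None
            continue
        gaps = [b - a for a, b in zip(starts, starts[1:])]
        out[chrom] = round(sum(gaps) / len(gaps) / 1e6, 1)
    return out


def _longest_chain(pairs: list[tuple[int, int, int]], max_gap: int,
                   direction: int) -> list[int]:
    """Longest chain over (rank_a, rank_b, idx): strictly increasing on A,
    monotonic on B with the given direction, consecutive gaps <= max_gap."""
    order = sorted(range(len(pairs)), key=lambda i: (pairs[i][0], pairs[i][1]))
    best_len = [1] * len(pairs)
    prev = [-1] * len(pairs)
    for oi, i in enumerate(order):
        ra, rb, _ = pairs[i]
        for j in order[:oi]:
            qa, qb, _ = pairs[j]
            if qa >= ra or abs(ra - qa) > max_gap:
                continue
            if direction * (rb - qb) <= 0 or abs(rb - qb) > max_gap:
                continue
            if best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    if not pairs:
        return []
    end = max(range(len(pairs)), key=lambda i: (best_len[i], -pairs[i][0]))
    chain = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    return chain[::-1]


def chain_collinear_blocks(pairs: Iterable[tuple[str, str]],
                           loci: Sequence[GeneLocus],
                           params: DupParams = DupParams()) -> list[CollinearBlock]:
    """Chain homolog pairs into collinear blocks, greedy longest-chain first.

    A block is a maximal chain of anchor pairs, strictly increasing in rank on
    side A and monotonic (either direction) on side B, with consecutive anchors
    within ``max_anchor_rank_gap`` on both sides and length >= ``min_anchors``.
    Each anchor pair is consumed by at most one block.
    """
    known = {g.gene_id for g in loci}
    rank = {g.gene_id: g.rank for g in loci if not g.excluded}
    chrom = {g.gene_id: g.chromosome for g in loci if not g.excluded}
    pair_list = []
    for a, b in pairs:
        for x in (a, b):
            if x not in known:
                raise ValueError(f"pair references unknown gene {x!r}")
        if a in rank and b in rank:
            pair_list.append((a, b))
    groups: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for a, b in pair_list:
        key = (chrom[a], chrom[b])
        groups.setdefault(key, []).append((a, b))
    blocks: list[CollinearBlock] = []
    n = 0
    for key in sorted(groups):
        remaining = groups[key]
        while True:
            indexed = [(rank[a], rank[b], i) for i, (a, b) in enumerate(remaining)]
            best_chain: list[int] = []
            for direction in (1, -1):
                chain = _longest_chain(indexed, params.max_anchor_rank_gap, direction)
                if len(chain) > len(best_chain):
                    best_chain = chain
            if len(best_chain) < params.min_anchors:
                break
            n += 1
            anchors = tuple(remaining[indexed[i][2]] for i in best_chain)
            blocks.append(CollinearBlock(block_id=f"block{n}", anchors=anchors))
            used = {indexed[i][2] for i in best_chain}
            remaining = [p for i, p in enumerate(remaining) if i not in used]
            if not remaining:
                break
    return blocks


def classify_duplications(loci: Sequence[GeneLocus],
                          pairs: Iterable[tuple[str, str]],
                          blocks: Sequence[CollinearBlock],
                          params: DupParams = DupParams(),
                          gene_ids: Optional[Iterable[str]] = None
                          ) -> list[DuplicationCall]:
    """Assign each (mapped) gene exactly one duplication class by priority:
    WGD/segmental > tandem > proximal > dispersed > singleton."""
    known = {g.gene_id for g in loci}
    rank = {g.gene_id: g.rank for g in loci if not g.excluded}
    chrom = {g.gene_id: g.chromosome for g in loci if not g.excluded}
    targets = list(gene_ids) if gene_ids is not None else [
        g.gene_id for g in loci if not g.excluded]
    partners: dict[str, list[str]] = {t: [] for t in targets}
    for a, b in pairs:
        for x in (a, b):
            if x not in known:
                raise ValueError(f"pair references unknown gene {x!r}")
        if a in partners:
            partners[a].append(b)
        if b in partners:
            partners[b].append(a)
    in_block: dict[str, list[str]] = {}
    for blk in blocks:
        for a, b in blk.anchors:
            in_block.setdefault(a, []).append(blk.block_id)
            in_block.setdefault(b, []).append(blk.block_id)
    calls = []
    for gid in targets:
        if gid in in_block:
            calls.append(DuplicationCall(gid, "WGD_segmental",
                                         tuple(in_block[gid])))
            continue
        mates = [m for m in partners.get(gid, []) if m in rank]
        same = [m for m in mates if chrom.get(m) == chrom.get(gid)]
        gapped = sorted((abs(rank[m] - rank[gid]), m) for m in same)
        if gapped and gapped[0][0] <= params.tandem_max_rank_gap:
            calls.append(DuplicationCall(gid, "tandem", (gapped[0][1],)))
        elif gapped and gapped[0][0] <= params.proximal_max_rank_gap:
            calls.append(DuplicationCall(gid, "proximal", (gapped[0][1],)))
        elif mates:
            calls.append(DuplicationCall(gid, "dispersed", (sorted(mates)[0],)))
        else:
            calls.append(DuplicationCall(gid, "singleton"))
    return calls


def class_counts(calls: Sequence[DuplicationCall]) -> dict[str, int]:
    out = {c: 0 for c in DUP_CLASSES}
    for call in calls:
        out[call.dup_class] += 1
    return out
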