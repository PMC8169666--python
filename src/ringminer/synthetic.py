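"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emits data whose true structure is known by construction and is
returned alongside the data as a :class:`SyntheticTruth`.  Noise-free settings
round-trip exactly through the consuming stage; all randomness flows through an
explicit seed (no hidden global RNG state).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ringminer.qpcr import CtTable
from ringminer.rules import N_LIGANDS, RuleSet
from ringminer.scanner import scan_domains
from ringminer.util import AA20
from ringminer.variants import (GeneModel, VariantCall, Windows, _splice_labels,
                                annotate_variants)


class PlanError(ValueError):
    """An infeasible or unrealizable generation plan."""


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying generated data."""

    planted_domains: list = field(default_factory=list)
    dup_classes: dict = field(default_factory=dict)
    venn_spec: Optional[tuple] = None
    fc_profiles: dict = field(default_factory=dict)
    variant_effects: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# proteomes with planted RING motifs
# --------------------------------------------------------------------------

_BG = sorted(AA20)
_BG_WEIGHTS = np.array([0.3 if a in "CH" else 1.0 for a in _BG])
_BG_WEIGHTS = _BG_WEIGHTS / _BG_WEIGHTS.sum()


def _gap_alphabet(ruleset: RuleSet) -> list[str]:
    ligandish = set().union(*ruleset.union_allowed())
    letters = sorted(AA20 - ligandish)
    if not letters:
        raise PlanError("rule set leaves no non-ligand residues for gap filler")
    return letters


def _build_domain(entry: str, ruleset: RuleSet, rng: np.random.Generator
                  ) -> tuple[str, list[int], str, frozenset]:
    """Residue string for one planted domain: (text, ligand offsets, subtype, flags)."""
    flags: set[str] = set()
    name = entry
    if entry.endswith("!rbx"):
        name = entry[: -len("!rbx")]
        flags.add("RBX")
    incomplete = name == "INCOMPLETE"
    base = ruleset.subtypes[0].name if incomplete else name
    try:
        rule = ruleset.get(base)
    except KeyError:
        raise PlanError(f"unknown subtype {entry!r} in domain plan") from None
    for _ in range(200):
        gaps = [int(rng.integers(lo, hi + 1)) for lo, hi in rule.gap_ranges]
        if N_LIGANDS + sum(gaps) <= ruleset.max_domain_span:
            break
    else:
        raise PlanError(f"cannot sample a span <= {ruleset.max_domain_span} "
                        f"for {base!r}")
    residues = [sorted(s)[int(rng.integers(len(s)))]
                for s in rule.allowed_residues]
    if "RBX" in flags:
        if rule.rbx_substitution is None:
            raise PlanError(f"subtype {base!r} defines no RBX substitution")
        idx, res = rule.rbx_substitution
        residues[idx - 1] = res
    if incomplete:
        residues[N_LIGANDS - 1] = "A"  # substituted ML8 -> incomplete candidate
    filler = _gap_alphabet(ruleset)
    parts: list[str] = []
    offsets: list[int] = []
    pos = 0
    for i, res in enumerate(residues):
        offsets.append(pos)
        parts.append(res)
        pos += 1
        if i < N_LIGANDS - 1:
            gap = gaps[i]
            parts.append("".join(filler[int(j)] for j in
                                 rng.integers(0, len(filler), size=gap)))
            pos += gap
    subtype = "INCOMPLETE" if incomplete else base
    return "".join(parts), offsets, subtype, frozenset(flags)


def gen_proteome(ruleset: RuleSet, n_proteins: int,
                 domain_plan: Sequence[Sequence[str]] = (),
                 decoy_rate: float = 0.0, seed: int = 0,
                 min_length: int = 150, max_length: int = 400
                 ) -> tuple[list[tuple[str, str]], SyntheticTruth]:
    """Proteins with planted RING domains of requested subtypes.

    ``domain_plan[i]`` lists the subtype entries for protein i (may be empty);
    entries are rule names, ``"NAME!rbx"`` for the RBX variant, or
    ``"INCOMPLETE"`` (ML8 substituted).  Remaining proteins carry no planted
    domain; a ``decoy_rate`` fraction of them receives an incomplete decoy.
    Background residues are drawn with Cys/His down-weighted x0.3 and any
    window that would create a spurious complete match is re-drawn, so the
    complete domains recovered by the scanner equal the planted truth exactly.
    """
    if len(domain_plan) > n_proteins:
        raise PlanError("domain plan longer than the number of proteins")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth()
    records: list[tuple[str, str]] = []
    sep = ruleset.max_domain_span + 10  # prevents cross-domain chaining

    for i in range(n_proteins):
        pid = f"P{i + 1:04d}"
        entries = list(domain_plan[i]) if i < len(domain_plan) else []
        if not entries and decoy_rate > 0 and rng.random() < decoy_rate:
            entries = ["INCOMPLETE"]
        domains = []
        cursor = int(rng.integers(10, 30))
        for entry in entries:
            text, offsets, subtype, flags = _build_domain(entry, ruleset, rng)
            domains.append((cursor, text, offsets, subtype, flags))
            cursor += len(text) + sep
        needed = cursor + 10
        length = max(needed, int(rng.integers(min_length, max_length + 1)))
        protected = np.zeros(length, dtype=bool)
        seq = list(rng.choice(_BG, size=length, p=_BG_WEIGHTS))
        for start, text, offsets, subtype, flags in domains:
            seq[start:start + len(text)] = list(text)
            protected[start:start + len(text)] = True
            truth.planted_domains.append({
                "protein_id": pid,
                "start": start + 1,
                "ligand_positions": [start + o + 1 for o in offsets],
                "subtype": subtype,
                "flags": sorted(flags),
            })
        planted_complete = {
            tuple(d["ligand_positions"]) for d in truth.planted_domains
            if d["protein_id"] == pid and d["subtype"] != "INCOMPLETE"
        }
        for _ in range(300):
            hits = [h for h in scan_domains("".join(seq), ruleset, pid)
                    if h.is_complete_candidate]
            extra = [h for h in hits
                     if h.ligand_positions not in planted_complete]
            missing = planted_complete - {h.ligand_positions for h in hits}
            if not extra and not missing:
                break
            windows = [(h.start - 1, h.end) for h in extra]
            for positions in missing:
                windows.append((max(0, positions[0] - 1 - sep), positions[-1]))
            redraw = [p for lo, hi in windows for p in range(lo, hi)
                      if 0 <= p < length and not protected[p]]
            for p in redraw:
                seq[p] = str(rng.choice(_BG, p=_BG_WEIGHTS))
            if not redraw:  # nothing left to redraw: give up loudly
                raise RuntimeError("could not sanitize background sequence")
        else:
            raise RuntimeError("background sanitation did not converge")
        records.append((pid, "".join(seq)))
    return records, truth


# --------------------------------------------------------------------------
# gene maps with planted duplication classes
# --------------------------------------------------------------------------

_CLASS_ALIASES = {
    "singleton": "singleton", "dispersed": "dispersed", "proximal": "proximal",
    "tandem": "tandem", "wgd": "WGD_segmental", "wgd_segmental": "WGD_segmental",
    "wgd/segmental": "WGD_segmental",
}


def _pair_triple_split(n: int, label: str) -> list[int]:
    if n == 0:
        return []
    if n == 1:
        raise PlanError(f"{label}: a single gene cannot form a homolog pair")
    groups = []
    if n % 2 == 1:
        groups.append(3)
        n -= 3
    groups.extend([2] * (n // 2))
    return groups


def gen_gene_map(n_genes: int, n_chroms: int, class_plan: Mapping[str, int],
                 params=None, seed: int = 0
                 ) -> tuple[str, list[tuple[str, str]], SyntheticTruth]:
    """Gene map (GFF3 text), homolog pairs and planted duplication classes.

    The emitted ranks and pair list yield exactly ``class_plan`` under
    ``classify_duplications`` with the same parameters.  Filler (non-family)
    genes are interleaved to realize the rank-gap windows, mirroring the
    convention that rank gaps count all genes on a chromosome.
    """
    from ringminer.genome import DupParams
    from ringminer.io import gff3_gene_lines

    params = params or DupParams()
    plan: dict[str, int] = {}
    for key, count in class_plan.items():
        norm = _CLASS_ALIASES.get(str(key).lower())
        if norm is None:
            raise PlanError(f"unknown duplication class {key!r}")
        if count < 0:
            raise PlanError(f"negative count for class {key!r}")
        plan[norm] = plan.get(norm, 0) + int(count)
    if sum(plan.values()) != n_genes:
        raise PlanError(f"class counts sum to {sum(plan.values())}, "
                        f"expected n_genes={n_genes}")
    if n_chroms < 1:
        raise PlanError("need at least one chromosome")
    wgd = plan.get("WGD_segmental", 0)
    if wgd % 2 != 0:
        raise PlanError("WGD/segmental gene count must be even (anchor pairs)")
    if wgd and wgd // 2 < params.min_anchors:
        raise PlanError(f"WGD block infeasible: {wgd // 2} anchors < "
                        f"min_anchors={params.min_anchors}")
    if plan.get("dispersed", 0) or wgd:
        if n_chroms < 2:
            raise PlanError("dispersed/WGD classes need >= 2 chromosomes")
    if plan.get("dispersed", 0) % 2 == 1 and n_chroms < 3:
        raise PlanError("an odd dispersed count needs >= 3 chromosomes")

    rng = np.random.default_rng(seed)  # reserved: layout is deterministic
    chroms = [f"Chr{i + 1}" for i in range(n_chroms)]
    genes_on: dict[str, list[str]] = {c: [] for c in chroms}
    pairs: list[tuple[str, str]] = []
    truth = SyntheticTruth()
    sep = max(params.proximal_max_rank_gap, params.max_anchor_rank_gap) + 2
    counters = {"fam": 0, "fill": 0}

    def fam(cls: str) -> str:
        counters["fam"] += 1
        gid = f"G{counters['fam']:05d}"
        truth.dup_classes[gid] = cls
        return gid

    def pad(chrom: str, n: int) -> None:
        for _ in range(n):
            counters["fill"] += 1
            genes_on[chrom].append(f"F{counters['fill']:06d}")

    cyc = 0

    def next_chrom(k: int = 1) -> list[str]:
        nonlocal cyc
        out = [chroms[(cyc + j) % n_chroms] for j in range(k)]
        cyc += k
        return out

    for _ in range(plan.get("singleton", 0)):
        (c,) = next_chrom()
        genes_on[c].append(fam("singleton"))
        pad(c, sep)

    for size in _pair_triple_split(plan.get("tandem", 0), "tandem"):
        (c,) = next_chrom()
        ids = [fam("tandem") for _ in range(size)]
        genes_on[c].extend(ids)
        pairs.extend(zip(ids, ids[1:]))
        pad(c, sep)

    for size in _pair_triple_split(plan.get("proximal", 0), "proximal"):
        (c,) = next_chrom()
        ids = []
        for j in range(size):
            gid = fam("proximal")
            ids.append(gid)
            genes_on[c].append(gid)
            if j < size - 1:
                pad(c, params.tandem_max_rank_gap)  # rank gap tandem+1
        pairs.extend(zip(ids, ids[1:]))
        pad(c, sep)

    for size in _pair_triple_split(plan.get("dispersed", 0), "dispersed"):
        cs = next_chrom(size)
        if len(set(cs)) < size:
            raise PlanError("dispersed group needs distinct chromosomes")
        ids = [fam("dispersed") for _ in range(size)]
        for gid, c in zip(ids, cs):
            genes_on[c].append(gid)
            pad(c, sep)
        pairs.extend(zip(ids, ids[1:]))

    anchors = wgd // 2
    if anchors:
        sizes = [params.min_anchors] * (anchors // params.min_anchors)
        rem = anchors % params.min_anchors
        if rem:
            if sizes:
                sizes[-1] += rem
            else:  # pragma: no cover - guarded above
                raise PlanError("WGD block smaller than min_anchors")
        for k in sizes:
            ca, cb = next_chrom(2)
            if ca == cb:
                ca, cb = chroms[0], chroms[1]
            a_ids = [fam("WGD_segmental") for _ in range(k)]
            b_ids = [fam("WGD_segmental") for _ in range(k)]
            genes_on[ca].extend(a_ids)
            genes_on[cb].extend(b_ids)
            pairs.extend(zip(a_ids, b_ids))
            pad(ca, sep)
            pad(cb, sep)

    lines: list[str] = []
    spacing = 10_000
    for c in chroms:
        for idx, gid in enumerate(genes_on[c]):
            start = 1 + idx * spacing
            lines.extend(gff3_gene_lines(gid, c, start, start + 999))
    gff3 = "##gff-version 3\n" + "\n".join(lines) + "\n"
    return gff3, pairs, truth


# --------------------------------------------------------------------------
# expression matrices realizing an exact Venn partition
# --------------------------------------------------------------------------

_VENN_MASKS = (
    (1, 1, 1), (1, 1, 0), (0, 1, 1), (1, 0, 1), (1, 0, 0), (0, 1, 0), (0, 0, 1),
)


def gen_expression(venn_spec: Sequence[int], n_silent: int,
                   threshold: float = 0.5, seed: int = 0,
                   stages: Sequence[str] = ("2DAA", "14DAA", "30DAA")
                   ) -> pd.DataFrame:
    """TPM matrix whose expressed/silent structure realizes ``venn_spec`` exactly.

    Region order: all three stages; stages 1&2 only; 2&3 only; 1&3 only;
    stage-1 only; stage-2 only; stage-3 only.  Expressed entries are drawn
    Uniform(threshold+0.5, 100), silent entries Uniform(0, threshold/2), so
    calls at the generating threshold are unambiguous.
    """
    spec = [int(x) for x in venn_spec]
    if len(spec) != 7 or any(x < 0 for x in spec) or n_silent < 0:
        raise PlanError("venn_spec must be 7 non-negative counts")
    rng = np.random.default_rng(seed)
    rows = []
    for count, mask in zip(spec, _VENN_MASKS):
        rows.extend([mask] * count)
    rows.extend([(0, 0, 0)] * n_silent)
    n = len(rows)
    hi = rng.uniform(threshold + 0.5, 100.0, size=(n, 3))
    lo = rng.uniform(0.0, threshold * 0.5, size=(n, 3))
    mask_arr = np.array(rows, dtype=bool)
    values = np.where(mask_arr, hi, lo)
    order = rng.permutation(n)
    ids = [f"RG{i + 1:05d}" for i in range(n)]
    return pd.DataFrame(values[order], index=[ids[i] for i in order],
                        columns=list(stages)).sort_index()


# --------------------------------------------------------------------------
# qPCR Ct tables with planted fold-change profiles
# --------------------------------------------------------------------------

def gen_qpcr(fc_profiles: Mapping[str, Mapping[str, Sequence[float]]],
             ref_gene_ct: float = 20.0, noise_sd: float = 0.0,
             replicates: int = 3, techreps: int = 3, seed: int = 0,
             control: str = "C306", ref_gene: str = "ARF",
             base_offset: float = 2.0,
             stages: Sequence = (7, 14, 21, 28)) -> CtTable:
    """Long-format Ct table realizing per-gene, per-mutant log2FC targets.

    Ct model: the reference gene sits at ``ref_gene_ct`` in every run; the
    target gene in the control genotype at ``ref_gene_ct + base_offset``; in a
    mutant genotype the log2FC component is subtracted, so the Livak ddCt
    recovers the planted value exactly when ``noise_sd`` is 0.
    """
    if replicates < 1 or techreps < 1:
        raise PlanError("need at least one replicate")
    if noise_sd < 0:
        raise PlanError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    genotypes = sorted({g for prof in fc_profiles.values() for g in prof}
                       | {control})
    rows = []

    def emit(gene: str, genotype: str, stage, ct: float) -> None:
        for b in range(1, replicates + 1):
            for t in range(1, techreps + 1):
                noise = rng.normal(0.0, noise_sd) if noise_sd else 0.0
                rows.append((gene, genotype, stage, b, t, ct + noise))

    for genotype in genotypes:
        for stage in stages:
            emit(ref_gene, genotype, stage, ref_gene_ct)
    for gene in sorted(fc_profiles):
        prof = fc_profiles[gene]
        for genotype in genotypes:
            for si, stage in enumerate(stages):
                ct = ref_gene_ct + base_offset
                if genotype != control and genotype in prof:
                    ct -= float(prof[genotype][si])
                emit(gene, genotype, stage, ct)
    df = pd.DataFrame(rows, columns=["gene", "genotype", "stage",
                                     "biorep", "techrep", "ct"])
    return CtTable(data=df, reference_gene=ref_gene)


# --------------------------------------------------------------------------
# variants with planted effect categories
# --------------------------------------------------------------------------

VARIANT_CATEGORIES = (
    "intergenic", "upstream_gene", "downstream_gene", "intron",
    "splice_donor&intron", "splice_acceptor&intron", "splice_region&intron",
    "splice_donor&splice_region&intron",
    "5_prime_UTR", "5_prime_UTR_premature_start_gain", "3_prime_UTR",
    "synonymous", "missense", "missense&splice_region",
    "frameshift", "frameshift&splice_region",
    "conservative_inframe_deletion", "disruptive_inframe_deletion",
    "conservative_inframe_insertion", "disruptive_inframe_insertion",
    "disruptive_inframe_insertion&splice_region",
)

_PATTERN = "CCTGG"  # background with no ATG/CAT on either strand
_INTRON_LEN = 30


def toy_gene_models(effect_plan: Mapping[str, int],
                    windows: Windows = Windows(),
                    chrom: str = "Chr1") -> tuple[list[GeneModel], int]:
    """One plus-strand multi-exon gene model sized to carry ``effect_plan``.

    Returns (models, chromosome length).  Capacity rules: one dedicated intron
    per splice-edge variant, six splice-region and seven interior slots per
    extra intron, one stride-2 codon slot per coding variant in the first
    exon.
    """
    p = {k: int(effect_plan.get(k, 0)) for k in VARIANT_CATEGORIES}
    unknown = set(effect_plan) - set(VARIANT_CATEGORIES)
    if unknown:
        raise PlanError(f"unknown variant categories: {sorted(unknown)}")
    n_coding = (p["synonymous"] + p["missense"] + p["frameshift"]
                + p["conservative_inframe_deletion"]
                + 2 * p["disruptive_inframe_deletion"]
                + p["conservative_inframe_insertion"]
                + p["disruptive_inframe_insertion"])
    n_exon_start = (p["missense&splice_region"] + p["frameshift&splice_region"]
                    + p["disruptive_inframe_insertion&splice_region"])
    n_introns = (p["splice_donor&intron"] + p["splice_acceptor&intron"]
                 + p["splice_donor&splice_region&intron"] + n_exon_start
                 + math.ceil(p["splice_region&intron"] / 6)
                 + math.ceil(p["intron"] / 7))
    utr5_len = 5 * (p["5_prime_UTR"] + p["5_prime_UTR_premature_start_gain"]) + 15
    utr3_len = 3 * p["3_prime_UTR"] + 15
    exon1_codons = 2 * n_coding + 10
    inter_zone = 2 * p["intergenic"] + 60

    pos = inter_zone + windows.upstream + 1  # gene start (1-based)
    gene_start = pos
    exons: list[tuple[int, int]] = []
    cds: list[tuple[int, int]] = []
    # exon 1: 5'UTR + first CDS chunk
    e1_len = utr5_len + 3 * exon1_codons
    exons.append((pos, pos + e1_len - 1))
    cds.append((pos + utr5_len, pos + e1_len - 1))
    pos += e1_len
    for _ in range(n_introns):
        pos += _INTRON_LEN  # intron
        exon_len = 3 * 6  # 6 codons
        exons.append((pos, pos + exon_len - 1))
        cds.append((pos, pos + exon_len - 1))
        pos += exon_len
    # final exon: 3 codons (incl. stop) + 3'UTR
    last_len = 9 + utr3_len
    if n_introns:
        pos += _INTRON_LEN
        exons.append((pos, pos + last_len - 1))
        cds.append((pos, pos + 8))
        pos += last_len
    else:  # single-exon gene: extend exon 1
        s, e = exons.pop()
        _, ce = cds.pop()
        exons.append((s, e + last_len))
        cds.append((s + utr5_len, ce + 9))
        pos += last_len
    gene_end = pos - 1
    model = GeneModel(gene_id="ToyGene1", chromosome=chrom,
                      start=gene_start, end=gene_end, strand="+",
                      exons=tuple(exons), cds=tuple(cds))
    chrom_len = gene_end + windows.downstream + inter_zone
    return [model], chrom_len


def _complement(base: str) -> str:
    return {"A": "T", "T": "A", "C": "G", "G": "C"}[base]


def _alt_for(ref: str, in_utr5: bool = False) -> str:
    if in_utr5:  # never create an ATG context from the CCTGG background
        return "G" if ref != "G" else "C"
    return {"A": "C", "C": "A", "G": "T", "T": "G"}[ref]


def gen_variants(gene_models: Sequence[GeneModel],
                 effect_plan: Mapping[str, int], seed: int = 0,
                 windows: Windows = Windows(),
                 chrom_length: Optional[int] = None, verify: bool = True
                 ) -> tuple[list[VariantCall], dict[str, str], SyntheticTruth]:
    """Plant variants realizing ``effect_plan`` on the given gene models.

    Builds the reference sequence itself (background plus canonical gene
    structure: ATG start, GT..AG introns, stop codon), places each requested
    category at a dedicated location, and — with ``verify=True`` — re-annotates
    the output to confirm the plan is reproduced exactly.  Genic placements
    require plus-strand models; an unrealizable category raises
    :class:`PlanError` naming it.
    """
    plan = {k: int(v) for k, v in effect_plan.items() if int(v) != 0}
    unknown = set(plan) - set(VARIANT_CATEGORIES)
    if unknown:
        raise PlanError(f"unknown variant categories: {sorted(unknown)}")
    for k, v in plan.items():
        if v < 0:
            raise PlanError(f"negative count for {k!r}")
    chroms = sorted({g.chromosome for g in gene_models})
    if len(chroms) != 1:
        raise PlanError("toy generation supports a single chromosome")
    chrom = chroms[0]
    genic_cats = [c for c in plan if c not in ("intergenic",)]
    plus_genes = [g for g in gene_models if g.strand == "+"]
    if genic_cats and not plus_genes:
        raise PlanError("genic placements require a plus-strand gene model")

    max_end = max(g.end for g in gene_models)
    length = chrom_length or (max_end + windows.downstream
                              + 2 * plan.get("intergenic", 0) + 60)
    seq = [_PATTERN[i % len(_PATTERN)] for i in range(length)]

    # canonical gene structure
    for gene in gene_models:
        for istart, iend in gene.introns():
            seq[istart - 1], seq[istart] = "G", "T"
            seq[iend - 2], seq[iend - 1] = "A", "G"
        cpos = [p for s, e in sorted(gene.cds) for p in range(s, e + 1)]
        if gene.strand == "-":
            cpos = cpos[::-1]
        coding = ["ATG"] + ["GGT"] * (len(cpos) // 3 - 2) + ["TGA"]
        fill = "".join(coding)
        for p, base in zip(cpos, fill):
            seq[p - 1] = base if gene.strand == "+" else _complement(base)

    used: set[int] = set()

    def reserve(*positions: int) -> None:
        for p in positions:
            used.update((p - 1, p, p + 1))

    def take(pool: list, label: str):
        while pool:
            item = pool.pop(0)
            pts = item if isinstance(item, tuple) else (item,)
            if all(p not in used for p in pts):
                reserve(*pts)
                return item
        raise PlanError(f"category {label!r} unrealizable on these gene models")

    # ---- build slot pools -------------------------------------------------
    gene = plus_genes[0] if plus_genes else None
    donor_pool: list[int] = []
    acceptor_pool: list[int] = []
    region_pool: list[int] = []
    interior_pool: list[int] = []
    donor_region_pool: list[tuple[int, ...]] = []
    exon_start_pool: list[tuple[int, int, int]] = []
    codon_pool: list[tuple[int, int, int]] = []
    utr5_pool: list[int] = []
    gain_pool: list[tuple[int, int, int]] = []
    utr3_pool: list[int] = []
    upstream_pool: list[int] = []
    downstream_pool: list[int] = []

    if gene is not None:
        for istart, iend in gene.introns():
            donor_pool.extend([istart, istart + 1])
            acceptor_pool.extend([iend, iend - 1])
            ilen = iend - istart + 1
            for off in range(2, 8):
                if off < ilen - 2:
                    region_pool.append(istart + off)
            lo, hi = istart + 8, iend - 8
            interior_pool.extend(range(lo, hi + 1, 2))
            if ilen >= 12:
                donor_region_pool.append(
                    tuple(range(istart, istart + 4)))  # anchor d1 + d2,r3,r4
        cpos = [p for s, e in sorted(gene.cds) for p in range(s, e + 1)]
        n_codons = len(cpos) // 3
        for k in range(2, n_codons - 2):
            b = cpos[3 * k:3 * k + 3]
            if b[2] != b[0] + 2:
                continue
            labels = set()
            for p in b:
                labels |= _splice_labels(gene, [p], windows)
            slot = (b[0], b[1], b[2])
            # plain codon slots need contiguous neighbours (anchor/next base)
            flanked = (cpos[3 * k - 1] == b[0] - 1
                       and cpos[3 * k + 3] == b[2] + 1)
            if not labels and k % 2 == 0 and flanked:
                codon_pool.append(slot)
            elif labels == {"splice_region"}:
                exon_start_pool.append(slot)
        cds_lo = min(s for s, _ in gene.cds)
        utr5_positions = [p for s, e in gene.utr5() for p in range(s, e + 1)
                          if p < cds_lo - 4]
        for j in range(2, len(utr5_positions) - 3, 5):
            p = utr5_positions[j]
            gain_pool.append((p, p + 1, p + 2))
        utr5_pool = utr5_positions[0::3]
        utr3_pool = [p for s, e in gene.utr3()
                     for p in range(s + 2, e - 1, 3)]
    for g in gene_models:
        if g.strand == "+":
            upstream_pool.extend(range(g.start - windows.upstream + 2,
                                       g.start - 2, 2))
            downstream_pool.extend(range(g.end + 3, g.end + windows.downstream - 1, 2))
        else:
            upstream_pool.extend(range(g.end + 3, g.end + windows.upstream - 1, 2))
            downstream_pool.extend(range(g.start - windows.downstream + 2,
                                         g.start - 2, 2))
    flank_hulls = [
        (g.start - (windows.upstream if g.strand == "+" else windows.downstream),
         g.end + (windows.downstream if g.strand == "+" else windows.upstream))
        for g in gene_models]
    intergenic_pool = [p for p in range(3, length - 2, 2)
                       if all(p < lo or p > hi for lo, hi in flank_hulls)]

    # ---- overrides and variant construction -------------------------------
    overrides: dict[int, str] = {}
    variants: list[tuple[str, VariantCall]] = []
    rng = np.random.default_rng(seed)  # reserved; placement is deterministic
    vid = 0

    def add(category: str, pos: int, ref_len: int, alt_builder) -> None:
        nonlocal vid
        vid += 1
        ref = "".join(overrides.get(p, seq[p - 1])
                      for p in range(pos, pos + ref_len))
        alt = alt_builder(ref)
        variants.append((category,
                         VariantCall(chromosome=chrom, position=pos, ref=ref,
                                     alt=alt, variant_id=f"v{vid:05d}")))

    def snp(category: str, pos: int, alt: Optional[str] = None,
            utr5: bool = False) -> None:
        add(category, pos, 1,
            lambda ref: alt if alt else _alt_for(ref, in_utr5=utr5))

    for category in VARIANT_CATEGORIES:
        for _ in range(plan.get(category, 0)):
            if category == "intergenic":
                snp(category, take(intergenic_pool, category))
            elif category == "upstream_gene":
                snp(category, take(upstream_pool, category))
            elif category == "downstream_gene":
                snp(category, take(downstream_pool, category))
            elif category == "intron":
                snp(category, take(interior_pool, category))
            elif category == "splice_donor&intron":
                snp(category, take(donor_pool, category))
            elif category == "splice_acceptor&intron":
                snp(category, take(acceptor_pool, category))
            elif category == "splice_region&intron":
                snp(category, take(region_pool, category))
            elif category == "splice_donor&splice_region&intron":
                pts = take(donor_region_pool, category)
                add(category, pts[0], 4, lambda ref: ref[0])
            elif category == "5_prime_UTR":
                snp(category, take(utr5_pool, category), utr5=True)
            elif category == "5_prime_UTR_premature_start_gain":
                pts = take(gain_pool, category)
                for p, b in zip(pts, "AAG"):
                    overrides[p] = b
                snp(category, pts[1], alt="T")
            elif category == "3_prime_UTR":
                snp(category, take(utr3_pool, category), utr5=True)
            elif category == "synonymous":
                b = take(codon_pool, category)
                for p, base in zip(b, "CTT"):
                    overrides[p] = base
                snp(category, b[2], alt="C")
            elif category in ("missense", "missense&splice_region"):
                pool = codon_pool if category == "missense" else exon_start_pool
                b = take(pool, category)
                for p, base in zip(b, "GCT"):
                    overrides[p] = base
                if category == "missense":
                    snp(category, b[1], alt="T")  # GCT(Ala) -> GTT(Val)
                else:
                    snp(category, b[0], alt="C")  # GCT(Ala) -> CCT(Pro)
            elif category in ("frameshift", "frameshift&splice_region"):
                pool = codon_pool if category == "frameshift" else exon_start_pool
                b = take(pool, category)
                add(category, b[0], 2, lambda ref: ref[0])  # delete base 2
            elif category == "conservative_inframe_deletion":
                b = take(codon_pool, category)
                reserve(b[0] - 1)
                add(category, b[0] - 1, 4, lambda ref: ref[0])
            elif category == "disruptive_inframe_deletion":
                b = take(codon_pool, category)
                nxt = b[2] + 1
                reserve(nxt)
                add(category, b[0], 4, lambda ref: ref[0])  # deletes b2,b3,next
            elif category == "conservative_inframe_insertion":
                b = take(codon_pool, category)
                add(category, b[2], 1, lambda ref: ref + "GGT")
            elif category in ("disruptive_inframe_insertion",
                              "disruptive_inframe_insertion&splice_region"):
                pool = (codon_pool if category == "disruptive_inframe_insertion"
                        else exon_start_pool)
                b = take(pool, category)
                add(category, b[0], 1, lambda ref: ref + "GGT")
            else:  # pragma: no cover
                raise PlanError(f"unhandled category {category!r}")

    for p, base in overrides.items():
        seq[p - 1] = base
    reference = {chrom: "".join(seq)}
    # re-materialize REF alleles from the final sequence
    final: list[VariantCall] = []
    truth = SyntheticTruth()
    for category, v in variants:
        ref = reference[chrom][v.position - 1:v.position - 1 + len(v.ref)]
        alt = v.alt if len(v.alt) <= len(v.ref) else ref + v.alt[len(v.ref):]
        if len(v.ref) > len(v.alt):  # deletion: keep anchored alt
            alt = ref[0]
        elif len(v.ref) == len(v.alt) and len(v.ref) == 1:
            alt = v.alt
        vc = VariantCall(chromosome=chrom, position=v.position, ref=ref,
                         alt=alt, variant_id=v.variant_id)
        final.append(vc)
        truth.variant_effects[v.variant_id] = category
    final.sort(key=lambda v: v.position)
    if verify:
        anns = annotate_variants(final, list(gene_models), reference, windows)
        got: dict[str, int] = {}
        for a in anns:
            got[a.category] = got.get(a.category, 0) + 1
        if got != {k: v for k, v in plan.items()}:
            diffs = {k: (plan.get(k, 0), got.get(k, 0))
                     for k in set(plan) | set(got)
                     if plan.get(k, 0) != got.get(k, 0)}
            raise RuntimeError(f"planted plan not reproduced: {diffs}")
    return final, reference, truth


# --------------------------------------------------------------------------
# differential-expression tables with planted pass counts
# --------------------------------------------------------------------------

def gen_deg_table(n_pass_group1: int = 9, n_pass_group2: int = 6,
                  n_fail_per_group: int = 30, seed: int = 0) -> pd.DataFrame:
    """Fold-change/p-value table with an exact number of records passing the
    |log2FC| > 1, p <= 0.05 filter in each comparison group."""
    rng = np.random.default_rng(seed)
    rows = []
    gi = 0
    for group, n_pass in (("Group1", n_pass_group1), ("Group2", n_pass_group2)):
        for j in range(n_pass):
            gi += 1
            sign = -1.0 if j % 2 else 1.0
            fc = sign * (1.2 + 2.0 * rng.random())
            rows.append((f"DG{gi:04d}", group, round(fc, 3),
                         round(0.001 + 0.04 * rng.random(), 4)))
        for j in range(n_fail_per_group):
            gi += 1
            if j % 2:  # strong but not significant
                fc, p = 1.5 + rng.random(), 0.06 + 0.5 * rng.random()
            else:  # significant but weak
                fc, p = 0.9 * rng.random(), 0.04 * rng.random()
            rows.append((f"DG{gi:04d}", group, round(fc, 3), round(p, 4)))
    return pd.DataFrame(rows, columns=["gene", "group", "log2fc", "pvalue"])


# --------------------------------------------------------------------------
# stage-mean profiles with planted target correlations
# --------------------------------------------------------------------------

def gen_correlated_means(n_genes: int = 36,
                         plan: Mapping[str, int] = None,
                         targets: tuple[str, str] = ("GBSSI", "SBEIIa"),
                         n_stages: int = 4, seed: int = 0
                         ) -> tuple[dict[str, list[float]], dict[str, set]]:
    """Per-gene stage means planting genes correlated with one or both targets.

    ``plan`` gives counts for 'both', 'first_only', 'second_only'; remaining
    genes are constructed orthogonal to both target profiles.  Planted
    members pass (p <= 0.05 and r^2 >= 0.60) for exactly their planned
    targets under the n-stage two-sided t-test.
    """
    plan = dict(plan or {"both": 5, "first_only": 2, "second_only": 3})
    n_planted = sum(plan.values())
    if n_planted > n_genes:
        raise PlanError("planted counts exceed n_genes")
    if n_stages < 4:
        raise PlanError("need >= 4 stages for a 3-dimensional centered space")
    rng = np.random.default_rng(seed)

    base = np.linspace(10.0, 1.0, n_stages)
    u = base - base.mean()
    u /= np.linalg.norm(u)
    # orthonormal helpers in the centered subspace
    w1 = np.ones(n_stages)
    w1[: n_stages // 2] = -1.0
    w1 -= w1.mean()
    w1 -= (w1 @ u) * u
    w1 /= np.linalg.norm(w1)
    w2 = np.zeros(n_stages)
    w2[0], w2[-1] = 1.0, 1.0
    w2 -= w2.mean()
    w2 -= (w2 @ u) * u
    w2 -= (w2 @ w1) * w1
    w2 /= np.linalg.norm(w2)

    cos_phi = 0.88  # target-target |r|: tight enough for shared candidates
    v = cos_phi * u + math.sqrt(1 - cos_phi ** 2) * w1  # direction of -SBEIIa
    bis = u + v
    bis /= np.linalg.norm(bis)

    def profile(direction: np.ndarray, scale: float, shift: float) -> list[float]:
        return list(direction * scale + shift)

    means: dict[str, list[float]] = {
        targets[0]: profile(u, 4.0, 12.0),
        targets[1]: profile(-v, 4.0, 12.0),
    }
    truth: dict[str, set] = {"both": set(), "first_only": set(),
                             "second_only": set()}
    gi = 0

    def next_gene() -> str:
        nonlocal gi
        gi += 1
        return f"RQ{gi:03d}"

    for j in range(plan.get("both", 0)):
        g = next_gene()
        sgn = 1.0 if j % 2 == 0 else -1.0
        means[g] = profile(sgn * bis, 2.0 + 0.3 * j, 10.0 + j)
        truth["both"].add(g)
    for j in range(plan.get("first_only", 0)):
        g = next_gene()
        sgn = 1.0 if j % 2 == 0 else -1.0
        means[g] = profile(sgn * u, 1.5 + 0.2 * j, 9.0 + j)
        truth["first_only"].add(g)
    for j in range(plan.get("second_only", 0)):
        g = next_gene()
        sgn = 1.0 if j % 2 == 0 else -1.0
        means[g] = profile(sgn * (-v), 1.5 + 0.2 * j, 9.0 + j)
        truth["second_only"].add(g)
    for j in range(n_genes - n_planted):
        g = next_gene()
        means[g] = profile(w2, 1.0 + 0.1 * j, 8.0 + 0.5 * j)
    return means, truth
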