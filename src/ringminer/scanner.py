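"""Variable-gap eight-ligand RING-domain scanner and subtype classifier.

Detection works on the union of the rule set's constraints: a candidate chain
is eight strictly increasing sequence positions whose residues lie in the
per-slot union of allowed metal ligands and whose seven gaps lie in the
per-slot union of gap ranges.  Chains that satisfy the gaps but miss or
substitute up to ``8 - incomplete_min_ligands`` ligand residues are emitted as
incomplete candidates (ML1 itself must always match, anchoring the chain).

Overlap resolution is greedy leftmost-start with a shortest-span tie-break;
complete chains are resolved first so a nearby degenerate chain can never
shadow a complete domain.  Because any two chains sharing a start position
overlap, and under leftmost-first greedy a chain is blocked iff its *start*
lies inside an accepted interval, keeping only the best chain per start
position is exactly equivalent to enumerating every chain — the scanner
exploits this.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from ringminer.rules import N_LIGANDS, RuleSet
from ringminer.util import SEQUENCE_ALPHABET, percent

INCOMPLETE = "INCOMPLETE"


@dataclass
class DomainHit:
    """One detected RING domain (1-based inclusive residue coordinates)."""

    protein_id: str
    start: int
    end: int
    ligand_positions: tuple[int, ...]  # 8 positions, 1-based
    ligand_residues: tuple[str, ...]  # 8 letters as found in the sequence
    subtype: Optional[str] = None  # rule name, INCOMPLETE, or None before classify
    flags: frozenset[str] = frozenset()
    missing_ligands: tuple[int, ...] = ()  # 1-based ML indices (incomplete hits)
    domain_name: Optional[str] = None

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def is_complete_candidate(self) -> bool:
        return not self.missing_ligands


class ScanError(ValueError):
    pass


def _best_chain_from(seq: str, start0: int, allowed, gaps, max_span: int,
                     max_missing: int):
    """Best chain anchored at 0-based ``start0``: minimal (n_missing, span).

    Depth-first search over gap choices with branch-and-bound on the final
    span.  Returns (missing_slots, positions) or None.
    """
    n = len(seq)
    min_rest = [0] * N_LIGANDS  # minimal residues needed after slot i
    for i in range(N_LIGANDS - 2, -1, -1):
        min_rest[i] = min_rest[i + 1] + gaps[i][0] + 1

    best: list = [None]  # (n_missing, span, positions, missing)

    def dfs(slot: int, pos: int, missing: tuple[int, ...]) -> None:
        if slot == N_LIGANDS:
            span = pos - start0 + 1
            cand = (len(missing), span, tuple(positions))
            if best[0] is None or cand < best[0][:3]:
                best[0] = (len(missing), span, tuple(positions), missing)
            return
        lo, hi = gaps[slot - 1]
        for gap in range(lo, hi + 1):
            nxt = pos + gap + 1
            if nxt >= n:
                break
            span_final_min = nxt - start0 + 1 + min_rest[slot]
            if span_final_min > max_span:
                break
            if best[0] is not None:
                # bound: cannot beat current best
                if (len(missing), span_final_min) > (best[0][0], best[0][1]):
                    continue
            res = seq[nxt]
            if res in allowed[slot]:
                positions.append(nxt)
                dfs(slot + 1, nxt, missing)
                positions.pop()
            elif len(missing) < max_missing and res != "X":
                positions.append(nxt)
                dfs(slot + 1, nxt, missing + (slot + 1,))
                positions.pop()

    positions = [start0]
    dfs(1, start0, ())
    if best[0] is None:
        return None
    _, _, pos_tuple, missing = best[0]
    return missing, pos_tuple


def resolve_overlaps(candidates: Sequence[DomainHit]) -> list[DomainHit]:
    """Greedy selection: complete chains first, leftmost start, shortest span."""
    accepted: list[DomainHit] = []

    def free(hit: DomainHit, taken: list[tuple[int, int]]) -> bool:
        return all(hit.end < s or hit.start > e for s, e in taken)

    for complete_pass in (True, False):
        pool = [h for h in candidates if h.is_complete_candidate == complete_pass]
        pool.sort(key=lambda h: (h.start, len(h.missing_ligands), h.span,
                                 h.ligand_positions))
        taken = [(h.start, h.end) for h in accepted]
        for hit in pool:
            if free(hit, taken):
                accepted.append(hit)
                taken.append((hit.start, hit.end))
    accepted.sort(key=lambda h: h.start)
    return accepted


def scan_domains(sequence: str, ruleset: RuleSet, protein_id: str = "") -> list[DomainHit]:
    """Detect candidate RING-domain ligand chains in one protein sequence.

    Returns unclassified hits (complete candidates plus incomplete candidates
    per ``ruleset.incomplete_min_ligands``), mutually non-overlapping,
    ordered by start.  Positions are 1-based.  ``X`` never matches a ligand.
    """
    seq = sequence.strip().upper()
    if not seq:
        return []
    bad = set(seq) - SEQUENCE_ALPHABET
    if bad:
        raise ScanError(f"non-amino-acid characters in sequence: {sorted(bad)}")

    allowed = ruleset.union_allowed()
    gaps = ruleset.union_gaps()
    max_missing = (0 if ruleset.incomplete_policy == "drop"
                   else N_LIGANDS - ruleset.incomplete_min_ligands)

    candidates: list[DomainHit] = []
    for start0, res in enumerate(seq):
        if res not in allowed[0]:  # ML1 anchors every chain
            continue
        found = _best_chain_from(seq, start0, allowed, gaps,
                                 ruleset.max_domain_span, max_missing)
        if found is None:
            continue
        missing, positions = found
        candidates.append(
            DomainHit(
                protein_id=protein_id,
                start=positions[0] + 1,
                end=positions[-1] + 1,
                ligand_positions=tuple(p + 1 for p in positions),
                ligand_residues=tuple(seq[p] for p in positions),
                missing_ligands=missing,
            )
        )
    return resolve_overlaps(candidates)


def _gaps_of(hit: DomainHit) -> list[int]:
    p = hit.ligand_positions
    return [p[i + 1] - p[i] - 1 for i in range(N_LIGANDS - 1)]


def classify_hit(hit: DomainHit, ruleset: RuleSet) -> DomainHit:
    """Assign the first matching subtype (priority order), RBX flag, or INCOMPLETE."""
    gaps = _gaps_of(hit)
    best_score = -1
    best_missing: tuple[int, ...] = tuple(range(1, N_LIGANDS + 1))
    for rule in ruleset.subtypes:
        gaps_ok = all(lo <= g <= hi for g, (lo, hi) in zip(gaps, rule.gap_ranges))
        mism = [i + 1 for i in range(N_LIGANDS)
                if hit.ligand_residues[i] not in rule.allowed_residues[i]]
        if gaps_ok and not mism:
            return replace(hit, subtype=rule.name)
        if gaps_ok and rule.rbx_substitution is not None:
            idx, res = rule.rbx_substitution
            if mism == [idx] and hit.ligand_residues[idx - 1] == res:
                return replace(hit, subtype=rule.name, flags=hit.flags | {"RBX"})
        score = (N_LIGANDS - len(mism)) + sum(
            lo <= g <= hi for g, (lo, hi) in zip(gaps, rule.gap_ranges))
        if score > best_score:
            best_score = score
            best_missing = tuple(mism)
    return replace(hit, subtype=INCOMPLETE, missing_ligands=best_missing)


def assign_domain_names(hits: Iterable[DomainHit]) -> list[DomainHit]:
    """Name domains: bare protein ID, or ID + 'a','b',... suffix in start order."""
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    out: list[DomainHit] = []
    for pid, group in by_protein.items():
        group = sorted(group, key=lambda h: h.start)
        if len(group) == 1:
            out.append(replace(group[0], domain_name=pid))
        else:
            for i, h in enumerate(group):
                out.append(replace(h, domain_name=f"{pid}{chr(ord('a') + i)}"))
    out.sort(key=lambda h: (h.protein_id, h.start))
    return out


@dataclass
class GroupSummary:
    """Per-subtype domain counts/percentages and domains-per-protein tallies."""

    subtype_counts: dict[str, int]
    subtype_percent: dict[str, float]
    total_classified: int
    incomplete_domains: int
    incomplete_proteins: int
    total_domains: int
    total_proteins: int
    proteins_by_domain_count: dict[int, int]
    warnings: list[str] = field(default_factory=list)


def summarize_counts(subtype_counts: dict[str, int],
                     incomplete_domains: int = 0,
                     incomplete_proteins: int = 0,
                     total_proteins: int = 0,
                     proteins_by_domain_count: Optional[dict[int, int]] = None,
                     ) -> GroupSummary:
    """Summary arithmetic from raw counts (percentages over classified domains,
    half-up to 2 decimals); incomplete domains sit outside the subtype groups."""
    total_classified = sum(subtype_counts.values())
    warnings: list[str] = []
    if total_classified == 0:
        warnings.append("no classified domains; percentages reported as 0")
        pct = {k: 0.0 for k in subtype_counts}
    else:
        pct = {k: percent(v, total_classified, 2) for k, v in subtype_counts.items()}
    return GroupSummary(
        subtype_counts=dict(subtype_counts),
        subtype_percent=pct,
        total_classified=total_classified,
        incomplete_domains=incomplete_domains,
        incomplete_proteins=incomplete_proteins,
        total_domains=total_classified + incomplete_domains,
        total_proteins=total_proteins,
        proteins_by_domain_count=dict(proteins_by_domain_count or {}),
        warnings=warnings,
    )


def summarize_groups(hits: Sequence[DomainHit], total_proteins: int,
                     ruleset: Optional[RuleSet] = None) -> GroupSummary:
    """Tally classified hits into the per-subtype group summary."""
    order = ruleset.names() if ruleset is not None else sorted(
        {h.subtype for h in hits if h.subtype and h.subtype != INCOMPLETE})
    counts = {name: 0 for name in order}
    incomplete = 0
    per_protein: dict[str, int] = {}
    incomplete_prot: set[str] = set()
    for h in hits:
        if h.subtype is None:
            raise ValueError("summarize_groups requires classified hits")
        if h.subtype == INCOMPLETE:
            incomplete += 1
            incomplete_prot.add(h.protein_id)
            continue
        counts[h.subtype] = counts.get(h.subtype, 0) + 1
        per_protein[h.protein_id] = per_protein.get(h.protein_id, 0) + 1
    by_n: dict[int, int] = {}
    for n in per_protein.values():
        by_n[n] = by_n.get(n, 0) + 1
    return summarize_counts(counts, incomplete, len(incomplete_prot),
                            total_proteins, by_n)


def scan_proteome(records: Iterable[tuple[str, str]], ruleset: RuleSet
                  ) -> list[DomainHit]:
    """Scan, classify and name domains for (protein_id, sequence) records."""
    hits: list[DomainHit] = []
    for pid, seq in records:
        for h in scan_domains(seq, ruleset, protein_id=pid):
            hits.append(classify_hit(h, ruleset))
    if ruleset.incomplete_policy == "drop":
        hits = [h for h in hits if h.subtype != INCOMPLETE]
    return assign_domain_names(hits)
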