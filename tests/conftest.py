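"""Shared fixtures and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from ringminer.rules import N_LIGANDS, RuleSet, default_ruleset
from ringminer.scanner import DomainHit, resolve_overlaps


@pytest.fixture(scope="session")
def ruleset() -> RuleSet:
    return default_ruleset()


def brute_force_complete_chains(seq: str, ruleset: RuleSet) -> list[tuple[int, ...]]:
    """Exhaustive enumeration of every valid complete 8-ligand chain.

    Independent of the scanner's search: plain forward recursion over all
    positions, filtering by the union residue sets and gap ranges, keeping
    every chain with span <= max_domain_span.
    """
    allowed = ruleset.union_allowed()
    gaps = ruleset.union_gaps()
    max_span = ruleset.max_domain_span
    chains: list[tuple[int, ...]] = []

    def rec(slot: int, positions: list[int]) -> None:
        if slot == N_LIGANDS:
            chains.append(tuple(positions))
            return
        lo, hi = gaps[slot - 1]
        p = positions[-1]
        for q in range(p + lo + 1, min(p + hi + 2, len(seq))):
            if q - positions[0] + 1 > max_span:
                break
            if seq[q] in allowed[slot]:
                rec(slot + 1, positions + [q])

    for s0, res in enumerate(seq):
        if res in allowed[0]:
            rec(1, [s0])
    return chains


def brute_force_scan(seq: str, ruleset: RuleSet) -> list[tuple[int, ...]]:
    """Oracle scanner: all complete chains + the shared overlap resolution."""
    hits = [
        DomainHit(protein_id="", start=c[0] + 1, end=c[-1] + 1,
                  ligand_positions=tuple(p + 1 for p in c),
                  ligand_residues=tuple(seq[p] for p in c))
        for c in brute_force_complete_chains(seq, ruleset)
    ]
    return [h.ligand_positions for h in resolve_overlaps(hits)]


def random_protein(rng: np.random.Generator, length: int) -> str:
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    return "".join(rng.choice(letters, size=length))
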