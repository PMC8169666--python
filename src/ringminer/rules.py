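"""RING-domain subtype rule sets.

A rule set declares, for each subtype, the residues allowed at the eight
zinc-coordinating metal-ligand positions (ML1..ML8) and the inclusive ranges of
residue counts between consecutive ligands.  Subtype order is a priority order:
classification assigns the first matching rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from ringminer.util import AA20

N_LIGANDS = 8


class RuleSetError(ValueError):
    """Raised for malformed or inconsistent rule-set configuration."""


@dataclass(frozen=True)
class SubtypeRule:
    """One RING subtype: allowed metal-ligand residues and inter-ligand gaps.

    ``rbx_substitution`` optionally names a single tolerated ligand swap
    (1-based ligand index, residue); a hit matching the rule everywhere except
    that one position is assigned the subtype with an RBX flag (e.g. Asp
    instead of Cys at ML8).
    """

    name: str
    allowed_residues: tuple[frozenset[str], ...]  # 8 sets
    gap_ranges: tuple[tuple[int, int], ...]  # 7 inclusive (lo, hi)
    rbx_substitution: Optional[tuple[int, str]] = None

    def min_span(self) -> int:
        return N_LIGANDS + sum(lo for lo, _ in self.gap_ranges)

    def max_span(self) -> int:
        return N_LIGANDS + sum(hi for _, hi in self.gap_ranges)


@dataclass(frozen=True)
class RuleSet:
    """Ordered collection of subtype rules plus scanner-level policies."""

    subtypes: tuple[SubtypeRule, ...]
    max_domain_span: int = 102
    incomplete_policy: str = "flag"  # flag | drop
    incomplete_min_ligands: int = 6

    def __post_init__(self) -> None:
        names = [s.name for s in self.subtypes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise RuleSetError(f"duplicate subtype names: {dupes}")
        if not 0 <= self.incomplete_min_ligands <= N_LIGANDS:
            raise RuleSetError("incomplete_min_ligands must be in [0, 8]")
        if self.incomplete_policy not in ("flag", "drop"):
            raise RuleSetError("incomplete_policy must be 'flag' or 'drop'")

    def names(self) -> list[str]:
        return [s.name for s in self.subtypes]

    def get(self, name: str) -> SubtypeRule:
        for s in self.subtypes:
            if s.name == name:
                return s
        raise KeyError(f"unknown subtype {name!r}")

    # Union constraints drive candidate-chain enumeration in the scanner.
    def union_allowed(self) -> tuple[frozenset[str], ...]:
        sets: list[set[str]] = [set() for _ in range(N_LIGANDS)]
        for rule in self.subtypes:
            for i, allowed in enumerate(rule.allowed_residues):
                sets[i] |= allowed
            if rule.rbx_substitution is not None:
                idx, res = rule.rbx_substitution
                sets[idx - 1].add(res)
        return tuple(frozenset(s) for s in sets)

    def union_gaps(self) -> tuple[tuple[int, int], ...]:
        gaps = []
        for i in range(N_LIGANDS - 1):
            gaps.append(
                (
                    min(r.gap_ranges[i][0] for r in self.subtypes),
                    max(r.gap_ranges[i][1] for r in self.subtypes),
                )
            )
        return tuple(gaps)


def _parse_residues(raw: object, where: str, errors: list[str]) -> frozenset[str]:
    if isinstance(raw, str):
        letters = set(raw)
    elif isinstance(raw, Iterable):
        letters = set()
        for item in raw:  # type: ignore[union-attr]
            letters |= set(str(item))
    else:  # pragma: no cover - yaml rarely produces this
        errors.append(f"{where}: unreadable residue spec {raw!r}")
        return frozenset()
    bad = letters - AA20
    if bad:
        errors.append(f"{where}: unknown residue letters {sorted(bad)}")
    if not letters:
        errors.append(f"{where}: empty residue set")
    return frozenset(letters)


def _parse_subtype(entry: Mapping, errors: list[str]) -> Optional[SubtypeRule]:
    name = str(entry.get("name", "")).strip()
    where = f"subtype {name or '<unnamed>'}"
    if not name:
        errors.append("subtype with missing name")
    ligands = entry.get("ligands")
    gaps = entry.get("gaps")
    if not isinstance(ligands, Sequence) or len(ligands) != N_LIGANDS:
        errors.append(f"{where}: expected exactly {N_LIGANDS} ligand slots")
        return None
    if not isinstance(gaps, Sequence) or len(gaps) != N_LIGANDS - 1:
        errors.append(f"{where}: expected exactly {N_LIGANDS - 1} gap ranges")
        return None
    allowed = tuple(
        _parse_residues(lig, f"{where} ML{i + 1}", errors)
        for i, lig in enumerate(ligands)
    )
    gap_ranges: list[tuple[int, int]] = []
    for i, g in enumerate(gaps):
        if isinstance(g, int):
            lo = hi = g
        else:
            try:
                lo, hi = int(g[0]), int(g[1])
            except (TypeError, ValueError, IndexError):
                errors.append(f"{where} gap {i + 1}: malformed range {g!r}")
                continue
        if lo < 0 or hi < 0:
            errors.append(f"{where} gap {i + 1}: negative bound {g!r}")
        if lo > hi:
            errors.append(f"{where} gap {i + 1}: min {lo} > max {hi}")
        gap_ranges.append((lo, hi))
    if len(gap_ranges) != N_LIGANDS - 1:
        return None
    rbx = entry.get("rbx_substitution")
    rbx_parsed: Optional[tuple[int, str]] = None
    if rbx is not None:
        try:
            idx = int(rbx["ligand"])
            res = str(rbx["residue"]).strip()
        except (KeyError, TypeError, ValueError):
            errors.append(f"{where}: malformed rbx_substitution {rbx!r}")
        else:
            if not 1 <= idx <= N_LIGANDS:
                errors.append(f"{where}: rbx ligand index {idx} out of range")
            elif res not in AA20:
                errors.append(f"{where}: rbx residue {res!r} not an amino acid")
            else:
                rbx_parsed = (idx, res)
    return SubtypeRule(name=name, allowed_residues=allowed, gap_ranges=tuple(gap_ranges),
                       rbx_substitution=rbx_parsed)


def parse_ruleset(config) -> RuleSet:
    """Build a validated :class:`RuleSet` from YAML text, a path, or a mapping.

    Raises :class:`RuleSetError` listing every offending entry at once.
    """
    if isinstance(config, (str, Path)):
        p = Path(config)
        if isinstance(config, Path) or (len(str(config)) < 260 and p.is_file()):
            doc = yaml.safe_load(p.read_text())
        else:
            doc = yaml.safe_load(str(config))
    else:
        doc = config
    if not isinstance(doc, Mapping):
        raise RuleSetError("rule-set document must be a mapping")
    entries = doc.get("subtypes")
    if not isinstance(entries, Sequence) or not entries:
        raise RuleSetError("rule-set must define a non-empty 'subtypes' list")
    errors: list[str] = []
    rules = []
    for entry in entries:
        rule = _parse_subtype(entry, errors)
        if rule is not None:
            rules.append(rule)
    if errors:
        raise RuleSetError("invalid rule set: " + "; ".join(errors))
    return RuleSet(
        subtypes=tuple(rules),
        max_domain_span=int(doc.get("max_domain_span", 102)),
        incomplete_policy=str(doc.get("incomplete_policy", "flag")),
        incomplete_min_ligands=int(doc.get("incomplete_min_ligands", 6)),
    )


def default_ruleset() -> RuleSet:
    """The shipped 4-subtype rule set (RING-H2, RING-HC, RING-v, RING-G)."""
    text = resources.files("ringminer.data").joinpath("default_rules.yaml").read_text()
    return parse_ruleset(yaml.safe_load(text))
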