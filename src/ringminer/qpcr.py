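"""Relative quantification (Livak ddCt) and candidate-gene screening from
qRT-PCR cycle-threshold tables.

The Ct table is long-format: one row per (gene, genotype, stage, biological
replicate, technical replicate).  Technical replicates are averaged within
each biological replicate first; the log2 fold change for a target gene in a
mutant genotype versus the control genotype is

    log2FC = -[(Ct_target,mut - Ct_ref,mut) - (Ct_target,ctl - Ct_ref,ctl)]

with each Ct the mean over biological replicates of per-bio-replicate means.
The dispersion reported is the SD of the per-bio-replicate delta-Ct
(target - reference), combined across genotypes in quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("gene", "genotype", "stage", "biorep", "ct")


@dataclass
class CtTable:
    """Wrapper holding the long-format Ct frame and the reference-gene id."""

    data: pd.DataFrame
    reference_gene: str

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"Ct table missing columns: {missing}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        if self.reference_gene not in set(self.data["gene"]):
            raise ValueError(f"reference gene {self.reference_gene!r} absent")

    def genes(self) -> list[str]:
        return sorted(set(self.data["gene"]) - {self.reference_gene})

    def stages(self) -> list:
        return sorted(set(self.data["stage"]))


def _biorep_means(table: CtTable, gene: str, genotype: str, stage) -> pd.Series:
    """Per-biological-replicate Ct (technical replicates averaged)."""
    df = table.data
    sub = df[(df["gene"] == gene) & (df["genotype"] == genotype)
             & (df["stage"] == stage)]
    if sub.empty:
        raise ValueError(
            f"missing Ct cell: gene={gene!r} genotype={genotype!r} stage={stage!r}")
    return sub.groupby("biorep")["ct"].mean()


def ddct(table: CtTable, gene: str, mutant: str, control: str, stage
         ) -> tuple[float, float]:
    """log2 fold change of ``gene`` in ``mutant`` vs ``control`` at ``stage``.

    Returns (log2fc, sd).  Raises a ValueError naming the first missing cell.
    """
    cells = {}
    for genotype in (mutant, control):
        for g in (gene, table.reference_gene):
            cells[(g, genotype)] = _biorep_means(table, g, genotype, stage)
    dct = {}
    sd = {}
    for genotype in (mutant, control):
        tgt = cells[(gene, genotype)]
        ref = cells[(table.reference_gene, genotype)]
        joined = pd.concat([tgt.rename("t"), ref.rename("r")], axis=1).dropna()
        deltas = joined["t"] - joined["r"]
        dct[genotype] = float(deltas.mean())
        sd[genotype] = float(deltas.std(ddof=1)) if len(deltas) > 1 else 0.0
    log2fc = -(dct[mutant] - dct[control])
    return log2fc, math.hypot(sd[mutant], sd[control])


def fc_profile(table: CtTable, gene: str, mutant: str, control: str,
               stages: Optional[Sequence] = None) -> dict:
    """Per-stage log2 fold changes (and SDs) for one gene and one comparison."""
    stages = list(stages) if stages is not None else table.stages()
    values, sds = [], []
    for stage in stages:
        fc, sd = ddct(table, gene, mutant, control, stage)
        values.append(fc)
        sds.append(sd)
    return {"gene": gene, "mutant": mutant, "control": control,
            "stages": stages, "log2fc": values, "sd": sds}


def profile_classify(log2fc: Sequence[float], magnitude_min: float = 2.0,
                     min_strong_stages: int = 2) -> str:
    """Classify a complete per-stage fold-change profile.

    * ``down_candidate`` / ``up_candidate``: same strict sign at every stage
      AND |log2FC| >= ``magnitude_min`` at >= ``min_strong_stages`` stages.
    * ``consistent_only``: same strict sign everywhere but too weak.
    * ``mixed``: any sign change or zero.
    """
    v = list(log2fc)
    if not v:
        raise ValueError("empty profile")
    if all(x > 0 for x in v):
        sign = "up"
    elif all(x < 0 for x in v):
        sign = "down"
    else:
        return "mixed"
    strong = sum(abs(x) >= magnitude_min for x in v)
    if strong >= min_strong_stages:
        return f"{sign}_candidate"
    return "consistent_only"


def count_candidates(profiles: Mapping[str, Sequence[float]],
                     magnitude_min: float = 2.0,
                     min_strong_stages: int = 2) -> dict:
    """Tally up/down candidates over per-gene fold-change profiles."""
    down, up = [], []
    status = {}
    for gene in sorted(profiles):
        s = profile_classify(profiles[gene], magnitude_min, min_strong_stages)
        status[gene] = s
        if s == "down_candidate":
            down.append(gene)
        elif s == "up_candidate":
            up.append(gene)
    return {"n_down": len(down), "n_up": len(up),
            "down_ids": down, "up_ids": up, "status": status}
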