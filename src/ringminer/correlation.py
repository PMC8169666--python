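"""Pearson correlation screening of family genes against starch-pathway targets.

Correlations are computed on per-gene stage means (typically n = 4 seed
developmental stages); significance is a two-sided t-test with n - 2 degrees of
freedom; strength bins are on r-squared (very strong >= 0.80, strong >= 0.60).
With n = 4 the test has only 2 degrees of freedom, so a warning is attached
whenever n < 5.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats


@dataclass
class CorrelationResult:
    gene: str
    target: str
    r: Optional[float]
    r_squared: Optional[float]
    p: Optional[float]
    strength: str
    sign: str
    n: int


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Pearson r, r^2 and two-sided p from t = r*sqrt((n-2)/(1-r^2)), df = n-2.

    Raises on n < 3; zero variance in either vector yields (nan, nan, nan)
    with a warning.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    n = xa.size
    if n < 3 or ya.size != n:
        raise ValueError("need equal-length vectors with n >= 3")
    if n < 5:
        warnings.warn(f"n = {n}: correlation test has only {n - 2} degrees of freedom")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        warnings.warn("zero variance: correlation undefined (NA)")
        return float("nan"), float("nan"), float("nan")
    r = float(np.corrcoef(xa, ya)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 1.0, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return r, r * r, min(p, 1.0)


def strength_bin(r_squared: float) -> str:
    """very_strong (r2 >= 0.80), strong (0.60 <= r2 < 0.80), else moderate_or_weak."""
    if math.isnan(r_squared):
        return "undefined"
    if r_squared >= 0.80:
        return "very_strong"
    if r_squared >= 0.60:
        return "strong"
    return "moderate_or_weak"


def correlate_targets(means: Mapping[str, Sequence[float]],
                      targets: Sequence[str],
                      use_abs_r: bool = False) -> list[CorrelationResult]:
    """Correlate every non-target gene against each target profile.

    ``use_abs_r=False`` (default) bins strength on r-squared; ``True`` bins on
    |r| instead, for the alternative reading of printed thresholds.
    """
    results = []
    for target in targets:
        if target not in means:
            raise ValueError(f"target profile {target!r} missing")
        ty = means[target]
        for gene in sorted(means):
            if gene in targets:
                continue
            r, r2, p = pearson_with_p(means[gene], ty)
            stat = abs(r) if use_abs_r else r2
            results.append(CorrelationResult(
                gene=gene, target=target, r=r, r_squared=r2, p=p,
                strength=strength_bin(stat if not math.isnan(r) else float("nan")),
                sign="negative" if r < 0 else "positive",
                n=len(means[gene]),
            ))
    return results


def select_correlated_candidates(results: Sequence[CorrelationResult],
                                 p_max: float = 0.05,
                                 min_r2: float = 0.60) -> dict:
    """Per-target significant sets, their overlap, and the candidate union.

    A gene enters a target's set when p <= p_max and r^2 >= min_r2 (either
    sign).  The summary reports |A|, |B|, |A∩B| and |A∪B| per target pair.
    """
    per_target: dict[str, set[str]] = {}
    for res in results:
        per_target.setdefault(res.target, set())
        if res.p is not None and not math.isnan(res.r_squared) \
                and res.p <= p_max and res.r_squared >= min_r2:
            per_target[res.target].add(res.gene)
    targets = sorted(per_target)
    union: set[str] = set()
    for s in per_target.values():
        union |= s
    out = {
        "per_target": {t: sorted(per_target[t]) for t in targets},
        "per_target_counts": {t: len(per_target[t]) for t in targets},
        "candidates": sorted(union),
        "n_candidates": len(union),
    }
    if len(targets) == 2:
        a, b = (per_target[t] for t in targets)
        out["overlap"] = sorted(a & b)
        out["n_overlap"] = len(a & b)
    return out
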