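"""Expressed-gene calls, 3-stage Venn partition, hierarchical clustering and
differential-expression filtering.

Clustering uses the uncentered Pearson correlation distance
``d = 1 - sum(x*y) / sqrt(sum(x^2) * sum(y^2))`` (range [0, 2]) with complete
linkage and a deterministic tie-break (lexicographically smallest member
label), matching the classic expression-heatmap workflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class VennPartition:
    """Disjoint 7-region partition of genes expressed at three stages.

    Region order: all three; stage1&2 only; stage2&3 only; stage1&3 only;
    stage1 only; stage2 only; stage3 only.
    """

    all3: int
    s1s2_only: int
    s2s3_only: int
    s1s3_only: int
    s1_only: int
    s2_only: int
    s3_only: int

    @property
    def total_expressed(self) -> int:
        return (self.all3 + self.s1s2_only + self.s2s3_only + self.s1s3_only
                + self.s1_only + self.s2_only + self.s3_only)

    def as_tuple(self) -> tuple[int, ...]:
        return (self.all3, self.s1s2_only, self.s2s3_only, self.s1s3_only,
                self.s1_only, self.s2_only, self.s3_only)


def call_expressed(matrix: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Boolean expressed calls: value strictly greater than ``threshold`` TPM."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return matrix > threshold


def venn_partition(calls: pd.DataFrame) -> VennPartition:
    """Partition genes by which of exactly three stages they are expressed at."""
    if calls.shape[1] != 3:
        raise ValueError(f"venn_partition requires exactly 3 stage columns, "
                         f"got {calls.shape[1]}")
    b = calls.to_numpy(dtype=bool)
    s1, s2, s3 = b[:, 0], b[:, 1], b[:, 2]
    return VennPartition(
        all3=int((s1 & s2 & s3).sum()),
        s1s2_only=int((s1 & s2 & ~s3).sum()),
        s2s3_only=int((~s1 & s2 & s3).sum()),
        s1s3_only=int((s1 & ~s2 & s3).sum()),
        s1_only=int((s1 & ~s2 & ~s3).sum()),
        s2_only=int((~s1 & s2 & ~s3).sum()),
        s3_only=int((~s1 & ~s2 & s3).sum()),
    )


def uncentered_pearson_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """d = 1 - sum(xy)/sqrt(sum(x^2) sum(y^2)), in [0, 2]; zero-norm input
    yields distance 1 with a warning."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1 or xa.size < 2:
        raise ValueError("profiles must be equal-length 1-d vectors of length >= 2")
    nx = float(np.sqrt((xa * xa).sum()))
    ny = float(np.sqrt((ya * ya).sum()))
    if nx == 0.0 or ny == 0.0:
        warnings.warn("zero-norm profile: uncentered distance defined as 1")
        return 1.0
    d = 1.0 - float((xa * ya).sum()) / (nx * ny)
    return min(max(d, 0.0), 2.0)


def _distance_matrix(matrix: pd.DataFrame) -> np.ndarray:
    x = matrix.to_numpy(dtype=float)
    norms = np.sqrt((x * x).sum(axis=1))
    zero = norms == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-norm profile(s): distances set to 1")
    safe = np.where(zero, 1.0, norms)
    sim = (x @ x.T) / np.outer(safe, safe)
    d = 1.0 - sim
    d[zero, :] = 1.0
    d[:, zero] = 1.0
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


@dataclass
class Dendrogram:
    """Agglomerative merge trace.

    ``merges[t] = (left, right, height)`` where ``left``/``right`` are cluster
    indices: 0..n-1 are leaves (row order of ``labels``), n+t is the cluster
    created by merge t.  Compatible with a scipy linkage matrix via ``to_linkage``.
    """

    labels: list[str]
    merges: list[tuple[int, int, float]]

    def to_linkage(self) -> np.ndarray:
        n = len(self.labels)
        sizes = {i: 1 for i in range(n)}
        z = np.zeros((len(self.merges), 4))
        for t, (a, b, h) in enumerate(self.merges):
            size = sizes[a] + sizes[b]
            sizes[n + t] = size
            z[t] = [a, b, h, size]
        return z


def hcluster_complete(matrix: pd.DataFrame,
                      distance=uncentered_pearson_distance) -> Dendrogram:
    """Agglomerative complete-linkage clustering of gene rows.

    At each step the pair of clusters with minimal complete-linkage (maximum
    pairwise) distance is merged; ties break on the lexicographically smallest
    member label of the candidate pairs, making the trace permutation-invariant.
    """
    labels = [str(i) for i in matrix.index]
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 gene profiles to cluster")
    if distance is uncentered_pearson_distance:
        dm = _distance_matrix(matrix)
    else:
        dm = np.zeros((n, n))
        rows = matrix.to_numpy(dtype=float)
        for i in range(n):
            for j in range(i + 1, n):
                dm[i, j] = dm[j, i] = distance(rows[i], rows[j])
    d = dm.copy()
    np.fill_diagonal(d, np.inf)
    ids = list(range(n))  # cluster id per matrix row
    minlab = [labels[i] for i in range(n)]  # smallest member label per row
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(ids) > 1:
        dmin = d.min()
        cand = np.argwhere(d == dmin)
        # ties: lexicographically smallest (sorted label pair)
        best_rc = min(
            ((r, c) for r, c in cand if r < c),
            key=lambda rc: tuple(sorted((minlab[rc[0]], minlab[rc[1]]))),
        )
        r, c = best_rc
        merges.append((ids[r], ids[c], float(dmin)))
        # complete linkage: merged row = elementwise max
        merged = np.maximum(d[r], d[c])
        d[r, :] = merged
        d[:, r] = merged
        d[r, r] = np.inf
        d = np.delete(np.delete(d, c, axis=0), c, axis=1)
        ids[r] = next_id
        minlab[r] = min(minlab[r], minlab[c])
        next_id += 1
        del ids[c], minlab[c]
    return Dendrogram(labels=labels, merges=merges)


def cut_clusters(dendrogram: Dendrogram, k: Optional[int] = None,
                 height: Optional[float] = None) -> dict[str, int]:
    """Cut into k groups (or at a merge height), returning label -> group id.

    Group ids are 1-based, numbered by first appearance in row order.
    """
    n = len(dendrogram.labels)
    if k is None and height is None:
        raise ValueError("provide k or height")
    if k is not None:
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}]")
        n_merges = n - k
    else:
        n_merges = sum(1 for (_, _, h) in dendrogram.merges if h <= height)
    parent = list(range(n + len(dendrogram.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(n_merges):
        a, b, _ = dendrogram.merges[t]
        new = n + t
        parent[find(a)] = new
        parent[find(b)] = new
    roots: dict[int, int] = {}
    out: dict[str, int] = {}
    for i, label in enumerate(dendrogram.labels):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots) + 1
        out[label] = roots[r]
    return out


def heatmap_groups(matrix: pd.DataFrame, k: int = 4,
                   subsplit: tuple[int, ...] = (3, 4)) -> pd.Series:
    """Four major expression groups with sub-splits of groups III and IV.

    Cuts the complete-linkage dendrogram at ``k``; groups are numbered I..IV by
    increasing expression-weighted mean stage index of the group centroid
    (early-peaking first); groups listed in ``subsplit`` are re-cut at k=2 into
    A/B subgroups ordered the same way.
    """
    dend = hcluster_complete(matrix)
    assign = cut_clusters(dend, k=k)
    ser = pd.Series(assign).reindex([str(i) for i in matrix.index])

    def mean_stage(ids: pd.Index) -> float:
        sub = matrix.loc[[i for i in matrix.index if str(i) in set(ids)]]
        prof = sub.to_numpy(dtype=float).mean(axis=0)
        w = prof.sum()
        stages = np.arange(len(prof), dtype=float)
        return float((prof * stages).sum() / w) if w > 0 else float(len(prof))

    order = sorted(ser.unique(), key=lambda g: (mean_stage(ser[ser == g].index), g))
    roman = {i + 1: r for i, r in enumerate(["I", "II", "III", "IV", "V", "VI"])}
    relabel = {g: roman[i + 1] for i, g in enumerate(order)}
    labels = ser.map(relabel)
    for gnum in subsplit:
        gname = roman[gnum]
        members = [i for i in matrix.index if labels[str(i)] == gname]
        if len(members) < 2:
            continue
        sub = matrix.loc[members]
        sub_assign = cut_clusters(hcluster_complete(sub), k=min(2, len(members)))
        sub_ser = pd.Series(sub_assign)
        sub_order = sorted(sub_ser.unique(),
                           key=lambda g: (mean_stage(sub_ser[sub_ser == g].index), g))
        ab = {g: s for g, s in zip(sub_order, "AB")}
        for m in members:
            labels[str(m)] = f"{gname}{ab[sub_assign[str(m)]]}"
    return labels


def deg_filter(records: pd.DataFrame, min_abs_log2fc: float = 1.0,
               max_p: float = 0.05) -> pd.DataFrame:
    """Keep records with |log2fc| strictly > ``min_abs_log2fc`` and
    p-value <= ``max_p`` (inclusive)."""
    for col in ("log2fc", "pvalue"):
        if col not in records.columns:
            raise ValueError(f"DEG table missing column {col!r}")
    keep = (records["log2fc"].abs() > min_abs_log2fc) & (records["pvalue"] <= max_p)
    return records.loc[keep].copy()
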