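"""Expressed calls, Venn partition, uncentered-Pearson clustering, DEG filter."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ringminer.expression import (Dendrogram, call_expressed, cut_clusters,
                                  deg_filter, hcluster_complete,
                                  heatmap_groups, uncentered_pearson_distance,
                                  venn_partition)
from ringminer.synthetic import gen_expression


def test_expressed_call_is_strictly_greater():
    m = pd.DataFrame({"s1": [0.0, 0.5, 0.6], "s2": [0.0, 0.0, 0.0],
                      "s3": [2.0, 0.49, 0.51]}, index=["a", "b", "c"])
    calls = call_expressed(m, threshold=0.5)
    assert not calls.loc["b", "s1"]  # exactly at threshold -> not expressed
    assert calls.loc["c", "s1"]
    assert not call_expressed(m * 0.0).any().any()


def test_venn_partition_against_set_algebra_oracle():
    rng = np.random.default_rng(12)
    b = pd.DataFrame(rng.random((500, 3)) < 0.4, columns=list("ABC"))
    vp = venn_partition(b)
    sets = [set(np.flatnonzero(b[c].to_numpy())) for c in "ABC"]
    s1, s2, s3 = sets
    assert vp.all3 == len(s1 & s2 & s3)
    assert vp.s1s2_only == len((s1 & s2) - s3)
    assert vp.s2s3_only == len((s2 & s3) - s1)
    assert vp.s1s3_only == len((s1 & s3) - s2)
    assert vp.s1_only == len(s1 - s2 - s3)
    assert vp.s2_only == len(s2 - s1 - s3)
    assert vp.s3_only == len(s3 - s1 - s2)
    assert vp.total_expressed == len(s1 | s2 | s3)


def test_venn_requires_exactly_three_stages():
    with pytest.raises(ValueError, match="3 stage"):
        venn_partition(pd.DataFrame(np.ones((2, 4), dtype=bool)))


def test_generated_matrix_realizes_spec_exactly():
    spec = (306, 22, 3, 156, 152, 5, 54)
    df = gen_expression(spec, n_silent=557, threshold=0.5, seed=9)
    assert len(df) == 1255
    vp = venn_partition(call_expressed(df, 0.5))
    assert vp.as_tuple() == spec
    assert vp.total_expressed == 698


def test_single_gene_everywhere_and_empty_spec():
    df1 = gen_expression((1, 0, 0, 0, 0, 0, 0), 0, seed=1)
    assert venn_partition(call_expressed(df1, 0.5)).as_tuple() == (
        1, 0, 0, 0, 0, 0, 0)
    df0 = gen_expression((0,) * 7, 10, seed=1)
    assert venn_partition(call_expressed(df0, 0.5)).total_expressed == 0


@pytest.mark.parametrize("x, y, expected", [
    ((1.0, 2.0, 3.0), (1.0, 2.0, 3.0), 0.0),
    ((1.0, 2.0, 3.0), (-1.0, -2.0, -3.0), 2.0),
    ((1.0, 2.0, 3.0), (3.0, 2.0, 1.0), 1.0 - 10.0 / 14.0),
])
def test_uncentered_distance_values(x, y, expected):
    assert uncentered_pearson_distance(x, y) == pytest.approx(expected, abs=1e-12)


def test_uncentered_distance_zero_norm_warns():
    with pytest.warns(UserWarning, match="zero-norm"):
        assert uncentered_pearson_distance((0.0, 0.0), (1.0, 2.0)) == 1.0


def test_uncentered_distance_properties():
    rng = np.random.default_rng(3)
    for _ in range(100):
        x, y = rng.normal(size=(2, 5))
        d = uncentered_pearson_distance(x, y)
        assert 0.0 <= d <= 2.0
        assert d == pytest.approx(uncentered_pearson_distance(y, x))
        assert uncentered_pearson_distance(x, x) == pytest.approx(0.0, abs=1e-12)


def _hand_trace_n3(matrix):
    """Manual complete-linkage trace for three profiles."""
    labels = list(matrix.index)
    d = {}
    for i, j in itertools.combinations(range(3), 2):
        d[(i, j)] = uncentered_pearson_distance(matrix.iloc[i], matrix.iloc[j])
    (i, j), first = min(d.items(), key=lambda kv: kv[1])
    k = ({0, 1, 2} - {i, j}).pop()
    second = max(d[tuple(sorted((i, k)))], d[tuple(sorted((j, k)))])
    return [(i, j, first), (k, second)]


def test_merge_trace_equals_hand_oracle_on_three_profiles():
    m = pd.DataFrame([[1.0, 2.0, 3.0], [1.1, 2.0, 2.9], [3.0, 1.0, 0.5]],
                     index=["g1", "g2", "g3"])
    dend = hcluster_complete(m)
    (i, j, first), (k, second) = _hand_trace_n3(m)
    assert sorted(dend.merges[0][:2]) == sorted((i, j))
    assert dend.merges[0][2] == pytest.approx(first)
    assert dend.merges[1][2] == pytest.approx(second)
    assert sorted(dend.merges[1][:2]) == [k, 3]


def test_identical_profiles_merge_at_height_zero():
    m = pd.DataFrame([[1.0, 2.0], [2.0, 4.0], [5.0, 1.0]],
                     index=["a", "b", "c"])  # b = 2a: distance 0
    dend = hcluster_complete(m)
    assert dend.merges[0][2] == pytest.approx(0.0, abs=1e-12)
    assert sorted(dend.merges[0][:2]) == [0, 1]


def test_clustering_agrees_with_scipy_complete_linkage():
    from scipy.cluster import hierarchy
    rng = np.random.default_rng(8)
    m = pd.DataFrame(rng.random((12, 4)) + 0.1,
                     index=[f"g{i:02d}" for i in range(12)])
    dend = hcluster_complete(m)
    x = m.to_numpy()
    sim = (x @ x.T) / np.sqrt(np.outer((x * x).sum(1), (x * x).sum(1)))
    dmat = 1.0 - sim
    np.fill_diagonal(dmat, 0.0)
    from scipy.spatial.distance import squareform
    z = hierarchy.linkage(squareform(dmat, checks=False), method="complete")
    np.testing.assert_allclose(dend.to_linkage()[:, 2], z[:, 2], atol=1e-10)


def test_planted_archetypes_recovered_at_k4():
    rng = np.random.default_rng(21)
    archetypes = np.array([[10.0, 1.0, 1.0], [1.0, 1.0, 10.0],
                           [8.0, 1.0, 8.0], [1.0, 10.0, 1.0]])
    rows, truth = [], []
    for a, base in enumerate(archetypes):
        for _ in range(10):
            rows.append(base + rng.normal(0, 0.3, size=3))
            truth.append(a)
    m = pd.DataFrame(rows, index=[f"g{i:02d}" for i in range(40)])
    groups = cut_clusters(hcluster_complete(m), k=4)
    assign = [groups[f"g{i:02d}"] for i in range(40)]
    mapping = {}
    for got, want in zip(assign, truth):
        mapping.setdefault(want, got)
        assert mapping[want] == got  # each archetype lands in one cluster
    assert len(set(mapping.values())) == 4


def test_clustering_permutation_invariance():
    rng = np.random.default_rng(4)
    m = pd.DataFrame(rng.random((10, 3)) + 0.1,
                     index=[f"g{i}" for i in range(10)])
    shuffled = m.sample(frac=1.0, random_state=1)
    a = cut_clusters(hcluster_complete(m), k=3)
    b = cut_clusters(hcluster_complete(shuffled), k=3)
    # same partition of labels, group ids may differ
    part_a = {}
    part_b = {}
    for g, c in a.items():
        part_a.setdefault(c, set()).add(g)
    for g, c in b.items():
        part_b.setdefault(c, set()).add(g)
    assert sorted(map(sorted, part_a.values())) == sorted(
        map(sorted, part_b.values()))


def test_cut_validation_and_heatmap_subgroups():
    m = pd.DataFrame(np.eye(4) + 0.2, index=list("abcd"))
    dend = hcluster_complete(m)
    with pytest.raises(ValueError):
        cut_clusters(dend, k=9)
    rng = np.random.default_rng(2)
    big = pd.DataFrame(rng.random((30, 3)) + 0.1,
                       index=[f"g{i:02d}" for i in range(30)])
    labels = heatmap_groups(big)
    assert set(labels) <= {"I", "II", "IIIA", "IIIB", "IVA", "IVB"}
    assert len(labels) == 30


def test_deg_filter_boundaries_and_counts():
    df = pd.DataFrame({
        "gene": [f"g{i}" for i in range(6)],
        "group": ["Group1"] * 3 + ["Group2"] * 3,
        "log2fc": [2.81, 0.9, 1.0, -1.5, 1.01, -3.4],
        "pvalue": [0.01, 0.001, 0.04, 0.05, 0.051, 0.2],
    })
    kept = deg_filter(df)
    # |fc| strictly > 1; p <= 0.05 inclusive
    assert list(kept["gene"]) == ["g0", "g3"]


def test_deg_filter_monotone_in_both_thresholds():
    rng = np.random.default_rng(17)
    df = pd.DataFrame({"gene": range(200),
                       "log2fc": rng.normal(0, 2, 200),
                       "pvalue": rng.random(200)})
    base = set(deg_filter(df, 1.0, 0.05)["gene"])
    assert base <= set(deg_filter(df, 0.5, 0.05)["gene"])
    assert base <= set(deg_filter(df, 1.0, 0.10)["gene"])


def test_planted_deg_table_yields_counts():
    from ringminer.synthetic import gen_deg_table
    df = gen_deg_table(n_pass_group1=9, n_pass_group2=6, seed=5)
    kept = deg_filter(df)
    assert len(kept) == 15
    assert kept["group"].value_counts().to_dict() == {"Group1": 9, "Group2": 6}
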