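"""Gene mapping, spacing statistics, collinearity chaining, duplication classes."""

import itertools

import pytest

from ringminer.genome import (DupParams, GeneLocus, chain_collinear_blocks,
                              chrom_distribution, class_counts,
                              classify_duplications, load_gene_loci,
                              mean_adjacent_distance)
from ringminer.synthetic import PlanError, gen_gene_map

GFF = """##gff-version 3
Chr1\t.\tgene\t100\t500\t.\t+\t.\tID=g2
Chr1\t.\tgene\t50\t80\t.\t-\t.\tID=g1
Chr1\t.\tgene\t200\t900\t.\t+\t.\tID=g3
ChrUn\t.\tgene\t10\t60\t.\t+\t.\tID=gU
"""


def _loci(spec):
    """spec: list of (gene_id, chrom, start) -> ranked loci."""
    out = []
    by_chrom = {}
    for gid, chrom, start in spec:
        by_chrom.setdefault(chrom, []).append((start, gid))
    for chrom, genes in by_chrom.items():
        for rank, (start, gid) in enumerate(sorted(genes), 1):
            out.append(GeneLocus(gid, chrom, start, start + 10, "+", rank))
    return out


def test_load_gene_loci_ranks_and_scaffold_exclusion():
    loci = {g.gene_id: g for g in load_gene_loci(GFF)}
    assert (loci["g1"].rank, loci["g2"].rank, loci["g3"].rank) == (1, 2, 3)
    assert loci["gU"].excluded and loci["gU"].rank == 0
    assert load_gene_loci("##gff-version 3\n") == []


def test_chrom_distribution_percentages():
    spec = [(f"a{i}", "Chr1", i * 100) for i in range(43)]
    spec += [(f"b{i}", "Chr2", i * 100) for i in range(1238 - 43)]
    dist = chrom_distribution(_loci(spec))
    assert dist["Chr1"]["count"] == 43
    assert dist["Chr1"]["percent"] == 3.5  # 100*43/1238 = 3.47 -> 3.5
    only = chrom_distribution(_loci([("x", "Chr3", 5)]))
    assert only["Chr3"]["percent"] == 100.0


def test_mean_adjacent_distance_in_mb():
    loci = _loci([("a", "Chr1", 1_000_000), ("b", "Chr1", 8_600_000),
                  ("c", "Chr2", 1), ("d", "Chr3", 10_000_000),
                  ("e", "Chr3", 20_000_000), ("f", "Chr3", 30_000_000)])
    out = mean_adjacent_distance(loci)
    assert out["Chr1"] == 7.6
    assert out["Chr2"] is None  # single gene: NA
    assert out["Chr3"] == 10.0


def test_mean_distance_matches_direct_recomputation():
    import numpy as np
    rng = np.random.default_rng(3)
    starts = sorted(int(s) for s in rng.integers(1, 10**8, size=20))
    loci = _loci([(f"g{i}", "Chr5", s) for i, s in enumerate(starts)])
    expected = round(np.mean(np.diff(sorted(starts))) / 1e6, 1)
    assert mean_adjacent_distance(loci)["Chr5"] == expected


def _pairs_to_blocks_oracle(pairs, loci, params):
    """Exhaustive optimal chaining for tiny instances (<= 20 pairs)."""
    rank = {g.gene_id: g.rank for g in loci}
    chrom = {g.gene_id: g.chromosome for g in loci}

    def valid_chain(chain):
        for (a1, b1), (a2, b2) in zip(chain, chain[1:]):
            if chrom[a1] != chrom[a2] or chrom[b1] != chrom[b2]:
                return False
            da, db = rank[a2] - rank[a1], rank[b2] - rank[b1]
            if da <= 0 or abs(da) > params.max_anchor_rank_gap:
                return False
            if abs(db) > params.max_anchor_rank_gap:
                return False
        dirs = {1 if rank[b2] > rank[b1] else -1
                for (_, b1), (_, b2) in zip(chain, chain[1:])}
        return len(dirs) <= 1 and all(
            rank[b2] != rank[b1] for (_, b1), (_, b2) in zip(chain, chain[1:]))

    # a valid chain is strictly increasing in rank on side A, so enumerating
    # ordered subsets of the rank_a-sorted pair list is exhaustive
    remaining = sorted(pairs, key=lambda p: rank[p[0]])
    blocks = []
    while True:
        best = ()
        for n in range(len(remaining), params.min_anchors - 1, -1):
            for combo in itertools.combinations(remaining, n):
                if valid_chain(list(combo)):
                    best = combo
                    break
            if best:
                break
        if not best:
            return blocks
        blocks.append(set(best))
        remaining = [p for p in remaining if p not in set(best)]


def test_collinear_chaining_examples():
    params = DupParams(min_anchors=5)
    spec = [(f"a{i}", "ChrA", i * 100) for i in range(8)]
    spec += [(f"b{i}", "ChrB", i * 100) for i in range(8)]
    loci = _loci(spec)
    pairs5 = [(f"a{i}", f"b{i}") for i in range(5)]
    blocks = chain_collinear_blocks(pairs5, loci, params)
    assert len(blocks) == 1 and len(blocks[0].anchors) == 5
    assert chain_collinear_blocks(pairs5[:4], loci, params) == []


def test_interleaved_blocks_recovered_like_oracle():
    params = DupParams(min_anchors=5, max_anchor_rank_gap=25)
    spec = [(f"a{i}", "ChrA", i * 100) for i in range(11)]
    spec += [(f"b{i}", "ChrB", i * 100) for i in range(11)]
    spec += [(f"c{i}", "ChrC", i * 100) for i in range(6)]
    loci = _loci(spec)
    # 6-anchor block A->B increasing, 5-anchor block A->C decreasing, interleaved
    six = [(f"a{i}", f"b{i}") for i in (0, 2, 4, 6, 8, 10)]
    five = [(f"a{i}", f"c{5 - j}") for j, i in enumerate((1, 3, 5, 7, 9))]
    pairs = [p for pair in itertools.zip_longest(six, five) for p in pair if p]
    blocks = chain_collinear_blocks(pairs, loci, params)
    got = sorted([sorted(b.anchors) for b in blocks])
    oracle = _pairs_to_blocks_oracle(pairs, loci, params)
    assert got == sorted(sorted(b) for b in oracle)
    assert {len(b.anchors) for b in blocks} == {5, 6}


def test_classification_priority_ladder():
    params = DupParams()
    # fillers f1/f2 give the proximal pair a rank gap of 3 (counted over
    # all genes on the chromosome, not only family members)
    spec = [("w1", "ChrA", 100), ("w2", "ChrB", 100),
            ("t1", "ChrA", 200), ("t2", "ChrA", 300),
            ("p1", "ChrA", 400), ("f1", "ChrA", 500), ("f2", "ChrA", 600),
            ("p2", "ChrA", 700),
            ("d1", "ChrA", 900), ("d2", "ChrC", 100),
            ("s1", "ChrC", 900)]
    loci = _loci(spec)
    pairs = [("w1", "w2"), ("t1", "t2"), ("p1", "p2"), ("d1", "d2")]
    from ringminer.genome import CollinearBlock
    blocks = [CollinearBlock("blk1", (("w1", "w2"),))]
    calls = {c.gene_id: c.dup_class
             for c in classify_duplications(loci, pairs, blocks, params)}
    assert calls["w1"] == calls["w2"] == "WGD_segmental"
    assert calls["t1"] == calls["t2"] == "tandem"
    assert calls["p1"] == calls["p2"] == "proximal"
    assert calls["d1"] == calls["d2"] == "dispersed"
    assert calls["s1"] == "singleton"


def test_unknown_pair_gene_raises():
    loci = _loci([("a", "Chr1", 1)])
    with pytest.raises(ValueError, match="unknown gene"):
        classify_duplications(loci, [("a", "ghost")], [], DupParams())


def test_planted_class_plan_recovered_exactly():
    params = DupParams()
    plan = {"singleton": 4, "dispersed": 9, "proximal": 5, "tandem": 10,
            "WGD": 20}
    gff3, pairs, truth = gen_gene_map(48, 7, plan, params, seed=2)
    loci = load_gene_loci(gff3)
    blocks = chain_collinear_blocks(pairs, loci, params)
    calls = classify_duplications(loci, pairs, blocks, params,
                                  gene_ids=sorted(truth.dup_classes))
    assert all(truth.dup_classes[c.gene_id] == c.dup_class for c in calls)
    counts = class_counts(calls)
    assert counts == {"singleton": 4, "dispersed": 9, "proximal": 5,
                      "tandem": 10, "WGD_segmental": 20}


def test_raising_min_anchors_only_demotes_wgd():
    # one 10-anchor block; raising min_anchors can only move genes out of
    # WGD/segmental, never into it
    plan = {"WGD": 20, "singleton": 2}
    gff3, pairs, truth = gen_gene_map(22, 4, plan, DupParams(min_anchors=10),
                                      seed=4)
    loci = load_gene_loci(gff3)
    prev_wgd = 21
    for anchors in (5, 8, 10, 11):
        params = DupParams(min_anchors=anchors)
        blocks = chain_collinear_blocks(pairs, loci, params)
        calls = class_counts(classify_duplications(
            loci, pairs, blocks, params, gene_ids=sorted(truth.dup_classes)))
        assert calls["WGD_segmental"] <= prev_wgd
        prev_wgd = calls["WGD_segmental"]
        if anchors <= 10:
            assert calls["WGD_segmental"] == 20
        else:  # blocks dissolve; anchors fall through to dispersed
            assert calls["WGD_segmental"] == 0
            assert calls["dispersed"] == 20


@pytest.mark.parametrize("n, plan, message", [
    (1, {"tandem": 1}, "single gene"),
    (7, {"WGD": 7}, "even"),
    (4, {"WGD": 4}, "min_anchors"),
    (3, {"singleton": 2}, "sum"),
])
def test_infeasible_plans_raise(n, plan, message):
    with pytest.raises(PlanError, match=message):
        gen_gene_map(n, 4, plan, DupParams(), seed=0)


def test_dup_params_validation():
    with pytest.raises(ValueError):
        DupParams(tandem_max_rank_gap=10, proximal_max_rank_gap=10)
    with pytest.raises(ValueError):
        DupParams(min_anchors=1)
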