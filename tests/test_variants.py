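"""Variant-effect categories, impact tiers and distribution summaries."""

import numpy as np
import pytest
from Bio.Seq import Seq

from ringminer.synthetic import PlanError, gen_variants, toy_gene_models
from ringminer.variants import (GeneModel, VariantCall, Windows,
                                annotate_variant, annotate_variants,
                                distribution_summary, read_vcf_lite)

W = Windows(upstream=50, downstream=50)


def _plus_gene(seq_len=400):
    """Two-exon plus-strand gene with UTRs for hand-checked annotation.

    layout (1-based): 101..130 exon1 (101..112 5'UTR, 113..130 CDS),
    131..170 intron, 171..230 exon2 (171..212 CDS, 213..230 3'UTR).
    """
    gene = GeneModel("G1", "chr", 101, 230, "+",
                     exons=((101, 130), (171, 230)),
                     cds=((113, 130), (171, 212)))
    seq = ["C"] * seq_len
    # CDS: ATG + GGT... + TGA over the 60 coding bases
    coding = "ATG" + "GGT" * 18 + "TGA"
    cpos = list(range(113, 131)) + list(range(171, 213))
    for p, b in zip(cpos, coding):
        seq[p - 1] = b
    seq[130], seq[131] = "G", "T"  # donor
    seq[168], seq[169] = "A", "G"  # acceptor
    return gene, {"chr": "".join(seq)}


def _minus_mirror(gene, ref):
    """Reverse-complement the chromosome and mirror all features."""
    n = len(ref["chr"])
    flip = lambda s, e: (n - e + 1, n - s + 1)
    mirrored = GeneModel(gene.gene_id, gene.chromosome, *flip(gene.start, gene.end),
                         "-" if gene.strand == "+" else "+",
                         exons=tuple(sorted(flip(s, e) for s, e in gene.exons)),
                         cds=tuple(sorted(flip(s, e) for s, e in gene.cds)))
    return mirrored, {"chr": str(Seq(ref["chr"]).reverse_complement())}


def _mirror_variant(v, n):
    if v.vtype in ("SNP", "MNP"):
        pos = n - (v.position + len(v.ref) - 1) + 1
        rc = lambda s: str(Seq(s).reverse_complement())
        return VariantCall("chr", pos, rc(v.ref), rc(v.alt), v.variant_id)
    raise NotImplementedError


def test_region_categories_on_hand_built_gene():
    gene, ref = _plus_gene()
    snp = lambda pos, alt: VariantCall("chr", pos, ref["chr"][pos - 1], alt)
    cases = {
        20: "intergenic",          # beyond the 50 bp windows
        80: "upstream_gene",
        260: "downstream_gene",
        105: "5_prime_UTR",
        220: "3_prime_UTR",
        150: "intron",
        131: "splice_donor&intron",
        170: "splice_acceptor&intron",
        135: "splice_region&intron",   # intron base 5
        165: "splice_region&intron",   # intron base 35 = 6 from acceptor
    }
    for pos, want in cases.items():
        alt = "A" if ref["chr"][pos - 1] != "A" else "T"
        ann = annotate_variant(snp(pos, alt), [gene], ref, W)
        assert ann.category == want, (pos, ann.category)


def test_coding_effects_and_impacts():
    gene, ref = _plus_gene()
    # codon 2 spans 116..118 = GGT (Gly)
    syn = annotate_variant(VariantCall("chr", 118, "T", "A"), [gene], ref, W)
    assert syn.category == "synonymous" and syn.impact == "LOW"  # GGA = Gly
    mis = annotate_variant(VariantCall("chr", 117, "G", "A"), [gene], ref, W)
    assert mis.category == "missense" and mis.impact == "MODERATE"  # GAT = Asp
    # 1-bp deletion in CDS: frameshift, HIGH
    fs = annotate_variant(VariantCall("chr", 116, "GG", "G"), [gene], ref, W)
    assert fs.category == "frameshift" and fs.impact == "HIGH"
    # 3-bp insertion at a codon boundary: conservative inframe, MODERATE
    ins = annotate_variant(VariantCall("chr", 118, "T", "TGGT"), [gene], ref, W)
    assert ins.category == "conservative_inframe_insertion"
    assert ins.impact == "MODERATE"
    # 3-bp insertion mid-codon: disruptive
    ins2 = annotate_variant(VariantCall("chr", 116, "G", "GAAA"), [gene], ref, W)
    assert ins2.category == "disruptive_inframe_insertion"
    # whole-codon deletion anchored on previous base: conservative
    dele = annotate_variant(VariantCall("chr", 118, "TGGT", "T"), [gene], ref, W)
    assert dele.category == "conservative_inframe_deletion"
    # stop gain: codon 19 ends at 212; make codon 2 GGT -> TGA-like change
    stop = annotate_variant(VariantCall("chr", 116, "GGT", "TGA"), [gene], ref, W)
    assert stop.category == "stop_gained" and stop.impact == "HIGH"
    # start lost
    start = annotate_variant(VariantCall("chr", 113, "A", "C"), [gene], ref, W)
    assert start.category == "start_lost" and start.impact == "HIGH"


def test_exon_edge_compounds():
    gene, ref = _plus_gene()
    # exon2 first codon starts at 171 (GGT); its bases sit in the splice band
    mis = annotate_variant(VariantCall("chr", 172, "G", "A"), [gene], ref, W)
    assert mis.category == "missense&splice_region"
    fs = annotate_variant(VariantCall("chr", 171, "GG", "G"), [gene], ref, W)
    assert fs.category == "frameshift&splice_region"
    # deletion spanning donor base 2 and region bases 3-4
    combo = annotate_variant(
        VariantCall("chr", 131,
                    ref["chr"][130:134], ref["chr"][130]), [gene], ref, W)
    assert combo.category == "splice_donor&splice_region&intron"
    assert combo.impact == "HIGH"


def test_premature_start_gain_in_utr5():
    gene, ref = _plus_gene()
    seq = list(ref["chr"])
    seq[104:107] = "AAG"  # 5'UTR positions 105..107
    ref2 = {"chr": "".join(seq)}
    ann = annotate_variant(VariantCall("chr", 106, "A", "T"), [gene], ref2, W)
    assert ann.category == "5_prime_UTR_premature_start_gain"
    assert ann.impact == "MODERATE"
    # same position, non-ATG-creating change stays plain 5'UTR
    ann2 = annotate_variant(VariantCall("chr", 106, "A", "G"), [gene], ref2, W)
    assert ann2.category == "5_prime_UTR"


def test_strand_symmetry_of_categories():
    gene, ref = _plus_gene()
    mgene, mref = _minus_mirror(gene, ref)
    n = len(ref["chr"])
    for pos in (80, 105, 117, 118, 131, 135, 150, 170, 220, 260, 20):
        alt = "A" if ref["chr"][pos - 1] != "A" else "T"
        v = VariantCall("chr", pos, ref["chr"][pos - 1], alt)
        fwd = annotate_variant(v, [gene], ref, W)
        rev = annotate_variant(_mirror_variant(v, n), [mgene], mref, W)
        assert fwd.category == rev.category, pos
        assert fwd.impact == rev.impact


def test_codon_calls_match_translation_diff_oracle():
    """SNP/MNP missense/synonymous and indel frameshift calls vs full
    translate-and-compare on CDS <= 300 bp."""
    gene, ref = _plus_gene()
    rng = np.random.default_rng(13)
    cds_positions = [p for s, e in gene.cds for p in range(s, e + 1)]
    interior = cds_positions[3:-3]  # skip start/stop codons
    ref_cds = gene.cds_sequence(ref["chr"])
    ref_prot = str(Seq(ref_cds).translate())
    for _ in range(200):
        p = int(rng.choice(interior))
        base = ref["chr"][p - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != base]))
        ann = annotate_variant(VariantCall("chr", p, base, alt), [gene], ref, W)
        # oracle: substitute in the spliced CDS, translate, diff
        off = gene.cds_offset(p)
        alt_cds = ref_cds[:off] + alt + ref_cds[off + 1:]
        alt_prot = str(Seq(alt_cds).translate())
        want = "synonymous" if alt_prot == ref_prot else "missense"
        assert ann.primary == want, (p, base, alt)
    # indels: frame disruption iff length change not divisible by 3
    for dlen in (1, 2, 3, 4, 6):
        pos = 116  # mid-CDS, far from junctions
        refslice = ref["chr"][pos - 1:pos + dlen]
        ann = annotate_variant(VariantCall("chr", pos, refslice, refslice[0]),
                               [gene], ref, W)
        if dlen % 3:
            assert ann.primary == "frameshift"
        else:
            assert ann.primary.endswith("inframe_deletion")


def test_ref_mismatch_and_bounds_errors():
    gene, ref = _plus_gene()
    with pytest.raises(ValueError, match="ref allele mismatch"):
        annotate_variant(VariantCall("chr", 150, "T", "A"), [gene], ref, W)
    with pytest.raises(ValueError, match="outside reference"):
        annotate_variant(VariantCall("chr", 9999, "C", "A"), [gene], ref, W)
    with pytest.raises(ValueError, match="identical"):
        VariantCall("chr", 1, "A", "A")
    with pytest.raises(ValueError, match="multiple of 3"):
        GeneModel("bad", "chr", 1, 10, "+", exons=((1, 10),), cds=((1, 5),))


def test_distribution_summary_and_planted_plan():
    plan = {"intergenic": 4, "missense": 2, "synonymous": 1, "intron": 3,
            "frameshift": 1, "upstream_gene": 2}
    models, clen = toy_gene_models(plan)
    variants, ref, truth = gen_variants(models, plan, seed=6,
                                        chrom_length=clen)
    anns = annotate_variants(variants, models, ref)
    summary = distribution_summary(anns, ndigits=2)
    assert summary["total"] == 13
    got = {c: v["count"] for c, v in summary["categories"].items()}
    assert got == plan
    assert sum(summary["impacts"].values()) == 13
    single = distribution_summary([anns[0]])
    assert list(single["categories"].values())[0]["percent"] == 100.0
    assert distribution_summary([])["total"] == 0


def test_unrealizable_category_names_itself():
    # a single-exon model cannot host intron variants
    models, clen = toy_gene_models({"missense": 1})
    with pytest.raises(PlanError, match="intron"):
        gen_variants(models, {"intron": 2}, chrom_length=clen)


def test_vcf_lite_roundtrip(tmp_path):
    from ringminer.io import write_vcf_lite
    plan = {"missense": 1, "frameshift": 1, "intergenic": 1}
    models, clen = toy_gene_models(plan)
    variants, ref, _ = gen_variants(models, plan, chrom_length=clen)
    path = tmp_path / "v.vcf"
    write_vcf_lite(variants, path)
    back = read_vcf_lite(path)
    assert [(v.position, v.ref, v.alt) for v in back] == \
        [(v.position, v.ref, v.alt) for v in variants]
    types = {v.vtype for v in back}
    assert types == {"SNP", "deletion"}
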