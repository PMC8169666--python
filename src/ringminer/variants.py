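"""Variant-effect annotation on toy gene models.

Each variant receives one compound category (labels joined by '&', ordered by
precedence: coding > splice donor/acceptor > splice region > UTR > intron >
up/downstream > intergenic) and an impact tier (HIGH/MODERATE/LOW/MODIFIER)
determined by the primary (first) label through a configurable mapping.

Coordinates follow the VCF convention: 1-based positions, indels left-anchored
on a shared first base.  Coding effects are computed on the strand-corrected
spliced CDS by codon comparison: substitutions translate ref vs alt;
indels are frameshift when the CDS length change is not a multiple of three,
otherwise conservative (codon-boundary aligned) or disruptive inframe events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
from Bio.Seq import Seq

from ringminer.util import percent

NUCS = frozenset("ACGT")

PRECEDENCE = (
    "stop_gained",
    "stop_lost",
    "start_lost",
    "frameshift",
    "splice_acceptor",
    "splice_donor",
    "disruptive_inframe_insertion",
    "disruptive_inframe_deletion",
    "conservative_inframe_insertion",
    "conservative_inframe_deletion",
    "missense",
    "synonymous",
    "5_prime_UTR_premature_start_gain",
    "splice_region",
    "5_prime_UTR",
    "3_prime_UTR",
    "intron",
    "upstream_gene",
    "downstream_gene",
    "intergenic",
)
_RANK = {label: i for i, label in enumerate(PRECEDENCE)}

DEFAULT_IMPACT_MAP: dict[str, str] = {
    "stop_gained": "HIGH", "stop_lost": "HIGH", "start_lost": "HIGH",
    "frameshift": "HIGH", "splice_acceptor": "HIGH", "splice_donor": "HIGH",
    "missense": "MODERATE",
    "disruptive_inframe_insertion": "MODERATE",
    "disruptive_inframe_deletion": "MODERATE",
    "conservative_inframe_insertion": "MODERATE",
    "conservative_inframe_deletion": "MODERATE",
    "5_prime_UTR_premature_start_gain": "MODERATE",
    "synonymous": "LOW", "splice_region": "LOW",
    "5_prime_UTR": "MODIFIER", "3_prime_UTR": "MODIFIER",
    "intron": "MODIFIER", "upstream_gene": "MODIFIER",
    "downstream_gene": "MODIFIER", "intergenic": "MODIFIER",
}


@dataclass(frozen=True)
class Windows:
    """Context windows (bp) used by the annotator."""

    upstream: int = 5000
    downstream: int = 5000
    splice_site: int = 2  # donor/acceptor: first/last intron bases
    splice_region_intron: tuple[int, int] = (3, 8)  # intron bases from junction
    splice_region_exon: int = 3  # exon bases adjacent to a junction


@dataclass(frozen=True)
class VariantCall:
    chromosome: str
    position: int  # 1-based
    ref: str
    alt: str
    variant_id: str = ""

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        bad = (set(self.ref) | set(self.alt)) - NUCS
        if bad:
            raise ValueError(f"alleles must be over ACGT, got {sorted(bad)}")

    @property
    def vtype(self) -> str:
        if len(self.ref) == len(self.alt):
            return "SNP" if len(self.ref) == 1 else "MNP"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    def affected_span(self) -> tuple[int, int]:
        """Genomic positions whose reference identity changes (inclusive).

        Insertions affect the anchor/next-base boundary, reported as
        (pos, pos + 1)."""
        if self.vtype in ("SNP", "MNP"):
            return self.position, self.position + len(self.ref) - 1
        if self.vtype == "deletion":
            return self.position + 1, self.position + len(self.ref) - 1
        return self.position, self.position + 1


@dataclass(frozen=True)
class GeneModel:
    """Toy gene model: genomic exon and CDS segments (1-based inclusive)."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        for name, segs in (("exon", self.exons), ("CDS", self.cds)):
            for s, e in segs:
                if s > e:
                    raise ValueError(f"{self.gene_id}: inverted {name} segment")
        cds_len = sum(e - s + 1 for s, e in self.cds)
        if self.cds and cds_len % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: CDS length {cds_len} not a multiple of 3 "
                "(inconsistent phase)")

    def introns(self) -> list[tuple[int, int]]:
        exons = sorted(self.exons)
        return [(a_end + 1, b_start - 1)
                for (_, a_end), (b_start, _) in zip(exons, exons[1:])
                if b_start > a_end + 1]

    def in_any(self, pos: int, segs: Iterable[tuple[int, int]]) -> bool:
        return any(s <= pos <= e for s, e in segs)

    def cds_offset(self, pos: int) -> int:
        """0-based offset of a genomic CDS position in coding orientation."""
        segs = sorted(self.cds)
        if self.strand == "+":
            off = 0
            for s, e in segs:
                if pos > e:
                    off += e - s + 1
                elif pos >= s:
                    return off + pos - s
                else:
                    break
        else:
            off = 0
            for s, e in reversed(segs):
                if pos < s:
                    off += e - s + 1
                elif pos <= e:
                    return off + e - pos
                else:
                    break
        raise ValueError(f"position {pos} not in CDS of {self.gene_id}")

    def cds_sequence(self, chrom_seq: str) -> str:
        parts = [chrom_seq[s - 1:e] for s, e in sorted(self.cds)]
        seq = "".join(parts)
        return str(Seq(seq).reverse_complement()) if self.strand == "-" else seq

    def utr5(self) -> list[tuple[int, int]]:
        return self._utrs(five_prime=True)

    def utr3(self) -> list[tuple[int, int]]:
        return self._utrs(five_prime=False)

    def _utrs(self, five_prime: bool) -> list[tuple[int, int]]:
        if not self.cds:
            return []
        cds_lo = min(s for s, _ in self.cds)
        cds_hi = max(e for _, e in self.cds)
        left = (five_prime == (self.strand == "+"))
        out = []
        for s, e in sorted(self.exons):
            if left:  # exonic bases genomically before the CDS
                lo, hi = s, min(e, cds_lo - 1)
            else:
                lo, hi = max(s, cds_hi + 1), e
            if lo <= hi:
                out.append((lo, hi))
        return out


@dataclass
class EffectAnnotation:
    variant: VariantCall
    gene_id: Optional[str]
    category: str  # compound label, e.g. "missense&splice_region"
    impact: str
    detail: dict = field(default_factory=dict)

    @property
    def primary(self) -> str:
        return self.category.split("&", 1)[0]


def _splice_labels(gene: GeneModel, positions: Sequence[int], w: Windows
                   ) -> set[str]:
    labels: set[str] = set()
    k = w.splice_site
    r_lo, r_hi = w.splice_region_intron
    ex = w.splice_region_exon
    for istart, iend in gene.introns():
        ilen = iend - istart + 1
        left_site = set(range(istart, min(istart + k, iend + 1)))
        right_site = set(range(max(iend - k + 1, istart), iend + 1))
        donor, acceptor = ((left_site, right_site) if gene.strand == "+"
                           else (right_site, left_site))
        region = set()
        for off in range(r_lo - 1, r_hi):
            if off < ilen:
                region.add(istart + off)
                region.add(iend - off)
        region -= left_site | right_site
        exon_region = (set(range(istart - ex, istart))
                       | set(range(iend + 1, iend + 1 + ex)))
        for p in positions:
            if p in donor:
                labels.add("splice_donor")
            elif p in acceptor:
                labels.add("splice_acceptor")
            elif p in region or p in exon_region:
                labels.add("splice_region")
    return labels


def _coding_effect(variant: VariantCall, gene: GeneModel, chrom_seq: str
                   ) -> Optional[str]:
    span = variant.affected_span()
    affected = list(range(span[0], span[1] + 1))
    in_cds = [p for p in affected if gene.in_any(p, gene.cds)]
    if variant.vtype == "insertion":
        # coding only when the insertion boundary lies inside the CDS
        if len(in_cds) < 2:
            return None
        n_ins = len(variant.alt) - len(variant.ref)
        if n_ins % 3 != 0:
            return "frameshift"
        left, right = sorted(variant.affected_span())
        point = right if gene.strand == "+" else left
        aligned = gene.cds_offset(point) % 3 == 0
        return ("conservative_inframe_insertion" if aligned
                else "disruptive_inframe_insertion")
    if not in_cds:
        return None
    if variant.vtype == "deletion":
        if len(in_cds) % 3 != 0:
            return "frameshift"
        first = min(in_cds) if gene.strand == "+" else max(in_cds)
        aligned = gene.cds_offset(first) % 3 == 0
        return ("conservative_inframe_deletion" if aligned
                else "disruptive_inframe_deletion")
    # SNP / MNP: codon comparison on the spliced, strand-corrected CDS
    ref_cds = gene.cds_sequence(chrom_seq)
    alt_list = list(ref_cds)
    for p, base in zip(affected, variant.alt):
        if gene.in_any(p, gene.cds):
            off = gene.cds_offset(p)
            alt_list[off] = (base if gene.strand == "+"
                             else str(Seq(base).complement()))
    alt_cds = "".join(alt_list)
    ref_prot = str(Seq(ref_cds).translate())
    alt_prot = str(Seq(alt_cds).translate())
    if ref_prot == alt_prot:
        return "synonymous"
    diffs = [i for i, (a, b) in enumerate(zip(ref_prot, alt_prot)) if a != b]
    if 0 in diffs and ref_prot[0] == "M":
        return "start_lost"
    if any(alt_prot[i] == "*" for i in diffs):
        return "stop_gained"
    if any(ref_prot[i] == "*" for i in diffs):
        return "stop_lost"
    return "missense"


def _utr5_start_gain(variant: VariantCall, gene: GeneModel, chrom_seq: str) -> bool:
    """Does a substitution in the 5'UTR create a new ATG on the coding strand?"""
    if variant.vtype not in ("SNP", "MNP"):
        return False
    span = variant.affected_span()
    lo = max(1, span[0] - 2)
    hi = min(len(chrom_seq), span[1] + 2)
    ref_win = chrom_seq[lo - 1:hi]
    alt_win = list(ref_win)
    for i, base in enumerate(variant.alt):
        idx = variant.position + i - lo
        if 0 <= idx < len(alt_win):
            alt_win[idx] = base
    alt_win = "".join(alt_win)
    motif = "ATG" if gene.strand == "+" else "CAT"
    return alt_win.count(motif) > ref_win.count(motif)


def annotate_variant(variant: VariantCall, genes: Sequence[GeneModel],
                     reference: Mapping[str, str],
                     windows: Windows = Windows(),
                     impact_map: Optional[Mapping[str, str]] = None
                     ) -> EffectAnnotation:
    """Annotate one variant against gene models and a reference sequence."""
    impact_map = dict(impact_map or DEFAULT_IMPACT_MAP)
    if variant.chromosome not in reference:
        raise ValueError(f"variant on unknown chromosome {variant.chromosome!r}")
    chrom_seq = reference[variant.chromosome]
    span = variant.affected_span()
    if span[0] < 1 or span[1] > len(chrom_seq):
        raise ValueError(f"variant at {variant.position} outside reference bounds")
    ref_slice = chrom_seq[variant.position - 1:
                          variant.position - 1 + len(variant.ref)]
    if ref_slice != variant.ref:
        raise ValueError(
            f"ref allele mismatch at {variant.chromosome}:{variant.position}: "
            f"expected {ref_slice!r}, variant says {variant.ref!r}")
    affected = list(range(span[0], span[1] + 1))

    best: Optional[tuple[int, str, str]] = None  # (rank, gene_id, category)
    for gene in genes:
        if gene.chromosome != variant.chromosome:
            continue
        if span[1] < gene.start - windows.upstream - windows.downstream or \
           span[0] > gene.end + windows.upstream + windows.downstream:
            continue
        labels: set[str] = set()
        genic = [p for p in affected if gene.start <= p <= gene.end]
        if genic:
            coding = _coding_effect(variant, gene, chrom_seq)
            if coding:
                labels.add(coding)
            labels |= _splice_labels(gene, genic, windows)
            utr5 = gene.utr5()
            utr3 = gene.utr3()
            for p in genic:
                if gene.in_any(p, gene.cds):
                    continue
                if gene.in_any(p, utr5):
                    if _utr5_start_gain(variant, gene, chrom_seq):
                        labels.add("5_prime_UTR_premature_start_gain")
                    else:
                        labels.add("5_prime_UTR")
                elif gene.in_any(p, utr3):
                    labels.add("3_prime_UTR")
                elif not gene.in_any(p, gene.exons):
                    labels.add("intron")
        else:
            up_lo, up_hi, dn_lo, dn_hi = _flank_windows(gene, windows)
            if any(up_lo <= p <= up_hi for p in affected):
                labels.add("upstream_gene")
            elif any(dn_lo <= p <= dn_hi for p in affected):
                labels.add("downstream_gene")
        if not labels:
            continue
        ordered = sorted(labels, key=lambda l: _RANK[l])
        cand = (_RANK[ordered[0]], gene.gene_id, "&".join(ordered))
        if best is None or cand < best:
            best = cand
    if best is None:
        return EffectAnnotation(variant, None, "intergenic",
                                impact_map["intergenic"])
    _, gene_id, category = best
    primary = category.split("&", 1)[0]
    return EffectAnnotation(variant, gene_id, category,
                            impact_map.get(primary, "MODIFIER"))


def _flank_windows(gene: GeneModel, w: Windows) -> tuple[int, int, int, int]:
    if gene.strand == "+":
        return (gene.start - w.upstream, gene.start - 1,
                gene.end + 1, gene.end + w.downstream)
    return (gene.end + 1, gene.end + w.upstream,
            gene.start - w.downstream, gene.start - 1)


def annotate_variants(variants: Iterable[VariantCall],
                      genes: Sequence[GeneModel],
                      reference: Mapping[str, str],
                      windows: Windows = Windows(),
                      impact_map: Optional[Mapping[str, str]] = None
                      ) -> list[EffectAnnotation]:
    return [annotate_variant(v, genes, reference, windows, impact_map)
            for v in variants]


def distribution_summary(annotations: Sequence[EffectAnnotation],
                         ndigits: int = 1) -> dict:
    """Per-category counts/percentages (full compound strings) and impact tallies."""
    total = len(annotations)
    cat: dict[str, int] = {}
    imp: dict[str, int] = {}
    for a in annotations:
        cat[a.category] = cat.get(a.category, 0) + 1
        imp[a.impact] = imp.get(a.impact, 0) + 1
    return {
        "total": total,
        "categories": {
            c: {"count": n, "percent": percent(n, total, ndigits) if total else 0.0}
            for c, n in sorted(cat.items())
        },
        "impacts": {k: imp.get(k, 0)
                    for k in ("HIGH", "MODERATE", "LOW", "MODIFIER")},
    }


def load_gene_models(gff3) -> list[GeneModel]:
    """Build gene models (gene + exon + CDS features) from GFF3 text or path."""
    text = str(gff3)
    if "\n" not in text and not text.lstrip().startswith("##"):
        text = open(text).read()
    db = gffutils.create_db(text, ":memory:", from_string=True,
                            merge_strategy="create_unique", force=True)
    out = []
    for gene in db.features_of_type("gene"):
        exons = tuple(sorted((f.start, f.end) for f in
                             db.children(gene, featuretype="exon")))
        cds = tuple(sorted((f.start, f.end) for f in
                           db.children(gene, featuretype="CDS")))
        gid = gene.attributes.get("ID", [gene.id])[0]
        out.append(GeneModel(gene_id=gid, chromosome=gene.seqid,
                             start=gene.start, end=gene.end,
                             strand=gene.strand if gene.strand in "+-" else "+",
                             exons=exons or ((gene.start, gene.end),), cds=cds))
    return out


def read_vcf_lite(source) -> list[VariantCall]:
    """Parse minimal VCF (CHROM POS ID REF ALT) text or path."""
    text = str(source)
    if "\n" not in text:
        text = open(text).read()
    out = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise ValueError(f"VCF line with <5 columns: {line!r}")
        chrom, pos, vid, ref, alt = fields[:5]
        out.append(VariantCall(chromosome=chrom, position=int(pos),
                               ref=ref, alt=alt, variant_id=vid))
    return out
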