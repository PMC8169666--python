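"""Variant-effect annotation on a toy gene model.

Plants a small per-category variant plan, annotates the variants against the
generated reference and prints the category/impact distribution.
"""

from ringminer import annotate_variants, distribution_summary
from ringminer.synthetic import gen_variants, toy_gene_models

plan = {"intergenic": 4, "upstream_gene": 3, "intron": 3,
        "splice_donor&intron": 1, "splice_region&intron": 2,
        "5_prime_UTR": 1, "3_prime_UTR": 2, "synonymous": 2, "missense": 3,
        "frameshift": 1, "conservative_inframe_deletion": 1}
models, chrom_len = toy_gene_models(plan)
variants, reference, truth = gen_variants(models, plan, seed=5,
                                          chrom_length=chrom_len)

annotations = annotate_variants(variants, models, reference)
for a in annotations[:5]:
    v = a.variant
    print(f"{v.variant_id} {v.chromosome}:{v.position} {v.ref}>{v.alt} "
          f"({v.vtype})  {a.category}  {a.impact}")

summary = distribution_summary(annotations, ndigits=1)
print("\ntotal variants:", summary["total"])
print("impact tiers:", summary["impacts"])
# Categories follow genomic context with coding > splice > UTR > intron >
# up/downstream > intergenic precedence; the impact tier (HIGH..MODIFIER)
# is derived from the primary category, e.g. frameshift and splice-site
# variants are HIGH, missense MODERATE, synonymous LOW.
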