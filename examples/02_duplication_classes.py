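"""Partition a synthetic gene family into the five duplication classes.

Generates a gene map with a known class plan, chains collinear homolog pairs
into blocks and classifies every family gene.
"""

from ringminer import (DupParams, chain_collinear_blocks,
                       classify_duplications, load_gene_loci)
from ringminer.genome import class_counts
from ringminer.synthetic import gen_gene_map

params = DupParams()  # tandem gap 1, proximal gap 10, blocks of >=5 anchors
plan = {"singleton": 2, "dispersed": 6, "proximal": 4, "tandem": 6, "WGD": 20}
gff3, pairs, truth = gen_gene_map(38, n_chroms=6, class_plan=plan,
                                  params=params, seed=1)

loci = load_gene_loci(gff3)
blocks = chain_collinear_blocks(pairs, loci, params)
calls = classify_duplications(loci, pairs, blocks, params,
                              gene_ids=sorted(truth.dup_classes))
print("collinear blocks:", [(b.block_id, len(b.anchors)) for b in blocks])
print("class counts:", class_counts(calls))
# The 20 WGD/segmental genes fall in two 5-anchor collinear blocks; tandem
# genes are rank-adjacent homolog pairs, proximal pairs sit within 10 gene
# ranks, dispersed pairs span chromosomes, singletons have no homolog at all.
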