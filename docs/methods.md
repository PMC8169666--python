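# Methods

This note documents the models, rules and numerical choices behind each stage,
what the synthetic generators do and do not emulate, and the known limitations.

## RING-domain scanner

**Model.** A candidate domain is a chain of eight positions whose residues lie
in the per-slot union of the rule set's allowed metal ligands and whose seven
inter-ligand gaps lie in the per-slot union of gap ranges, with total span
bounded by `max_domain_span` (default 102 residues).  The default gap ranges
(ML1–2: 2; ML2–3: 9–39; ML3–4: 1–3; ML4–5: 2–3; ML5–6: 2; ML6–7: 4–48;
ML7–8: 2, shared by RING-H2/RING-HC) give a minimum feasible span of 30.
The ambiguity code X never matches a ligand.

**Search and overlap resolution.** Chains are resolved greedily: leftmost
start first, shortest span as tie-break, and complete chains before incomplete
candidates so a degenerate nearby chain can never shadow a complete domain.
Under this policy a chain is blocked precisely when its start position lies
inside an already accepted interval, so keeping only the best chain per start
position — minimal (number of missing ligands, span), then lexicographically
smallest positions — is exactly equivalent to enumerating every chain.  The
scanner therefore runs one branch-and-bound search per anchor position; the
test suite certifies equivalence against an exhaustive enumeration oracle on
hundreds of random sequences.

**Incomplete domains.** A chain that satisfies all gap constraints but misses
or substitutes up to `8 − incomplete_min_ligands` ligands (default: up to 2)
is emitted as an INCOMPLETE candidate; ML1 must always match, anchoring the
chain.  This threshold is a package convention — detection rules for
partially conserved domains vary between annotation services — and is
configurable (`incomplete_policy: drop` discards the candidates entirely).
Note that when a substituted ligand sits near a spare Cys/His, the minimal-span
policy may prefer a shifted chain interpretation; incomplete coordinates are
therefore indicative, while complete-domain coordinates are exact.

**Subtype rules.** RING-H2 and RING-HC are the canonical C3H2C3/C3HC4
signatures distinguished by His vs Cys at ML5; the RBX variant is RING-H2 with
Asp at ML8.  RING-v (His shifted to ML5 with relaxed ML4–5/ML6–7 spacing) and
RING-G (Gly admitted at the ML5 slot) ship as clearly marked editable
placeholders: their precise published signatures should be verified against
the Arabidopsis classification literature before use on real proteomes.
Classification applies rules in priority order (file order); a hit matching no
rule is INCOMPLETE with missing-ligand indices reported relative to its
best-scoring rule.  Group percentages are computed over classified domains
only and rounded half-up to two decimals.

## Duplication classes

Classes are assigned per gene by strict priority: membership in any collinear
block → WGD/segmental; else a same-chromosome pair within the tandem rank
window (default 1) → tandem; within the proximal window (default 10) →
proximal; any remaining pair → dispersed; no pair → singleton.  Rank gaps are
counted over all genes on a chromosome, mirroring the duplicate-gene-classifier
convention, which is why the synthetic gene maps interleave filler genes.
Collinear blocks are maximal chains of anchor pairs, strictly increasing in
rank on one side and monotonic on the other, consecutive anchors within
`max_anchor_rank_gap` (default 25) on both sides, at least `min_anchors`
(default 5) long; chains are extracted greedily longest-first with each anchor
consumed once.  None of these window values is prescribed by the underlying
study; all are parameters.

Mean inter-gene distance is the mean start-to-start gap between consecutive
family genes per chromosome, reported in Mb to one decimal; chromosomes with a
single family gene report NA.  The start-to-start reading is a package
decision — span-based definitions are equally defensible — and is documented
here rather than hidden.

## Expression analysis

Expressed calls use strict `value > threshold` with a default of 0.5 TPM; the
public data behind the original analysis does not state its cutoff, so the
default is a package choice, and the Venn/total counts in the tests come from
the synthetic generator's exact construction, not from a claimed threshold
reconstruction.  The seven Venn regions are disjoint by construction and
always sum to the expressed total.

Clustering is agglomerative complete linkage under the uncentered Pearson
distance `d = 1 − Σxy/√(Σx²Σy²)` (range [0, 2]; zero-norm profiles get
distance 1 with a warning).  Ties in the minimal merge distance break on the
lexicographically smallest member label, making the trace permutation
invariant.  The heatmap grouping cuts the dendrogram at k = 4, orders groups
I–IV by the expression-weighted mean stage of their centroid (early-peaking
first) and re-cuts groups III and IV at k = 2 into A/B.  DEG filtering keeps
records with `|log₂FC| > 1` (strict) and `p ≤ 0.05` (inclusive), exactly the
printed boundary convention; p-values are consumed as given, with no
multiple-testing adjustment.

## qPCR screening

The ΔΔCt estimator averages technical replicates within each biological
replicate, then biological replicates, and reports the SD of the
per-bio-replicate ΔCt combined across genotypes in quadrature.  It is exact
for amplification efficiency 2 (no efficiency correction is applied).  The
candidate rule — consistent sign at all four stages and `|log₂FC| ≥ 2` at two
or more stages — reconstructs a narrative selection; both parameters are
arguments.  Zeros in a profile break sign consistency and classify as mixed.

## Variant annotation

Categories are assigned from genomic context with precedence coding > splice
donor/acceptor > splice region > UTR > intron > up/downstream > intergenic;
every applicable label is kept and joined with `&` in precedence order, so
per-category tables with compound rows are reproducible.  Windows: 5 kb
up/downstream of the TSS/TES; donor/acceptor are the first/last two intron
bases; splice region covers intron bases 3–8 and the three exon bases
adjacent to each junction — conventional annotator defaults, all configurable.
Coding effects compare the translated strand-corrected spliced CDS: indels
are frameshift when the CDS length change is not a multiple of three,
otherwise conservative (codon-boundary aligned) or disruptive inframe events;
substitutions are synonymous/missense/stop-gain/stop-loss/start-loss by
protein diff.  Impact tiers map from the primary category (HIGH: frameshift,
splice sites, start/stop disruptions; MODERATE: missense, inframe indels,
5'UTR premature start gain; LOW: synonymous, splice region; MODIFIER:
everything noncoding).

## Correlation screen

Pearson r on per-gene stage means with a two-sided t-test at n − 2 degrees of
freedom; with the four-stage design this leaves 2 df, so the screen warns
whenever n < 5.  Strength bins are applied to r² (≥ 0.80 very strong, ≥ 0.60
strong, inclusive bounds); a configuration switch allows binning on |r|
instead, since printed thresholds of this kind are sometimes meant on the
correlation scale.  A gene enters a target's significant set when `p ≤ 0.05`
and `r² ≥ 0.60`; with 2 df the p-criterion is the binding one (it requires
|r| ≳ 0.95).  The synthetic profile generator therefore plants candidate
genes as exact or near-exact affine images of the target profiles, and
non-candidates orthogonal to both targets, so the per-target set sizes are
structural rather than threshold-sensitive.

## Synthetic data: what it emulates, and what it does not

Each generator realizes its planted truth exactly under noise-free settings,
and all randomness flows through explicit seeds:

* **Proteomes** — background drawn uniformly over the 20 residues with
  Cys/His down-weighted ×0.3; planted-domain gap residues avoid all ligand
  letters; after assembly the sequence is scanned and any background window
  producing a spurious complete match (or shadowing a planted one) is redrawn.
  Scaled-down panels (tens of proteins) stand in for a full proteome.
* **Gene maps** — pair/triple constructions per class, WGD anchors laid out as
  perfect collinear runs, separator fillers wider than every rank window so
  placements cannot interact.  Gene spacing is uniform (10 kb), so spacing
  statistics exercise arithmetic, not genome geography.
* **Expression** — expressed entries Uniform(threshold + 0.5, 100), silent
  entries Uniform(0, threshold/2): calls are unambiguous at the generating
  threshold by construction.
* **Ct tables** — reference gene constant across runs, target = reference +
  offset − log₂FC component, Gaussian replicate noise; Livak-invertible by
  construction.
* **Variants** — the generator writes the reference itself (CCTGG background
  with no ATG/CAT on either strand, canonical GT..AG introns, ATG…stop CDS)
  and places each planned category at a dedicated, non-interacting location;
  it re-annotates its own output and fails loudly if the plan is not
  reproduced.  Genic placements require plus-strand models; the annotator
  itself is strand-general and is tested under reference mirroring.

None of the generators model hexaploid homeologues, real codon usage,
read-level noise, linkage between stages, or biologically realistic TPM
distributions.  Passing tests therefore certify the *algorithms* (rule
matching, chaining, partition arithmetic, estimators) against planted truth
and independent oracles — not the biological accuracy of any threshold on
real wheat data.

## Problem sizes and determinism

The default study conditions keep the published family-scale structure where
it is cheap (1238-gene duplication map, 1255-gene expression matrix, 457- and
667-variant plans, 36-gene qPCR and correlation panels) and scale down only
the proteome (80 proteins).  The full pipeline, test suite and acceptance
script each run in seconds to a few minutes on one CPU.  Reports are
deterministic for a fixed seed; rerunning on unchanged inputs reproduces
identical outputs.

## Known limitations

* RING-v/RING-G signatures are placeholders pending verification against the
  cited classification; counts for those subtypes on real data should not be
  trusted until the rules are confirmed.
* The incomplete-domain rule (≥ 6 of 8 ligands) is a stand-in for a manual
  curation step that has no published algorithmic definition.
* The correlation screen's significance test at n = 4 has very low power; the
  package reproduces the published arithmetic but a real study should use more
  stages or replicate-level correlation.
* The variant generator cannot place genic categories on minus-strand models
  (the annotator can consume them); multi-chromosome variant plans are not
  supported.
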