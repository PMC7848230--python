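# Methods

`phenomark` implements a metabolic-phenotype view of 16S amplicon
case/control studies: instead of (or alongside) genus-level taxonomic
features, each community is summarised by the expected fraction of its
cells that carry curated binary metabolic capabilities, and those
functional features drive cross-cohort disease classification and
biomarker analysis. This note records the models, the parameters that
matter, the numerical conventions, and what the synthetic test surface
does and does not establish.

## Multi-taxonomic assignment (MTA)

ASV representative sequences are aligned against a reference 16S
collection. With per-query hit identities F (fractions) and best identity
M, the accepted hits are those with

    F ∈ [M − (1 − M)/S, M]   and   F > D,

with scale S = 4 and drop threshold D = 0.85 by default. S narrows the
accepted band as the best hit weakens; D leaves low-identity queries
unassigned. Conventions fixed here: both interval endpoints are
inclusive, D is strict, and a query whose best hit does not exceed D is
unassigned — excluded from taxonomic features and from phenotype
probabilities, while its abundance still counts in the relative-abundance
denominator (an unknown organism dilutes a fraction-of-cells index; it
should not be renormalised away).

The accepted hits give (a) an MTA — the set of distinct lineages with
equal weights, rendered per rank as slash-joined, lexicographically
sorted names, where distinct strings (e.g. `A` vs `A/B`) are distinct
features — and (b) a genome mapping with equal weights over distinct
genomes. Multiple 16S copies of one genome are collapsed before
weighting so copy number cannot bias the mapping.

In-repo alignment identity (`mta.naive_identity`) is a unit-cost global
(Needleman–Wunsch) edit distance d reported as 1 − d/max(len). It is the
deterministic test-scale stand-in for an external aligner; tabular hits
from such an aligner (outfmt-6-like) can be supplied instead.

## CPI and PAD

For ASV i with relative abundance A_i and genome mapping weights w_g, the
probability that its cells carry phenotype ph is p_i = Σ_g w_g·BPM[g, ph],
the mapping-weighted average of the binary phenotype matrix column. The
Community Phenotype Index of a sample is

    CPI(ph) = Σ_i p_i · A_i,

the expected fraction of community cells carrying the phenotype. Unmapped
ASVs contribute zero (configurable but default, per the dilution argument
above).

Phenotype Alpha Diversity (PAD) is Faith's phylogenetic diversity — total
branch length of the minimal rooted subtree — of the carrier
sub-community: ASVs present in the sample (abundance > 0) whose p_i
strictly exceeds 0.6. PAD = 0 when no carrier is present. PAD exists to
flag phenotypes whose CPI merely tracks one narrow clade; such features
are removed before classification (filter below) because they are
phylogeny-driven rather than metabolism-driven signals.

Trees are built from pairwise global-alignment distances with the
Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3) (p capped at 0.70), then
neighbor joining and midpoint rooting; negative NJ branch lengths are
clamped to zero. The JC scale matters: branch lengths are expected
substitutions per site, the scale maximum-likelihood tree builders
report, and the absolute PAD filter threshold (3.5) presumes it. An
externally built Newick tree can be imported instead; it is
midpoint-rooted unless declared rooted.

## Dataset filters

Applied per cohort before profiling:

* coverage: samples with read counts not strictly above the threshold
  (default 15,000) are dropped;
* ASV retention: keep ASVs present in > 0.5% of samples, or with mean
  abundance > 0.25%, or with maximum abundance > 0.5% (any one
  suffices); abundances are then renormalised per sample so CPI keeps
  its fraction-of-cells meaning. The renormalisation choice is ours —
  the ~1–2% abundance the filter removes would otherwise leak out of
  every downstream fraction.

## Classifier grid

Seven dataset-division variants for three cohorts — Single (each cohort,
stratified 2/3 : 1/3 split), L1O (train on two cohorts, test on the whole
held-out third), Mixed (all cohorts pooled) — crossed with two predictor
sets (genus abundances vs phenotype CPIs) and two contrasts (CD vs HC,
UC vs HC) give 28 configurations. Random forests use depth 3, 200 trees,
50% of features per split, and class weights inversely proportional to
training-class frequency. Single and Mixed run 10 cross-validation
iterations; L1O runs 3.

Subsampling equalises cohort contributions: per status group the target
is the smallest group size among participating cohorts, drawn uniformly
without replacement (redrawn each Mixed iteration). Feature filtration
uses training data only, per cohort for multi-cohort strategies:
taxonomic features need nonzero abundance in ≥ 5 samples and maximum
abundance ≥ 1%; phenotype features need mean CPI within [0.1, 0.9],
CPI > 0.05 in ≥ 5 samples, and mean PAD ≥ 3.5. Feature extraction fits
10 forests on the training data and keeps the top 20 features by mean
Gini importance (ties break lexicographically; when ≤ 20 features are in
play the ranking cannot drop any, so the fits are skipped — an exact
shortcut). Test metrics are ROC-AUC plus sensitivity and specificity at
the 0.5 probability cut on the disease class; the operating point is a
package choice (Youden's J would be the natural alternative) since
balanced-weight forests centre their probabilities reasonably.

Reproducibility: one master seed deterministically derives every
iteration, sub-iteration, and subsampling seed (CRC-mixed
`numpy.random.SeedSequence`), so any single iteration can be re-run in
isolation and the grid is bit-reproducible.

## Stable predictors and PDP forms

Per variant, a feature's importance is the mean of its final-model Gini
importances across that variant's iterations — set to zero if the
feature was not extracted in *every* iteration. A feature is a stable
predictor when it has nonzero importance in at least six of the seven
variants (generalised to "all but one" for studies with fewer cohorts)
and the sign of its case-minus-control mean difference agrees across all
cohorts; its reported importance is the average over the seven variants.

Each stable predictor's effect shape comes from a 20-step partial
dependence plot: Mixed-strategy forests are refit on the stable
predictors alone (20 iterations), the feature is substituted to each of
20 grid values spanning the union of training ranges, predicted disease
probabilities are averaged over training rows and then over iterations.
With Δ_i = prob[i+5] − prob[i] (1-based i = 1..15):

* direction is the sign of the largest |Δ_i|; if both signs occur and
  the larger of max|Δ+|, max|Δ−| is less than twice the smaller, the
  curve is unclassified — as are flat curves and exact sign ties;
* the form is *sharp* if some |Δ_i| ≥ 3 × the larger of the probability
  ranges (max − min) over the outer intervals [1, i) and (i+5, 20]
  (empty or singleton intervals contribute 0 — the only reading under
  which a clean step is sharp), else *smooth*.

Labels are invariant under positive affine transforms of the probability
axis; reversing a curve swaps increasing/decreasing and preserves
sharp/smooth.

## Synthetic study generator

The generator emulates the statistical structure the analysis assumes,
not any particular cohort. A pure-birth tree over 150 reference genomes
(rescaled to unit height) carries Jukes–Cantor sequence evolution at
0.35 substitutions/site per unit height over 250-bp 16S-like amplicons;
this divergence scale was chosen so that community Faith PD lands in the
range observed for real gut 16S data (tens, for a few hundred ASVs) —
the regime the absolute PAD filter threshold presumes. Lineages come
from average-linkage clustering of patristic distances (genus/family/
phylum cuts; class and order deliberately blank to exercise missing-rank
handling). Of 60 phenotypes, a quarter are clustered — carriers form one
clade, the low-PAD features the filter should remove — and the rest are
Bernoulli(0.5) i.i.d. across genomes. The pool of 300 ASVs consists of
0–3-substitution copies of reference 16S genes shared across cohorts.

Abundances follow per-ASV log-normal baselines (σ = 1) with per-cohort
batch offsets (σ = 0.75, enough to separate cohorts in ordination) and
per-sample noise (σ = 1); counts are multinomial at log-normal read
depths around 30,000, so rare ASVs drop out of individual samples.
Planted case effects multiply the abundances of target ASVs (carriers of
a phenotype, or descendants of a genus clade) by 2^±lfc before
renormalisation; compositional closure shifts off-target features
slightly, which is accepted as realistic. Three cohorts of 60 HC / 30 CD
/ 30 UC samples are the default.

The phenotype count (60) is deliberately well above the top-20
extraction cut after filtration (~45 retained), mirroring the real
study's 94 + 229 features: with a small pool the extraction step would
be vacuous and chance sign-agreement alone would mint spurious "stable"
predictors under the null.

What the generator does *not* emulate: sequencing error profiles,
chimeras, primer/denoising artefacts, indel variation (so identity
reduces to mismatch counting), uneven 16S copy numbers, and real
phylogenetic signal in disease effects. Passing tests therefore show the
pipeline's rules behave as specified on data with the assumed structure
— not that the biological findings of any cohort would be reproduced.

## Problem sizes in the checks

A full 7-variant suite for one predictor set × contrast costs ~539
forest fits; the test suite runs the end-to-end recovery check on three
master seeds at reduced cohort sizes (40/20/20) and requires recovery in
all three, with a zero-effect control (no stable predictors; Mixed AUC
within 3 Hanley–McNeil SEs of 0.5 — the appropriate null SE, since CV
iterations share one realized cohort and their spread understates the
dataset-level variance). The acceptance script repeats recovery at the
full default scenario. The planted effect in both is a 4-fold (log2 = 2)
enrichment of one diffuse phenotype's carriers.

## Known limitations

* NJ + JC distances are a test-scale tree; for real studies import an
  ML tree (FastTree/IQ-TREE Newick) instead.
* The sensitivity/specificity operating point (0.5) is a convention;
  AUC is the primary metric.
* PDP curves of near-constant features are rejected (degenerate range)
  rather than labelled.
* Genus-level features use the genus-rank MTA string; ASVs whose MTA has
  no genus-rank name are excluded from taxonomy features (logged), not
  aggregated at a higher rank.
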