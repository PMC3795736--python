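# Methods

`astrodirac` implements a rank-based network analysis of bulk expression
cohorts ordered along the astrocytoma grade ladder
Normal < G2 < G3 < {pGBM, sGBM} (primary and secondary glioblastoma, both WHO
grade 4, treated as parallel endpoints).  This note records the model, the
conventions the implementation pins down, the defaults and why, and what the
synthetic cohorts do and do not establish.

## Rank conservation over networks

For a network of m genes and one sample, the only information used is the
within-sample ordering of the m expression values, encoded as the binary
vector over all m(m−1)/2 gene pairs (i, j), i < j in the network's gene-list
order, with bit 1 iff expression(g_i) < expression(g_j).  Everything
downstream is a function of these bits, which makes all outputs invariant
under any strictly monotone per-sample transform of expression — the central
robustness property of the approach, and one the test suite checks directly.

Per (network, phenotype):

* **rank template** T: the strict-majority bit per pair over the phenotype's
  samples;
* **rank matching score** of a sample: the fraction of its pairs agreeing
  with T;
* **rank conservation index** R: the mean matching score of the phenotype's
  samples against their own template.  R near 1 means a tightly shared
  ordering ("regulated"); values toward 1/2 mean patient-to-patient
  heterogeneity ("dysregulated").  Against the own template, R ≥ 1/2 always
  (majority property), and the implementation's vectorized index is pinned to
  an explicit pair-enumeration oracle, exactly.

Ties are resolved deterministically and are part of the contract the oracle
pins: equal expression within a pair gives bit 0; an exact 50/50 template
split gives template bit 0 plus a tie-mask entry; matching scores keep all
pairs in the denominator, so a fully tied template scores 1/2 against any
sample.

**Global dysregulation** of a phenotype is the unweighted mean of R over all
networks.  For the global trend the two GBM subtypes can be pooled
(`merge_gbm`), which is also the view used for the one-way ANOVA across
phenotypes and the paired t-tests (paired per network) on the conservation
table.

## Differentially regulated networks

For two phenotypes A and B, each network gets Δ = R_A − R_B; networks are
ranked by |Δ|.  Significance permutes the A/B labels among the pooled A∪B
samples (not all five phenotypes — the question is pairwise), rebuilding both
templates and indices per permutation.  The default null pools |Δ| across all
networks and permutations, matching the "fraction at least as extreme"
framing; a per-network null is available (`per_network_null=True`).  p-values
use the add-one estimator (1 + r)/(1 + n), so 1000 permutations can report
p < 10⁻³.  A one-sided exact binomial test (k of n significant networks more
dysregulated in the higher grade, null probability 1/2) summarizes
directionality per comparison; one-sided is a deliberate choice — the
question asked is an excess in the higher grade.

The permutation inner loop uses the identity
mean-over-samples(matching score) = mean-over-pairs max(f, 1−f), where f is
the per-pair bit-1 frequency; this makes nulls a matrix product but is
algebraically the same statistic (tied pairs contribute exactly 1/2 either
way).  The audited per-sample-score path is kept for reporting, and both
paths are checked against the enumeration oracle.

## Template classification

Each network classifies A vs B by building one template per phenotype and
assigning every sample to the template it matches better.  Apparent accuracy
scores the training samples; leave-one-out cross-validation (LOOCV) rebuilds
*both* templates without the held-out sample (each class therefore needs ≥3
samples).  Score ties go to the larger class; with equal class sizes the
lexicographically smaller phenotype name wins, which keeps the rule symmetric
under swapping the class arguments.  In LOOCV the tie-break uses the
*full-cohort* class sizes, not the fold's training sizes: the fold sizes
always disfavor the held-out sample's own class (it is the one depleted by
the removal), and breaking ties on them biases null LOOCV accuracy well below
1/2.  With the prior-based rule, null cohorts calibrate at 1/2 (checked).

Raw accuracy is the default metric (balanced accuracy is also reported, which
matters for comparisons as unbalanced as 174 vs 30).  Significance pools
apparent accuracies of all networks over label permutations; the FDR at an
observed accuracy t is (expected null networks ≥ t per permutation) /
(observed networks ≥ t), clipped to [0, 1], with Benjamini–Hochberg available
as an option.  One-vs-rest pools all non-target phenotypes into a "rest"
class and reports the per-network table plus a top-k list sorted by apparent
accuracy, ties broken by network name.

## Monotonically changing genes

Run on the rank layer.  Candidates must be differentially expressed
(two-sided Wilcoxon rank-sum; exact when the smaller group has ≤8 values and
no ties, otherwise normal approximation with tie and continuity corrections;
Bonferroni over all genes tested at α = 0.05) in **all four** adjacent
comparisons: Normal–G2, G2–G3, G3–pGBM, and G3–sGBM — both grade-4 subtypes
must continue the trend.  Within that intersection, direction is assessed on
per-phenotype *mean within-array ranks* with *strict* inequalities
(Normal < G2 < G3 < each GBM subtype for increasing; mirrored for
decreasing); pGBM and sGBM are unordered relative to each other.  Mean +
strict was chosen for determinism and exact antisymmetry: negating all
expression values swaps the increasing and decreasing sets exactly (tested).
Intersection-first (DEGs, then monotonicity) is the implemented order.

Two resampling procedures qualify the lists:

* **subsampling robustness** — draw 80% of each phenotype without
  replacement, rerun, count how often each full-data gene recurs *with the
  same direction*; genes at ≥ half the replicates are high-confidence;
* **directionality test** — permute all labels jointly, recount monotone
  genes per direction, p = (1 + #{null ≥ observed})/(n_perm + 1), separately
  for increasing and decreasing.  The Bonferroni family size is recomputed
  identically inside every permutation.

## Synthetic cohorts

The generator emulates the post-normalization output of a multi-study
microarray compendium; GC-RMA itself, CEL parsing and present-call
computation are upstream and out of scope.  The model is

    expr(g, s) = mu_g + step(s)·delta·dir_g + batch(b(s), g) + N(0, sigma(s) [+ extra])

with gene baselines mu_g ~ Uniform(0, 1000) (wide enough that an unperturbed
global ordering exists, giving a well-defined template at sigma = 0), grade
steps 0, 1, 2, 3, 3, additive per-(batch, gene) shifts with scale
`batch_sigma` (default 5) — the simplest model that makes the correlation QC
respond to lab effects — and additive Gaussian noise whose scale is set per
phenotype.  Defaults: the per-phenotype sample counts 30/31/57/174/44 of the
emulated compendium; 248 networks of 5–50 genes sampled without replacement
from a 2000-gene universe; a noise ladder 10/14/18/22/22 rising with grade so
that rank conservation falls with aggressiveness; planted-trend shift
`monotone_delta` = 45 per grade step (3× a uniform sigma of 15, the
recovery-study convention).  Planted dysregulation adds `extra_sigma` to the
noise scale of one network's genes in one phenotype; when plantings overlap,
the widest applies.  The probe layer gives ~10% of genes a second probe and
2% a third, adds ambiguous two-gene probes, draws present calls
Bernoulli(0.95), and can force chosen probes fully absent in one phenotype to
exercise the 0%-present filter.  All draws derive from one seed through named
substreams, so outputs are bit-identical under reruns and one stage's
parameters never perturb another stage's draws.

What the synthetic data does *not* emulate: heavy-tailed or intensity-
dependent microarray noise, probe-sequence effects, correlated gene modules
beyond the planted structure, or confounding between batch and phenotype.
Passing recovery and calibration tests here shows the statistics behave as
designed under a known generative model — not that real cohorts satisfy that
model.

A known interaction worth noting: planted monotone genes whose baseline sits
near the top (or bottom) of the expression range saturate at the maximal
(minimal) within-array rank after one or two grade steps, after which further
steps register no rank change and the gene can miss the later DEG
comparisons.  This is a genuine property of rank statistics, visible in the
recovery sensitivity (a little above 0.9 rather than 1.0 when planted genes
are drawn without regard to baseline).

## Preprocessing

Order fixed as: present-call filter (drop probes with zero present calls in
any phenotype) → collapse (drop multi-gene probes, then per-sample maximum
over a gene's probes — cell-wise, so different probes may win in different
samples) → within-array rank transform (ascending, average ranks for ties so
rank-sum statistics downstream are preserved; every column sums to
n(n+1)/2).  The mean off-diagonal Pearson correlation over all sample pairs
is the QC statistic; zero-variance samples are excluded from it with a
warning.  Dropped probes, genes and networks are logged with reasons at every
stage.

## Numerical and degenerate-input conventions

* Networks are intersected with the matrix's genes in gene-set order;
  networks with <2 genes present are dropped and logged.
* Phenotypes need ≥2 samples for templates, ≥3 for LOOCV.
* Paired t-tests: identical columns give p = 1 (t = 0); a constant nonzero
  shift has zero difference variance, is degenerate (t → ∞) and is reported
  as NaN with a warning rather than p = 0.
* ANOVA on a zero-variance conservation table raises instead of returning a
  meaningless statistic.
* The conservation index is computed as (total agreeing pair-sample cells) /
  (pairs × samples) in one division, so it equals the enumeration oracle to
  the last bit.

## Problem sizes used in the shipped checks

The acceptance script and the end-to-end tests run: the 248-network noise
ladder at 20 samples per phenotype; differential-regulation recovery with 5
planted among 45 null networks at 40 samples per phenotype and 1000
permutations; monotone-gene recovery with 20+20 planted among 1000 null genes
at the default compendium sample sizes, 200 subsampling replicates and 1000
directionality permutations; classification calibration over 50 networks with
20+20 samples; and a small full-pipeline run executed twice for bit-identical
outputs.  These sizes keep a full pass in the low minutes on one CPU while
leaving the permutation floors (p ≈ 10⁻³ at 1000 permutations) measurable.
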