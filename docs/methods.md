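# Methods

This note records the statistical models, the synthetic data generator, the
numerical choices, and the known limitations of `cernet`.  Everything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from external runs.

## Differential expression

**Normalization.** TPM and FPKM follow their standard definitions (feature
lengths are annotation interval lengths).  Between-sample normalization is
trimmed mean of M-values: the reference is the sample whose upper-quartile
CPM is closest to the mean upper quartile; per gene (zeros in either sample
excluded) M is the log2 ratio of relative abundances against the reference
and A the mean log2 abundance; the 30% tails of M and the 5% tails of A are
trimmed; the factor is 2^(weighted mean M) with inverse delta-method
variance weights, and factors are rescaled to geometric mean 1.  A sample
identical to the reference up to a global scale factor gets factor 1 — pure
depth differences are carried by the library size.

**Test.** Each proliferative time point is compared with the 0 h group by a
conditional negative-binomial exact test on group sums.  Counts are first
rescaled to the geometric-mean effective library size (library size × TMM
factor) so the group sums are exchangeable; the two group sums are then
NB-distributed with sizes n_g/φ and a common success probability, and the
two-sided p-value is the total probability of all splits of the observed
total no more probable than the observed split.  φ = 0 degenerates to the
conditional Poisson (binomial) test.  The per-dataset common dispersion φ
is estimated by maximizing the summed conditional log-likelihood of counts
given their group sums (the standard approach for this test family); a
method-of-moments alternative (per-gene (s²−m)/m² with a chi-square
median-bias correction, pooled by the median) is available via
`method="moments"`.  The conditional-likelihood default was chosen because
its bias is small enough to keep the test's type-I error at the nominal
level; the acceptance script measures ≈0.05 at α = 0.05 over 10,000 null
genes (n = 6 vs 6, φ = 0.1).

**Calls.** log2 fold changes are computed from TMM-normalized group-mean
CPM with a pseudo-count of 0.5 per group mean (computing them on TPM
instead is a config switch).  Class thresholds: fold change 1.5 for
lncRNA/miRNA/mRNA, 1.0 for circRNA (so the p criterion alone decides), raw
p < 0.05.  DE p-values are deliberately not multiplicity-adjusted; only
enrichment uses FDR.  A feature significant in ≥ 1 contrast is union-DE.

## Co-expression analysis

Input is log2(FPKM + 1) of the union-DE mRNAs (the transform is
configurable).  The network is unsigned: a_ij = |cor|^β.

**Outlier screening.** Samples are clustered by average linkage on
Euclidean distances of per-gene standardized expression; the default cut
height is mean + 2.5 sd of the merge heights, and a sample is removed only
if it is still a *singleton* at the cut.  The singleton rule matters in a
time course: whole time-point blocks legitimately merge late and must not
be discarded wholesale.

**Soft power.** For each power 1–20 the scale-free fit index is
−sign(slope)·R² of a log10 density vs log10 mean-connectivity regression
over 10 equal-occupancy connectivity bins.  The chosen β is the smallest
power whose fit reaches 0.85 *and* whose mean connectivity lies in a window
of roughly one to a few retained neighbours per gene (default [1, 2.5]).
The window is needed because the downstream constant-height cut requires
the background topological overlap compressed to near zero (low powers fail
this even with a good fit index) while an over-compressed network loses the
modules entirely (very high powers reach the fit target on an essentially
empty graph).  When no power lands in the window the rule degrades to
smallest-power-reaching-target, then argmax fit.

**Modules.** TOM_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij) with diagonal
1; the dendrogram is average linkage on 1 − TOM.  The cut is a simplified
hybrid dynamic tree cut with four deterministic stages:

1. constant-height cut at 0.99; clusters below `min_module_size` (30) are
   unassigned;
2. *deep split*: each module is recursively bisected at the highest
   junction of its own subtree whose two children both hold ≥ `min_size`
   leaves — this separates two expression programs that stayed attached
   below the global cut (with unsigned networks, strongly *anti*-correlated
   programs can do this);
3. eigengene merging: modules whose eigengenes correlate above
   1 − `merge_height` (0.75) merge iteratively, which also reunites halves
   of coherent modules produced by stage 2;
4. a PAM-like pass: every gene attaches to the module whose eigengene it
   correlates with most strongly when |cor| > `kme_to_stay` (0.6), and is
   released to the unassigned pool otherwise.  The retention threshold sits
   between the member KME distribution (≳0.6 in the benchmark regime) and
   the background (chance |cor| at 30 samples rarely exceeds 0.5).

Eigengenes are the first right-singular vector of the per-gene standardized
module submatrix, scaled to unit variance and sign-oriented to correlate
positively with members on average.  Module–trait correlations use one
binary indicator per time point; the key module per time point is the
argmax |r| (ties: smaller p, then larger module).  GS is the gene–indicator
correlation, MM the gene–eigengene correlation; hub genes are key-module
members with |MM| > 0.8 *and* |GS| > 0.5, both strict, the GS taken against
the trait the gene's module is key for.

## Regulatory pairs and ceRNA triads

Coordinates are 0-based half-open internally (GTF input is converted on
read).  The cis distance is the minimal interval gap, strand-agnostic,
with overlap = 0 and the 100-kb boundary inclusive; cis candidates must be
on the same chromosome and are kept at |r| > 0.6 (Pearson, two-sided t
p-value attached).  Trans pairs are DE lncRNA × DE mRNA pairs at |r| > 0.9;
window-eligible pairs are excluded by default so the two networks are
disjoint (configurable).  Parent pairs link each DE circRNA to its
annotated host mRNA with no correlation threshold.  Core networks restrict
targets to hub genes.

Triad candidates require a union-DE miRNA with declared binding (union of
the two target sources; intersection selectable) to both a union-DE
lncRNA/circRNA and a hub mRNA.  The filter keeps candidates with
ρ(ceRNA, mRNA) > 0, ρ(miRNA, ceRNA) < 0, ρ(miRNA, mRNA) < 0 and all three
correlation tests significant.  The significance threshold is written "ρ <
0.05" in some descriptions of this procedure, conflating the coefficient
symbol with a p-value; reading it as |ρ| < 0.05 would contradict the sign
requirements, so the p-value reading is the default and the magnitude
reading is exposed as `spearman_filter_on="rho"`.  Spearman p-values use
the t approximation for n > 10 and exhaustive permutation for n ≤ 10.

## Enrichment

Upper-tail hypergeometric p per term (universe = filtered features of the
relevant class), BH step-up FDR, significance at FDR < 0.05, ranked by p.
BH is not idempotent in general, so the tests verify it against the direct
step-up formula rather than a fixed-point property.

## Synthetic data generator

The generator emulates the motivating design: 5 time points × 6
replicates, four RNA classes (defaults 1,000 mRNA / 200 lncRNA / 40 circRNA
/ 80 miRNA — a desk-scale stand-in for a transcriptome).  Counts are
gamma-Poisson (NB) with var = µ + φµ², φ = 0.1 by default, per-sample
library factors log-uniform on [0.5, 2], and base means log-uniform per
class (mRNA 50–500).  The log2 mean of feature g in sample j is

    log2 µ = log2 base_g + profile_g(t_j) + z_{module(g),j} + w-terms

* **Modules** (4 × 100 mRNAs): archetype profiles with entries in
  {0, ±1.5 log2} — high at 0 h, peak at 12 h, peak at 48 h, peak at 72 h —
  plus a module-shared per-sample latent factor z (sd 0.6 log2).  Entries
  of exactly ±de_log2fc keep the DE truth labels exact.
* **Isolated DE features** in every class: one random perturbed time point,
  ±1.5 log2.
* **Cis pairs** (20): a lncRNA placed 0–100 kb from a module-member mRNA on
  the same chromosome (all other lncRNA–mRNA gaps exceed the window by
  construction: non-planted features sit on a 300-kb grid), sharing the
  partner's profile, module latent, and a pair-private latent (sd 0.6).
  Planted regulators draw base means from the upper half of their class
  range — a planted pair whose lncRNA has single-digit counts would not be
  "planted with high co-expression" in any meaningful sense.
* **Triads** (40 lncRNA- + 10 circRNA-anchored, 25 miRNAs): each miRNA
  opposes one module's profile; its ceRNAs and target mRNAs (module
  members) load +1, the miRNA −1, on a shared latent (sd 0.75).  The sd was
  set by a power calculation: it puts the weakest pairwise correlation of a
  triad near ρ ≈ 0.7, so each Spearman test at n = 30 misses with
  probability < 1% and 50-triad recall is limited by the method, not by
  planting noise.
* **Targets**: the two planted links per triad plus Bernoulli background
  links at density 0.05, split between two emulated prediction sources.
* An optional outlier sample (a random 30% of features × 8) exercises the
  outlier-screening stage; it is off in the default benchmark.

What the generator does *not* emulate: sequence-level binding (targets are
declared, not predicted), count-length biases, batch structure,
inter-module correlation beyond the archetype geometry, and the long
right tail of real library-size variation.  Passing the recovery
benchmarks therefore demonstrates the pipeline's correctness and power
under its own model assumptions, not performance on real libraries.

## Benchmarks and problem sizes

The named benchmarks (`cernet.benchmarks`) fix one generator configuration
per pipeline stage: DE recall/FDR and module ARI on the default
configuration above; hub precision/recall on a low-noise variant
(φ = 0.02, module latent sd 0.3, only the module program planted, so the
planted members are exactly the genes satisfying the hub definition in the
noiseless limit); cis recall on the default configuration with truth DE
sets; triad recall/FDP on the Spearman filter with 50 planted triads mixed
into 5,000 declared-target decoy triples whose expression is pure noise.
The decoy construction isolates the filter: module-co-regulated unplanted
triples genuinely satisfy the ceRNA correlation pattern and are not
counted against the filter.  These sizes keep the whole acceptance battery
under a minute on one CPU.

## Determinism

One global seed fans out to per-stage child seeds via
`numpy.random.SeedSequence`; identical config + seed yields byte-identical
output files.  Stage wall-times go to a separate `timings.json` so
`summary.json` stays deterministic.  All tabular outputs and network
exports are written in sorted order.

## Limitations

* The DE stage has no GLM layer: no batch covariates, no gene-wise
  dispersion shrinkage; the common-dispersion exact test loses power when
  dispersions vary strongly across genes.
* The tree cut is a deterministic simplification of hybrid dynamic tree
  cutting; label *identity* with the reference implementation is not a
  goal (planted-structure recovery is).
* Matrices are dense and in-memory; intended scale is ≤ ~10,000 genes.
* Enrichment has no ontology DAG propagation or pathway topology.
* The "ρ < 0.05" ambiguity above is resolved by configuration, not
  silently.
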