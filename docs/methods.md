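# Methods

## Data model and conventions

Beta values (methylation fractions) live in probes × samples matrices with
values in [0, 1] and explicit missingness; intensities are strictly positive.
Genomic coordinates are 1-based inclusive everywhere inside the package (the
SEG convention); BED export converts to 0-based half-open. Operations that
need complete data (quantile normalization, embedding, deconvolution) impute
missing betas with the per-probe cohort median — a deterministic, conservative
choice; differential testing instead requires imputation up front so every
probe is tested on the same sample set. All randomness flows from a single
config seed; each pipeline stage derives `seed + fixed offset` so stages are
independently reproducible.

## Quality control

Three per-sample metrics: missing-probe count, mean intensity, probe success
rate (1 − missing/probes). For each metric the adverse-tail cutoff is the 95%
quantile of the adverse direction, computed once on the full sample set; a
sample is excluded only if it lies *strictly* inside the adverse 5% tail of
all three metrics simultaneously. Strict inequalities make an all-identical
cohort a no-op, and the conjunction makes the filter deliberately
conservative: a sample extreme on two metrics survives.

## Quantile normalization

Mean-of-order-statistics dialect: the target distribution is the across-sample
mean of sorted columns; each sample's values are replaced by the target at
their within-sample ranks, with tied runs receiving the mean target value over
their rank span. On tie-free data the operation is exactly idempotent. With
heterogeneous tie structures across samples (e.g. betas clipped at 0/1) no
dialect of this normalization is strictly idempotent; the residual movement on
a second application is confined to tie blocks and is small (~1e-3 on heavily
clipped synthetic data). Reference and query cohorts are normalized jointly in
the cross-species stage, since the matching operates on the combined set.

Note a structural consequence exploited nowhere but worth knowing: a class
signature that is a pure global shift (all probes moved the same way) does not
survive quantile normalization. Real methylation signatures move probes in
both directions and are preserved.

## Differential methylation

Per probe, the base statistic is the Welch two-sample t (per-group variances,
Satterthwaite degrees of freedom) for target-vs-rest, with delta-beta as the
effect size. The Welch variance is shrunk toward a cohort-wide prior estimated
by moment matching of log variances (mean and spread of log s² against the
scaled-χ² model, trigamma-inverted for the prior df); the moderated statistic
uses the posterior variance with `df = df_Welch + df_prior`. Setting the prior
df to 0 disables shrinkage and recovers the classical Welch t exactly, which
is the package's cross-check against `scipy.stats.ttest_ind`. Degenerate
probes with zero posterior variance take t = 0, p = 1, so identical groups
yield a clean null. Multi-group site selection uses the analogous moderated
one-way F; both are exposed because panel selection may be one-vs-rest or
omnibus depending on the question. BH adjustment is applied over all probes.

Top-k site selection orders by p-value, then larger |delta-beta|, then probe
id — fully deterministic under ties.

## Synthetic data

The generators define the study conditions; they are not tuned per test.

* Baseline betas: two-component Gaussian mixture centered at 0.1 and 0.9
  (equal weight, sd 0.05, clipped to [0, 1]) — the characteristic bimodal
  marginal of methylation arrays.
* Class signatures: disjoint probe sets per class (default 200), shifted by
  the signature delta (default 0.5) *toward the opposite methylation mode* —
  low-baseline sites are hypermethylated, high-baseline sites demethylated —
  so the planted effect size survives clipping. This mirrors real signature
  CpGs, which flip between mostly-methylated and mostly-unmethylated states.
* Replicate noise: Gaussian on the beta scale, truncated by clipping
  (default sd 0.05). Clipping concentrates a little mass exactly at 0 and 1;
  population means of clipped replicates are therefore biased ~0.02 toward the
  interior at boundary probes, consistently on both reference and validation
  sides.
* Planted QC failures: 20% missing probes and 0.3× intensity.
* CNA cohorts: probes evenly spaced on each chromosome; log2 intensities are
  a flat base plus the planted per-segment shifts plus Gaussian noise
  (default sd 0.1).
* Ortholog maps pair the i-th mouse probe with the i-th human probe on a
  uniformly sampled index subset — injective, and class signatures survive at
  the sampled fraction in expectation.
* Synteny maps partition each mouse chromosome at random cut points and place
  the blocks sequentially on the human chromosomes with gaps, guaranteeing
  disjoint human intervals.

What the generator does **not** emulate: probe-type chemistry, FFPE
degradation, spatial/LD-like probe correlation, batch structure, and realistic
inter-population covariance (populations share the baseline exactly outside
their signature sites, making reference columns more collinear than real cell
types). Passing tests therefore demonstrate correctness of the machinery
under the stated statistical structure, not performance on real arrays.

## Cross-species matching

The reference's top differentially methylated sites (default 15,000, omnibus
moderated F) are intersected with the ortholog map; query probes are renamed
to their reference partners and both cohorts are jointly quantile-normalized
on the panel.

Embedding arm: per iteration (default 10), a random 90% of reference samples
is drawn (redrawn, with a log line, if a class empties; bounded retries), the
reference subset plus query is embedded into 2-D UMAP (n_neighbors 15 capped
at n−1, min_dist 0.1, Euclidean, iteration-derived seed), and each query
sample votes for the class with minimal mean embedding distance. A config
flag switches between embedding one query at a time (the literal per-sample
procedure) and all queries jointly (equivalent for well-separated references,
much faster — used in tests).

Forest arm: a random forest (default 1,000 trees, sqrt feature sampling)
where every tree trains on a stratified bootstrap of exactly min-class-size
samples per class, neutralizing class imbalance; out-of-bag votes are tracked
and verified to be ~50:50 on signal-free 90:10 data.

Consensus per model is the vote mode, ties broken lexicographically and
logged. Significance per model: one-sided exact binomial tail with trials =
query samples of the model, successes = samples whose embedding-arm consensus
equals the expected entity, null probability = the expected entity's frequency
among reference samples (a label-agnostic chance model; the forest arm is
reported descriptively). BH correction across models.

Embedding stability is quantified by re-embedding random 90% subsets and
correlating x and y coordinates over shared samples for every iteration pair,
after Procrustes alignment (translation/scale/rotation/reflection) because raw
UMAP axes are arbitrary; an unaligned mode is exposed for the literal
procedure.

## Deconvolution

Reference construction: for each of the populations (immune populations with
replicates, plus tumor-average and brain-average single profiles), a
one-vs-rest moderated test; sites with raw p < 0.05 are ranked by |delta-beta|
(both hyper- and hypomethylated markers are admissible — they are equally
discriminative) and the top 100 taken, skipping sites already claimed by an
earlier population so the pooled row set is exactly populations × 100 unique
CpGs. With the generator's disjoint signatures the skip rule never triggers.
The replicate-free tumor/brain profiles are tested with variance borrowed from
the rest pool (moderated), inflated for a single new observation — cohort
averages have no replicate variance of their own. A population with fewer
than 100 significant sites is an error naming the population.

Deconvolution solves `sample ≈ Reference @ w` with w on the probability
simplex. `nnls` is plain non-negative least squares with renormalization.
`robust` is Huber-weighted iteratively reweighted least squares whose inner
solve is itself NNLS, so the iterate never leaves the constraint set;
truncating negatives only after an unconstrained fit was measurably worse
(simplex-corner bias under the near-collinear synthetic reference). Residual
norm is reported; a collinear reference triggers a warning and a small ridge
augmentation. Validation purity (~94–95% self-weight at noise sd 0.05) is
structurally limited by reference-entry noise (population means over 5
replicates) and the one-sided noise geometry at the simplex corner, not by
the optimizer.

## Copy number

Per-probe log2(sample/reference) against the matched control reference —
female/male references average fresh controls of that sex, the FFPE reference
averages FFPE controls, and FFPE trumps sex when both apply — then
median-centering on autosomal probes, which removes uniform intensity shifts.
Probes are combined into fixed-width genomic bins (default 100 kb synthetic)
merged rightward until each holds ≥ 15 probes; the bin value is the mean
ratio.

Segmentation is circular binary segmentation per chromosome: the maximal
pooled-variance two-sample |t| over all contiguous arcs versus their
complement, assessed by a seeded permutation test (default α = 0.01, 10,000
permutations, vectorized in chunks with early stopping once non-significance
is certain), recursing on the resulting pieces. A minimum-width rule excludes
cuts that would create a piece shorter than 3 bins (empty flanks allowed) —
enforcing the minimum during the scan rather than merging afterwards, since
post-hoc merging of a short but genuinely distinct flank into an altered
neighbor dilutes the segment mean. Calls are strict: gain above +0.1, loss
below −0.1. Chromosomal instability is the fraction of bins with |value|
strictly above 0.1; the cohort figure is the mean over samples. Cohort
frequency assigns each grid bin the call of the segment containing its
midpoint.

## Synteny enrichment

Syntenic human bins are those whose midpoint falls in any block mapped from
the mouse chromosome of interest; sex chromosomes are excluded by default
(their copy-number reference is sex-dependent). The per-patient score is
direction-specific — a mouse gain is tested against human gains — with a
combined gain+loss mode exposed; it is the percentage of syntenic bins
altered minus the percentage of all bins altered, hence bounded by ±100 and
antitone in the background rate. Cohorts are compared with a one-sided Welch
t-test (pooled-variance flavor available); the final enrichment score is
mean(target) − mean(reference). The reference cohort builder draws a seeded
fixed number of patients (default 3) per non-target entity. Calibration and
power of the statistic are checked by simulation (type-I error ≈ 5% at
α = 0.05 over 1,000 null cohorts; ≥ 80% power at a 2× planted enrichment with
10 patients per cohort).

## Problem sizes

Tests run on scaled-down cohorts chosen to keep the statistical properties
identifiable: 3,000–10,000 probes, 4–10 classes, 3–5 replicates; the CNA
recovery suite uses 4 × 100 Mb chromosomes at 500 probes each with planted
segments of ≥ 150 probes; the acceptance study runs at the full stated
construction (50,000 probes, 10 populations × 5 replicates). The
embedding-stability default of 500 iterations is a config value; tests and
examples use 5–10 iterations since each iteration is a full UMAP fit.

## Known limitations

* The moderated statistic assumes approximately Gaussian beta noise; near the
  0/1 boundaries betas are heteroskedastic and clipped, which the generator
  reproduces but the test does not model (no logit/M-value transform).
* CBS permutation p-values are exchangeability-based; heavy autocorrelation
  within chromosomes (not simulated) would inflate splits.
* The binomial matching null treats samples within a model as independent
  trials; correlated replicates of one mouse model make it anti-conservative
  in that respect.
* Deconvolution assumes the reference spans the bulk's constituents; unknown
  populations are out of scope.
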