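# Methods

This note documents the models and procedures implemented in `rfaclust`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that make runs
bit-reproducible.

## Data model

A cohort is a `BiomarkerDataset`: a participants × markers concentration
matrix, marker metadata (functional pathway, baseline-vs-candidate panel
flag, and an integer rank fixing the order in which the cumulative
strategy tries candidates), and participant metadata (site/cohort label,
assay plate, age, sex, BMI, smoking category, dyslipidaemia, the binary
composite vascular phenotype with its hypertension/event components, and a
continuous 10-year risk score in (0, 100) consumed as given — the package
never computes pooled-cohort-equation scores).

## Preprocessing

The canonical chain is **impute → log → ComBat → scale**. The ordering is
a design choice: batch correction operates on the log scale (standard for
positive-valued assay data), and scaling runs last so the clustering input
has exactly unit variance per marker. The chain is configurable.

* **Imputation** — multiple imputation by chained equations, default m = 5
  completions of 50 cycles each. Continuous variables use predictive mean
  matching: each incomplete variable is regressed (OLS) on all others,
  each missing entry takes the observed value of a donor drawn from the
  `k_donors = 5` observed rows with closest predicted mean. Categorical
  variables use a single-tree CART draw (fit on observed rows, sample
  uniformly from the donor leaf). Markers with ≥ 10 % missing data are
  rejected rather than imputed. Downstream stages consume the first
  completion by default (`completion={"first","average",index}`); pooling
  cluster labels across completions is undefined, so no Rubin-rules
  machinery is provided. The matching is type-1 (no posterior draw of the
  regression coefficients); with m completions driven by independent donor
  draws this is a mild simplification that leaves between-imputation
  variability slightly understated.
* **ComBat** — parametric empirical-Bayes location/scale adjustment: markers
  are standardised against batch-mean-adjusted pooled variances, per-batch
  locations and scales are shrunk towards cross-marker priors (normal and
  inverse-gamma, moment-matched hyperparameters, iterative conditional
  update to 1e-4), effects removed, overall location/scale restored. The
  implementation matches the Bioconductor `sva` reference to ~1e-15 on a
  frozen fixture (tests/data). Note one consequence of the reference
  estimator's conventions: because per-batch variances use ddof = 1 while
  the pooled variance uses ddof = 0, even two *identical* batches receive a
  small uniform shrink (a few percent) — there is no differential
  between-batch adjustment, but output is not bit-identical to input.
  Singleton batches are an error; a single batch is the identity (with a
  warning).
* **Log/scale** — natural log with a per-marker offset of 0 (all values
  positive) or half the smallest positive value (zero-tolerant,
  deterministic), then centre/scale to mean 0, SD 1. Constant markers are
  an error naming the marker. Parameters are recorded so held-out rows can
  be transformed identically.

## Clustering

PCA (full SVD, deterministic sign convention: the largest-|loading| entry
of each component is positive) retains the smallest prefix of components
whose cumulative explained variance reaches 0.70; `n_components` can
override the threshold. Ward's minimum-variance method runs on the scores;
merge heights are stored directly as within-inertia gains (scipy's
Euclidean merge distances squared and halved), so the heights sum to the
total inertia of the score matrix — a convenient identity that the tests
assert.

The cluster count maximises the relative inertia-gain ratio
Δ(k)/Δ(k+1) over k ∈ [2, 6], where Δ(k) is the between-cluster inertia
gained by splitting k−1 clusters into k (the height of the corresponding
merge). Ties break toward smaller k; a zero denominator with a positive
numerator counts as +∞ (perfect separation at that k). Labels are
renumbered 1..k by decreasing cluster size, so "cluster k" is always the
smallest (in the applications of interest, the most inflamed) group. No
k-means consolidation follows the tree cut.

Cluster profiles use the v-test with the *population* variance of the
(already standardised) matrix, so worked examples are closed-form;
significance uses the two-sided normal quantile at α = 0.05 by default.

## Separability oracle

A random forest (default 500 trees) predicts the fixed baseline cluster
labels from a candidate panel. Data are split 70/30 with per-class counts
rounded to the nearest integer (never emptying either side), `mtry` is
tuned by stratified 3-fold CV over {⌊√p⌋−1, ⌊√p⌋, ⌊√p⌋+1} (clipped to
[1, p]); the held-out set is used only for final evaluation. Reported:
accuracy, Cohen's κ (from the confusion matrix; 0 in the degenerate
single-class case), and permutation importance (test-set shuffles, 10
repeats, negatives floored at 0, normalised to sum to 100 %; if nothing
moves accuracy the share is spread uniformly over non-constant markers).
`compute_importance=False` skips the permutation pass where only
accuracy/κ are consumed (greedy search, frequency resampling).

κ ≤ accuracy is *not* an invariant and is not asserted; κ = 1 iff the
confusion matrix is diagonal.

## Selection strategies

All strategies hold the baseline panel and the baseline cluster labels
fixed; candidates never displace baseline markers.

* **Model 1 (cumulative)** — candidates tried one at a time in their fixed
  rank order; a candidate is retained, and stays in the panel for later
  steps, iff the expanded panel exceeds accuracy 0.80 and κ 0.65
  (strictly) and the candidate's importance share is at least the uniform
  share 100/p of the evaluated panel (configurable; the uniform share is
  the natural "beats an equal split" default).
* **Model 2 (independent)** — each candidate judged on baseline + {candidate}
  alone under the same three thresholds; the retained set is invariant to
  evaluation order (asserted in tests).
* **Model 3 (greedy bidirectional)** — forward: add the candidate with the
  greatest strict held-out-accuracy improvement (ties: higher κ, then
  lexicographic marker id); backward: remove any previously added marker
  whose removal strictly improves accuracy; cycle until a full pass
  changes nothing, with a hard cap of 2 × |candidates| rounds. Accuracy is
  the primary metric with κ as tiebreak, matching the reporting of the
  greedy path as an accuracy trace.

**Selection frequency** — over n = 50 fresh stratified splits (iteration
seeds derived from a master seed), a candidate counts as selected when its
panel strictly improves *both* accuracy and κ over that iteration's
baseline (Models 1–2; for Model 1 a passing candidate joins the panel for
later candidates within the iteration) or when it survives the full
greedy path (Model 3). The improvement threshold defaults to strictly
greater than zero and is configurable.

## Stability and cohort effects

Bootstrap re-clustering resamples participants with replacement to the
original size, reruns the identical pipeline (same parameter fingerprint),
and scores the Adjusted Rand Index against the original assignments over
the participants drawn in that iteration — duplicated draws collapse to
the label of their first occurrence; undrawn participants are excluded
from that iteration's ARI. Iterations whose chosen k differs from the
original are *not* failures (k is recorded); iterations that raise are
counted as failures, and ≥ 50 % failures aborts. The summary (median,
mean, SD, min, max, IQR) is recomputable from the stored ARI values.

Cohort effects: Pearson chi-squared (no continuity correction) on the
cluster × cohort table, plus one-way ANOVA of each retained component
score on cohort with the between-cohort variance fraction.

## Outcome associations

Logistic regression (Newton, tolerance 1e-10) of the binary outcome on
cluster indicators, reference = the "uninflamed" cluster, identified
automatically as the cluster with the lowest mean v over
systemic-inflammation-pathway markers (overridable). Adjusted models add
age, sex, BMI, smoking collapsed to ever/never, and dyslipidaemia. ORs
carry 95 % profile-likelihood intervals: the likelihood-ratio statistic
for each cluster coefficient is inverted at the χ²₁ 0.95 quantile by
stepping out from the MLE and bisecting to 1e-6 on the coefficient scale
(the nested fits absorb the coefficient as an offset). |coefficient| > 15
is treated as separation and raises. The stratified bootstrap resamples
cases and controls separately with their original counts (preserving
prevalence), refits with Wald machinery for speed, drops and counts
failed refits (> 20 % is an error), and reports medians, percentile
intervals and the proportion of iterations with OR > 1. The continuous
risk score is compared as exp(OLS coefficients of log score on cluster
indicators) — unadjusted by design, since the score already encodes the
covariates — and by the tie-corrected Kruskal–Wallis test (all values
tied returns p = 1 by convention).

## Synthetic cohorts

The generator emulates the study setting: 408 participants, 55 markers
(24 baseline + 31 candidates with a fixed addition order), three latent
clusters with proportions (0.45, 0.45, 0.10), three sites with proportions
(0.27, 0.60, 0.13), four assay plates, < 10 % missingness (MCAR per
marker; the mechanism is a convention, not a reproduction). Markers are
drawn on the log scale — per-cluster mean shifts in SD units on a
block-correlated Gaussian (shared factor per pathway block, within-block
correlation 0.3) — then exponentiated; plate effects are applied as
location/scale perturbations on the log scale (shift SD 0.2, scale SD
0.05), i.e. multiplicatively on concentrations. Because generation is
log-Gaussian, the pipeline's log transform exactly normalises the data and
parameter-recovery tests are sharp.

The default shift pattern puts 2-SD shifts on all 24 baseline markers and
on the first 6 candidates (cluster 1 half a magnitude below the grand
mean, cluster 2 half above, cluster 3 alternating a full magnitude up and
down across markers), leaving 25 candidates as pure noise. The binary
outcome follows a logistic model with per-cluster log-odds offsets
(0, 0.2, 0.8) — the cluster-3 offset corresponds to a true OR of e^0.8 ≈
2.2 — plus covariate effects (age 0.07/yr, male 0.2, BMI 0.10/kg·m⁻²,
ever-smoker 0.62, dyslipidaemia 0.92 on the log-odds scale, centred
covariates); empirical prevalence matches the model's expectation within
2 points across seeds (asserted). Sites are independent of cluster by
default, so cohort-effect tests are calibrated under the null. The risk
score is a deterministic increasing function of age, smoking and
dyslipidaemia plus log-normal noise, truncated to (0.1, 99.9) — synthetic
and unitless.

Under these defaults the baseline panel separates the clusters
essentially perfectly, so the separability oracle sits at accuracy ≈ 1.0
and *no* candidate can strictly improve it — the right null for
selection-frequency calibration (noise candidates are selected in ~0 % of
iterations). Candidate-recovery studies instead use `headroom_config()`:
1-SD baseline shifts (held-out separability ≈ 0.9, leaving improvement
headroom) with overwhelming 4-SD shifts on the planted candidates, scored
against the true latent labels. Pilot exploration during design showed
that 2-SD candidates in this setting reach selection frequencies of only
0.6–0.9: with a strict zero-improvement threshold, frequency near 1
requires a candidate whose signal dominates split-to-split forest noise,
hence the overwhelming-signal convention for the recovery study.

What the generator does **not** emulate: detection limits and censored
concentrations, plate drift over time, assay-specific noise shapes,
marker–covariate confounding, site-specific marker profiles (available
only through explicit shift matrices), and longitudinal structure.
Passing recovery tests therefore demonstrate correctness of the machinery
under the stated generative model, not performance on real assay data.

## Problem sizes and numerical conventions

Tests and the acceptance script run the full-size cohort (408 × 55) for
cluster-count recovery (50 seeds), bootstrap stability (200 resamples) and
frequency studies (50 iterations, 3 planted + 3 noise candidates, 300
trees without CV tuning); unit tests use a compact 180 × 16 cohort. These
sizes were chosen to keep the full suite inside a half-hour desk run
while leaving the statistical conclusions unchanged — frequencies under
Model 2 are per-candidate quantities, so evaluating a candidate subset is
exact, not an approximation. All randomness flows from explicit seeds
(master seeds spawn per-stage and per-iteration seeds via
`numpy.random.SeedSequence` / seeded `default_rng` streams, kept below
2³¹); reruns at a fixed configuration are byte-identical, and every
tie-break in the package (component signs, cluster renumbering, greedy
selection order) is deterministic.

## Known limitations

* Type-1 PMM (no Bayesian coefficient draw) understates imputation
  uncertainty slightly; irrelevant for the clustering use-case here.
* The profile-likelihood search assumes a unimodal profile (true for
  logistic log-likelihoods) and brackets by geometric step-out; extremely
  flat profiles would be slow before they would be wrong.
* The greedy strategy can cycle add/remove in principle; the hard round
  cap converts pathological oscillation into an explicit error.
* Non-parametric ComBat and penalised logistic fallbacks for separation
  are out of scope; separation raises with a message suggesting the
  remedy.
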