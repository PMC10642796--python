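# Methods

## Scope and data model

The package implements the analysis layer of a connectome-based prediction
study: it starts from per-subject ROI time series (timepoints × ROIs) or
precomputed ROI×ROI connectivity matrices plus a behavioral table, and ends
at cross-validated predictions, permutation p values, network anatomy
tables, and a mediation model. Raw fMRI preprocessing (motion correction,
normalization, denoising, filtering) is upstream of this package and out of
scope.

Connectivity follows the standard convention: Pearson correlation of ROI
time series, Fisher z transform, negative values set to zero (their meaning
in resting-state data is ambiguous and preprocessing-dependent), zero
diagonal. Because atanh is sign-preserving, clipping after the transform is
identical to clipping before it; the implementation fixes the order
(r → z → clip → zero diagonal) purely to pin down bit-level behavior.
Perfect correlations are clamped at |r| = 1 − 1e−7 before atanh so z stays
finite; synthetic data can produce exact collinearity. All modules share
one edge enumeration — the 0-based row-major upper triangle — and
vectorize/devectorize are exact inverses.

## The CPM protocol

Edge screening uses the Pearson correlation of each edge with the score in
the training subjects and a strict two-tailed threshold p < α (default
α = 0.01), split by sign into a positive and a negative network. The two
networks are always modeled and evaluated separately. Network strength is
the unweighted sum of a subject's edge values over the selected set, and
the prediction model is an OLS line of score on strength. Within the
cross-validation hot path, the p < α screen is applied as the exact
algebraic equivalent |r| > r_crit with r_crit = sqrt(t²/(t² + df)),
t = t-quantile(1 − α/2, df), df = n_train − 2 — identical decisions without
per-edge distribution-function calls.

Degenerate folds are a normal occurrence on null-like data: when a training
fold selects no edges (or strengths are constant), the model predicts the
training mean for that fold, a warning is logged once per run, and the
pipeline continues. This keeps permutation reruns well-defined.

LOOCV fits N models on N−1 subjects each. The implementation computes all N
iterations as dense array algebra (leave-one-out sums are whole-sample sums
minus the held-out row; per-iteration strengths come from one
edges @ masks.T product per sign). The test suite verifies this path is
numerically identical (≤1e−10) to refitting the `CPMRegressor` estimator on
every sklearn `LeaveOneOut` split. Repeated k-fold CV (default k = 10,
100 repeats) draws a fresh near-equal partition per repeat from a child
seed, and reports the arithmetic mean of the per-repeat r and p values
(a Fisher-z mean for r is available). The averaged p is descriptive only;
inference comes from the permutation test. The consensus network is the
intersection of every per-iteration selection mask; its edge weight, where
needed, is the mean training-set r across iterations (the full-sample r is
available as an option).

The permutation test shuffles the scores and reruns the full
cross-validated pipeline — selection, fit, prediction, evaluation — per
permutation (default 1,000), the standard CPM null. p_perm is the fraction
of null r values strictly greater than the observed r; a
(count+1)/(n_perm+1) variant is exposed but not the default, matching the
plain-fraction definition. A cheap label-shuffle-only mode (re-correlating
fixed predictions) exists for exploration and is never used for reported
p values. For k-fold, each permutation uses a single repeat rather than
100 — a deliberate tractability deviation; the observed statistic still
uses the full repeat count.

Covariate control (age, sex, mean head motion) is applied at evaluation as
a partial correlation — predicted and observed scores are residualized on
the covariates with an intercept, residuals are correlated, and p uses
N − 2 − q df. Selection itself is not covariate-adjusted by default.

## Network anatomy

Consensus edges are counted per intra-/inter-network pair over the
7-network lookup (VIS, SMN, DAN, SAL, LIM, FPCN, DMN); the 7×7 table is
symmetric and its upper triangle including the diagonal sums to the edge
count. Ranked pair lists label pairs with the later network first
(DMN-SMN, FPCN-VIS), the customary reporting order, with ties broken
lexicographically. Node strength is the sum of |edge–behavior r| over
selected edges incident to an ROI, which satisfies the handshake identity
Σ_v strength(v) = 2 Σ_e |r_e| exactly; top-node rankings break ties by
roi_id.

## Mediation

Simple mediation (single mediator, PROCESS Model 4 structure) via three OLS
regressions: M ~ X (path a), Y ~ X (total c), Y ~ X + M (direct c′ and
path b); indirect effect a·b. On any one fitted sample c = c′ + a·b holds
to machine precision, and the test suite asserts it at 1e−10. Variables are
z-scored before fitting by default so paths are standardized coefficients
(raw-scale mode available); when bootstrapping, standardization is applied
once to the original sample. Inference on a·b uses a percentile bootstrap
over subjects (default 5,000 resamples, 95% interval); BCa is available as
an option. The percentile interval is the default because it is the
simplest method consistent with a plain bootstrapped CI; note that at the
joint null (a = b = 0) the product statistic is second-order degenerate and
the test is conservative — its type-I error sits below the nominal 5%.

If X and M are perfectly collinear the direct and mediator paths are not
separately identified; by convention the shared effect is attributed to the
mediator (c′ = 0, b from Y ~ M), so a perfect chain X→M→Y yields
a = b = c = 1, c′ = 0 on standardized data.

In the pipeline, M is each subject's summed FC over the consensus negative
network from the chosen CV scheme (LOOCV by default), X the rejection
score, Y the rumination score.

## Synthetic cohorts

The generator emulates the study's data model so every stage has a
recoverable ground truth. Latent structure per subject: X ~ N(0,1);
M = a·X + ε (Var M = 1); Y = c′·X + b·M + ε (Var Y = 1). Defaults
a = b = −0.5, c′ = 0.2 — higher rejection, weaker network, more rumination —
giving population cor(X, Y) = c′ + a·b = 0.45. Edge values are
baseline μ = 0.3 plus N(0, 0.1²) noise; a planted subset (default 30 of
1,770) additionally loads on M with coefficient λ chosen so that the
population edge–rumination correlation hits a target ρ (default −0.3).
With κ = Cov(M, Y) = c′·a + b, the correlation is
λκ/√(λ² + σ²), so λ = σρ·sign(κ)/√(κ² − ρ²), which requires |ρ| < |κ|: an
edge cannot correlate with the outcome more strongly than the mediator
carrying its signal. Effects enter edges only through M, so "network
strength mediates X→Y" is true by construction. Negative draws are clipped
to zero (≈0.1% of values at the defaults; the Monte-Carlo calibration test
absorbs this). A null generator keeps all marginals but zeroes every path
and loading.

Behavioral columns are cosmetic affine maps of the latent scores to
questionnaire-like ranges (rumination 25 + 5Y, mimicking a 10-item
two-subscale total; rejection 20 + 6X, mimicking an 8-item scale), recorded
in the `truth` sidecar. Covariates (age ≈ N(19.3, 1.3), ~72% female,
mean framewise displacement < 0.3 mm) are independent of everything, so
covariate control should not change conclusions on synthetic data.

What the generator does **not** emulate: temporal autocorrelation of BOLD,
motion artifacts, spatial atlas geometry, edge–edge dependence beyond the
single latent factor, or heavy-tailed questionnaire distributions. Passing
tests therefore demonstrate the correctness and calibration of the
machinery, not expected effect sizes on real cohorts; time series are not
simulated (matrix construction is tested against directly constructed
series instead).

## Default study conditions and problem sizes

Reference conditions used across the test and acceptance suites: cohorts of
300 subjects with 60 ROIs (1,770 edges) and 30 planted edges at ρ = −0.3;
permutation calibration uses 100 null cohorts of 120 subjects × 30 ROIs
with 200 full-pipeline permutations each; mediation recovery uses N = 500
with 1,000 bootstrap draws per simulation. These sizes were chosen to make
the stochastic properties (selection type-I error in the binomial 99%
band, permutation rejection rate near 5%, bootstrap coverage ≥ 95%
nominal, planted-edge sensitivity and false-positive rate) measurable with
tight Monte-Carlo error on a single CPU.

## Numerical conventions

- Strict inequality at the selection threshold (p < α, not ≤).
- Constant edges get r = 0, p = 1; they are never selected.
- Pearson r values are clipped to [−1, 1] after computation to absorb
  floating-point excursions; two-tailed p via the t transform with n − 2 df.
- Variance guards are relative (var > max(sum-of-squares, 1)·1e−12) because
  centered sums of squares lose precision for near-constant vectors.
- Every stochastic operation takes an explicit seed; k-fold partitions and
  pipeline stages derive child seeds from one master `SeedSequence`, so a
  config reproduces its report bit-for-bit (timestamps aside).

## Known limitations

- Strength-based CPM only; no multivariate (ridge/lasso) edge models.
- No 17-network variant, no site/scanner harmonization, no NIfTI handling.
- The averaged k-fold p is reported verbatim as a descriptive quantity; its
  sampling distribution under repetition is not standard.
- Bootstrap mediation assumes iid subjects; no moderated or multiple
  mediation, no causal sensitivity analysis.
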