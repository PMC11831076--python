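# Methods

## Scope and data model

`memconn` implements individual-level prediction of episodic memory from
whole-brain resting-state functional connectivity (FC), for cohorts on the
order of 50–100 subjects with ~90-node parcellations. The package operates
on regional mean time series or ready-made FC matrices; voxel-level
preprocessing (realignment, normalization, segmentation) is out of scope
and assumed done upstream.

A subject's connectome is the symmetric matrix of Fisher-z-transformed
Pearson correlations between regional time series. The canonical feature
vector is the strict upper triangle in row-major order with 0-based node
ids — a fixed convention so that weight vectors, truth records and reports
always align; for 90 nodes this gives 4005 edge features. Optional scalar
features (e.g. hippocampal volume) are appended after the edge block and
scaled together with the edges.

## Time-series processing

`detrend_and_bandpass` removes each node's linear trend and applies a
third-order Butterworth band-pass (default 0.01–0.1 Hz at TR = 2 s) run
forward and backward (`sosfiltfilt`), i.e. an effectively sixth-order
zero-phase filter. Measured on sinusoids, mid-band amplitudes are preserved
within ~2% and a 0.2 Hz tone is attenuated by ~98%. `regress_nuisance`
projects each regional series onto the complement of [1, regressors] by
least squares; the paper-like pipeline uses ten regressors (global, three
tissue-like, six motion-like). Nuisance regression at the regional level is
an approximation to voxelwise regression followed by averaging — the two
differ in general, but only regional series exist at this scale.
Correlations of ±1 are clamped at |r| = 1 − 1e-7 before `atanh` so
degenerate inputs cannot inject infinities.

## Relevance vector regression

The regression engine is the standard sparse Bayesian linear model on the
kernel design Φ = [1, K], K = X Xᵀ over caller-scaled features, trained by
type-II maximum likelihood with MacKay fixed-point updates
(α_i ← γ_i/μ_i², σ² ← RSS/(N − Σγ)) and pruning of basis columns whose
precision exceeds 1e9. The bias column is unpenalized (α₀ = 0) by default;
a config switch makes it an ordinary updatable column, which is also the
variant under which the logged marginal likelihood is a proper quantity
(an improper flat bias prior has no finite evidence). Kernel centring is
available but off by default. Defaults: α init 1, σ² init 0.1 × var(y),
tolerance 1e-6 on max |Δ log α|, at most 1000 iterations, σ² floored at
1e-12.

Numerical implementation (identical model and fixed points; these choices
only affect how, and how fast, the optimum is reached):

- Each iteration factorizes H = A + σ⁻²ΦᵀΦ by Cholesky and materializes
  only μ, diag(Σ) and log|H| — never a full inverse. H is positive
  definite whenever at most the bias precision is zero. Pivots are floored
  *relative* to the largest diagonal entry (1e-13 × max), which near the
  interpolation limit acts as the smallest jitter keeping the solve
  bounded.
- On ill-conditioned kernels σ² first collapses (the unconverged posterior
  interpolates) and then recovers geometrically over hundreds of
  iterations. When consecutive log-σ² steps show a stable geometric ratio
  during such an upward recovery, the iteration Aitken-extrapolates to the
  predicted limit (guarded, with a cooldown); downward crashes are never
  extrapolated.
- MacKay updates can enter limit cycles that oscillate above the tolerance
  forever (observed directly on permutation-null fits). A stagnation
  detector stops the fit when max |Δ log α| has set no new minimum for 40
  consecutive iterations and flags the model non-converged; the posterior
  at that point is a well-defined dense fit and predictions remain valid.
  Cross-validation records the count of non-converged folds rather than
  failing.
- The cross-validated permutation machinery re-fits the same design for
  hundreds of target vectors, so fold designs (scaling, kernel, ΦᵀΦ) are
  cached once per fold and the fit loop is compiled (numba). A single fit
  at n ≈ 50 costs ~1–2 ms.

Kernel trace-normalization was evaluated and rejected: on this problem
class it moves evidence maximization into a very sparse basin that
underfits badly (cross-validated r near 0 on cohorts with planted signal),
whereas the weakly-regularized basin reached from the defaults attains the
expected accuracy. The evidence surface is genuinely multimodal here; the
defaults select the basin with predictive value.

With the linear kernel, primal per-feature weights are recovered as
w = Σ_i μ_i x_i over the relevance vectors; primal-form and kernel-form
predictions agree to numerical precision (enforced by test). Fits are
deterministic given inputs; row-permuting the training set permutes the
relevance set identically and changes predictions only at BLAS
summation-order level (~1e-10).

## Prediction framework

Features are scaled to [0, 1] per feature with minima/maxima learned from
the training subjects of each fold only; test values are deliberately not
clipped, and a constant training feature maps to 0 everywhere. LOOCV fits
N models on N−1 subjects each. Repeated k-fold (default 10-fold × 100)
partitions the cohort at random per repeat (fold sizes within 1), computes
per-repeat r and MAE on that repeat's full prediction vector, and reports
the mean over repeats (a pooled-predictions alternative is available by
flag). Setting k = N reproduces LOOCV exactly.

Accuracy is Pearson r and MAE between actual and predicted scores, plus a
partial r computed by residualizing both vectors on [1, covariates]
(age, sex, education by default; a baseline score can be added). Covariate
adjustment is evaluation-only — training targets are never residualized.
If a prediction vector is constant its r is defined as 0.

The permutation test permutes the target vector across the whole cohort
once per repetition (without replacement), re-runs the complete
cross-validation, and counts null metrics at least as good as the observed
one: p_r = #(r_null ≥ r_obs)/n_perm, p_MAE = #(MAE_null ≤ MAE_obs)/n_perm.
Ties count against the observed value (a strict-inequality variant exists
by flag); no add-one smoothing is applied and a zero count is reported as
a bound (< 1/n_perm). A negative observed r is never significant under
this one-sided convention. The composite episodic memory score is the
arithmetic mean of AVLT-DR, LMT-DR and CFT-DR (a two-test variant without
AVLT-DR is provided).

## Interpretation of weights

Primal weights from the LOOCV fold models are averaged element-wise (mean
and mean absolute value); a full-data refit is available by flag. Edges
are ranked by mean |w|; the top-percent count rounds half away from zero
with a minimum of one, so 1% of 4005 → 40 and 10% of 4005 → 401. Ties at
the cut break deterministically by canonical edge order. Selected edges
are tabulated by unordered module pair (within-module flagged) and by
anatomical length, long-range meaning strictly greater than 75 mm between
centroids. Multiplying all weights by a positive constant leaves the
selection unchanged.

## Synthetic cohorts

The generator emulates the statistical structure this analysis assumes,
not the biophysics of BOLD. Per-subject z-FC edges follow

    z_e(s) = μ_e + (B f_s)_e + ε_es + [e ∈ S] η_es,

with per-edge cohort means μ_e ~ N(0.25, 0.25²); a low-rank factor model
(20 subject factors, factor k scaled 0.1/√k, loadings i.i.d. normal)
shared across all edges; i.i.d. residual SD 0.03; and, on the signal edges
S, extra subject variation of SD 0.15 correlated within 2 groups
(within-group correlation 0.5). The factor structure mimics the dominant
subject-level components of real connectomes (global connectivity
strength, arousal, residual motion) and is what keeps the effective
dimensionality of a 4005-edge space low enough for kernel regression to
work at n ≈ 50; the grouped signal mimics a coherently co-varying
(degenerating) subsystem. Both features are essential, not cosmetic: with
fully independent edge noise a 40-edge sparse signal sits below the
feature-noise floor and no non-sparse learner can recover it at these
sample sizes (verified against a tuned kernel-ridge oracle).

Scores follow y = b0 + Σ_e β_e z_e + γ_age(age − 68) + γ_edu(edu − 11.9) +
γ_sex(sex − 0.6) + ε with defaults b0 = 2.5, γ = (−0.05, +0.08, −0.2),
noise SD 1.0. Covariates: age 68.0 ± 7.3 y, education 11.9 ± 3.4 y, sex
Bernoulli(0.6) coded 1 = male — a typical aMCI cohort profile. Companion
LMT-DR and CFT-DR scores are generated correlated with the primary score
(0.6 and 0.5) on their natural scales, and the composite column is their
three-test mean. Scores are untruncated Gaussian by default to keep
linear-recovery tests clean; clipping to a plausible AVLT-DR range [0, 12]
is available on request. Optional extra features (e.g. hippocampal volume)
are generated with a requested score correlation.

The edge→score effect size has no empirical anchor and is an arbitrary
scale; the default 0.45 per unit z was calibrated once so that, with 40
signal edges, leave-one-out accuracy lands near r ≈ 0.5 at n = 50 (and
~0.5–0.7 at n = 100) — the operating point at which such analyses are
scientifically interesting. Setting all effect sizes to zero (or passing
no signal edges) gives the null regime.

In `timeseries` mode each subject's target correlation matrix tanh(z) is
projected to the nearest positive-definite correlation matrix (eigenvalue
clipping at 1e-4, rescaled diagonal) and realized as multivariate-normal
series; FC is then *recomputed* from the realized series and the score is
computed from those realized edges, so the linear truth stays exact while
the whole connectome stage is exercised. Nuisance contamination adds ten
regressors (global + 3 tissue-like smooth signals + 6 motion-like random
walks) with random node loadings; because the injection lies exactly in
the regressor span, least-squares clean-up removes it to numerical
precision. The generator does not emulate haemodynamics, spatial
smoothing, volume-level motion, or amyloid/tau biology — so passing tests
demonstrate statistical correctness of the pipeline, not performance on
real scanners.

Cohorts are bit-reproducible from their seed; seeds are mandatory for
every stochastic stage throughout the package (a missing seed is an
error).

## Validation studies run by the test suite

- Type-I error: 200 independent null cohorts (n = 50, 90 nodes, default
  generator, no signal), each analysed by LOOCV RVR with a 19-permutation
  label test; the empirical rate of p ≤ 0.05 must lie in [0.02, 0.09].
  With 19 permutations the rejection event "p ≤ 0.05" is exactly the event
  "no null metric reaches the observed one", which has probability 1/20
  under exchangeability — the same Bernoulli rate as with any longer
  permutation run — so the study size was chosen for runtime without
  changing what is being tested.
- Signal recovery: one 100-subject cohort with 40 planted default-mode/
  limbic edges at the calibrated SNR; LOOCV r must exceed the 95th
  percentile of a 39-permutation null, and the top-1% edge selection must
  be enriched for the planted edges at hypergeometric p < 0.01.
- Exactness: with frozen uniform hyperparameters the fit equals the
  closed-form kernel ridge solution (both an explicit matrix oracle and
  scikit-learn's dual solver) within 1e-8; primal and kernel predictions
  agree within 1e-8.
- Leakage and determinism: corrupting a held-out subject's features
  changes neither its fold's scaling parameters nor its fitted model;
  seeded pipeline runs produce byte-identical result files.

## Known limitations

- The evidence surface of RVR on near-singular kernels is multimodal; the
  reached basin depends on initialization (defaults documented above), and
  a fraction of fits terminate via the stagnation detector rather than the
  tolerance. Their posteriors are valid but carry a non-convergence flag.
- The generator's factor structure is stylized; real-data effective
  dimensionality, site effects and score floor/ceiling effects are not
  modelled.
- Atlas centroids and module assignments are synthetic stand-ins; analyses
  of real data must supply an authoritative node table (TSV: node_id,
  label, abbrev, module, x, y, z).
- Repeated k-fold at its full default (10-fold × 100 with 1000
  permutations) is computationally heavy; the test suite exercises reduced
  sizes and the defaults are intended for one-off analyses.
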