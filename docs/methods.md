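# Methods

This note documents the statistical model behind each pipeline stage, the
numerical choices made in the implementation, and the realism and limitations
of the synthetic data generator.

## 1. Synthetic data generator

### Population model

A participant has five matching covariates and 22 subscale scores.

Covariates are drawn from survey-like marginals: age ~ Normal(16.2, 1.24)
truncated to [14, 19] and rounded to 0.01; sex ~ Bernoulli(0.49) (1 = girl);
household registration ~ Categorical(city 0.487, township 0.416, other city
0.063, other province 0.034); only-child ~ Bernoulli(0.51); paternal
drunkenness ~ Bernoulli(0.10).

Exposure is assigned by a logistic model on (intercept, age − 16.2, sex,
three registration dummies, only-child, paternal drunkenness) with default
coefficients `(-2.27, 0.20, 0.45, -0.50, -0.70, -0.90, -0.55, 0.85)`. The
intercept is calibrated to ~8.5% population prevalence. The slope magnitudes
are set so every covariate carries a true pre-match standardized mean
difference of roughly 0.2–0.3 — the top of the plausible survey range, and
deliberately at least four standard errors above the post-match sampling
noise floor `sqrt(2/766) ≈ 0.05` at the default group size, so that matching
has unambiguous work to do on every covariate. Weaker, borderline-significant
confounding (SMD ≈ 0.05–0.1, which real surveys do report) would make
"matching strictly improves every covariate" a coin flip at this sample size;
see the limitations below.

Given exposure group g, the 22 scores are multivariate normal: standardized
draws with correlation `corr(inv(K_g))` from the group's planted precision
matrix `K_g`, scaled by the group's SD profile and shifted by the group's
mean profile. The default profiles use realistic two-group summary statistics
for all 22 subscales (e.g. Somatization 15.98 (6.29) unexposed vs
21.41 (10.18) exposed), with the exposed group scoring higher on every
symptom dimension and lower on every quality-of-life dimension.

### Planted networks

`make_planted_precision` builds a unit-diagonal precision matrix with
requested partial correlations: `K = I − R` where `R` holds the requested
values. Because partial correlations are invariant to diagonal rescaling, a
positive-definite completion with exactly the requested partials exists iff
`I − R` is positive definite; infeasible requests raise an error naming the
strongest edges rather than being silently "repaired".

The default scenario plants, in both groups, first- and second-neighbour
chains within each instrument (SCL chain 0.28, QOL chain 0.26, second
neighbours 0.12) plus four weak cross-instrument bridges. The exposed group
additionally gets nine extra edges and two strengthened ones — most notably
the interpersonal-sensitivity/negative-emotion bridge (SCL3–QOL7: 0.10
unexposed vs 0.35 exposed) — so its network is strictly denser and more
strongly connected.

### Realism and limitations

- Scores are continuous multivariate normal subscale totals, not item-level
  Likert sums; skewness, floors and ceilings of real subscale scores are not
  reproduced. Real symptom scores are right-skewed; normality makes the
  Pearson-correlation input exactly correct here, which flatters the
  estimator relative to real data.
- The two groups' mean/SD profiles and their network structures are set
  independently; in real data, group mean differences and covariance
  differences arise from one joint process.
- Exposure affects scores only through group membership; there is no
  dose-response or residual confounding between covariates and scores, so
  matching removes all planted confounding by construction.
- Confounding strength is set for detectability (SMD 0.2–0.3), stronger than
  the weakest effects real studies report (age differences of ~0.1 SD).
- The equal-group default (`n_per_group` each) conditionally oversamples the
  exposed group relative to its ~8.5% prevalence; covariate distributions
  within each group are unaffected by this conditioning.

## 2. Propensity-score matching

The propensity model is a logistic regression (statsmodels, Newton, tol 1e-8,
max 100 iterations) of exposure on the five covariates (registration entering
as three dummies against "city"). Rank-deficient designs raise; quasi-separated
fits warn (|standardized coefficient| > 20) and the linear predictor is
clipped to ±30 before the logistic transform.

Matching is greedy 1:1 nearest-neighbour without replacement on the
propensity logit: exposed units are processed in descending propensity order,
each taking the closest unmatched control within the caliper
(0.2 × SD of the logit over the full sample, the conventional multiplier).
Ties go to the lowest control id, which makes the procedure deterministic —
no random number is consumed. Unmatched exposed units are dropped and listed.

Balance diagnostics: standardized mean difference with the pooled-SD
denominator `sqrt((s1² + s0²)/2)`; Welch's t-test for age; Pearson chi-square
without continuity correction for the binary covariates and one 2×4 test for
registration (whose reported SMD is the largest absolute level-wise SMD).
Summary-statistic Welch tests (from printed means/SDs/n) use the
Welch–Satterthwaite degrees of freedom.

## 3. Network estimation

Columns are z-scored; the input is the Pearson correlation matrix S. The
graphical lasso maximizes `log det K − tr(SK) − λ‖K_off‖₁` with the penalty
on off-diagonal precision entries only, so fitted covariance diagonals equal
`S_jj` exactly. The solver is a numba-compiled block coordinate descent over
columns, each column solved by lasso coordinate descent on the dual; outer
tolerance is the mean absolute change of the working covariance (default
1e-6, max 500 sweeps), inner tolerance 1e-8-scaled. The λ-path sweep reuses
the previous solution as a warm start. Correctness is certified in the tests
two ways: against closed forms (λ = 0 gives `inv(S)`; λ above the largest
absolute off-diagonal correlation gives an empty graph), and against
scikit-learn's independent implementation within 1e-4 — granting the oracle
its own achieved KKT accuracy where it stops short of convergence — plus a
direct check that our solutions satisfy the stationarity conditions to 1e-8.

Model selection: 100 log-spaced penalties from `λ_max = max|S_ij|` down to
`0.01 λ_max`; the selected model minimizes
`EBIC = −2ℓ + E log n + 4γ E log p` with `ℓ = (n/2)(log det K − tr(SK))`,
`E` the number of nonzero upper-triangle precision entries, and γ = 0.5
(the conservative conventional value; γ = 0 recovers BIC).

Edge weights are partial correlations `−K_ij / sqrt(K_ii K_jj)`. Node
predictability is `R²_i = 1 − 1/K_ii`, valid because the data are
standardized; it equals the R² of nodewise least-squares regression when
λ = 0 (verified in the tests).

Small-sample behaviour worth knowing: with n a few hundred and chain-like
correlation ≈ 0.2, EBIC at γ = 0.5 can legitimately select the empty graph —
the criterion is bistable between "empty" and "chains" near that boundary.
This is a property of EBIC, not a solver failure.

## 4. Centrality

Strength `Σ_j |w_ij|`; one-step expected influence `Σ_j w_ij` (signed);
bridge expected influence `Σ_{j ∉ community(i)} w_ij` (signed, cross-community
only). The table also carries z-standardized versions (population SD over the
22 nodes). Ranking sorts descending with ties broken by node order.

## 5. Resampling diagnostics

Edge accuracy: nonparametric row bootstrap (B ≥ 100 enforced) with a full
EBIC-glasso refit per resample; 95% CIs are type-7 quantiles of the replicate
edge weights.

Centrality stability: case-dropping bootstrap over the proportion grid 0.05,
0.10, …, 0.75; at each proportion q, B subsamples of `ceil((1−q)·n)` rows are
refit and their centrality vector is Pearson-correlated with the full-sample
one. Grid points where the retained row count would not exceed the node count
are skipped and reported. The CS coefficient is the largest grid q at which
at least 95% of replicates correlate above 0.7; a linearly interpolated
variant between the last passing and first failing grid point is also
reported (off-grid values such as 0.749 can only arise from interpolation;
the grid value is the primary statistic here).

## 6. Permutation network comparison

Both groups are estimated with the identical EBIC-glasso pipeline. The null
distribution pools all rows and re-splits them at random into the original
group sizes, refitting both networks per permutation (default 2000). Three
tests: network structure `M = max|W₁ − W₂|`; global strength
`S = |‖W₁‖₁ − ‖W₂‖₁|` over upper triangles; and per-edge `|ΔW_ij|` read
against a strict α = 0.001 with no multiple-comparison correction. All
p-values use the finite-sample form `p = (1 + #{perm ≥ obs}) / (1 + n_perm)`,
so the smallest attainable p is `1/(n_perm+1)` — per-edge significance at
α = 0.001 therefore requires at least 1000 permutations. Permutations whose
refit fails are skipped and the effective count reported. Null calibration of
`p_M` is verified in the acceptance tests (type-I error within [0.01, 0.12]
at α = 0.05 over 100 null replicates).

## 7. Pipeline determinism

`run_study` derives independent child seeds for each stochastic stage from
the master seed via `numpy.random.default_rng(seed).integers(2**31)` and logs
them in the run-config artifact; identical configs produce byte-identical
JSON artifacts.
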