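# Methods

This note documents the models, calibrations and numerical choices
behind `ravensim`, in the spirit of a statistical package's model
documentation: what is computed, under which assumptions, and what the
synthetic data do and do not establish.

## The scientific question

Working-memory capacity (WMC) correlates substantially with total
scores on progressive-matrices tests of fluid reasoning, yet several
studies reported that the *item-wise* point-biserial correlations
between WMC and single-item accuracy stay flat as items get harder.
`ravensim` implements the argument that this flatness is an artifact of
a low overall correlation: once the overall WMC x test correlation is
moderate to high, the combination of (a) near-ceiling accuracy on early
items and (b) a fixed, declining item-accuracy profile forces the
item-wise correlation to grow with item difficulty. The package
provides four coordinated instruments: a margin-constrained binary
matrix simulator, an item-wise correlation/slope analysis, an
attenuation bootstrap, and mixed-effects logistic models, plus a
synthetic-cohort generator that stands in for behavioral data.

## Margin-constrained matrix simulation

Each replication draws N = 255 (WMC, Raven's) pairs from a bivariate
normal with means (0.61, 0.55), SDs (0.15, 0.16) and population
correlation rho, truncated to [0, 1] on both axes. Truncation is by
rejection resampling, not clipping: clipping would create probability
atoms at the bounds and distort the tails that point-biserial
correlations load on. At these parameter values the [0, 1] bounds sit
roughly three SDs out, so the realized correlation shrinkage is small
(verified to within +-0.03 in the test suite).

Raven's proportions are converted to integer row-sum targets by
rounding to `round(p * n_items)` and then reconciling the grand total
against the fixed column sums `round(accuracy_j * N)`: the discrepancy
is distributed as +-1 adjustments over subjects drawn without
replacement with probability proportional to their rounding residual.
Row sums are adjusted rather than column sums because the item
accuracies are the fixed empirical anchor of the design.

The binary matrix is generated column by column (easiest item first).
Within a column, exactly `col_sum` subjects are selected without
replacement with probability proportional to their *remaining* quota of
correct answers, the quota of each selected subject is decremented, and
the process repeats on the next column. The without-replacement draw
is implemented by Gumbel-top-k perturbation, which is mathematically
identical to sequential draws with renormalized weights. Two forcing
rules guarantee the margins: subjects whose remaining quota equals the
number of remaining columns are selected unconditionally, and subjects
with quota zero are excluded. Because forcing alone is necessary but
not sufficient, the remaining margins are checked after every column
with the Gale-Ryser inequalities and the column is redrawn on failure
(capped at 100 retries; the realized restart count is recorded on the
returned matrix). Importance weights are deliberately not tracked —
draws are treated as plain replications of the data-generating process,
not as weighted estimates over the fixed-margin ensemble — so the
sampler is *not* uniform over that ensemble, and no such claim is
tested. Exact uniform (swap/MCMC) sampling is out of scope.

### Item-accuracy profile

The original study's per-item accuracies were published only as a
figure. The default reconstruction is a linear decline from 0.95 to
0.15 across 36 items, which reproduces the printed overall mean of 0.55
exactly. The profile is a configuration input (`--accuracy-profile`)
so digitized values can be substituted. This choice matters: the mean
item-wise slope is highly sensitive to profile *shape* (a convex
profile can even flip its sign). With the linear default the sweep
over rho = 0.1 ... 0.9 is strictly monotone and matches the published
slopes in order of magnitude, but the point values come out roughly
twice as large; all profile-dependent numbers should be read as
approximate by construction.

### Slope aggregation

Per replication, the item-wise curve is the per-column Pearson
correlation with the WMC vector (undefined, NaN-marked, when a column
has zero variance; such items are excluded from slope fits rather than
imputed as 0, because imputing 0 fabricates signal at ceiling items).
Both the mean of per-replication OLS slopes (the headline number) and
the slope of the mean curve are reported; for fully defined curves the
two coincide in expectation, and whether the original analysis used one
or the other is not documented. The confidence band is 1.96 times the
across-replication SD per item.

## Attenuation bootstrap

Given a response matrix sorted by the observed composite `zWMC`, each
run draws `zWMC_n = nu * zWMC + eps`, `eps ~ N(0, 1 - nu^2)`, and
re-pairs rows with covariate values by rank (ascending `zWMC_n` rank k
is paired with the k-th smallest actual `zWMC`). The matrix margins
are untouched, so item accuracies and per-subject totals are preserved
exactly while the covariate coupling is attenuated. `zWMC` is
re-standardized to unit variance internally; the additive-noise model
is variance-preserving only under that convention, and under it the
expected achieved correlation is `nu` times the observed correlation.
Rank-pairing was fixed as the re-sorting semantics because it
reproduces the unattenuated data bit-exactly at nu = 1 — the natural
continuity requirement. Ties in `zWMC_n` are broken by original index
order. Note that under this convention the published triple of
achieved correlations is proportional to nu times the observed 0.56
only at nu = 0.95 (0.53); the package treats the two smaller published
values as qualitative anchors (slope decreasing with nu), not as
quantitative targets.

Because the analysis conditions on the *observed* overall correlation,
the driver that feeds the bootstrap selects a synthetic cohort whose
realized (not just expected) composite-total correlation is within 0.01
of 0.56, by rejection over whole cohorts.

## Synthetic cohorts

A cohort is N = 126 subjects with four WMC task scores and 36 binary
item responses. Latent structure: a WMC factor W and an ability factor
theta, bivariate standard normal with correlation c_W; parallel tasks
`task_k = a W + sqrt(1-a^2) e_k`, rescaled to the published task means
and SDs (OSPAN 0.71/0.14, SS 0.70/0.15, SSTM 0.84/0.06, MU 0.66/0.18);
responses from a 2PL-style model `P = logit^{-1}(b_j + c theta)` with
discrimination c = 1 and difficulties b_j solved by quadrature plus
root-finding so each item hits its target marginal accuracy.

The default accuracy profile is a logistic-shaped decline from 0.98
toward 0.15 (width 6 items) whose midpoint is solved so the mean total
score equals 24.47/36, honoring near-ceiling accuracy on the first few
items; the endpoint of the realized profile is therefore ~0.25 rather
than the 0.15 asymptote.

`calibrate_loadings` solves the two moment equations that make one task
and the 4-task composite hit prescribed *latent* validities: with
targets s (single) and c (composite), `a c_W = s` and
`a c_W / sqrt(a^2 + (1-a^2)/4) = c`, with closed-form unique positive
solution (a = 0.4666, c_W = 0.7716 at s = 0.36, c = 0.56). The
published validities, however, are *sample correlations with the
integer total score*, which is an imperfect measure of theta. The
pipeline-level `calibrate_cohort` therefore inflates the targets by two
analytically computed factors before solving: the theta-total
correlation of the calibrated item bank (~0.906 under the defaults,
computed from the item response curves by quadrature) and the O(1/n)
downward bias of a sample correlation at n = 126
(`E[r] ~= rho - rho(1-rho^2)/(2(n-1))`). With both corrections the
mean realized correlations across cohorts match 0.56 / 0.36 to within a
few thousandths; the residual (~0.002) comes from standardizing tasks
by sample moments and is accepted.

Fidelity limits: tasks are Gaussian (the published skewness/kurtosis
are not matched); a single common ability drives all items (no item
factors, no learning across items); response times and session
structure are not modeled. Passing tests therefore certify the
correlational structure the downstream analyses consume, not the full
psychology of the battery.

## Mixed-effects logistic models

The model family is `y_ij ~ Bernoulli(logit^{-1}(x_ij' beta + z_ij'
u_i))` with subject random effects `u_i ~ N(0, D)`, D diagonal. Fixed
terms: intercept, the WMC composite z, item position raised to a power
lambda (psi^lambda), novelty, token counts raised to gamma, and the
z-by-item interactions. The standard model ladder (Models 1-4 and the
token model) is predefined. The printed form of the model equations
mixes token symbols into the position models; the implementation
follows the parameter tables' row structure instead.

Estimation is maximum marginal likelihood. Random-intercept-only
models use adaptive Gauss-Hermite quadrature (15 nodes by default): per
likelihood evaluation, each subject's integrand mode is found by
vectorized Newton iterations and the grid is recentered and rescaled by
the curvature. Multi-dimensional (diagonal) random effects use the
Laplace approximation with per-subject Newton solves. The outer
optimizer is L-BFGS-B over (beta, log sd), started from the plain
logistic fit plus sd = 0.3; a log-sd at its lower bound (-6.5) is
flagged as a boundary fit. Standard errors come from the numerical
observed-information matrix.

Design columns are standardized internally for optimizer conditioning
and the estimates mapped back to the raw predictor scale — an exact
linear reparametrization, so reported coefficients are directly
comparable to conventionally tabulated fits (intercepts refer to
psi^lambda = 0, not to the centered mean). Setting `fix_random_sd=0`
pins the variance components and reduces the fit to plain logistic
regression; this exact reduction is the oracle used in tests, and an
independent cross-check against `lme4::glmer` (nAGQ = 15) is part of
the suite.

BIC is `-2 loglik + df ln(n_obs)` with `n_obs` the total observation
count (subjects x items), consistent with the magnitudes of the
published tables; df counts estimated fixed effects plus variance
components. Ties rank toward fewer parameters.

The White-style non-linearity screen is implemented as a
likelihood-ratio test of logistic(y ~ x) against logistic(y ~ x + x^2 +
x^3) with the added terms standardized, chi-square with 2 df — the
publication names the test but not its concrete form, and this form
matches the printed 2-df statistics. The Box-Tidwell exponent is
estimated iteratively: at each step the main coefficient beta comes
from the base fit on x^lambda and the auxiliary coefficient delta from
the augmented fit adding x^lambda ln x; the first-order expansion gives
the update `lambda <- lambda + delta/beta` (taking beta from the base
fit avoids the near-collinear augmented design destabilizing the
ratio). Steps are clipped to +-2, convergence tolerance 1e-3, maximum
20 iterations. Token analyses accept an arbitrary item subset through
the profiles table, since the historically excluded items are not
enumerated in the source material.

## Problem sizes and tolerances

Monte Carlo sizes were chosen to keep every statistic's Monte Carlo
error well inside its assertion tolerance: 2,000 replications per rho
for the simulation sweep (slope SE ~2e-5), 2,000 bootstrap runs, 1,000
cohorts for calibration checks (SEs ~0.002 on correlations), 50
simulate-refit GLMM cycles, and 200 Box-Tidwell recoveries. The
default `--reps` of the CLI remains 10,000, matching the replication
count of the original analyses. All randomness flows through injected
`numpy` generators; CLI runs record seed, config hash and version in a
manifest for exact replay.

## Known limitations

* The simulation sweep's point values inherit the uncertainty of the
  reconstructed accuracy profile (see above); only monotonicity in rho
  and order of magnitude are robust claims.
* The matrix sampler is sequential-importance-sampling-shaped, not
  uniform over the fixed-margin ensemble; ensemble-average statements
  would require importance weighting that is intentionally omitted.
* The Laplace approximation for multi-dimensional random effects is
  less accurate than quadrature when cluster sizes are small and
  variances large; in this package it is used only for model-structure
  comparisons, which are BIC-dominated by the fixed effects.
* Behavioral-study quantities that depend on the undeposited raw data
  (published parameter tables on real data) are targets for
  parameter-recovery simulations, not reproduction.
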