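# ravensim

Why item-wise correlations between working-memory capacity (WMC) and
progressive-matrices accuracy must grow with item difficulty whenever
the overall WMC x test correlation is moderate to high — as a tested,
reproducible pipeline.

Progressive-matrices tests are built so that accuracy declines steeply
with ordinal item position: early items are solved by >90% of
participants, the last items by <10%. Several studies reported that the
per-item point-biserial correlation r_pb(item_j, WMC) is *flat* across
this difficulty gradient and took that as evidence against
working-memory accounts of matrix reasoning. `ravensim` implements the
counter-argument: the flat pattern is what a *low* overall correlation
rho(WMC, total) looks like under margin constraints, and the item-wise
slope necessarily rises with rho. It is intended for researchers in
individual differences and psychometrics who want to simulate,
re-analyze, or teach this phenomenon.

## What it computes

* **Margin-constrained matrix simulation** — subjects' (WMC, Raven's)
  pairs are drawn from a truncated bivariate normal; binary
  subject x item matrices are generated column-sequentially with
  exactly prescribed row sums (each subject's total correct) and column
  sums (each item's accuracy count), per the Gale–Ryser condition. The
  per-item correlations with WMC and their OLS slope over item position
  are aggregated across replications.
* **Attenuation bootstrap** — starting from an observed (or synthetic)
  matrix, the covariate is degraded as `zWMC_n = nu*zWMC + eps`,
  `eps ~ N(0, 1-nu^2)`, rows are re-paired by rank, and the achieved
  overall correlation and item-wise slope are tracked as functions of
  nu, with all matrix margins preserved exactly.
* **Multilevel logistic models** — random-intercept models
  `logit P(y_ij=1) = b0 + bz*z_i + bpsi*psi_j^lambda +
  bzp*z_i*psi_j^lambda (+ novelty, token terms) + S_i`, fitted by
  adaptive Gauss–Hermite maximum likelihood, with a White-style
  non-linearity screen, Box–Tidwell estimation of lambda, and BIC
  selection of the random-effects structure.
* **Synthetic cohorts** — a 4-task WMC battery plus 36-item responses
  whose task moments, composite validity (r = 0.56 with the total
  score), single-task validity (r = 0.36) and mean total score (24.47)
  are calibrated analytically before any data are drawn.

See `docs/methods.md` for the model details and numerical choices.

## Worked example

```python
import numpy as np
from ravensim import TraitSpec, linear_accuracy_profile, run_simulation

rng = np.random.default_rng(1)
acc = linear_accuracy_profile()          # 36 items, 0.95 declining to 0.15
for rho in (0.1, 0.3, 0.9):
    res = run_simulation(TraitSpec(rho=rho), acc, n_reps=2000, rng=rng)
    print(f"rho={rho:.1f}  mean item-wise slope = {res.mean_slope:.5f}")
```

```
rho=0.1  mean item-wise slope = 0.00040
rho=0.3  mean item-wise slope = 0.00108
rho=0.9  mean item-wise slope = 0.00342
```

The slope of the item-wise correlation function grows monotonically
with the population correlation rho: at rho = 0.1 the curve is nearly
flat (the classic "invariance" pattern), while at rho = 0.9 the later,
harder items correlate far more strongly with WMC than the early ones.
Absolute slope values depend on the reconstructed item-accuracy
profile; monotonicity in rho does not.

The same sweep from the shell:

```sh
ravensim simulate --rho 0.1 --rho 0.3 --rho 0.9 --reps 2000 --seed 1 --out sweep/
```

writes `sweep/itemwise.csv` (per-item mean correlations and 95% band
half-widths), `sweep/summary.csv` (mean slope per rho) and a manifest
with the seed and config hash. Other subcommands: `cohort` (generate a
synthetic battery + responses), `bootstrap` (attenuation analysis of a
matrix CSV), `itemwise` (curve + slope for observed data), `glmm`
(mixed-model fit reported as JSON).

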