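"""Synthetic behavioral cohorts: a 4-task WMC battery plus item responses.

The generator emulates the structure of a working-memory / Raven's
individual-differences study: N subjects complete four WMC tasks
(operation span, sentence span, spatial short-term memory, memory
updating) and a 36-item progressive-matrices test.  The latent model is

* a WMC factor ``W`` and an ability factor ``theta``, bivariate standard
  normal with correlation ``c_W``;
* parallel tasks ``task_k = a * W + sqrt(1 - a^2) * e_k`` rescaled to the
  published task means and SDs;
* item responses from a 2PL-like model
  ``P(correct) = logit^{-1}(b_j + c * theta)`` with difficulties ``b_j``
  calibrated so each item's marginal accuracy hits its target.

``calibrate_loadings`` solves the two moment equations that make a
single task and the 4-task composite hit prescribed validities
simultaneously; ``calibrate_cohort`` additionally disattenuates those
targets for the imperfect coupling between the latent ability and the
integer total score (and for the small-sample bias of a sample
correlation at the cohort size), so that the printed validities are
matched on the observable scale on which they were reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, special

from .margins import ResponseMatrix

__all__ = [
    "NOVEL_ITEMS",
    "CohortSpec",
    "CohortData",
    "calibrate_loadings",
    "calibrate_item_difficulties",
    "calibrate_cohort",
    "generate_cohort",
    "generate_cohort_near_correlation",
    "logistic_accuracy_profile",
    "latent_total_correlation",
]

# Items introducing novel rules or rule combinations (1-based positions).
NOVEL_ITEMS = (2, 10, 14, 16, 18, 21, 25, 28, 30, 31, 35)

_TASK_NAMES = ("OSPAN", "SS", "SSTM", "MU")
_TASK_MEANS = (0.71, 0.70, 0.84, 0.66)
_TASK_SDS = (0.14, 0.15, 0.06, 0.18)

# Gauss-Hermite rule for expectations over the standard-normal ability.
_GH_X, _GH_W = np.polynomial.hermite_e.hermegauss(61)
_GH_W = _GH_W / _GH_W.sum()


def logistic_accuracy_profile(
    n_items: int = 36,
    hi: float = 0.98,
    lo: float = 0.15,
    mean_accuracy: float = 24.47 / 36,
    width: float = 6.0,
) -> np.ndarray:
    """Logistic-shaped declining accuracy profile tuned to a target mean.

    Near-ceiling accuracy on the first few items, a floor at ``lo`` for
    the last ones; the midpoint of the decline is solved so the profile
    mean equals ``mean_accuracy`` (default 24.47/36 correct).
    """
    j = np.arange(1, n_items + 1, dtype=float)

    def profile(mid: float) -> np.ndarray:
        return lo + (hi - lo) / (1.0 + np.exp((j - mid) / width))

    lo_mid, hi_mid = -n_items, 3 * n_items
    mid = optimize.brentq(
        lambda m: profile(m).mean() - mean_accuracy, lo_mid, hi_mid, xtol=1e-10
    )
    return profile(mid)


@dataclass(frozen=True)
class CohortSpec:
    """Generator configuration for one synthetic cohort."""

    n_subjects: int = 126
    n_items: int = 36
    task_names: tuple[str, ...] = _TASK_NAMES
    task_means: tuple[float, ...] = _TASK_MEANS
    task_sds: tuple[float, ...] = _TASK_SDS
    task_loading: float | None = None  # a
    latent_validity: float | None = None  # c_W
    item_discrimination: float = 1.0  # c
    item_accuracy_targets: np.ndarray | None = None
    item_difficulties: np.ndarray | None = None  # b_j, set by calibration
    novelty_items: tuple[int, ...] = NOVEL_ITEMS
    token_counts: np.ndarray | None = None
    target_composite_r: float = 0.56
    target_single_r: float = 0.36

    def __post_init__(self) -> None:
        if len(self.task_means) != len(self.task_names) or len(self.task_sds) != len(
            self.task_names
        ):
            raise ValueError("task moment vectors must match task_names length")
        for name, v in (("task_loading", self.task_loading), ("latent_validity", self.latent_validity)):
            if v is not None and not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.item_discrimination < 0:
            raise ValueError("item_discrimination must be >= 0")
        if self.item_accuracy_targets is not None:
            t = np.asarray(self.item_accuracy_targets, dtype=float)
            if np.any((t <= 0) | (t >= 1)):
                raise ValueError("item accuracy targets must lie strictly in (0, 1)")

    @property
    def accuracy_targets(self) -> np.ndarray:
        if self.item_accuracy_targets is None:
            return logistic_accuracy_profile(self.n_items)
        return np.asarray(self.item_accuracy_targets, dtype=float)


@dataclass
class CohortData:
    """One generated cohort: task battery, composite, and item responses."""

    task_scores: np.ndarray  # n_subjects x n_tasks
    zwmc: np.ndarray  # mean of column-standardized task scores
    responses: ResponseMatrix
    total_scores: np.ndarray
    theta: np.ndarray = field(repr=False, default=None)

    @property
    def composite_total_correlation(self) -> float:
        return float(np.corrcoef(self.zwmc, self.total_scores)[0, 1])


def calibrate_loadings(
    target_single_task_r: float, target_composite_r: float, n_tasks: int = 4
) -> tuple[float, float]:
    """Task loading ``a`` and factor validity ``c_W`` hitting both targets.

    Under the parallel-task model ``task_k = a W + sqrt(1-a^2) e_k`` (unit
    variances, independent errors) the task-ability correlation is
    ``a * c_W`` and the composite-ability correlation is
    ``a * c_W / sqrt(a^2 + (1 - a^2)/n_tasks)``.  Setting these to the two
    targets gives a closed-form unique positive solution.
    """
    s, c = target_single_task_r, target_composite_r
    if not 0 < s < c < 1:
        raise ValueError(
            "targets must satisfy 0 < single < composite < 1 "
            f"(got single={s}, composite={c})"
        )
    ratio_sq = (s / c) ** 2  # = a^2 + (1 - a^2)/n
    a_sq = (ratio_sq - 1.0 / n_tasks) / (1.0 - 1.0 / n_tasks)
    if a_sq <= 0 or a_sq >= 1:
        raise ValueError("no loading in (0, 1) satisfies the targets")
    a = float(np.sqrt(a_sq))
    c_w = s / a
    if not 0 < c_w < 1:
        raise ValueError("implied factor validity falls outside (0, 1)")
    return a, c_w


def _mean_accuracy(b: float, c: float) -> float:
    """E_theta[logit^{-1}(b + c * theta)] by Gauss-Hermite quadrature."""
    return float(_GH_W @ special.expit(b + c * _GH_X))


def calibrate_item_difficulties(
    accuracy_targets: np.ndarray, discrimination: float
) -> np.ndarray:
    """Per-item intercepts ``b_j`` inducing the target marginal accuracies."""
    targets = np.asarray(accuracy_targets, dtype=float)
    if np.any((targets <= 0) | (targets >= 1)):
        raise ValueError("accuracy targets must lie strictly in (0, 1)")
    c = float(discrimination)
    if c == 0.0:
        return special.logit(targets)
    out = np.empty_like(targets)
    for j, p in enumerate(targets):
        try:
            out[j] = optimize.brentq(
                lambda b: _mean_accuracy(b, c) - p, -20.0, 20.0, xtol=1e-10
            )
        except ValueError as exc:  # root bracketing failed
            raise ValueError(
                f"item difficulty for target accuracy {p} outside [-20, 20]"
            ) from exc
    return out


def latent_total_correlation(difficulties: np.ndarray, discrimination: float) -> float:
    """Population correlation between the ability theta and the total score.

    Items are conditionally independent given theta, so the covariance
    matrix of the binary responses follows from one-dimensional
    expectations of the item curves, all evaluated by quadrature.
    """
    b = np.asarray(difficulties, dtype=float)
    c = float(discrimination)
    probs = special.expit(b[:, None] + c * _GH_X[None, :])  # items x nodes
    p = probs @ _GH_W
    cov_theta = ((probs * _GH_X[None, :]) @ _GH_W).sum()  # Cov(theta, total)
    e_cross = probs @ (probs * _GH_W[None, :]).T  # E[P_j P_k]
    var_items = p * (1 - p)
    cov_jk = e_cross - np.outer(p, p)
    np.fill_diagonal(cov_jk, 0.0)
    var_total = var_items.sum() + cov_jk.sum()
    return float(cov_theta / np.sqrt(var_total))


def _sample_r_inflation(target: float, n: int) -> float:
    """Population correlation whose expected sample r at size n is ``target``.

    Uses the first-order expansion E[r] = rho - rho (1 - rho^2)/(2(n-1)).
    """
    def f(rho: float) -> float:
        return rho - rho * (1 - rho**2) / (2 * (n - 1)) - target

    return float(optimize.brentq(f, target, min(1.0, target + 0.1), xtol=1e-12))


def calibrate_cohort(spec: CohortSpec) -> CohortSpec:
    """Resolve item difficulties and loadings so observable targets are met.

    The printed validities are sample correlations with the integer
    total score, so the latent-side targets handed to
    ``calibrate_loadings`` are inflated by (i) the analytic theta-total
    correlation of the calibrated item bank and (ii) the O(1/n) downward
    bias of a sample correlation at ``n_subjects``.
    """
    targets = spec.accuracy_targets
    b = (
        np.asarray(spec.item_difficulties, dtype=float)
        if spec.item_difficulties is not None
        else calibrate_item_difficulties(targets, spec.item_discrimination)
    )
    r_t = latent_total_correlation(b, spec.item_discrimination)
    comp = _sample_r_inflation(spec.target_composite_r, spec.n_subjects) / r_t
    single = _sample_r_inflation(spec.target_single_r, spec.n_subjects) / r_t
    if comp >= 1:
        raise ValueError(
            "composite target unreachable: latent-total correlation "
            f"{r_t:.3f} is too low"
        )
    a, c_w = calibrate_loadings(single, comp, len(spec.task_names))
    return replace(
        spec,
        task_loading=a,
        latent_validity=c_w,
        item_difficulties=b,
        item_accuracy_targets=targets,
    )


def generate_cohort(spec: CohortSpec, rng: np.random.Generator) -> CohortData:
    """Draw one cohort from a calibrated spec."""
    if spec.task_loading is None or spec.latent_validity is None:
        spec = calibrate_cohort(spec)
    n, m = spec.n_subjects, spec.n_items
    a, c_w, c = spec.task_loading, spec.latent_validity, spec.item_discrimination
    b = np.asarray(spec.item_difficulties, dtype=float)

    w = rng.standard_normal(n)
    theta = c_w * w + np.sqrt(1 - c_w**2) * rng.standard_normal(n)
    k = len(spec.task_names)
    errs = rng.standard_normal((n, k))
    tasks_std = a * w[:, None] + np.sqrt(1 - a**2) * errs
    tasks = np.asarray(spec.task_means) + np.asarray(spec.task_sds) * tasks_std

    zcols = (tasks - tasks.mean(axis=0)) / tasks.std(axis=0)
    zwmc = zcols.mean(axis=1)

    p = special.expit(b[None, :] + c * theta[:, None])
    cells = (rng.random((n, m)) < p).astype(np.int8)
    responses = ResponseMatrix(cells=cells)
    return CohortData(
        task_scores=tasks,
        zwmc=zwmc,
        responses=responses,
        total_scores=cells.sum(axis=1),
        theta=theta,
    )


def generate_cohort_near_correlation(
    spec: CohortSpec,
    rng: np.random.Generator,
    target_r: float | None = None,
    tol: float = 0.01,
    max_tries: int = 500,
) -> CohortData:
    """A cohort whose *realized* composite-total correlation is near target.

    The bootstrap analyses condition on the observed correlation of the
    study sample; this helper rejects cohorts until the sample
    correlation falls within ``tol`` of the target, emulating that
    conditioning.
    """
    if spec.task_loading is None:
        spec = calibrate_cohort(spec)
    if target_r is None:
        target_r = spec.target_composite_r
    for _ in range(max_tries):
        cohort = generate_cohort(spec, rng)
        if abs(cohort.composite_total_correlation - target_r) <= tol:
            return cohort
    raise RuntimeError(
        f"no cohort within {tol} of r={target_r} after {max_tries} draws"
    )
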