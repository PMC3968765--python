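"""Subject-level trait sampling for the matrix simulation.

Each synthetic subject is a (WMC, Raven's) pair drawn from a truncated
bivariate normal distribution whose moments and population correlation
``rho`` are configurable.  The Raven's proportion-correct score is then
converted into an integer row-sum target (number of items answered
correctly) that is reconciled against fixed per-item column sums, so
that a binary response matrix with those exact margins exists.

Truncation is performed by rejection resampling of out-of-range pairs
rather than clipping: clipping would pile probability mass at the range
bounds and distort the tails that the item-wise point-biserial analysis
is sensitive to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TraitSpec",
    "TraitSample",
    "sample_traits",
    "reconcile_row_sums",
]


class ConfigurationError(ValueError):
    """Raised when a specification cannot produce valid data."""


class InfeasibilityError(ValueError):
    """Raised when integer margin targets cannot be met."""


@dataclass(frozen=True)
class TraitSpec:
    """Population description of the paired (WMC, Raven's) traits.

    Both traits live on the proportion-correct scale.  ``rho`` is the
    population correlation of the *untruncated* bivariate normal; the
    truncation shrinks the realized correlation slightly.
    """

    mean_wmc: float = 0.61
    mean_raven: float = 0.55
    sd_wmc: float = 0.15
    sd_raven: float = 0.16
    rho: float = 0.3
    n_subjects: int = 255
    n_items: int = 36
    range_wmc: tuple[float, float] = (0.0, 1.0)
    range_raven: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.sd_wmc < 0 or self.sd_raven < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        if not -1.0 <= self.rho <= 1.0:
            raise ConfigurationError("rho must lie in [-1, 1]")
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if self.n_items < 2:
            raise ConfigurationError("n_items must be >= 2")
        for rng_, mean, name in (
            (self.range_wmc, self.mean_wmc, "wmc"),
            (self.range_raven, self.mean_raven, "raven"),
        ):
            lo, hi = rng_
            if not lo < hi:
                raise ConfigurationError(f"range_{name} must be a proper interval")
            if not lo <= mean <= hi:
                raise ConfigurationError(
                    f"range_{name} must contain mean_{name} ({mean} not in [{lo}, {hi}])"
                )


@dataclass
class TraitSample:
    """Sampled subjects: continuous traits plus integer row-sum targets."""

    wmc: np.ndarray
    raven_prop: np.ndarray
    row_sums: np.ndarray | None = None
    seed_info: str | None = field(default=None, repr=False)

    @property
    def n_subjects(self) -> int:
        return len(self.wmc)


def sample_traits(spec: TraitSpec, rng: np.random.Generator) -> TraitSample:
    """Draw ``spec.n_subjects`` (WMC, Raven's) pairs.

    Pairs falling outside either truncation range are rejected and
    redrawn.  Degenerate specs (both SDs zero) return every subject at
    the mean point.
    """
    n = spec.n_subjects
    rho = spec.rho
    wmc = np.empty(n)
    raven = np.empty(n)
    filled = 0
    attempts = 0
    # The pair is built from two standard normals so that degenerate
    # specs (zero SD, |rho| = 1) need no covariance factorization.
    while filled < n:
        attempts += 1
        if attempts > 1000:
            raise ConfigurationError(
                "truncation ranges reject virtually all probability mass"
            )
        z1 = rng.standard_normal(n - filled)
        z2 = rng.standard_normal(n - filled)
        w = spec.mean_wmc + spec.sd_wmc * z1
        r = spec.mean_raven + spec.sd_raven * (rho * z1 + np.sqrt(1 - rho**2) * z2)
        ok = (
            (w >= spec.range_wmc[0])
            & (w <= spec.range_wmc[1])
            & (r >= spec.range_raven[0])
            & (r <= spec.range_raven[1])
        )
        kept_w, kept_r = w[ok], r[ok]
        take = min(len(kept_w), n - filled)
        wmc[filled : filled + take] = kept_w[:take]
        raven[filled : filled + take] = kept_r[:take]
        filled += take
    return TraitSample(wmc=wmc, raven_prop=raven)


def _weighted_choice_without_replacement(
    weights: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices of k items drawn sequentially w/o replacement, P ∝ weight.

    Uses the Gumbel-top-k identity, which reproduces sequential draws
    with renormalized weights exactly.
    """
    if k == 0:
        return np.empty(0, dtype=np.intp)
    with np.errstate(divide="ignore"):
        keys = np.log(weights) + rng.gumbel(size=len(weights))
    idx = np.argpartition(-keys, k - 1)[:k]
    return idx


def reconcile_row_sums(
    raven_prop: np.ndarray,
    n_items: int,
    col_total: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Integer row-sum targets whose grand total equals ``col_total``.

    Each subject starts from ``round(raven_prop * n_items)``.  The
    residual discrepancy with ``col_total`` is distributed as +/-1
    adjustments over randomly chosen subjects, weighted by how far each
    subject's rounding already leaned in the needed direction, so the
    rank order of subjects is preserved up to ties.  Column sums are the
    fixed empirical anchor; only row sums are adjusted.
    """
    raven_prop = np.asarray(raven_prop, dtype=float)
    n = len(raven_prop)
    if not 0 <= col_total <= n * n_items:
        raise InfeasibilityError(
            f"col_total={col_total} outside achievable range [0, {n * n_items}]"
        )
    exact = raven_prop * n_items
    sums = np.rint(exact).astype(np.int64)
    np.clip(sums, 0, n_items, out=sums)
    residual = exact - sums  # in [-0.5, 0.5]

    diff = col_total - int(sums.sum())
    while diff != 0:
        step = 1 if diff > 0 else -1
        if step > 0:
            eligible = sums < n_items
            w = (residual + 0.5)[eligible]
        else:
            eligible = sums > 0
            w = (0.5 - residual)[eligible]
        idx_el = np.flatnonzero(eligible)
        if len(idx_el) == 0:
            raise InfeasibilityError("no subjects eligible for further adjustment")
        w = np.maximum(w, 1e-12)
        k = min(abs(diff), len(idx_el))
        chosen = idx_el[_weighted_choice_without_replacement(w, k, rng)]
        sums[chosen] += step
        residual[chosen] -= step  # discourage repeat adjustment in later passes
        diff -= step * k
    assert sums.sum() == col_total
    return sums
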