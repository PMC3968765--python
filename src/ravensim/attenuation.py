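"""Attenuation bootstrap: degrade the covariate-matrix coupling.

Starting from an observed (or synthetic) binary response matrix whose
rows are ordered by the composite WMC covariate, each bootstrap run
draws a noisy covariate ``zWMC_n = nu * zWMC + eps`` with
``eps ~ N(0, 1 - nu^2)`` and re-pairs response rows with covariate
values by rank: the row whose noisy score ranks k-th from the bottom is
assigned to the k-th smallest actual covariate value.  Row sums and
column sums of the matrix are untouched, so the item accuracies and the
per-subject totals of the original data are preserved exactly while the
covariate-response correlation is attenuated toward ``nu`` times its
observed value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .itemwise import ItemwiseCurve
from .margins import ResponseMatrix

__all__ = ["AttenuationSpec", "BootstrapSummary", "attenuate", "bootstrap_run"]


@dataclass(frozen=True)
class AttenuationSpec:
    """Attenuation factor nu in [0, 1] and number of bootstrap runs."""

    nu: float
    n_runs: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.nu <= 1.0:
            raise ValueError("nu must lie in [0, 1]")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass
class BootstrapSummary:
    """Averages over bootstrap runs at one attenuation level."""

    achieved_correlation: float
    mean_curve: ItemwiseCurve
    mean_slope: float
    nu: float
    n_runs: int


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std()
    if s == 0:
        raise ValueError("covariate has zero variance")
    return (x - x.mean()) / s


def attenuate(zwmc: np.ndarray, nu: float, rng: np.random.Generator) -> np.ndarray:
    """nu * zwmc + Gaussian noise of variance 1 - nu^2.

    The input is re-standardized to mean 0 / unit variance first, so the
    output has unit expected variance and expected correlation ``nu``
    with the input.  ``nu = 1`` returns the standardized input exactly.
    """
    if not 0.0 <= nu <= 1.0:
        raise ValueError("nu must lie in [0, 1]")
    z = _standardize(np.asarray(zwmc, dtype=float))
    if nu == 1.0:
        return z.copy()
    eps = rng.normal(0.0, np.sqrt(1.0 - nu**2), size=len(z))
    return nu * z + eps


def bootstrap_run(
    matrix: ResponseMatrix,
    zwmc: np.ndarray,
    spec: AttenuationSpec,
    rng: np.random.Generator,
) -> BootstrapSummary:
    """Run the attenuation bootstrap and average over ``spec.n_runs``.

    ``matrix`` rows must already be sorted ascending by ``zwmc`` (and
    ``zwmc`` itself ascending); the identity pairing then corresponds to
    the observed data, which ``nu = 1`` reproduces bit-exactly.
    Ties in the noisy covariate are broken by original index order.
    """
    z = np.asarray(zwmc, dtype=float)
    if np.any(np.diff(z) < 0):
        raise ValueError("zwmc (and matrix rows) must be sorted ascending by zwmc")
    cells = np.asarray(matrix.cells, dtype=float)
    if cells.shape[0] != len(z):
        raise ValueError("matrix rows and zwmc length differ")
    z = _standardize(z)
    totals = cells.sum(axis=1)
    n = len(z)
    positions = np.asarray(matrix.item_positions, dtype=float)
    xc = positions - positions.mean()
    slope_w = xc / (xc**2).sum()

    # Correlating the fixed covariate with permuted columns reduces to
    # permuting the covariate, so the cell matrix is pre-centered once.
    col_mean = cells.mean(axis=0)
    col_ss = (cells**2).sum(axis=0) - n * col_mean**2
    col_sd = np.sqrt(np.maximum(col_ss, 0.0))
    z_ss = np.sqrt((z**2).sum() - n * z.mean() ** 2)

    ach = np.empty(spec.n_runs)
    slopes = np.empty(spec.n_runs)
    curve_acc = np.zeros(cells.shape[1])
    curve_cnt = np.zeros(cells.shape[1])
    for run in range(spec.n_runs):
        zn = attenuate(z, spec.nu, rng)
        order = np.argsort(zn, kind="stable")  # row order[k] pairs with z[k]
        # paired covariate seen by each original row
        w = np.empty(n)
        w[order] = z
        ach[run] = np.corrcoef(z, totals[order])[0, 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(col_sd > 0, (w @ cells) / (col_sd * z_ss), np.nan)
        defined = ~np.isnan(r)
        curve_acc += np.where(defined, r, 0.0)
        curve_cnt += defined
        slopes[run] = (
            slope_w @ r
            if defined.all()
            else np.polyfit(positions[defined], r[defined], 1)[0]
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r = np.where(curve_cnt > 0, curve_acc / np.maximum(curve_cnt, 1), np.nan)
    mean_curve = ItemwiseCurve(
        item_positions=np.asarray(matrix.item_positions), r_pb=mean_r
    )
    return BootstrapSummary(
        achieved_correlation=float(ach.mean()),
        mean_curve=mean_curve,
        mean_slope=float(slopes.mean()),
        nu=spec.nu,
        n_runs=spec.n_runs,
    )
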