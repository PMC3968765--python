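"""Random binary matrices with fixed row and column sums.

The sampler walks the matrix column by column (item by item).  Within a
column it selects exactly ``col_sums[j]`` subjects without replacement,
with selection probability proportional to each subject's remaining
quota of correct answers — a sequential importance-sampling scheme in
the tradition of Chen-style fixed-margin table generation.  Two forcing
rules keep the walk inside the feasible polytope:

* a subject whose remaining quota equals the number of not-yet-filled
  columns must answer every remaining item correctly, so it is selected
  unconditionally;
* a subject with quota 0 is excluded.

Forcing alone is necessary but not sufficient, so after each column the
remaining margins are re-checked against the Gale–Ryser condition and
the column is redrawn on failure (capped retry budget).  Importance
weights are deliberately not tracked: draws are treated as plain
replications, not as weighted estimates of ensemble averages.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MarginSpec",
    "ResponseMatrix",
    "check_feasibility",
    "sample_matrix",
    "enumerate_matrices",
    "DeadEndError",
]


class DeadEndError(RuntimeError):
    """Sampler exhausted its column retry budget."""


@dataclass(frozen=True)
class MarginSpec:
    """Target row sums (per subject) and column sums (per item)."""

    row_sums: np.ndarray
    col_sums: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "row_sums", np.asarray(self.row_sums, dtype=np.int64)
        )
        object.__setattr__(
            self, "col_sums", np.asarray(self.col_sums, dtype=np.int64)
        )

    @property
    def n_subjects(self) -> int:
        return len(self.row_sums)

    @property
    def n_items(self) -> int:
        return len(self.col_sums)


@dataclass
class ResponseMatrix:
    """Binary subject-by-item responses with exact margins."""

    cells: np.ndarray
    subject_ids: np.ndarray | None = None
    item_positions: np.ndarray | None = None
    n_restarts: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells)
        if self.subject_ids is None:
            self.subject_ids = np.arange(1, self.cells.shape[0] + 1)
        if self.item_positions is None:
            self.item_positions = np.arange(1, self.cells.shape[1] + 1)

    @property
    def row_sums(self) -> np.ndarray:
        return self.cells.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.cells.sum(axis=0)


def _gale_ryser_ok(row_sums: np.ndarray, col_sums: np.ndarray, n_cols: int) -> tuple[bool, str]:
    """Existence check for a binary matrix with the given margins.

    Uses the Gale–Ryser inequalities on the descending row sums against
    the conjugate of the column sums.
    """
    n = len(row_sums)
    if np.any(row_sums < 0) or np.any(col_sums < 0):
        return False, "negative margin entry"
    if np.any(row_sums > n_cols):
        return False, f"row sum exceeds number of columns ({n_cols})"
    if np.any(col_sums > n):
        return False, f"column sum exceeds number of rows ({n})"
    if row_sums.sum() != col_sums.sum():
        return False, (
            f"margin totals differ (rows {int(row_sums.sum())} != "
            f"cols {int(col_sums.sum())})"
        )
    r = np.sort(row_sums)[::-1]
    lhs = np.cumsum(r)
    ks = np.arange(1, n + 1)
    # sum over columns of min(c_j, k), vectorized over k
    rhs = np.minimum(col_sums[None, :], ks[:, None]).sum(axis=1)
    bad = np.flatnonzero(lhs > rhs)
    if bad.size:
        k = int(bad[0]) + 1
        return False, (
            f"Gale-Ryser inequality violated at k={k}: "
            f"sum of {k} largest row sums {int(lhs[k - 1])} > {int(rhs[k - 1])}"
        )
    return True, "feasible"


def check_feasibility(spec: MarginSpec) -> tuple[bool, str]:
    """True iff a 0/1 matrix with ``spec``'s margins exists, plus a diagnostic."""
    return _gale_ryser_ok(spec.row_sums, spec.col_sums, spec.n_items)


def _gumbel_top_k(log_w: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    keys = log_w + rng.gumbel(size=len(log_w))
    return np.argpartition(-keys, k - 1)[:k]


def sample_matrix(
    spec: MarginSpec,
    rng: np.random.Generator,
    weights: np.ndarray | None = None,
    max_column_retries: int = 100,
) -> ResponseMatrix:
    """Draw one binary matrix with the exact margins of ``spec``.

    ``weights`` optionally replaces the default quota-proportional
    selection weights for the first column only in spirit; by default
    (and after every column) each subject's weight is its remaining
    quota, mirroring the decrement-by-one bookkeeping of the sequential
    scheme.
    """
    ok, diag = check_feasibility(spec)
    if not ok:
        raise ValueError(f"infeasible margins: {diag}")
    n, m = spec.n_subjects, spec.n_items
    quota = spec.row_sums.astype(np.int64).copy()
    cells = np.zeros((n, m), dtype=np.int8)
    n_restarts = 0

    for j in range(m):
        k = int(spec.col_sums[j])
        remaining_cols = m - j
        tail_cols = spec.col_sums[j + 1 :]
        for attempt in itertools.count():
            if attempt >= max_column_retries:
                raise DeadEndError(
                    f"column {j + 1}: retry budget ({max_column_retries}) exhausted"
                )
            forced = quota >= remaining_cols  # must be correct on every remaining item
            selectable = (quota > 0) & ~forced
            n_forced = int(forced.sum())
            sel = forced.copy()
            free = k - n_forced
            if free < 0 or free > int(selectable.sum()):
                n_restarts += 1
                continue  # cannot happen under feasible margins + forcing, but guard
            if free > 0:
                idx = np.flatnonzero(selectable)
                if weights is None:
                    w = quota[idx].astype(float)
                else:
                    w = np.asarray(weights, dtype=float)[idx] * quota[idx]
                chosen = idx[_gumbel_top_k(np.log(w), free, rng)]
                sel[chosen] = True
            new_quota = quota - sel
            ok, _ = _gale_ryser_ok(new_quota, tail_cols, m - j - 1)
            if ok:
                break
            n_restarts += 1
        cells[sel, j] = 1
        quota = new_quota

    out = ResponseMatrix(cells=cells, n_restarts=n_restarts)
    assert np.array_equal(out.row_sums, spec.row_sums)
    assert np.array_equal(out.col_sums, spec.col_sums)
    return out


def enumerate_matrices(spec: MarginSpec, max_cells: int = 20) -> list[np.ndarray]:
    """All binary matrices with the given margins (test oracle; tiny inputs only)."""
    n, m = spec.n_subjects, spec.n_items
    if n * m > max_cells:
        raise ValueError(f"enumeration guarded to <= {max_cells} cells, got {n * m}")
    out = []
    for bits in itertools.product((0, 1), repeat=n * m):
        mat = np.array(bits, dtype=np.int8).reshape(n, m)
        if np.array_equal(mat.sum(axis=1), spec.row_sums) and np.array_equal(
            mat.sum(axis=0), spec.col_sums
        ):
            out.append(mat)
    return out
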