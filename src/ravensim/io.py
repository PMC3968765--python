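"""CSV serialization for matrices, traits and cohorts, plus run manifests.

CSV is used throughout: the objects are small (a few hundred subjects by
a few dozen items) and human inspection of response matrices and trait
tables is routine practice in psychometrics.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .margins import ResponseMatrix
from .traits import TraitSample

__all__ = [
    "read_response_matrix",
    "write_response_matrix",
    "read_covariate",
    "write_covariate",
    "write_trait_sample",
    "read_trait_sample",
    "write_manifest",
]


class MatrixFormatError(ValueError):
    """Malformed response-matrix CSV."""


def write_response_matrix(matrix: ResponseMatrix, path: str | Path) -> None:
    """CSV with header subject_id,item_1..item_n and 0/1 cells."""
    n_items = matrix.cells.shape[1]
    df = pd.DataFrame(
        matrix.cells.astype(int), columns=[f"item_{j}" for j in range(1, n_items + 1)]
    )
    df.insert(0, "subject_id", matrix.subject_ids)
    df.to_csv(path, index=False)


def read_response_matrix(path: str | Path) -> ResponseMatrix:
    df = pd.read_csv(path)
    if df.columns[0] != "subject_id":
        raise MatrixFormatError("first column must be subject_id")
    ids = df["subject_id"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        raise MatrixFormatError("duplicate subject ids")
    cells = df.iloc[:, 1:].to_numpy()
    bad = np.argwhere(~np.isin(cells, (0, 1)))
    if len(bad):
        i, j = bad[0]
        raise MatrixFormatError(
            f"non-binary cell value {cells[i, j]!r} at row {i + 1}, "
            f"column {df.columns[j + 1]!r}"
        )
    positions = np.array([int(c.split("_")[-1]) for c in df.columns[1:]])
    return ResponseMatrix(
        cells=cells.astype(np.int8), subject_ids=ids, item_positions=positions
    )


def write_covariate(values: np.ndarray, path: str | Path, name: str = "zwmc") -> None:
    pd.DataFrame(
        {"subject_id": np.arange(1, len(values) + 1), name: values}
    ).to_csv(path, index=False)


def read_covariate(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    return df.iloc[:, -1].to_numpy(dtype=float)


def write_trait_sample(sample: TraitSample, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "subject_id": np.arange(1, sample.n_subjects + 1),
            "wmc": sample.wmc,
            "raven_prop": sample.raven_prop,
            "row_sum": sample.row_sums
            if sample.row_sums is not None
            else np.full(sample.n_subjects, -1),
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_trait_sample(path: str | Path) -> TraitSample:
    df = pd.read_csv(path)
    row_sums = df["row_sum"].to_numpy()
    return TraitSample(
        wmc=df["wmc"].to_numpy(float),
        raven_prop=df["raven_prop"].to_numpy(float),
        row_sums=None if (row_sums < 0).all() else row_sums.astype(np.int64),
    )


def write_manifest(
    out_dir: str | Path, seed: int, config: dict, version: str
) -> Path:
    """Record seed, config hash and version so a run can be replayed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": config,
        "version": version,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
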