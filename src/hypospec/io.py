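"""File formats for spectral matrices, labels, splits and reports.

The spectral matrix format is plain delimited text: the first row holds the
wavenumbers, every subsequent row one spectrum.  Provenance travels in a
side-car labels CSV with one row per spectrum (class, animal_id, map_id,
x, y).  Everything else (configs, splits, models, reports) is JSON/YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import WavenumberGrid, SpectralDataset

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_dataset",
    "read_dataset",
    "write_json",
    "read_json",
]

_META_COLS = ["class", "animal_id", "map_id", "x", "y"]


def write_matrix(path, dataset: SpectralDataset, fmt: str = "%.8g") -> None:
    """First row wavenumbers, one spectrum per subsequent row (CSV)."""
    stacked = np.vstack([dataset.grid.values, dataset.matrix])
    np.savetxt(path, stacked, fmt=fmt, delimiter=",")


def read_matrix(path, segments=None) -> tuple[WavenumberGrid, np.ndarray]:
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    if data.shape[0] < 2:
        raise ValueError(f"{path}: expected a wavenumber row plus spectra rows")
    return WavenumberGrid(data[0]), data[1:]


def _labels_path(matrix_path) -> Path:
    p = Path(matrix_path)
    return p.with_name(p.stem + "_labels.csv")


def write_dataset(matrix_path, dataset: SpectralDataset) -> None:
    """Write the matrix plus its side-car labels file."""
    write_matrix(matrix_path, dataset)
    dataset.meta[_META_COLS].to_csv(_labels_path(matrix_path), index=False)
    segs_path = Path(matrix_path).with_suffix(".segments.json")
    with open(segs_path, "w") as fh:
        json.dump({"segments": [list(s) for s in dataset.segments]}, fh)


def read_dataset(matrix_path) -> SpectralDataset:
    grid, matrix = read_matrix(matrix_path)
    meta = pd.read_csv(_labels_path(matrix_path), dtype={"class": str})
    if len(meta) != matrix.shape[0]:
        raise ValueError(
            f"{matrix_path}: labels file has {len(meta)} rows for "
            f"{matrix.shape[0]} spectra"
        )
    segs_path = Path(matrix_path).with_suffix(".segments.json")
    segments = []
    if segs_path.exists():
        with open(segs_path) as fh:
            segments = [tuple(s) for s in json.load(fh)["segments"]]
    return SpectralDataset(
        grid=grid,
        matrix=matrix,
        labels=meta["class"].to_numpy(),
        meta=meta,
        segments=segments,
    )


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
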