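"""Core containers shared by every stage of the pipeline.

A :class:`WavenumberGrid` is the spectral axis (Raman shift, cm^-1), a
:class:`Spectrum` is one acquisition on that axis, and a
:class:`SpectralDataset` is the spectra-by-channels matrix the chemometric
stages operate on, carrying class labels and per-spectrum provenance
(animal, map, raster position).

Datasets additionally carry ``segments``: half-open index spans marking the
contiguous blocks of the (possibly region-cropped) channel axis.  Trapezoidal
integration for unit-area normalization must not bridge the gap between,
say, the fingerprint and high-wavenumber regions, so every operation that
crops channels is responsible for keeping ``segments`` consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["WavenumberGrid", "Spectrum", "SpectralDataset"]


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly increasing, finite wavenumber axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("grid must be a non-empty 1-D array")
        if not np.all(np.isfinite(values)):
            raise ValueError("grid contains non-finite wavenumbers")
        if not np.all(np.diff(values) > 0):
            raise ValueError("grid wavenumbers must be strictly increasing")
        object.__setattr__(self, "values", values)

    @classmethod
    def uniform(cls, start: float, end: float, n_points: int) -> "WavenumberGrid":
        return cls(np.linspace(float(start), float(end), int(n_points)))

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:  # frozen dataclass wants it; identity is fine
        return hash((self.values.size, float(self.values[0]), float(self.values[-1])))


@dataclass
class Spectrum:
    """One acquisition: intensities aligned to a grid plus provenance."""

    grid: WavenumberGrid
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        y = np.asarray(self.intensities, dtype=float)
        if y.ndim != 1 or y.size != len(self.grid):
            raise ValueError(
                f"intensities length {y.size} does not match grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("intensities contain non-finite values")
        self.intensities = y

    @property
    def class_label(self):
        return self.meta.get("class")


_META_COLUMNS = ["class", "animal_id", "map_id", "x", "y"]


@dataclass
class SpectralDataset:
    """Spectra × channels matrix with labels, provenance and segment spans."""

    grid: WavenumberGrid
    matrix: np.ndarray
    labels: np.ndarray
    meta: pd.DataFrame
    segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        X = np.asarray(self.matrix, dtype=float)
        if X.ndim != 2:
            raise ValueError("matrix must be 2-D (spectra x channels)")
        if X.shape[1] != len(self.grid):
            raise ValueError(
                f"matrix has {X.shape[1]} channels but grid has {len(self.grid)}"
            )
        labels = np.asarray(self.labels)
        if labels.shape != (X.shape[0],):
            raise ValueError("one label per matrix row required")
        if len(self.meta) != X.shape[0]:
            raise ValueError("meta must have one row per spectrum")
        self.matrix = X
        self.labels = labels.astype(str)
        if not self.segments:
            self.segments = [(0, X.shape[1])]
        lo_prev = 0
        for lo, hi in self.segments:
            if not (lo_prev <= lo < hi <= X.shape[1]):
                raise ValueError(f"invalid segment span ({lo}, {hi})")
            lo_prev = hi

    @property
    def n_spectra(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.matrix.shape[1])

    @property
    def classes(self) -> list[str]:
        seen: list[str] = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return seen

    def rows_for_class(self, class_label: str) -> np.ndarray:
        mask = self.labels == str(class_label)
        if not mask.any():
            raise KeyError(f"no spectra with class label {class_label!r}")
        return np.flatnonzero(mask)

    def subset_rows(self, rows) -> "SpectralDataset":
        rows = np.asarray(rows, dtype=int)
        return SpectralDataset(
            grid=self.grid,
            matrix=self.matrix[rows],
            labels=self.labels[rows],
            meta=self.meta.iloc[rows].reset_index(drop=True),
            segments=list(self.segments),
        )

    def copy(self) -> "SpectralDataset":
        return SpectralDataset(
            grid=self.grid,
            matrix=self.matrix.copy(),
            labels=self.labels.copy(),
            meta=self.meta.copy(),
            segments=list(self.segments),
        )
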