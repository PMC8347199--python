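"""Baseline correction, region selection, normalization and matrix assembly.

Fluorescence removal is two-stage, in the order the acquisition workflow
applies them: an iterative 5th-order "modified polyfit" takes out the gross
background (refit to the pointwise minimum of signal and fit until the fit
stabilizes), then penalized asymmetric least squares (AsLS) removes the
residual slowly-varying baseline while smoothing.  The AsLS solve exploits
the pentadiagonal structure of W + lam * D'D, so its cost is linear in the
channel count.

After correction, only the informative windows are kept (fingerprint
500-1800 cm^-1 and high-wavenumber/silent-zone 2100-3100 cm^-1 by default),
each spectrum is scaled to unit trapezoidal area over the retained
(piecewise) grid, and the matrix is mean-centered with training-row means
only so no test information leaks into the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solveh_banded

from .datatypes import WavenumberGrid, Spectrum, SpectralDataset

__all__ = [
    "AslsParams",
    "RegionSet",
    "polyfit_baseline",
    "polyfit_baseline_matrix",
    "asls_baseline",
    "asls_baseline_matrix",
    "subtract_baseline",
    "select_regions",
    "normalize_unit_area",
    "normalize_dataset",
    "mean_center",
    "assemble_matrix",
    "DEFAULT_REGIONS",
]


@dataclass(frozen=True)
class AslsParams:
    """Penalized asymmetric least-squares parameters.

    lam: second-difference smoothness penalty (dimensionless, grid-index
    scale); p: asymmetry weight given to positive residuals (peaks);
    n_iter: number of reweighting iterations (fixed count, no convergence
    test).  Defaults are standard practice for fluorescence-dominated
    biological Raman spectra.
    """

    lam: float = 1e5
    p: float = 0.001
    n_iter: int = 10

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if not (0.0 < self.p < 0.5):
            raise ValueError("p must lie in (0, 0.5)")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass(frozen=True)
class RegionSet:
    """Sorted, non-overlapping closed wavenumber intervals [lo, hi]."""

    intervals: tuple

    def __post_init__(self) -> None:
        ivs = tuple((float(lo), float(hi)) for lo, hi in self.intervals)
        if not ivs:
            raise ValueError("at least one interval required")
        prev_hi = -np.inf
        for lo, hi in ivs:
            if lo >= hi:
                raise ValueError(f"interval [{lo}, {hi}] must have lo < hi")
            if lo <= prev_hi:
                raise ValueError("intervals must be sorted and non-overlapping")
            prev_hi = hi
        object.__setattr__(self, "intervals", ivs)

    @classmethod
    def parse(cls, text: str) -> "RegionSet":
        """Parse e.g. ``"500-1800,2100-3100"``."""
        ivs = []
        for part in text.split(","):
            part = part.strip()
            lo, sep, hi = part.partition("-")
            if not sep:
                raise ValueError(f"cannot parse region {part!r}; expected 'lo-hi'")
            try:
                ivs.append((float(lo), float(hi)))
            except ValueError as exc:
                raise ValueError(f"cannot parse region {part!r}") from exc
        return cls(intervals=tuple(ivs))


DEFAULT_REGIONS = RegionSet(intervals=((500.0, 1800.0), (2100.0, 3100.0)))


def _signal_and_x(spectrum, x=None):
    if isinstance(spectrum, Spectrum):
        return spectrum.intensities, spectrum.grid.values
    y = np.asarray(spectrum, dtype=float)
    if x is None:
        x = np.arange(y.size, dtype=float)
    return y, np.asarray(x, dtype=float)


def _poly_projector(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    # Chebyshev-scaled Vandermonde keeps the normal equations well conditioned.
    lo, hi = x.min(), x.max()
    u = 2.0 * (x - lo) / (hi - lo) - 1.0 if hi > lo else np.zeros_like(x)
    V = np.polynomial.polynomial.polyvander(u, order)
    return V, np.linalg.pinv(V)


def polyfit_baseline(
    spectrum,
    x=None,
    order: int = 5,
    max_iter: int = 100,
    tol: float = 1e-4,
    return_history: bool = False,
):
    """Iterative modified polynomial baseline (fluorescence estimate).

    Fits a polynomial of the given order, clips the working signal to the
    pointwise minimum of signal and fit, and refits until the fit changes
    by less than ``tol`` (relative, sup-norm) or ``max_iter`` is reached.
    The returned baseline therefore relaxes below the peaks while following
    the broad background.
    """
    y, xv = _signal_and_x(spectrum, x)
    if not np.all(np.isfinite(y)):
        raise ValueError("input signal contains non-finite values")
    if order < 0:
        raise ValueError("order must be >= 0")
    if y.size <= order + 1:
        raise ValueError("need more channels than polynomial coefficients")
    V, pinv = _poly_projector(xv, order)
    work = y.copy()
    fit = V @ (pinv @ work)
    history = [fit]
    for _ in range(max_iter - 1):
        work = np.minimum(work, fit)
        new_fit = V @ (pinv @ work)
        history.append(new_fit)
        denom = max(float(np.max(np.abs(fit))), 1e-12)
        change = float(np.max(np.abs(new_fit - fit))) / denom
        fit = new_fit
        if change < tol:
            break
    if return_history:
        return fit, history
    return fit


def polyfit_baseline_matrix(
    Y: np.ndarray,
    x: np.ndarray,
    order: int = 5,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> np.ndarray:
    """Vectorized modified polyfit over the rows of a spectra matrix.

    Identical per-row result to :func:`polyfit_baseline`; all rows iterate
    together and each stops (is frozen) once its own fit has converged.
    """
    Y = np.asarray(Y, dtype=float)
    if not np.all(np.isfinite(Y)):
        raise ValueError("input matrix contains non-finite values")
    V, pinv = _poly_projector(np.asarray(x, dtype=float), order)
    work = Y.copy()
    fit = (pinv @ work.T).T @ V.T
    active = np.ones(Y.shape[0], dtype=bool)
    for _ in range(max_iter - 1):
        if not active.any():
            break
        w_act = np.minimum(work[active], fit[active])
        new_fit = (pinv @ w_act.T).T @ V.T
        denom = np.maximum(np.max(np.abs(fit[active]), axis=1), 1e-12)
        change = np.max(np.abs(new_fit - fit[active]), axis=1) / denom
        work[active] = w_act
        fit[active] = new_fit
        still = change >= tol
        idx = np.flatnonzero(active)
        active[idx[~still]] = False
    return fit


def _second_difference_banded(n: int) -> np.ndarray:
    """Upper banded form (for solveh_banded) of D'D, D the order-2 difference."""
    dtd = np.zeros((3, n))
    # main diagonal of D'D: 1, 5, 6, ..., 6, 5, 1
    main = np.full(n, 6.0)
    main[[0, -1]] = 1.0
    if n > 2:
        main[[1, -2]] = 5.0
    if n <= 2:
        main[:] = 0.0
    # first off-diagonal: -2, -4, ..., -4, -2 ; second off-diagonal: 1
    off1 = np.full(n - 1, -4.0)
    if off1.size:
        off1[[0, -1]] = -2.0
    off2 = np.full(max(n - 2, 0), 1.0)
    dtd[2, :] = main
    dtd[1, 1:] = off1
    dtd[0, 2:] = off2
    return dtd


def asls_baseline(y, params: AslsParams = AslsParams()) -> np.ndarray:
    """Asymmetric least-squares baseline via a banded (O(n)) Whittaker solve.

    Solves (W + lam * D'D) z = W y with second-difference penalty D,
    starting from uniform weights and reweighting residuals asymmetrically
    (p above the baseline, 1-p below) for a fixed number of iterations.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("signal must be 1-D with length >= 3")
    if not np.all(np.isfinite(y)):
        raise ValueError("signal contains non-finite values")
    n = y.size
    ab_penalty = params.lam * _second_difference_banded(n)
    w = np.ones(n)
    z = y
    for _ in range(params.n_iter):
        ab = ab_penalty.copy()
        ab[2, :] += w
        z = solveh_banded(ab, w * y, lower=False)
        w = np.where(y > z, params.p, 1.0 - params.p)
    return z


def asls_baseline_matrix(Y: np.ndarray, params: AslsParams = AslsParams()) -> np.ndarray:
    """Row-wise AsLS baselines of a spectra matrix."""
    Y = np.asarray(Y, dtype=float)
    out = np.empty_like(Y)
    for i in range(Y.shape[0]):
        out[i] = asls_baseline(Y[i], params)
    return out


def subtract_baseline(spectrum: Spectrum, baseline) -> Spectrum:
    """Elementwise signal minus baseline; metadata preserved, no clipping."""
    b = np.asarray(baseline, dtype=float)
    if b.shape != spectrum.intensities.shape:
        raise ValueError(
            f"baseline length {b.size} does not match spectrum length "
            f"{spectrum.intensities.size}"
        )
    return Spectrum(
        grid=spectrum.grid,
        intensities=spectrum.intensities - b,
        meta=dict(spectrum.meta),
    )


def region_mask(grid: WavenumberGrid, regions: RegionSet) -> np.ndarray:
    """Boolean channel mask: wavenumber inside any closed interval."""
    w = grid.values
    mask = np.zeros(w.size, dtype=bool)
    for lo, hi in regions.intervals:
        mask |= (w >= lo) & (w <= hi)
    return mask


def select_regions(dataset: SpectralDataset, regions: RegionSet) -> SpectralDataset:
    """Keep only channels inside the given intervals (inclusive endpoints).

    Channels stay in grid order; the per-interval spans are recorded as
    dataset segments so that later trapezoidal integration never bridges
    the gap between retained regions.
    """
    w = dataset.grid.values
    pieces: list[np.ndarray] = []
    segments: list[tuple[int, int]] = []
    start = 0
    for lo, hi in regions.intervals:
        idx = np.flatnonzero((w >= lo) & (w <= hi))
        if idx.size == 0:
            continue
        pieces.append(idx)
        segments.append((start, start + idx.size))
        start += idx.size
    if not pieces:
        raise ValueError("region selection retained no channels")
    keep = np.concatenate(pieces)
    return SpectralDataset(
        grid=WavenumberGrid(w[keep]),
        matrix=dataset.matrix[:, keep],
        labels=dataset.labels,
        meta=dataset.meta,
        segments=segments,
    )


def _piecewise_trapezoid(Y: np.ndarray, w: np.ndarray, segments) -> np.ndarray:
    """Trapezoidal integral per row, summed over contiguous segments only."""
    Y2 = np.atleast_2d(Y)
    total = np.zeros(Y2.shape[0])
    for lo, hi in segments:
        total += np.trapezoid(Y2[:, lo:hi], w[lo:hi], axis=1)
    return total


def normalize_unit_area(spectrum: Spectrum, segments=None) -> Spectrum:
    """Scale a spectrum so its trapezoidal integral over the grid equals 1."""
    segments = segments or [(0, spectrum.intensities.size)]
    area = float(
        _piecewise_trapezoid(spectrum.intensities, spectrum.grid.values, segments)[0]
    )
    if area <= 0:
        raise ValueError(
            f"spectrum area {area:.4g} is not positive; baseline correction "
            "failed or the spectrum is pathological"
        )
    return Spectrum(
        grid=spectrum.grid,
        intensities=spectrum.intensities / area,
        meta=dict(spectrum.meta),
    )


def normalize_dataset(dataset: SpectralDataset) -> SpectralDataset:
    """Unit-area normalize every row over the dataset's retained segments."""
    areas = _piecewise_trapezoid(dataset.matrix, dataset.grid.values, dataset.segments)
    bad = np.flatnonzero(areas <= 0)
    if bad.size:
        raise ValueError(
            f"{bad.size} spectra have non-positive area (first at row {bad[0]})"
        )
    out = dataset.copy()
    out.matrix = dataset.matrix / areas[:, None]
    return out


def mean_center(train: SpectralDataset, *apply_to: SpectralDataset):
    """Center by the column means of the training rows only.

    Returns the centered datasets (training first) and the mean vector, so
    the centering can be persisted and applied to future data.
    """
    for other in apply_to:
        if other.grid != train.grid:
            raise ValueError("grid mismatch between training and applied dataset")
    mean = train.matrix.mean(axis=0)
    centered = []
    for ds in (train, *apply_to):
        out = ds.copy()
        out.matrix = ds.matrix - mean
        centered.append(out)
    return tuple(centered), mean


def assemble_matrix(spectra) -> SpectralDataset:
    """Join individual spectra into one dataset, ordered by (class, map, position)."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("cannot assemble an empty list of spectra")
    grid = spectra[0].grid
    for s in spectra:
        if s.grid != grid:
            raise ValueError(
                f"grid mismatch for spectrum from map "
                f"{s.meta.get('map_id', '<unknown>')!r}"
            )
    meta = pd.DataFrame(
        [
            {
                "class": s.meta.get("class", ""),
                "animal_id": s.meta.get("animal_id", ""),
                "map_id": s.meta.get("map_id", ""),
                "x": float(s.meta.get("x", 0.0)),
                "y": float(s.meta.get("y", 0.0)),
            }
            for s in spectra
        ]
    )
    order = meta.sort_values(
        ["class", "map_id", "y", "x"], kind="stable"
    ).index.to_numpy()
    matrix = np.vstack([spectra[i].intensities for i in order])
    meta = meta.iloc[order].reset_index(drop=True)
    return SpectralDataset(
        grid=grid,
        matrix=matrix,
        labels=meta["class"].to_numpy(),
        meta=meta,
    )
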