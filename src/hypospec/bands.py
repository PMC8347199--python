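"""Band-level analytics: class averages, peak detection, heights, the
1655/1444 lipid-saturation ratio, and chemical assignment.

"Intensity" here means peak height on baseline-corrected spectra, not
integrated band area, and peak positions are reported as nearest-integer
wavenumbers, matching how bands are labeled on published mean spectra.
The height ratio 1655/1444 is a lipid unsaturation index: lower means
more saturated lipid.  All ratios are invariant under positive rescaling
of the spectrum, so they are unaffected by unit-area normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .datatypes import WavenumberGrid, Spectrum, SpectralDataset
from .synth import BandLibrary

__all__ = [
    "Peak",
    "AverageSpectrum",
    "class_average",
    "detect_peaks",
    "band_height",
    "intensity_ratio",
    "assign_peaks",
    "peak_table",
]


@dataclass(frozen=True)
class Peak:
    position: int  # nearest-integer wavenumber, cm^-1
    height: float
    prominence: float


@dataclass
class AverageSpectrum:
    """Channelwise mean and population SD of one class."""

    grid: WavenumberGrid
    mean: np.ndarray
    sd: np.ndarray
    n: int
    class_label: str

    def as_spectrum(self) -> Spectrum:
        return Spectrum(
            grid=self.grid, intensities=self.mean, meta={"class": self.class_label}
        )


def class_average(dataset: SpectralDataset, class_label: str) -> AverageSpectrum:
    rows = dataset.rows_for_class(class_label)
    block = dataset.matrix[rows]
    return AverageSpectrum(
        grid=dataset.grid,
        mean=block.mean(axis=0),
        sd=block.std(axis=0),  # population SD
        n=int(rows.size),
        class_label=str(class_label),
    )


def _as_xy(spectrum) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(spectrum, AverageSpectrum):
        return spectrum.grid.values, spectrum.mean
    if isinstance(spectrum, Spectrum):
        return spectrum.grid.values, spectrum.intensities
    raise TypeError("expected a Spectrum or AverageSpectrum")


def _window_slice(w: np.ndarray, lo: float, hi: float) -> np.ndarray:
    idx = np.flatnonzero((w >= lo) & (w <= hi))
    if idx.size == 0:
        raise ValueError(f"window [{lo}, {hi}] contains no grid channels")
    return idx


def detect_peaks(spectrum, window=None, min_prominence: float = 0.05) -> list[Peak]:
    """Local maxima in a wavenumber window, filtered by prominence.

    ``min_prominence`` is a fraction of the maximum intensity inside the
    window.  Peaks are returned sorted by descending height, positions
    rounded to the nearest integer cm^-1.
    """
    w, y = _as_xy(spectrum)
    if window is None:
        window = (w[0], w[-1])
    idx = _window_slice(w, *window)
    y_win = y[idx]
    top = float(y_win.max())
    if top <= 0:
        return []
    locs, props = find_peaks(y_win, prominence=min_prominence * top)
    peaks = [
        Peak(
            position=int(round(w[idx[loc]])),
            height=float(y_win[loc]),
            prominence=float(prom),
        )
        for loc, prom in zip(locs, props["prominences"])
    ]
    return sorted(peaks, key=lambda p: -p.height)


def band_height(spectrum, center: float, halfwidth: float = 10.0) -> float:
    """Maximum intensity within +/- halfwidth of a band center."""
    w, y = _as_xy(spectrum)
    if center - halfwidth < w[0] or center + halfwidth > w[-1]:
        raise ValueError(
            f"window [{center - halfwidth}, {center + halfwidth}] falls outside "
            f"the grid span [{w[0]}, {w[-1]}]"
        )
    idx = _window_slice(w, center - halfwidth, center + halfwidth)
    return float(y[idx].max())


def intensity_ratio(
    spectrum,
    numerator_center: float = 1655.0,
    denominator_center: float = 1444.0,
    halfwidth: float = 10.0,
) -> float:
    """Height ratio of two bands (default: the 1655/1444 saturation index)."""
    num = band_height(spectrum, numerator_center, halfwidth)
    den = band_height(spectrum, denominator_center, halfwidth)
    if den <= 0:
        raise ZeroDivisionError(
            f"denominator band at {denominator_center} cm^-1 has non-positive height"
        )
    if num <= 0:
        raise ValueError(
            f"numerator band at {numerator_center} cm^-1 has non-positive height"
        )
    return num / den


def assign_peaks(peaks, library: BandLibrary, tol: float = 5.0):
    """Greedy nearest one-to-one matching of peaks to library bands.

    Peak-band pairs are considered in order of increasing distance; a pair
    is accepted when both the peak and the band are still free and the
    distance is within ``tol``.  Returns (peak, assignment-or-None) in the
    original peak order.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    peaks = list(peaks)
    candidates = []
    for i, pk in enumerate(peaks):
        for j, band in enumerate(library.bands):
            d = abs(pk.position - band.center)
            if d <= tol:
                candidates.append((d, i, j))
    candidates.sort()
    assigned: dict[int, str] = {}
    used_bands: set[int] = set()
    for d, i, j in candidates:
        if i in assigned or j in used_bands:
            continue
        assigned[i] = library.bands[j].assignment
        used_bands.add(j)
    return [(pk, assigned.get(i)) for i, pk in enumerate(peaks)]


def peak_table(peaks_with_assignments) -> pd.DataFrame:
    """Flatten (peak, assignment) pairs into a report table."""
    return pd.DataFrame(
        [
            {
                "position_cm1": pk.position,
                "height": pk.height,
                "prominence": pk.prominence,
                "assignment": assignment if assignment is not None else "",
            }
            for pk, assignment in peaks_with_assignments
        ]
    )
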