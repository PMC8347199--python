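"""Synthetic Raman map generator.

Emulates confocal Raman maps of the hypothalamic arcuate-median eminence
(Arc-ME) complex from control (CTRL) and high-fat-diet (HFD) mice: a fixed
library of biochemical bands (glycogen, collagen, lipid esters, the
silent-zone C≡N stretch, C-H stretches) rendered as Lorentzian lines with
class-dependent amplitudes, sitting on a map-level polynomial fluorescence
background that dominates the bands by 5-20x, plus exposure-averaged
Gaussian noise.

The class contrast encoded in the library is the ground truth every
downstream stage is judged against: HFD amplitudes exceed CTRL at the
glycogen, collagen, ester-carbonyl (1748 cm^-1) and cyanide (2248 cm^-1)
bands, CTRL exceeds HFD at the =C-H band (3000 cm^-1), and the amide-I /
CH2-bending height ratio 1655/1444 is exactly 0.88 for CTRL and 0.55 for
HFD in the noiseless profile.  Because the 1444/1460 and 1655/1661 pairs
overlap within a linewidth, the two free amplitudes are solved from a 2x2
linear system per class rather than assigned naively.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from .datatypes import WavenumberGrid, Spectrum, SpectralDataset

__all__ = [
    "BandSpec",
    "BandLibrary",
    "GeneratorConfig",
    "default_band_library",
    "synth_spectrum",
    "synth_dataset",
]

logger = logging.getLogger(__name__)

CTRL = "CTRL"
HFD = "HFD"

#: Target noiseless 1655/1444 height ratios per class (lipid saturation index).
SATURATION_RATIO = {CTRL: 0.88, HFD: 0.55}
#: Target noiseless height of the 1444 cm^-1 CH2-bending band per class.
_H1444 = {CTRL: 2.0, HFD: 3.0}


def lorentzian(delta: np.ndarray, fwhm: float) -> np.ndarray:
    """Unit-height Lorentzian profile as a function of offset from center."""
    return 1.0 / (1.0 + (2.0 * np.asarray(delta, dtype=float) / fwhm) ** 2)


def gaussian(delta: np.ndarray, fwhm: float) -> np.ndarray:
    """Unit-height Gaussian profile as a function of offset from center."""
    return np.exp(-4.0 * np.log(2.0) * (np.asarray(delta, dtype=float) / fwhm) ** 2)


_SHAPES = {"lorentzian": lorentzian, "gaussian": gaussian}


@dataclass(frozen=True)
class BandSpec:
    """One Raman band: position, width, line shape, chemical assignment and
    per-class amplitude multipliers."""

    center: float
    fwhm: float
    assignment: str
    base_amplitude: float
    class_multiplier: dict
    shape: str = "lorentzian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"band at {self.center}: fwhm must be > 0")
        if self.base_amplitude < 0:
            raise ValueError(f"band at {self.center}: base_amplitude must be >= 0")
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown line shape {self.shape!r}")
        for cls, mult in self.class_multiplier.items():
            if mult < 0:
                raise ValueError(f"band at {self.center}: multiplier for {cls} < 0")

    def amplitude(self, class_label: str) -> float:
        return self.base_amplitude * self.class_multiplier[class_label]

    def profile(self, wavenumbers: np.ndarray, class_label: str) -> np.ndarray:
        return self.amplitude(class_label) * _SHAPES[self.shape](
            np.asarray(wavenumbers, dtype=float) - self.center, self.fwhm
        )


@dataclass(frozen=True)
class BandLibrary:
    """Collection of bands plus the class labels their multipliers cover."""

    bands: tuple
    classes: tuple

    def __post_init__(self) -> None:
        centers = [b.center for b in self.bands]
        if len(set(centers)) != len(centers):
            raise ValueError("band centers must be unique")
        for b in self.bands:
            missing = set(self.classes) - set(b.class_multiplier)
            if missing:
                raise ValueError(f"band at {b.center} lacks multipliers for {missing}")
        object.__setattr__(self, "bands", tuple(self.bands))
        object.__setattr__(self, "classes", tuple(self.classes))

    def band_at(self, center: float) -> BandSpec:
        for b in self.bands:
            if b.center == center:
                return b
        raise KeyError(f"no band centered at {center}")

    def evaluate(self, wavenumbers, class_label: str) -> np.ndarray:
        """Noiseless, background-free class profile at arbitrary wavenumbers."""
        if class_label not in self.classes:
            raise KeyError(f"unknown class label {class_label!r}")
        w = np.asarray(wavenumbers, dtype=float)
        out = np.zeros_like(w)
        for b in self.bands:
            out += b.profile(w, class_label)
        return out

    def max_band_height(self) -> float:
        return max(b.amplitude(c) for b in self.bands for c in self.classes)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "bands": [asdict(b) for b in self.bands],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BandLibrary":
        return cls(
            bands=tuple(BandSpec(**b) for b in d["bands"]),
            classes=tuple(d["classes"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "BandLibrary":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "BandLibrary":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


_DEFAULT_FWHM = 12.0

# center, assignment, base amplitude, CTRL multiplier, HFD multiplier.
# HFD > CTRL for glycogen, collagen and lipid-ester bands, CTRL > HFD at the
# unsaturation marker 3000 cm^-1, equal where the groups do not differ.
_FIXED_BANDS = [
    (484.0, "glycogen (C-C-C / C-O-C glycosidic bend)", 1.0, 0.55, 1.0),
    (747.0, "phenylalanine (COO- deformation)", 0.6, 0.80, 1.0),
    (858.0, "glycogen C(1)-H bend / proline ring", 1.2, 0.60, 1.0),
    (1007.0, "phenylalanine ring breathing (collagen)", 1.5, 0.75, 1.0),
    (1105.0, "proline C-C skeletal stretch", 0.7, 0.80, 1.0),
    (1127.0, "proline delta-NCH (collagen I)", 0.8, 0.70, 1.0),
    (1172.0, "tyrosine C-H modes", 0.6, 0.70, 1.0),
    (1260.0, "amide III (collagen, 1240-1280 range)", 1.0, 0.75, 1.0),
    (1460.0, "glycogen C-C-C bend / lysine COO-", 1.0, 0.65, 1.0),
    # modest amide-I amplitude: the 1661 wing overlaps the 1655 ratio band
    (1661.0, "amide I (collagen I/III)", 0.5, 0.70, 1.0),
    (1748.0, "ester C=O stretch (triacylglycerols)", 1.2, 0.45, 1.0),
    (2248.0, "cyanide group (-CN)", 0.9, 0.15, 1.0),
    (2850.0, "CH2 symmetric stretch", 1.6, 1.0, 1.0),
    (2878.0, "CH2 antisymmetric stretch", 1.4, 1.0, 1.0),
    (2930.0, "CH3 / aromatic C-H stretch (glucosides)", 1.8, 1.0, 1.0),
    (3000.0, "=C-H stretch (unsaturated fatty acids)", 0.8, 1.0, 0.7),
]

_RATIO_NUM = 1655.0  # amide I / C=C lipid stretch
_RATIO_DEN = 1444.0  # CH2 bending (lipid)


def default_band_library() -> BandLibrary:
    """Band library encoding the CTRL/HFD contrast of the Arc-ME study system.

    The amplitudes of the two ratio-defining bands (1444 and 1655 cm^-1)
    are solved per class so that the *net* noiseless heights at those exact
    positions — including the wings of the neighbouring 1460 and 1661
    bands — satisfy height(1655)/height(1444) = 0.88 (CTRL) and 0.55 (HFD).
    """
    fixed = [
        BandSpec(
            center=c,
            fwhm=_DEFAULT_FWHM,
            assignment=a,
            base_amplitude=base,
            class_multiplier={CTRL: mc, HFD: mh},
        )
        for c, a, base, mc, mh in _FIXED_BANDS
    ]

    pts = np.array([_RATIO_DEN, _RATIO_NUM])
    # Cross-talk matrix between the two solved bands at the two positions.
    cross = lorentzian(_RATIO_NUM - _RATIO_DEN, _DEFAULT_FWHM)
    M = np.array([[1.0, cross], [cross, 1.0]])

    mult_1444: dict = {}
    mult_1655: dict = {}
    for cls in (CTRL, HFD):
        background = np.zeros(2)
        for b in fixed:
            background += b.profile(pts, cls)
        h_den = _H1444[cls]
        target = np.array([h_den, SATURATION_RATIO[cls] * h_den]) - background
        a_den, a_num = np.linalg.solve(M, target)
        if a_den <= 0 or a_num <= 0:
            raise RuntimeError(
                "ratio-band amplitude solve produced non-positive amplitudes; "
                "fixed-band amplitudes are inconsistent with the target ratios"
            )
        mult_1444[cls] = float(a_den)
        mult_1655[cls] = float(a_num)

    solved = [
        BandSpec(
            center=_RATIO_DEN,
            fwhm=_DEFAULT_FWHM,
            assignment="CH2 bending (lipids)",
            base_amplitude=1.0,
            class_multiplier=mult_1444,
        ),
        BandSpec(
            center=_RATIO_NUM,
            fwhm=_DEFAULT_FWHM,
            assignment="C=C stretch / amide I (lipid unsaturation)",
            base_amplitude=1.0,
            class_multiplier=mult_1655,
        ),
    ]
    bands = sorted(fixed + solved, key=lambda b: b.center)
    return BandLibrary(bands=tuple(bands), classes=(CTRL, HFD))


@dataclass
class GeneratorConfig:
    """Acquisition-level knobs of the synthetic study.

    Defaults mirror the emulated acquisition: 8 maps (4 per class) of 1000
    spectra each on a 3180-channel grid spanning 200-3400 cm^-1, at least
    30 exposures averaged per spectrum, and a map-level 5th-order
    fluorescence background 5-20x stronger than the bands.
    ``roi_fraction`` < 1 keeps only a random subset of each map, emulating
    the manual region-of-interest selection that reduced ~8000 collected
    spectra to the analyzed matrix.
    """

    n_maps_per_class: int = 4
    spectra_per_map: int = 1000
    grid: tuple = (200.0, 3400.0, 3180)
    classes: tuple = (CTRL, HFD)
    bg_amp_range: tuple = (5.0, 20.0)  # background peak-to-trough, x max band height
    bg_offset_range: tuple = (0.5, 1.5)  # background floor, x max band height
    bg_order: int = 5
    noise_sd: float = 0.6  # single-exposure noise, intensity units
    exposures: int = 30
    roi_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_maps_per_class < 1 or self.spectra_per_map < 1:
            raise ValueError("map and spectrum counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.exposures < 1:
            raise ValueError("exposures must be >= 1")
        if not (0.0 < self.roi_fraction <= 1.0):
            raise ValueError("roi_fraction must lie in (0, 1]")
        if self.bg_order < 0:
            raise ValueError("bg_order must be >= 0")

    def make_grid(self) -> WavenumberGrid:
        """Channel axis: n channels covering [start, end) with spacing
        (end - start) / n, the grating span divided by the channel count
        (left-edge sampling, as spectrometer channel grids are laid out)."""
        start, end, n = self.grid
        n = int(n)
        step = (float(end) - float(start)) / n
        return WavenumberGrid(float(start) + step * np.arange(n))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = list(self.grid)
        d["classes"] = list(self.classes)
        d["bg_amp_range"] = list(self.bg_amp_range)
        d["bg_offset_range"] = list(self.bg_offset_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("grid", "classes", "bg_amp_range", "bg_offset_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _grid_coord(grid: WavenumberGrid) -> np.ndarray:
    """Map the grid onto [0, 1]; background polynomials live in this coordinate."""
    lo, hi = grid.span
    return (grid.values - lo) / (hi - lo)


def _poly_eval(coeffs: np.ndarray, u: np.ndarray) -> np.ndarray:
    return np.polynomial.polynomial.polyval(u, coeffs)


def _draw_map_baseline(
    rng: np.random.Generator, config: GeneratorConfig, ref_height: float, u: np.ndarray
) -> np.ndarray:
    """Draw one map's fluorescence polynomial (coefficients over u in [0,1]).

    A random polynomial is rescaled so its trough sits at a positive offset
    and its peak-to-trough span is ``bg_amp_range`` times the tallest band:
    the background always dominates the signal, so the baseline-correction
    stages genuinely matter.
    """
    raw = rng.uniform(-1.0, 1.0, size=config.bg_order + 1)
    vals = _poly_eval(raw, u)
    lo, hi = float(vals.min()), float(vals.max())
    amp = rng.uniform(*config.bg_amp_range) * ref_height
    off = rng.uniform(*config.bg_offset_range) * ref_height
    if hi - lo < 1e-12:  # constant draw; keep the offset only
        coeffs = np.zeros_like(raw)
        coeffs[0] = off
        return coeffs
    scale = amp / (hi - lo)
    coeffs = raw * scale
    coeffs[0] += off - lo * scale
    return coeffs


def synth_spectrum(
    grid: WavenumberGrid,
    library: BandLibrary,
    class_label: str,
    map_baseline=0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    exposures: int = 1,
    meta: dict | None = None,
) -> Spectrum:
    """Render one synthetic spectrum: band mixture + polynomial background + noise.

    ``map_baseline`` holds polynomial coefficients over the grid mapped to
    [0, 1] (scalar = flat background).  Noise is i.i.d. Gaussian with
    standard deviation ``noise_sd / sqrt(exposures)``, reflecting exposure
    averaging.  Deterministic for a fixed ``seed``.
    """
    if class_label not in library.classes:
        raise KeyError(f"unknown class label {class_label!r}")
    signal = library.evaluate(grid.values, class_label)
    coeffs = np.atleast_1d(np.asarray(map_baseline, dtype=float))
    u = _grid_coord(grid)
    y = signal + _poly_eval(coeffs, u)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd / np.sqrt(exposures), size=y.size)
    return Spectrum(grid=grid, intensities=y, meta=dict(meta or {}, **{"class": class_label}))


def _roi_keep_counts(config: GeneratorConfig) -> list[int]:
    """Per-map kept-spectrum counts for a global ROI fraction.

    The total kept count is round(fraction x collected); the remainder after
    even division is given to the first maps, so e.g. 8 maps of 1000 at
    fraction 7409/8000 keep exactly 7409 spectra (927 + 7 x 926).
    """
    n_maps = config.n_maps_per_class * len(config.classes)
    total = int(round(config.roi_fraction * n_maps * config.spectra_per_map))
    total = max(n_maps, min(total, n_maps * config.spectra_per_map))
    base, rem = divmod(total, n_maps)
    return [base + (1 if i < rem else 0) for i in range(n_maps)]


def synth_dataset(config: GeneratorConfig, library: BandLibrary | None = None) -> SpectralDataset:
    """Generate a full multi-map, two-class dataset.

    Fluorescence coefficients are drawn once per map (spectra within a map
    share a background, the map-level correlation real mosaics show), then
    per-spectrum noise is added.  Spectra are laid out on a square raster
    with a 25 um step.  Bit-reproducible for a fixed config.
    """
    library = library or default_band_library()
    for cls in config.classes:
        if cls not in library.classes:
            raise KeyError(f"config class {cls!r} missing from band library")
    grid = config.make_grid()
    lo, hi = grid.span
    for b in library.bands:
        if not (lo <= b.center <= hi):
            logger.warning(
                "band at %.1f cm^-1 (%s) outside grid span %.1f-%.1f; skipped",
                b.center, b.assignment, lo, hi,
            )
    in_span = [b for b in library.bands if lo <= b.center <= hi]
    lib_used = BandLibrary(bands=tuple(in_span), classes=library.classes)

    rng = np.random.default_rng(config.seed)
    u = _grid_coord(grid)
    ref = lib_used.max_band_height() if in_span else 1.0
    noise_scale = config.noise_sd / np.sqrt(config.exposures)
    side = int(np.ceil(np.sqrt(config.spectra_per_map)))
    step_um = 25.0

    keep_counts = _roi_keep_counts(config)
    class_profiles = {c: lib_used.evaluate(grid.values, c) for c in config.classes}

    blocks: list[np.ndarray] = []
    labels: list[str] = []
    meta_rows: list[dict] = []
    map_index = 0
    for cls in config.classes:
        for m in range(config.n_maps_per_class):
            map_id = f"{cls}_map{m + 1}"
            animal_id = f"{cls}_animal{m + 1}"
            coeffs = _draw_map_baseline(rng, config, ref, u)
            n_keep = keep_counts[map_index]
            map_index += 1
            kept = np.sort(
                rng.choice(config.spectra_per_map, size=n_keep, replace=False)
            )
            base_row = class_profiles[cls] + _poly_eval(coeffs, u)
            block = np.tile(base_row, (n_keep, 1))
            if noise_scale > 0:
                block += rng.normal(0.0, noise_scale, size=block.shape)
            blocks.append(block)
            for idx in kept:
                labels.append(cls)
                meta_rows.append(
                    {
                        "class": cls,
                        "animal_id": animal_id,
                        "map_id": map_id,
                        "x": float((idx % side) * step_um),
                        "y": float((idx // side) * step_um),
                    }
                )
    matrix = np.vstack(blocks)
    meta = pd.DataFrame(meta_rows)
    return SpectralDataset(grid=grid, matrix=matrix, labels=np.array(labels), meta=meta)
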