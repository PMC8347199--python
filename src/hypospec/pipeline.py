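"""End-to-end orchestration: generate -> correct -> crop -> normalize ->
split -> select complexity -> fit -> evaluate -> band analytics.

The stage order is fixed: per-spectrum modified polyfit then AsLS baseline
correction, region cropping, unit-area normalization over the retained
segments, stratified duplex splitting, training-mean centering, 10-fold CV
selection of the number of latent variables, final PLS-DA fit, held-out
evaluation, and band-level analytics (class averages, peak tables, the
1655/1444 saturation ratio, VIP discriminant regions).  Identical config
and seeds give a bit-identical report.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import bands as bands_mod
from . import io as io_mod
from . import plsda as plsda_mod
from .datatypes import SpectralDataset
from .preprocess import (
    AslsParams,
    RegionSet,
    DEFAULT_REGIONS,
    asls_baseline_matrix,
    normalize_dataset,
    polyfit_baseline_matrix,
    select_regions,
)
from .split import stratified_duplex
from .synth import BandLibrary, GeneratorConfig, default_band_library, synth_dataset

__all__ = [
    "PipelineConfig",
    "RunReport",
    "baseline_correct_dataset",
    "preprocess_dataset",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

RATIO_BANDS = (1655.0, 1444.0)
PEAK_WINDOWS = {
    "silent_zone": (2100.0, 2800.0),
    "carbonyl": (1700.0, 1800.0),
    "glycogen_low": (400.0, 600.0),
}


@dataclass
class PipelineConfig:
    """Everything one run depends on; all randomness flows from the seeds here."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    asls: AslsParams = field(default_factory=AslsParams)
    polyfit_order: int = 5
    polyfit_max_iter: int = 100
    polyfit_tol: float = 1e-4
    regions: RegionSet = field(default_factory=lambda: DEFAULT_REGIONS)
    train_fraction: float = 5600 / 7409
    a_max: int = 10
    k_folds: int = 10
    cv_seed: int = 17
    ratio_halfwidth: float = 10.0

    def to_dict(self) -> dict:
        return {
            "generator": self.generator.to_dict(),
            "asls": {
                "lam": self.asls.lam,
                "p": self.asls.p,
                "n_iter": self.asls.n_iter,
            },
            "polyfit_order": self.polyfit_order,
            "polyfit_max_iter": self.polyfit_max_iter,
            "polyfit_tol": self.polyfit_tol,
            "regions": [list(iv) for iv in self.regions.intervals],
            "train_fraction": self.train_fraction,
            "a_max": self.a_max,
            "k_folds": self.k_folds,
            "cv_seed": self.cv_seed,
            "ratio_halfwidth": self.ratio_halfwidth,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kwargs: dict = {}
        if "generator" in d:
            kwargs["generator"] = GeneratorConfig.from_dict(d.pop("generator"))
        if "asls" in d:
            kwargs["asls"] = AslsParams(**d.pop("asls"))
        if "regions" in d:
            kwargs["regions"] = RegionSet(
                intervals=tuple(tuple(iv) for iv in d.pop("regions"))
            )
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class RunReport:
    """Everything a run found, JSON-serializable."""

    config: dict
    dataset_shape: tuple
    split_counts: dict
    cv_curve: dict
    chosen_components: int
    train_accuracy: dict
    test_accuracy: dict
    ratio_per_class: dict
    peaks_per_class: dict
    discriminant_regions: list

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "dataset_shape": list(self.dataset_shape),
            "split_counts": self.split_counts,
            "cv_curve": self.cv_curve,
            "chosen_components": self.chosen_components,
            "train_accuracy": self.train_accuracy,
            "test_accuracy": self.test_accuracy,
            "ratio_per_class": self.ratio_per_class,
            "peaks_per_class": self.peaks_per_class,
            "discriminant_regions": self.discriminant_regions,
        }


class _StageTimer:
    def __init__(self) -> None:
        self.timings: dict[str, float] = {}
        self._t0 = 0.0
        self._name = ""

    def start(self, name: str, **info) -> None:
        self._name, self._t0 = name, time.perf_counter()
        logger.info("stage %s: start %s", name, info or "")

    def stop(self, **info) -> None:
        dt = time.perf_counter() - self._t0
        self.timings[self._name] = round(dt, 3)
        logger.info("stage %s: done in %.2fs %s", self._name, dt, info or "")


def baseline_correct_dataset(
    dataset: SpectralDataset, config: PipelineConfig
) -> SpectralDataset:
    """Two-stage fluorescence removal on the full grid: modified polyfit
    for the gross background, then AsLS for the residual baseline."""
    x = dataset.grid.values
    base = polyfit_baseline_matrix(
        dataset.matrix,
        x,
        order=config.polyfit_order,
        max_iter=config.polyfit_max_iter,
        tol=config.polyfit_tol,
    )
    corrected = dataset.matrix - base
    resid = asls_baseline_matrix(corrected, config.asls)
    corrected -= resid
    out = dataset.copy()
    out.matrix = corrected
    return out


def preprocess_dataset(
    dataset: SpectralDataset,
    config: PipelineConfig,
    corrected: SpectralDataset | None = None,
) -> SpectralDataset:
    """Baseline-correct every spectrum, crop to the analysis regions and
    unit-area normalize (in that order)."""
    if corrected is None:
        corrected = baseline_correct_dataset(dataset, config)
    out = select_regions(corrected, config.regions)
    return normalize_dataset(out)


def _band_analytics(dataset: SpectralDataset, config: PipelineConfig):
    library = default_band_library()
    ratios: dict = {}
    peaks: dict = {}
    for cls in dataset.classes:
        avg = bands_mod.class_average(dataset, cls)
        ratios[cls] = bands_mod.intensity_ratio(
            avg, *RATIO_BANDS, halfwidth=config.ratio_halfwidth
        )
        per_window = {}
        for name, window in PEAK_WINDOWS.items():
            found = bands_mod.detect_peaks(avg, window=window)
            assigned = bands_mod.assign_peaks(found, library)
            per_window[name] = [
                {
                    "position_cm1": pk.position,
                    "height": pk.height,
                    "prominence": pk.prominence,
                    "assignment": asg,
                }
                for pk, asg in assigned
            ]
        peaks[cls] = per_window
    return ratios, peaks


def run_pipeline(
    config: PipelineConfig,
    outdir=None,
    library: BandLibrary | None = None,
    save_spectra: bool = False,
) -> RunReport:
    """Execute the full chain and (optionally) persist every artifact."""
    timer = _StageTimer()
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    timer.start("generate", maps=config.generator.n_maps_per_class)
    raw = synth_dataset(config.generator, library)
    timer.stop(shape=raw.matrix.shape)

    timer.start("preprocess")
    corrected = baseline_correct_dataset(raw, config)
    pre = preprocess_dataset(raw, config, corrected=corrected)
    timer.stop(shape=pre.matrix.shape)

    timer.start("split")
    assignment = stratified_duplex(pre, config.train_fraction)
    timer.stop(train=assignment.n_train, test=assignment.n_test)
    train = pre.subset_rows(assignment.train_rows)
    test = pre.subset_rows(assignment.test_rows)

    timer.start("cv_select")
    curve = plsda_mod.crossval_select(
        train.matrix,
        train.labels,
        a_max=config.a_max,
        k=config.k_folds,
        seed=config.cv_seed,
    )
    timer.stop(chosen=curve.chosen)

    timer.start("fit")
    model = plsda_mod.fit_plsda(train.matrix, train.labels, curve.chosen, strict=False)
    timer.stop()

    timer.start("evaluate")
    train_acc = plsda_mod.evaluate(model, train.matrix, train.labels)
    test_acc = plsda_mod.evaluate(model, test.matrix, test.labels)
    timer.stop(test=test_acc["per_class"])

    # band analytics read the corrected but uncropped spectra: the ratio is
    # scale-invariant and the 484 cm^-1 glycogen band sits below the crop
    timer.start("band_analytics")
    ratios, peaks = _band_analytics(corrected, config)
    report_regions = plsda_mod.discriminant_regions(model, pre.grid)
    timer.stop()

    report = RunReport(
        config=config.to_dict(),
        dataset_shape=tuple(pre.matrix.shape),
        split_counts={
            "train": assignment.n_train,
            "test": assignment.n_test,
            "per_class": {k: list(v) for k, v in assignment.per_class_counts.items()},
        },
        cv_curve=curve.to_dict(),
        chosen_components=curve.chosen,
        train_accuracy=train_acc,
        test_accuracy=test_acc,
        ratio_per_class=ratios,
        peaks_per_class=peaks,
        discriminant_regions=report_regions.regions.to_dict(orient="records"),
    )

    if outdir is not None:
        io_mod.write_json(outdir / "report.json", report.to_dict())
        # timings are run-dependent, so they live outside the (deterministic) report
        io_mod.write_json(outdir / "timings.json", timer.timings)
        assignment.to_json(outdir / "split.json")
        model.to_json(outdir / "model.json")
        report_regions.to_table().to_csv(outdir / "discriminant_channels.csv", index=False)
        report_regions.regions.to_csv(outdir / "discriminant_regions.csv", index=False)
        config.to_yaml(outdir / "config.yaml")
        if save_spectra:
            io_mod.write_dataset(outdir / "preprocessed.csv", pre)
            io_mod.write_dataset(outdir / "raw.csv", raw)
    return report
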