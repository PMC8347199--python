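"""Generate the default synthetic Raman map dataset and summarize it.

Writes a per-map summary table and the generator's band library to
results/.  The full-size spectral matrix (7409 x 3180 at the emulated
study's ROI fraction) is assembled to check its dimensions but not written
to disk at full scale; a down-sampled matrix is saved for inspection.
"""

from pathlib import Path

from hypospec import GeneratorConfig, default_band_library, synth_dataset
from hypospec import io as io_mod

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    library = default_band_library()
    library.to_json(RESULTS / "band_library.json")
    print(f"band library: {len(library.bands)} bands, classes {library.classes}")

    cfg = GeneratorConfig(
        n_maps_per_class=4, spectra_per_map=1000, roi_fraction=7409 / 8000, seed=42
    )
    ds = synth_dataset(cfg)
    print(f"assembled matrix: {ds.matrix.shape[0]} spectra x {ds.matrix.shape[1]} channels")

    summary = (
        ds.meta.groupby(["class", "map_id"])
        .size()
        .rename("n_spectra")
        .reset_index()
    )
    summary.to_csv(RESULTS / "map_summary.csv", index=False)
    print(summary.to_string(index=False))

    # compact inspectable preview: every 400th spectrum, every 10th channel
    from hypospec.datatypes import SpectralDataset, WavenumberGrid

    rows = ds.subset_rows(range(0, ds.n_spectra, 400))
    preview = SpectralDataset(
        grid=WavenumberGrid(rows.grid.values[::10]),
        matrix=rows.matrix[:, ::10],
        labels=rows.labels,
        meta=rows.meta,
    )
    io_mod.write_dataset(RESULTS / "sample_spectra_preview.csv", preview)
    print(
        f"wrote {preview.n_spectra} x {preview.n_channels} preview to "
        "results/sample_spectra_preview.csv"
    )


if __name__ == "__main__":
    main()
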