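"""Baseline-correct a 1000-spectra-per-class dataset and extract band-level
biochemistry: class-average spectra, peak tables with assignments, and the
1655/1444 lipid-saturation ratio per class.

Expected outcome: the HFD class shows the stronger glycogen (484/858/1460),
collagen, ester-carbonyl (1748) and silent-zone cyanide (2248) bands, and a
lower 1655/1444 ratio (~0.55 vs ~0.88), i.e. more saturated lipid.
"""

from pathlib import Path

import pandas as pd

from hypospec import (
    GeneratorConfig,
    assign_peaks,
    class_average,
    default_band_library,
    detect_peaks,
    intensity_ratio,
    synth_dataset,
)
from hypospec.bands import peak_table
from hypospec.pipeline import PipelineConfig, baseline_correct_dataset
from hypospec.plotting import plot_class_averages

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    gen = GeneratorConfig(n_maps_per_class=4, spectra_per_map=250, seed=42)
    ds = synth_dataset(gen)
    corrected = baseline_correct_dataset(ds, PipelineConfig(generator=gen))
    library = default_band_library()

    averages = []
    ratio_rows = []
    for cls in ("CTRL", "HFD"):
        avg = class_average(corrected, cls)
        averages.append(avg)
        ratio = intensity_ratio(avg)
        ratio_rows.append({"class": cls, "ratio_1655_1444": round(ratio, 3)})
        peaks = detect_peaks(avg, min_prominence=0.10)
        table = peak_table(assign_peaks(peaks, library))
        table.insert(0, "class", cls)
        table.to_csv(RESULTS / f"peaks_{cls}.csv", index=False)
        print(f"\n{cls}: ratio 1655/1444 = {ratio:.3f}; top peaks:")
        print(table.head(10).to_string(index=False))

    pd.DataFrame(ratio_rows).to_csv(RESULTS / "saturation_ratio.csv", index=False)
    plot_class_averages(averages, path=RESULTS / "class_averages.png")
    print("\nwrote peak tables, saturation_ratio.csv and class_averages.png")


if __name__ == "__main__":
    main()
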