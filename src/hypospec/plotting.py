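"""Optional plots: class-average spectra with SD envelopes and the VIP map."""

from __future__ import annotations

import numpy as np


def plot_class_averages(averages, path=None, ax=None):
    """Mean spectra with +/- 1 SD shading, one curve per class."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    for avg in averages:
        w = avg.grid.values
        ax.plot(w, avg.mean, label=f"{avg.class_label} (n={avg.n})", lw=1)
        ax.fill_between(w, avg.mean - avg.sd, avg.mean + avg.sd, alpha=0.25)
    ax.set_xlabel("Raman shift (cm$^{-1}$)")
    ax.set_ylabel("intensity (a.u.)")
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax


def plot_discriminant_map(report, mean_spectrum=None, path=None, ax=None):
    """VIP-significant channels shaded by regression-coefficient sign."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    w = report.wavenumbers
    base = mean_spectrum if mean_spectrum is not None else report.vip
    ax.plot(w, base, color="k", lw=1)
    pos = report.significant & (report.coef > 0)
    neg = report.significant & (report.coef <= 0)
    ax.fill_between(w, 0, np.where(pos, base, 0), color="red", alpha=0.4,
                    label="higher in code-1 class")
    ax.fill_between(w, 0, np.where(neg, base, 0), color="blue", alpha=0.4,
                    label="higher in code-0 class")
    ax.set_xlabel("Raman shift (cm$^{-1}$)")
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
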