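"""Optional figures: error histograms, scatter and Bland-Altman plots."""

from __future__ import annotations

import numpy as np

from .agreement import AgreementStats


def error_histograms(errors, unit: str = "", ax_signed=None, ax_abs=None):
    """Side-by-side histograms of signed and absolute errors."""
    import matplotlib.pyplot as plt

    if ax_signed is None or ax_abs is None:
        _, (ax_signed, ax_abs) = plt.subplots(1, 2, figsize=(9, 3.5))
    errors = np.asarray(errors, float)
    errors = errors[np.isfinite(errors)]
    ax_signed.hist(errors, bins=60, color="tab:blue")
    ax_signed.set_xlabel(f"signed error {unit}".strip())
    ax_abs.hist(np.abs(errors), bins=60, color="tab:orange")
    ax_abs.set_xlabel(f"absolute error {unit}".strip())
    for ax in (ax_signed, ax_abs):
        ax.set_ylabel("frames" if unit.endswith("deg") else "count")
    return ax_signed, ax_abs


def bland_altman_plot(table, stats: AgreementStats, unit: str = "mm", ax=None):
    """Bland-Altman scatter with mean difference and 95% limits of agreement."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(table["mean"], table["diff"], s=4, alpha=0.4)
    for y, style, label in ((stats.mean_signed, "-", "mean"),
                            (stats.loa_low, "--", "-1.96 SD"),
                            (stats.loa_high, "--", "+1.96 SD")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
        ax.annotate(f"{label}: {y:.2f}", (0.99, y), xycoords=("axes fraction", "data"),
                    ha="right", va="bottom", fontsize=8)
    ax.set_xlabel(f"pair mean ({unit})")
    ax.set_ylabel(f"pair difference ({unit})")
    return ax


def agreement_scatter(a_vals, b_vals, labels=("A", "B"), unit: str = "mm", ax=None):
    """Scatter of condition A vs condition B with the identity line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    a = np.asarray(a_vals, float)
    b = np.asarray(b_vals, float)
    ax.scatter(b, a, s=4, alpha=0.4)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    ax.plot([lo, hi], [lo, hi], "k-", linewidth=1)
    ax.set_xlabel(f"{labels[1]} ({unit})")
    ax.set_ylabel(f"{labels[0]} ({unit})")
    return ax
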