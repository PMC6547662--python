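"""Minimal plotting: measured-vs-predicted scatter with 1:1 and fit lines."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_measured_vs_predicted"]


def plot_measured_vs_predicted(measured, predicted, label: str = "", ax=None):
    """Scatter of predicted against measured content with the 1:1 line (red)
    and the least-squares fit line (black), the way calibration papers draw it."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    m = np.asarray(measured, dtype=np.float64)
    p = np.asarray(predicted, dtype=np.float64)
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(m, p, s=14, alpha=0.6, edgecolor="none")
    lo = min(m.min(), p.min())
    hi = max(m.max(), p.max())
    ax.plot([lo, hi], [lo, hi], color="red", lw=1, label="1:1")
    slope, intercept = np.polyfit(m, p, 1)
    ax.plot([lo, hi], [intercept + slope * lo, intercept + slope * hi],
            color="black", lw=1, label="fit")
    ax.set_xlabel("measured (% dry weight)")
    ax.set_ylabel("predicted (% dry weight)")
    if label:
        ax.set_title(label)
    ax.legend(frameon=False)
    return ax
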