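"""Diagnostic plot: log-scale UMI histogram with the QC window."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .thresholds import ThresholdSet

__all__ = ["plot_umi_histogram"]


def plot_umi_histogram(
    umi_totals: Sequence[float],
    thresholds: ThresholdSet,
    path: str | Path,
    bins: int = 100,
) -> Path:
    """Histogram of log10(UMI+1) with the lower/upper thresholds marked."""
    values = np.log10(np.asarray(umi_totals, float) + 1.0)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(values, bins=bins, color="0.7", edgecolor="none")
    for bound, style, label in (
        (thresholds.lower, "--", f"lower = {thresholds.lower:.0f}"),
        (thresholds.upper, "-", f"upper = {thresholds.upper:.0f}"),
    ):
        ax.axvline(np.log10(bound + 1.0), color="crimson", linestyle=style, label=label)
    ax.set_xlabel("log10(UMI total + 1)")
    ax.set_ylabel("barcodes")
    ax.set_title(f"{thresholds.sample_id}: UMI window")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
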