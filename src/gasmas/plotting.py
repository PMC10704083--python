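"""Cosmetic figure rendering for QC outputs (pathlength and box plots)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .stats_qc import BoxSummary, ConfigSummary


def plot_pathlength_summary(
    summaries: Sequence[ConfigSummary], path: str | Path, title: str = ""
) -> None:
    """Mean +- SD calculated pathlength per source-detector configuration."""
    kept = [s for s in summaries if s.mean_pathlength is not None]
    fig, ax = plt.subplots(figsize=(10, 4))
    x = range(len(kept))
    ax.errorbar(
        x,
        [s.mean_pathlength * 1e3 for s in kept],
        yerr=[(s.sd_pathlength or 0.0) * 1e3 for s in kept],
        fmt="o",
        capsize=3,
    )
    ax.axhline(230, color="crimson", ls="--", lw=1, label="outlier bound (230 mm)")
    ax.set_xticks(list(x))
    ax.set_xticklabels([s.config_id for s in kept], rotation=90, fontsize=6)
    ax.set_ylabel("pathlength (mm)")
    ax.set_title(title or "Calculated mean pathlength per configuration")
    ax.legend(loc="upper right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_concentration_boxes(
    boxes: Sequence[BoxSummary], path: str | Path, title: str = ""
) -> None:
    """Box plots of estimated O2 concentration per nominal gas batch."""
    fig, ax = plt.subplots(figsize=(6, 4))
    stats = [
        {
            "label": f"{b.label:g}%",
            "med": b.median,
            "q1": b.q1,
            "q3": b.q3,
            "whislo": b.whisker_low,
            "whishi": b.whisker_high,
            "fliers": list(b.outlier_values),
        }
        for b in boxes
    ]
    ax.bxp(stats, showfliers=True, medianprops={"color": "red"})
    for i, b in enumerate(boxes, start=1):
        ax.hlines(b.label, i - 0.35, i + 0.35, colors="k", linestyles=":", lw=1)
    ax.set_ylabel("estimated O2 concentration (%)")
    ax.set_xlabel("nominal O2 concentration")
    ax.set_title(title or "Estimated vs nominal O2 concentration")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
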