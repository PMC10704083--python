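#!/usr/bin/env python
"""Render summary figures from the QC tables.

Produces a per-configuration mean +- SD pathlength figure and estimated-vs-
nominal O2 concentration box plots from results/estimates.csv.

Run: python analysis/04_report.py
"""

import argparse
from pathlib import Path

import pandas as pd

from gasmas.inversion import GasEstimate
from gasmas.plotting import plot_concentration_boxes, plot_pathlength_summary
from gasmas.stats_qc import ConfigSummary, concentration_boxes


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--estimates", type=Path, default=Path("results/estimates.csv"))
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    frame = pd.read_csv(args.estimates)
    kept = frame[frame["valid"] & ~frame["outlier"]]

    summaries = []
    for config_id, group in kept.groupby("config_id"):
        summaries.append(
            ConfigSummary(
                config_id=config_id,
                n_total=len(frame[frame["config_id"] == config_id]),
                n_outliers=int(frame[frame["config_id"] == config_id]["outlier"].sum()),
                mean_pathlength=float(group["pathlength_m"].mean()),
                sd_pathlength=float(group["pathlength_m"].std() or 0.0),
                mean_o2=float(group["o2_fraction"].mean()),
                sd_o2=float(group["o2_fraction"].std() or 0.0),
            )
        )
    estimates = [
        GasEstimate(
            config_id=row.config_id,
            replicate=int(row.replicate),
            o2_nominal=float(row.o2_nominal),
            pathlength=float(row.pathlength_m),
            o2_fraction=float(row.o2_fraction),
            snr_764=float(row.snr_764),
            snr_820=float(row.snr_820),
            valid=bool(row.valid),
            outlier=bool(row.outlier),
        )
        for row in kept.itertuples(index=False)
    ]

    args.out_dir.mkdir(parents=True, exist_ok=True)
    plot_pathlength_summary(summaries, args.out_dir / "fig_pathlengths.png")
    plot_concentration_boxes(
        concentration_boxes(estimates), args.out_dir / "fig_o2_boxes.png"
    )
    print(f"figures -> {args.out_dir}/fig_pathlengths.png, fig_o2_boxes.png")


if __name__ == "__main__":
    main()
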