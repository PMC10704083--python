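#!/usr/bin/env python
"""Aggregate replicates and test configuration comparability.

From results/estimates.csv: per-configuration mean/SD pathlength over the
non-outlier replicates, pairwise two-sample KS tests between concentration
groups of each configuration (the constant-pathlength expectation), and box
statistics of the estimated O2 concentrations per nominal gas batch.

Run: python analysis/03_qc.py
"""

import argparse
from itertools import combinations
from pathlib import Path

import pandas as pd

from gasmas.stats_qc import ks_two_sample


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--estimates", type=Path, default=Path("results/estimates.csv"))
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    frame = pd.read_csv(args.estimates)
    kept = frame[frame["valid"] & ~frame["outlier"]]

    summary = (
        kept.groupby("config_id")
        .agg(
            n_kept=("pathlength_m", "size"),
            mean_pathlength_m=("pathlength_m", "mean"),
            sd_pathlength_m=("pathlength_m", "std"),
            mean_o2=("o2_fraction", "mean"),
            sd_o2=("o2_fraction", "std"),
        )
        .reset_index()
    )
    outlier_counts = frame.groupby("config_id")["outlier"].sum().rename("n_outliers")
    summary = summary.merge(outlier_counts, on="config_id", how="left")
    summary.to_csv(args.out_dir / "config_summaries.csv", index=False)

    rows = []
    for config_id, group in kept.groupby("config_id"):
        samples = {c: g["pathlength_m"].to_numpy() for c, g in group.groupby("o2_nominal")}
        for c1, c2 in combinations(sorted(samples), 2):
            res = ks_two_sample(samples[c1], samples[c2], method="asymp")
            rows.append({
                "config_id": config_id, "conc1": c1, "conc2": c2,
                "d": res.d_statistic, "p": res.p_value, "comparable": res.comparable,
            })
    ks = pd.DataFrame(rows)
    ks.to_csv(args.out_dir / "ks_concentration_pairs.csv", index=False)

    boxes = (
        kept.assign(o2_pct=kept["o2_fraction"] * 100,
                    nominal_pct=kept["o2_nominal"] * 100)
        .groupby("nominal_pct")["o2_pct"]
        .describe()[["count", "25%", "50%", "75%"]]
        .rename(columns={"25%": "q1", "50%": "median", "75%": "q3"})
    )
    boxes.to_csv(args.out_dir / "box_stats.csv")

    frac = ks["comparable"].mean() if len(ks) else float("nan")
    print(f"{len(summary)} configurations summarised "
          f"({int(frame['outlier'].sum())} outlier records excluded)")
    print(f"constant-pathlength check: {100 * frac:.1f}% of "
          f"{len(ks)} concentration-pair KS comparisons have p > 0.05")
    print(boxes.round(2).to_string())
    print(f"tables -> {args.out_dir}/config_summaries.csv, "
          f"ks_concentration_pairs.csv, box_stats.csv")


if __name__ == "__main__":
    main()
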