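#!/usr/bin/env python
"""Invert simulated scans into pathlengths and O2 concentrations.

Reads the JSON-lines scan file produced by 01_simulate.py, fits every
(764, 820) scan pair (baseline x Beer-Lambert Voigt model), converts the
820 nm water-vapor absorbance into an equivalent pathlength and the 764 nm
absorbance into an O2 fraction, applies the 0 m / >0.23 m outlier rule, and
writes per-replicate estimates to results/estimates.csv.

Run: python analysis/02_invert.py --scans scratch/scans_seed11_beta0.jsonl
"""

import argparse
from pathlib import Path

from gasmas.gas_physics import AmbientConditions
from gasmas.inversion import LinePair, invert_dataset
from gasmas.lines import h2o_line_820, o2_line_764
from gasmas.stats_qc import flag_outliers
from gasmas.workflow import estimates_frame, read_dataset


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--scans", type=Path,
                        default=Path("scratch/scans_seed11_beta0.jsonl"))
    parser.add_argument("--out", type=Path, default=Path("results/estimates.csv"))
    args = parser.parse_args()

    dataset = read_dataset(args.scans)
    conditions = next(iter(dataset.truth.values())).conditions if dataset.truth \
        else AmbientConditions()
    lines = LinePair(o2=o2_line_764(), h2o=h2o_line_820())
    estimates = flag_outliers(invert_dataset(dataset, conditions, lines))

    frame = estimates_frame(estimates)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(args.out, index=False)
    n_valid = int(frame["valid"].sum())
    n_out = int(frame["outlier"].sum())
    print(f"inverted {len(frame)} scan pairs: {n_valid} valid, "
          f"{n_out} flagged as outliers (0 m / >0.23 m rule or failed fit)")
    print(f"estimates -> {args.out}")


if __name__ == "__main__":
    main()
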