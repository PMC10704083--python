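"""End-to-end pipeline: configuration, file formats, manifest, reproducibility.

``run_pipeline`` chains simulate -> invert -> outlier QC -> aggregate ->
KS comparability -> concentration boxes, writing every artifact as plain
text (JSON-lines scans, CSV tables) plus a manifest with content hashes so
reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gas_physics import AmbientConditions
from .inversion import LinePair, SNR_MIN, invert_dataset
from .lines import h2o_line_820, o2_line_764
from .scan_synthesis import (
    ExperimentDesign,
    GroundTruth,
    ScanRecord,
    SimulatedDataset,
    default_design,
    sample_truth,
    simulate_experiment,
)
from .stats_qc import (
    OUTLIER_HIGH,
    OUTLIER_LOW,
    aggregate_replicates,
    compare_configurations,
    concentration_boxes,
    flag_outliers,
)

__all__ = ["RunConfig", "run_pipeline", "write_dataset", "read_dataset"]


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; YAML round-trips losslessly."""

    master_seed: int = 0
    noise_rel: float = 1e-5
    dark_noise: float = 1e-9
    beta: float = 0.0  # gas-mixing bias fraction
    n_tracheal: int = 15
    n_dermal: int = 15
    replicates: int = 21
    concentrations: list[float] = field(default_factory=lambda: [0.21, 0.30, 0.50, 1.00])
    n_undetectable: int = 2
    temperature: float = 293.15  # K
    pressure: float = 101325.0  # Pa
    relative_humidity: float = 1.0
    snr_min: float = SNR_MIN
    outlier_low: float = OUTLIER_LOW
    outlier_high: float = OUTLIER_HIGH
    out_dir: str = "results/run"
    write_scans: bool = True

    def conditions(self) -> AmbientConditions:
        return AmbientConditions(self.temperature, self.pressure, self.relative_humidity)

    def design(self) -> ExperimentDesign:
        design = default_design(self.n_tracheal, self.n_dermal, self.replicates)
        return ExperimentDesign(
            configs=design.configs,
            replicates=self.replicates,
            concentrations=tuple(self.concentrations),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not hold a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _record_to_json(record: ScanRecord) -> str:
    return json.dumps(
        {
            "config_id": record.config_id,
            "replicate": record.replicate,
            "channel": record.channel,
            "o2_nominal": record.o2_nominal,
            "seed_used": record.seed_used,
            "clipped": record.clipped,
            "detuning": [float(v) for v in record.detuning],
            "intensity": [float(v) for v in record.intensity],
        }
    )


def write_dataset(dataset: SimulatedDataset, path: str | Path) -> None:
    """Write scan records as JSON-lines and the truth sidecar as CSV.

    ``path`` is the JSONL file; the sidecar lands next to it with suffix
    ``.truth.csv``. Numeric fields survive the round trip at full double
    precision (json emits repr-exact floats).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(json.dumps({"format": "gasmas-scans", "version": 1,
                             "n_records": len(dataset.records),
                             "master_seed": dataset.master_seed}) + "\n")
        for record in dataset.records:
            fh.write(_record_to_json(record) + "\n")
    truth_columns = [
        "config_id",
        "o2_nominal",
        "o2_effective",
        "true_pathlength_m",
        "tissue_transmission",
        "temperature_K",
        "pressure_Pa",
        "relative_humidity",
    ]
    truth_rows = [
        {
            "config_id": t.config_id,
            "o2_nominal": t.o2_fraction_nominal,
            "o2_effective": t.o2_fraction_effective,
            "true_pathlength_m": t.true_pathlength,
            "tissue_transmission": t.tissue_transmission,
            "temperature_K": t.conditions.temperature,
            "pressure_Pa": t.conditions.pressure,
            "relative_humidity": t.conditions.relative_humidity,
        }
        for t in dataset.truth.values()
    ]
    pd.DataFrame(truth_rows, columns=truth_columns).to_csv(
        truth_sidecar_path(path), index=False
    )


def truth_sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".truth.csv")


def read_dataset(path: str | Path) -> SimulatedDataset:
    """Read a JSON-lines scan file (and its truth sidecar) back in."""
    path = Path(path)
    records: list[ScanRecord] = []
    master_seed = 0
    with open(path) as fh:
        header = fh.readline()
        try:
            meta = json.loads(header)
            master_seed = int(meta.get("master_seed", 0))
        except (json.JSONDecodeError, AttributeError) as err:
            raise ValueError(f"{path}: malformed header line: {err}") from None
        for index, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                records.append(
                    ScanRecord(
                        config_id=obj["config_id"],
                        replicate=int(obj["replicate"]),
                        channel=int(obj["channel"]),
                        detuning=np.asarray(obj["detuning"], dtype=float),
                        intensity=np.asarray(obj["intensity"], dtype=float),
                        seed_used=int(obj["seed_used"]),
                        o2_nominal=float(obj["o2_nominal"]),
                        clipped=bool(obj["clipped"]),
                    )
                )
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as err:
                raise ValueError(
                    f"{path}: corrupted scan record at index {index}: {err}"
                ) from None
    truth: dict[tuple[str, float], GroundTruth] = {}
    sidecar = truth_sidecar_path(path)
    if sidecar.exists():
        frame = pd.read_csv(sidecar)
        for row in frame.itertuples(index=False):
            truth[(row.config_id, float(row.o2_nominal))] = GroundTruth(
                config_id=row.config_id,
                true_pathlength=float(row.true_pathlength_m),
                o2_fraction_nominal=float(row.o2_nominal),
                o2_fraction_effective=float(row.o2_effective),
                tissue_transmission=float(row.tissue_transmission),
                conditions=AmbientConditions(
                    float(row.temperature_K),
                    float(row.pressure_Pa),
                    float(row.relative_humidity),
                ),
            )
    return SimulatedDataset(records=tuple(records), truth=truth, master_seed=master_seed)


def estimates_frame(estimates) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "config_id": e.config_id,
                "replicate": e.replicate,
                "o2_nominal": e.o2_nominal,
                "pathlength_m": e.pathlength,
                "o2_fraction": e.o2_fraction,
                "snr_764": e.snr_764,
                "snr_820": e.snr_820,
                "valid": e.valid,
                "outlier": e.outlier,
                "failure_reason": e.failure_reason or "",
            }
            for e in estimates
        ]
    )


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full in-silico protocol and write all artifacts.

    Returns the manifest dict (also written to ``manifest.json``): config
    echo, row counts per stage, output files with SHA-256 hashes, wall time.
    Rerunning with an identical config reproduces all non-timestamp content
    byte-identically.
    """
    started = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        conditions = config.conditions()
        design = config.design()
        truth = sample_truth(
            design,
            seed=config.master_seed,
            conditions=conditions,
            n_undetectable=config.n_undetectable,
        )
        dataset = simulate_experiment(
            design,
            truth,
            noise_rel=config.noise_rel,
            beta=config.beta,
            master_seed=config.master_seed,
            dark_noise=config.dark_noise,
        )
        if config.write_scans:
            write_dataset(dataset, out / "scans.jsonl")

        stage = "invert"
        lines = LinePair(o2=o2_line_764(), h2o=h2o_line_820())
        estimates = invert_dataset(dataset, conditions, lines, snr_min=config.snr_min)

        stage = "qc"
        estimates = flag_outliers(estimates, config.outlier_low, config.outlier_high)
        estimates_frame(estimates).to_csv(out / "estimates.csv", index=False)

        by_config: dict[str, list] = {}
        for est in estimates:
            by_config.setdefault(est.config_id, []).append(est)
        summaries = [aggregate_replicates(v) for _, v in sorted(by_config.items())]
        pd.DataFrame([asdict(s) for s in summaries]).to_csv(
            out / "config_summaries.csv", index=False
        )

        # Constant-pathlength comparability: KS between concentration groups
        # of the same configuration (all pairs), non-outlier records only.
        samples: dict[str, list[float]] = {}
        for est in estimates:
            if est.outlier or not est.valid:
                continue
            samples.setdefault(
                f"{est.config_id}@{est.o2_nominal:g}", []
            ).append(est.pathlength)
        pairs = []
        for cid in sorted(by_config):
            keys = sorted(k for k in samples if k.startswith(f"{cid}@"))
            pairs.extend(combinations(keys, 2))
        ks_rows = [
            {
                "group1": k1,
                "group2": k2,
                "d": res.d_statistic,
                "p": res.p_value,
                "n1": res.n1,
                "n2": res.n2,
                "comparable": res.comparable,
            }
            for k1, k2, res in compare_configurations(samples, pairs, method="asymp")
        ]
        pd.DataFrame(ks_rows).to_csv(out / "ks_pairs.csv", index=False)

        boxes = concentration_boxes(estimates)
        pd.DataFrame(
            [
                {
                    "o2_nominal_pct": b.label,
                    "median": b.median,
                    "q1": b.q1,
                    "q3": b.q3,
                    "whisker_low": b.whisker_low,
                    "whisker_high": b.whisker_high,
                    "n_fliers": len(b.outlier_values),
                }
                for b in boxes
            ]
        ).to_csv(out / "box_stats.csv", index=False)
    except Exception as err:
        manifest = {
            "status": "incomplete",
            "failed_stage": stage,
            "error": str(err),
            "config": asdict(config),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    config.to_yaml(out / "config.yaml")
    files = sorted(
        p for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "status": "complete",
        "config": asdict(config),
        "row_counts": {
            "scans": len(dataset.records),
            "estimates": len(estimates),
            "summaries": len(summaries),
            "ks_pairs": len(ks_rows),
            "boxes": len(boxes),
        },
        "outputs": {p.name: _sha256(p) for p in files},
        "wall_time_s": round(time.time() - started, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
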