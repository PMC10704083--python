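"""Synthetic dual-laser GASMAS scan generator with known ground truth.

Emulates the phantom experiment design: 30 source-detector configurations
(15 with an endotracheal source, 15 dermal/remittance), 21 re-attachment
replicates, four administered O2 concentrations (21/30/50/100%), and two
time-multiplexed laser channels (764 nm O2, 820 nm H2O). Each configuration
carries a constant true gas pathlength and a scalar tissue transmission
derived from diffusion-theory attenuation through an effective muscle layer.

The detected intensity model per channel is

    I(dnu) = I0 * B(dnu) * T_tissue * exp(-mu_a_gas(dnu) * L_cm) + noise

with B a mild quadratic injection-current ramp, mu_a_gas the Voigt line
profile from :mod:`gasmas.gas_physics`, and Gaussian noise with a
multiplicative term (noise_rel * local intensity) plus an absolute detector
dark-noise term (dark_noise * I0) added in quadrature — the dark term is what
makes strongly attenuated configurations fail, as in the bench experiment.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .gas_physics import (
    AmbientConditions,
    SpectralLine,
    doppler_sigma,
    number_density,
    peak_oxygen_mu_a_per_fraction,
    pressure_hwhm,
    voigt_peak,
    water_partial_pressure,
)
from .lines import h2o_line_820, o2_line_764
from scipy.special import voigt_profile

__all__ = [
    "MeasurementConfig",
    "TissueOpticalProperties",
    "TISSUE_OPTICAL_PROPERTIES",
    "GroundTruth",
    "ScanRecord",
    "ExperimentDesign",
    "default_design",
    "muscle_mu_eff",
    "sample_truth",
    "apply_mixing_bias",
    "simulate_scan",
    "simulate_experiment",
    "record_seed",
    "baseline_ramp",
    "default_scan_grid",
]

#: Intensity floor (fraction of channel power) applied after noise; records
#: that clip are flagged via ScanRecord.clipped.
INTENSITY_FLOOR_FRACTION = 1e-12

#: Channel source powers in mW (dual distributed-feedback diode source).
SOURCE_POWER_MW = {764: 20.3, 820: 16.6}

#: Quadratic injection-current ramp coefficients (documented constants).
BASELINE_B1 = 0.20
BASELINE_B2 = 0.05

#: Scan grid: 512 points across +-0.6 cm^-1 around line center.
SCAN_HALF_WIDTH = 0.6
SCAN_POINTS = 512


@dataclass(frozen=True)
class MeasurementConfig:
    """One source-detector configuration on one phantom."""

    geometry: int  # 1 or 2 (which neonatal CT anatomy)
    phantom_props: int  # 764 or 820 (which optical-property set the phantom mimics)
    illumination: str  # "tracheal" (transmittance) or "dermal" (remittance)
    detector_position: int  # 1..16
    side: str  # "left" or "right"
    config_id: str = ""

    def __post_init__(self) -> None:
        if self.geometry not in (1, 2):
            raise ValueError("geometry must be 1 or 2")
        if self.phantom_props not in (764, 820):
            raise ValueError("phantom_props must be 764 or 820")
        if self.illumination not in ("tracheal", "dermal"):
            raise ValueError("illumination must be 'tracheal' or 'dermal'")
        if not 1 <= self.detector_position <= 16:
            raise ValueError("detector_position must be in 1..16")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if not self.config_id:
            object.__setattr__(
                self,
                "config_id",
                f"{self.illumination}-g{self.geometry}-p{self.detector_position:02d}-{self.side}",
            )


@dataclass(frozen=True)
class TissueOpticalProperties:
    """Absorption and reduced scattering of one phantom tissue, cm^-1."""

    tissue: str
    mu_a: float
    mu_s_prime: float
    wavelength: int

    def __post_init__(self) -> None:
        if self.mu_a <= 0 or self.mu_s_prime <= 0:
            raise ValueError("optical coefficients must be positive")
        if self.wavelength not in (764, 820):
            raise ValueError("wavelength must be 764 or 820")


#: Phantom tissue optical properties (cm^-1) at the two laser wavelengths.
TISSUE_OPTICAL_PROPERTIES: dict[tuple[str, int], TissueOpticalProperties] = {
    (t, wl): TissueOpticalProperties(t, mu_a, mu_s, wl)
    for (t, wl, mu_a, mu_s) in [
        ("skin", 764, 0.03, 24.8),
        ("fat", 764, 0.13, 13.9),
        ("muscle", 764, 0.20, 14.1),
        ("bone", 764, 0.10, 9.30),
        ("heart", 764, 0.25, 4.89),
        ("skin", 820, 0.03, 22.8),
        ("fat", 820, 0.07, 13.2),
        ("muscle", 820, 0.20, 12.8),
        ("bone", 820, 0.11, 8.40),
        ("heart", 820, 0.11, 4.45),
    ]
}


@dataclass(frozen=True)
class GroundTruth:
    """Per-configuration truth shared by every replicate and concentration."""

    config_id: str
    true_pathlength: float  # m
    o2_fraction_nominal: float
    o2_fraction_effective: float
    tissue_transmission: float
    conditions: AmbientConditions

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_pathlength <= 0.5:
            raise ValueError("true_pathlength must lie in [0, 0.5] m")
        if not 0.0 < self.o2_fraction_effective <= 1.0:
            raise ValueError("o2_fraction_effective must lie in (0, 1]")
        if not 0.0 < self.tissue_transmission <= 1.0:
            raise ValueError("tissue_transmission must lie in (0, 1]")


@dataclass(frozen=True)
class ScanRecord:
    """One simulated intensity-vs-detuning sweep for one channel."""

    config_id: str
    replicate: int
    channel: int  # 764 or 820
    detuning: np.ndarray = field(repr=False)  # cm^-1
    intensity: np.ndarray = field(repr=False)  # detector units
    seed_used: int = 0
    o2_nominal: float = 0.21
    clipped: bool = False

    def __post_init__(self) -> None:
        det = np.asarray(self.detuning, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if det.shape != inten.shape:
            raise ValueError("detuning and intensity must have equal length")
        if np.any(np.diff(det) <= 0):
            raise ValueError("detuning must be strictly increasing")
        if self.channel not in (764, 820):
            raise ValueError("channel must be 764 or 820")


@dataclass(frozen=True)
class ExperimentDesign:
    """The full measurement plan: configurations x replicates x concentrations."""

    configs: tuple[MeasurementConfig, ...]
    replicates: int = 21
    concentrations: tuple[float, ...] = (0.21, 0.30, 0.50, 1.00)
    #: position pairs (per illumination mode) measured at the same spot
    duplicate_pairs: tuple[tuple[int, int], ...] = ((10, 11), (14, 15))

    def __post_init__(self) -> None:
        ids = [c.config_id for c in self.configs]
        if len(set(ids)) != len(ids):
            raise ValueError("config_id values must be unique within a design")

    def truth_key(self, config: MeasurementConfig) -> str:
        """Key under which a config's ground truth is drawn.

        Duplicated detector positions (consecutive measurements at the same
        spot) collapse onto the lower-numbered partner config of the same
        illumination mode and geometry, so both share one truth draw.
        """
        pos = config.detector_position
        for lo, hi in self.duplicate_pairs:
            if pos == hi:
                for other in self.configs:
                    if (
                        other.illumination == config.illumination
                        and other.geometry == config.geometry
                        and other.detector_position == lo
                    ):
                        return other.config_id
        return config.config_id


def default_design(
    n_tracheal: int = 15, n_dermal: int = 15, replicates: int = 21
) -> ExperimentDesign:
    """The study's default plan: 30 configurations, 21 replicates, 4 gases.

    Per illumination mode, detector positions 1..15: positions 1-8 on
    anatomy geometry 1 (phantom optical-property set 764 nm), 9-15 on
    geometry 2 (set 820 nm); odd positions on the right, even on the left.
    Pairs (10, 11) and (14, 15) are repeat placements sharing one truth.
    """
    configs: list[MeasurementConfig] = []
    for illumination, count in (("tracheal", n_tracheal), ("dermal", n_dermal)):
        for pos in range(1, count + 1):
            geometry = 1 if pos <= 8 else 2
            configs.append(
                MeasurementConfig(
                    geometry=geometry,
                    phantom_props=764 if geometry == 1 else 820,
                    illumination=illumination,
                    detector_position=pos,
                    side="right" if pos % 2 == 1 else "left",
                )
            )
    return ExperimentDesign(configs=tuple(configs), replicates=replicates)


def muscle_mu_eff(wavelength: int) -> float:
    """Effective attenuation sqrt(3 mu_a (mu_a + mu_s')) of muscle, cm^-1."""
    props = TISSUE_OPTICAL_PROPERTIES[("muscle", wavelength)]
    return float(np.sqrt(3.0 * props.mu_a * (props.mu_a + props.mu_s_prime)))


def sample_truth(
    design: ExperimentDesign,
    seed: int,
    conditions: AmbientConditions | None = None,
    pathlength_range: tuple[float, float] = (0.01, 0.20),
    thickness_range_mm: tuple[float, float] = (5.0, 25.0),
    n_undetectable: int = 2,
    detectability_floor: float = 1e-5,
) -> dict[str, GroundTruth]:
    """Draw per-configuration ground truth (pathlength, tissue transmission).

    Pathlengths are uniform on (0.01, 0.20) m, drawn once per truth key and
    reused across all concentrations. Tissue transmission is
    exp(-mu_eff * d) with mu_eff from the muscle optical properties of the
    phantom's wavelength set and thickness d uniform on 5-25 mm.
    ``n_undetectable`` configurations are assigned a transmission far below
    ``detectability_floor`` so their inversions fail, mimicking configurations
    lost to strong tissue attenuation.
    """
    if conditions is None:
        conditions = AmbientConditions()
    rng = np.random.default_rng(seed)
    truth: dict[str, GroundTruth] = {}
    drawn: dict[str, tuple[float, float]] = {}
    for config in design.configs:
        key = design.truth_key(config)
        if key not in drawn:
            length = rng.uniform(*pathlength_range)
            thickness_cm = rng.uniform(*thickness_range_mm) / 10.0
            drawn[key] = (length, thickness_cm)
        length, thickness_cm = drawn[key]
        transmission = float(
            np.exp(-muscle_mu_eff(config.phantom_props) * thickness_cm)
        )
        truth[config.config_id] = GroundTruth(
            config_id=config.config_id,
            true_pathlength=length,
            o2_fraction_nominal=0.21,
            o2_fraction_effective=0.21,
            tissue_transmission=transmission,
            conditions=conditions,
        )
    if n_undetectable > 0:
        unlucky = rng.choice(
            sorted(truth), size=min(n_undetectable, len(truth)), replace=False
        )
        for cid in unlucky:
            truth[cid] = replace(
                truth[cid], tissue_transmission=detectability_floor * 1e-2
            )
    return truth


def apply_mixing_bias(
    nominal_sequence: Sequence[float], beta: float
) -> list[float]:
    """Residual-gas mixing model for incompletely purged lung cavities.

    Each administered concentration mixes with a fraction ``beta`` of the
    previous cavity content: effective[k] = (1-beta)*nominal[k] +
    beta*effective[k-1], anchored at air (0.21) before the first step. With
    beta > 0 and an increasing administration sequence the 100% step stays
    strictly below 1.0 — the underestimation seen at full O2 supply.
    """
    if not 0.0 <= beta < 1.0:
        raise ValueError("beta must lie in [0, 1)")
    effective: list[float] = []
    previous = 0.21
    for nominal in nominal_sequence:
        value = (1.0 - beta) * nominal + beta * previous
        effective.append(value)
        previous = value
    return effective


def default_scan_grid() -> np.ndarray:
    """The instrument sweep grid: 512 points over +-0.6 cm^-1."""
    return np.linspace(-SCAN_HALF_WIDTH, SCAN_HALF_WIDTH, SCAN_POINTS)


def baseline_ramp(detuning: np.ndarray) -> np.ndarray:
    """Quadratic injection-current intensity ramp, ~unity at line center."""
    x = np.asarray(detuning, dtype=float) / SCAN_HALF_WIDTH
    return 1.0 + BASELINE_B1 * x + BASELINE_B2 * x * x


def record_seed(
    master_seed: int, config_id: str, replicate: int, o2_nominal: float, channel: int
) -> int:
    """Stable per-record seed < 2^31 derived from the master seed and keys."""
    key = f"{master_seed}|{config_id}|{replicate}|{o2_nominal:.6f}|{channel}"
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _gas_mu_a_profile(
    channel: int,
    truth: GroundTruth,
    grid: np.ndarray,
    h2o_line: SpectralLine,
    o2_line: SpectralLine,
) -> np.ndarray:
    """Gas absorption coefficient (cm^-1) on the sweep grid for one channel."""
    cond = truth.conditions
    if channel == 820:
        line = h2o_line
        strength_density = number_density(
            water_partial_pressure(cond), cond.temperature
        )
        peak = strength_density * line.line_strength
    else:
        line = o2_line
        kappa = peak_oxygen_mu_a_per_fraction(cond, line)
        sigma = doppler_sigma(line, cond.temperature)
        gamma = pressure_hwhm(line, cond.pressure)
        peak = truth.o2_fraction_effective * kappa / voigt_peak(sigma, gamma)
    sigma = doppler_sigma(line, cond.temperature)
    gamma = pressure_hwhm(line, cond.pressure)
    return peak * voigt_profile(np.asarray(grid, dtype=float), sigma, gamma)


def simulate_scan(
    truth: GroundTruth,
    channel: int,
    replicate: int,
    noise_rel: float,
    seed: int,
    dark_noise: float = 1e-9,
    grid: np.ndarray | None = None,
    h2o_line: SpectralLine | None = None,
    o2_line: SpectralLine | None = None,
) -> ScanRecord:
    """Simulate one detector sweep for one channel of one replicate."""
    if noise_rel < 0 or dark_noise < 0:
        raise ValueError("noise levels must be non-negative")
    if grid is None:
        grid = default_scan_grid()
    h2o_line = h2o_line or h2o_line_820()
    o2_line = o2_line or o2_line_764()
    mu_a = _gas_mu_a_profile(channel, truth, grid, h2o_line, o2_line)
    i0 = SOURCE_POWER_MW[channel]
    length_cm = truth.true_pathlength * 100.0
    clean = (
        i0
        * baseline_ramp(grid)
        * truth.tissue_transmission
        * np.exp(-mu_a * length_cm)
    )
    rng = np.random.default_rng(seed)
    sigma = np.sqrt((noise_rel * clean) ** 2 + (dark_noise * i0) ** 2)
    intensity = clean + rng.normal(0.0, 1.0, clean.shape) * sigma
    floor = INTENSITY_FLOOR_FRACTION * i0
    clipped = bool(np.any(intensity < floor))
    intensity = np.maximum(intensity, floor)
    return ScanRecord(
        config_id=truth.config_id,
        replicate=replicate,
        channel=channel,
        detuning=np.asarray(grid, dtype=float),
        intensity=intensity,
        seed_used=seed,
        o2_nominal=truth.o2_fraction_nominal,
        clipped=clipped,
    )


@dataclass(frozen=True)
class SimulatedDataset:
    """All scan records of one simulated experiment plus the truth sidecar."""

    records: tuple[ScanRecord, ...]
    truth: dict[tuple[str, float], GroundTruth]  # keyed by (config_id, o2_nominal)
    master_seed: int

    def __len__(self) -> int:
        return len(self.records)

    def pairs(self) -> Iterable[tuple[ScanRecord, ScanRecord]]:
        """Yield matched (764, 820) scan pairs per config/replicate/gas."""
        by_key: dict[tuple[str, int, float], dict[int, ScanRecord]] = {}
        for rec in self.records:
            by_key.setdefault(
                (rec.config_id, rec.replicate, rec.o2_nominal), {}
            )[rec.channel] = rec
        for key in sorted(by_key):
            channels = by_key[key]
            if set(channels) == {764, 820}:
                yield channels[764], channels[820]


def simulate_experiment(
    design: ExperimentDesign,
    truth: dict[str, GroundTruth],
    noise_rel: float = 1e-5,
    beta: float = 0.0,
    master_seed: int = 0,
    dark_noise: float = 1e-9,
) -> SimulatedDataset:
    """Simulate the full design: configs x replicates x gases x 2 channels.

    The default design yields 30 x 21 x 4 x 2 = 5040 scan records. Per-record
    seeds derive deterministically from ``master_seed`` and the record keys,
    so any single record — and the whole dataset — regenerates bit-identically.
    """
    nominals = list(design.concentrations)
    effectives = apply_mixing_bias(nominals, beta)
    records: list[ScanRecord] = []
    truth_sidecar: dict[tuple[str, float], GroundTruth] = {}
    for config in design.configs:
        base = truth[config.config_id]
        for nominal, effective in zip(nominals, effectives):
            truth_c = replace(
                base, o2_fraction_nominal=nominal, o2_fraction_effective=effective
            )
            truth_sidecar[(config.config_id, nominal)] = truth_c
            for replicate in range(1, design.replicates + 1):
                for channel in (764, 820):
                    seed = record_seed(
                        master_seed, config.config_id, replicate, nominal, channel
                    )
                    records.append(
                        simulate_scan(
                            truth_c,
                            channel,
                            replicate,
                            noise_rel,
                            seed,
                            dark_noise=dark_noise,
                        )
                    )
    return SimulatedDataset(
        records=tuple(records), truth=truth_sidecar, master_seed=master_seed
    )
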