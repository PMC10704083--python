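"""Gas-phase absorption physics for GASMAS inversion.

Water vapor (820 nm) and molecular oxygen (764 nm, A band) absorption
coefficients are built from first principles: Arden Buck hygrometry gives the
water partial pressure at ambient conditions, the ideal gas law converts
partial pressures to number densities, and a Voigt line shape (Doppler
Gaussian convolved with pressure-broadened Lorentzian) turns a tabulated line
strength into a peak absorption coefficient.

Units follow spectroscopic convention: wavenumbers and absorption
coefficients in cm^-1, line strengths in cm^-1/(molecule cm^-2), number
densities in molecules cm^-3. Everything else is SI (kelvin, pascal, metre).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import voigt_profile

__all__ = [
    "BOLTZMANN",
    "AmbientConditions",
    "SpectralLine",
    "AbsorptionSpectrum",
    "saturation_vapor_pressure",
    "water_partial_pressure",
    "number_density",
    "voigt_peak",
    "doppler_sigma",
    "pressure_hwhm",
    "default_grid",
    "absorption_spectrum",
    "peak_water_mu_a",
    "peak_oxygen_mu_a_per_fraction",
]

BOLTZMANN = 1.380649e-23  # J/K (exact, SI 2019)
SPEED_OF_LIGHT = 2.99792458e8  # m/s (exact)
AVOGADRO = 6.02214076e23  # 1/mol (exact)

#: Validity window of the Buck (1996) saturation-pressure fit, kelvin.
BUCK_T_MIN = 173.0
BUCK_T_MAX = 373.0


def saturation_vapor_pressure(temperature: float) -> float:
    """Saturation vapor pressure of water over liquid, Buck (1996) form.

    e_s = 611.21 * exp((18.678 - t/234.5) * (t / (257.14 + t))) with t in
    degrees Celsius; no enhancement factor (sub-0.5% at ambient pressure).

    Parameters
    ----------
    temperature : float
        Gas temperature in kelvin, within (173, 373) K.

    Returns
    -------
    float
        Saturation pressure in pascal.
    """
    if not (BUCK_T_MIN < temperature < BUCK_T_MAX):
        raise ValueError(
            f"temperature {temperature!r} K outside the Buck-equation validity "
            f"window ({BUCK_T_MIN:.0f}, {BUCK_T_MAX:.0f}) K"
        )
    t = temperature - 273.15
    return 611.21 * np.exp((18.678 - t / 234.5) * (t / (257.14 + t)))


@dataclass(frozen=True)
class AmbientConditions:
    """Ambient gas state driving all hygrometry and densities.

    Attributes
    ----------
    temperature : float
        Kelvin; must sit in the Buck validity window when humidity > 0.
    pressure : float
        Total ambient pressure, pascal.
    relative_humidity : float
        Fraction in [0, 1] (1.0 = saturated, the humidified-gas case).
    """

    temperature: float = 293.15
    pressure: float = 101325.0
    relative_humidity: float = 1.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if self.pressure <= 0:
            raise ValueError("pressure must be positive (pascal)")
        if not 0.0 <= self.relative_humidity <= 1.0:
            raise ValueError("relative_humidity must lie in [0, 1]")
        if self.relative_humidity > 0:
            e_w = self.relative_humidity * saturation_vapor_pressure(self.temperature)
            if e_w > self.pressure:
                raise ValueError(
                    "derived water partial pressure exceeds total pressure"
                )


@dataclass(frozen=True)
class SpectralLine:
    """One molecular absorption line (HITRAN-style parameters).

    ``line_strength`` is the integrated line intensity in
    cm^-1/(molecule cm^-2); ``lorentz_hwhm`` is the air-broadened half width
    at ``reference_pressure`` and scales linearly with total pressure.
    """

    species: str  # "H2O" or "O2"
    center_wavenumber: float  # cm^-1
    line_strength: float  # cm^-1 / (molecule cm^-2)
    lorentz_hwhm: float  # cm^-1 at reference_pressure
    reference_pressure: float = 101325.0  # Pa
    molar_mass: float = 18.010565  # g/mol

    def __post_init__(self) -> None:
        if self.species not in ("H2O", "O2"):
            raise ValueError(f"unknown species {self.species!r}")
        if self.center_wavenumber <= 0:
            raise ValueError("center_wavenumber must be positive")
        if self.line_strength <= 0:
            raise ValueError("line_strength must be positive")
        if self.lorentz_hwhm < 0:
            raise ValueError("lorentz_hwhm must be non-negative")


@dataclass(frozen=True)
class AbsorptionSpectrum:
    """Absorption coefficient sampled on a detuning grid around one line."""

    detuning_grid: np.ndarray = field(repr=False)  # cm^-1, strictly increasing
    mu_a: np.ndarray = field(repr=False)  # cm^-1
    mu_a_peak: float = 0.0  # cm^-1

    def __post_init__(self) -> None:
        grid = np.asarray(self.detuning_grid, dtype=float)
        mu = np.asarray(self.mu_a, dtype=float)
        if grid.shape != mu.shape:
            raise ValueError("detuning_grid and mu_a must have equal shape")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("detuning_grid must be strictly increasing")
        if np.any(mu < 0):
            raise ValueError("mu_a must be non-negative everywhere")

    def integral(self) -> float:
        """Trapezoidal integral of mu_a over the grid (cm^-2)."""
        return float(np.trapezoid(self.mu_a, self.detuning_grid))


def water_partial_pressure(conditions: AmbientConditions) -> float:
    """Partial pressure of water vapor e_w' = RH * e_s(T), pascal."""
    if conditions.relative_humidity == 0.0:
        return 0.0
    return conditions.relative_humidity * saturation_vapor_pressure(
        conditions.temperature
    )


def number_density(partial_pressure: float, temperature: float) -> float:
    """Ideal-gas number density p / (k_B T), in molecules cm^-3."""
    if partial_pressure < 0:
        raise ValueError("partial_pressure must be non-negative")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return partial_pressure / (BOLTZMANN * temperature) * 1e-6


def voigt_peak(gaussian_sigma: float, lorentz_hwhm: float) -> float:
    """Unit-area Voigt profile evaluated at line center, in cm.

    Reduces to 1/(pi*gamma) for a pure Lorentzian and 1/(sigma*sqrt(2*pi))
    for a pure Gaussian.
    """
    if gaussian_sigma < 0 or lorentz_hwhm < 0:
        raise ValueError("widths must be non-negative")
    if gaussian_sigma == 0.0 and lorentz_hwhm == 0.0:
        raise ValueError("at least one of the Voigt widths must be positive")
    return float(voigt_profile(0.0, gaussian_sigma, lorentz_hwhm))


def doppler_sigma(line: SpectralLine, temperature: float) -> float:
    """Gaussian (Doppler) standard deviation nu0*sqrt(kB*T/(m*c^2)), cm^-1."""
    mass_kg = line.molar_mass * 1e-3 / AVOGADRO
    return line.center_wavenumber * float(
        np.sqrt(BOLTZMANN * temperature / (mass_kg * SPEED_OF_LIGHT**2))
    )


def pressure_hwhm(line: SpectralLine, pressure: float) -> float:
    """Lorentzian HWHM scaled linearly from the line's reference pressure."""
    return line.lorentz_hwhm * pressure / line.reference_pressure


def _voigt_fwhm(sigma: float, gamma: float) -> float:
    # Olivero-Longbothum approximation; only used for grid-coverage checks.
    fl = 2.0 * gamma
    fg = 2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma
    return 0.5346 * fl + np.sqrt(0.2166 * fl**2 + fg**2)


def default_grid(
    line: SpectralLine,
    conditions: AmbientConditions,
    half_width: float = 20.0,
    n_points: int = 8001,
) -> np.ndarray:
    """Symmetric detuning grid wide enough for 1%-accurate line integrals.

    The Lorentzian wings carry ~2*gamma/(pi*X) of the area beyond +-X, so the
    default +-20 cm^-1 leaves ~0.3% outside for ambient-pressure lines.
    """
    del conditions  # grid width dominated by Lorentz wings at ambient P
    return np.linspace(-half_width, half_width, n_points)


def absorption_spectrum(
    line: SpectralLine,
    species_density: float,
    conditions: AmbientConditions,
    grid: np.ndarray,
) -> AbsorptionSpectrum:
    """Line absorption coefficient mu_a(detuning) = N * S * phi_V(detuning).

    phi_V is the area-normalized Voigt profile with Doppler sigma from the
    gas temperature and Lorentz HWHM pressure-scaled from the line's
    reference. A grid narrower than +-10 Voigt FWHM triggers a warning: line
    integrals on such a grid under-count the Lorentzian wings.
    """
    grid = np.asarray(grid, dtype=float)
    if species_density < 0:
        raise ValueError("species_density must be non-negative")
    sigma = doppler_sigma(line, conditions.temperature)
    gamma = pressure_hwhm(line, conditions.pressure)
    fwhm = _voigt_fwhm(sigma, gamma)
    if min(-grid[0], grid[-1]) < 10.0 * fwhm:
        warnings.warn(
            f"detuning grid covers less than +-10 line widths "
            f"({10 * fwhm:.3g} cm^-1); wing area will be truncated",
            stacklevel=2,
        )
    profile = voigt_profile(grid, sigma, gamma)
    mu = species_density * line.line_strength * profile
    peak = species_density * line.line_strength * voigt_peak(sigma, gamma)
    return AbsorptionSpectrum(detuning_grid=grid, mu_a=mu, mu_a_peak=float(peak))


def peak_water_mu_a(conditions: AmbientConditions, line: SpectralLine) -> float:
    """Peak (line-center) water-vapor absorption coefficient, cm^-1.

    Composes Buck hygrometry, the ideal gas law and the Voigt peak value.
    At 293 K, 100% RH and the packaged 820 nm line this is ~3.1e-5 cm^-1,
    the quantity the humidity-referenced pathlength inversion divides by.
    """
    if line.species != "H2O":
        raise ValueError("peak_water_mu_a requires an H2O line")
    n = number_density(water_partial_pressure(conditions), conditions.temperature)
    if n == 0.0:
        return 0.0
    sigma = doppler_sigma(line, conditions.temperature)
    gamma = pressure_hwhm(line, conditions.pressure)
    return n * line.line_strength * voigt_peak(sigma, gamma)


def peak_oxygen_mu_a_per_fraction(
    conditions: AmbientConditions, line: SpectralLine
) -> float:
    """Peak O2 absorption coefficient per unit O2 mole fraction, cm^-1.

    The fraction is defined on the dry-gas basis: the dry number density is
    (P - e_w')/(k_B T), because delivered O2 concentrations are specified
    before humidification.
    """
    if line.species != "O2":
        raise ValueError("peak_oxygen_mu_a_per_fraction requires an O2 line")
    e_w = water_partial_pressure(conditions)
    if e_w >= conditions.pressure:
        raise ValueError("water partial pressure consumes the total pressure")
    n_dry = number_density(conditions.pressure - e_w, conditions.temperature)
    sigma = doppler_sigma(line, conditions.temperature)
    gamma = pressure_hwhm(line, conditions.pressure)
    return n_dry * line.line_strength * voigt_peak(sigma, gamma)
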