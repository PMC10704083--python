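"""Packaged spectral-line fixtures and their plain-text constants file."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

from .gas_physics import SpectralLine

__all__ = ["load_line_table", "h2o_line_820", "o2_line_764"]


def _parse_constants(text: str) -> dict[str, float]:
    values: dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        stripped = raw.split("#", 1)[0].strip()
        if not stripped:
            continue
        parts = stripped.split()
        if len(parts) < 2:
            raise ValueError(f"malformed constants row at line {lineno}: {raw!r}")
        values[parts[0]] = float(parts[1])
    return values


@lru_cache(maxsize=1)
def load_line_table() -> dict[str, SpectralLine]:
    """Parse data/spectral_lines.txt into SpectralLine fixtures."""
    text = (
        resources.files("gasmas").joinpath("data/spectral_lines.txt").read_text()
    )
    v = _parse_constants(text)
    return {
        "H2O": SpectralLine(
            species="H2O",
            center_wavenumber=v["h2o.center_wavenumber"],
            line_strength=v["h2o.line_strength"],
            lorentz_hwhm=v["h2o.lorentz_hwhm"],
            reference_pressure=v["h2o.reference_pressure"],
            molar_mass=v["h2o.molar_mass"],
        ),
        "O2": SpectralLine(
            species="O2",
            center_wavenumber=v["o2.center_wavenumber"],
            line_strength=v["o2.line_strength"],
            lorentz_hwhm=v["o2.lorentz_hwhm"],
            reference_pressure=v["o2.reference_pressure"],
            molar_mass=v["o2.molar_mass"],
        ),
    }


def h2o_line_820() -> SpectralLine:
    """The packaged water-vapor line near 820.0 nm."""
    return load_line_table()["H2O"]


def o2_line_764() -> SpectralLine:
    """The packaged oxygen A-band line near 763.8 nm."""
    return load_line_table()["O2"]
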