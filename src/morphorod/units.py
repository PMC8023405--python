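"""Parsing of human-readable quantities ("20 h", "0.5 mm") into SI floats.

All internal computation is in SI units; values with units appear only at the
I/O boundary (config files, CLI, reports).
"""

from __future__ import annotations

import re

# multiplicative factors to SI base units
_FACTORS: dict[str, float] = {
    # time -> s
    "s": 1.0,
    "sec": 1.0,
    "min": 60.0,
    "h": 3600.0,
    "hr": 3600.0,
    "d": 86400.0,
    "day": 86400.0,
    # length -> m
    "m": 1.0,
    "cm": 1e-2,
    "mm": 1e-3,
    "um": 1e-6,
    # pressure -> Pa
    "Pa": 1.0,
    "kPa": 1e3,
    "MPa": 1e6,
    "GPa": 1e9,
    # density -> kg/m^3
    "kg/m^3": 1.0,
    "kg/m3": 1.0,
    "g/cm^3": 1e3,
    "g/cm3": 1e3,
    # acceleration -> m/s^2
    "m/s^2": 1.0,
    "m/s2": 1.0,
    # dimensionless
    "": 1.0,
    "1": 1.0,
}

_NUMBER = re.compile(r"^\s*([+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?)\s*(.*)$")


class UnitError(ValueError):
    """Raised for unparseable or unknown-unit quantity strings."""


def parse_quantity(value: float | int | str, *, field: str = "") -> float:
    """Convert ``value`` to an SI float.

    Numbers pass through unchanged (assumed SI); strings may carry a unit
    suffix, e.g. ``"12 min"`` -> 720.0, ``"10 MPa"`` -> 1.0e7.
    """
    if isinstance(value, (int, float)):
        return float(value)
    if not isinstance(value, str):
        raise UnitError(f"{field or 'quantity'}: cannot parse {value!r}")
    m = _NUMBER.match(value)
    if m is None:
        raise UnitError(f"{field or 'quantity'}: cannot parse {value!r}")
    number, unit = m.groups()
    unit = unit.strip()
    if unit not in _FACTORS:
        raise UnitError(f"{field or 'quantity'}: unknown unit {unit!r} in {value!r}")
    return float(number) * _FACTORS[unit]


def format_quantity(si_value: float, unit: str) -> str:
    """Format an SI value in the given display unit (inverse of parse)."""
    if unit not in _FACTORS:
        raise UnitError(f"unknown unit {unit!r}")
    return f"{si_value / _FACTORS[unit]:g} {unit}".strip()
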