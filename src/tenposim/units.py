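"""Unit-string parsing.

Configuration files carry every physical quantity as ``"<number> <unit>"``;
internally everything is SI (m, s, kg, T, Pa·s, A/m).  Only the handful of
units that appear in device configs are supported — this is a lookup table,
not a units system.
"""

from __future__ import annotations

import re

# Multiplicative factor to SI for each accepted unit string.
_TO_SI: dict[str, float] = {
    # length
    "m": 1.0,
    "mm": 1e-3,
    "um": 1e-6,
    "µm": 1e-6,
    "nm": 1e-9,
    # area
    "m^2": 1.0,
    "cm^2": 1e-4,
    "mm^2": 1e-6,
    # areal density (pores per area)
    "1/m^2": 1.0,
    "1/cm^2": 1e4,
    "m^-2": 1.0,
    "cm^-2": 1e4,
    # volumetric flow rate
    "m^3/s": 1.0,
    "mL/h": 1e-6 / 3600.0,
    "mL/hr": 1e-6 / 3600.0,
    "uL/min": 1e-9 / 60.0,
    # viscosity
    "Pa.s": 1.0,
    "Pa*s": 1.0,
    "mPa.s": 1e-3,
    # magnetic flux density
    "T": 1.0,
    "mT": 1e-3,
    "G": 1e-4,
    "gauss": 1e-4,
    # magnetic field strength / magnetization
    "A/m": 1.0,
    "kA/m": 1e3,
    # velocity
    "m/s": 1.0,
    "um/s": 1e-6,
    # time
    "s": 1.0,
    "ms": 1e-3,
    # dimensionless
    "": 1.0,
    "1": 1.0,
}

_QUANTITY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*(.*?)\s*$")


class UnitError(ValueError):
    """Raised for malformed or unknown unit strings."""


def parse_quantity(value, expect: str | None = None) -> float:
    """Convert ``"2.5 mL/h"`` (or a bare number) to SI.

    Parameters
    ----------
    value
        Either a number (returned unchanged: already SI) or a string of the
        form ``"<number> <unit>"``.
    expect
        Optional dimension hint used only in error messages.
    """
    if isinstance(value, (int, float)):
        return float(value)
    if not isinstance(value, str):
        raise UnitError(f"cannot parse quantity from {value!r}")
    m = _QUANTITY_RE.match(value)
    if m is None:
        raise UnitError(f"malformed quantity {value!r}")
    number, unit = m.groups()
    unit = unit.replace("μ", "u").replace("µ", "u").replace("²", "^2")
    # normalise the µ that _TO_SI spells out
    if unit not in _TO_SI and unit.replace("u", "µ") in _TO_SI:
        unit = unit.replace("u", "µ")
    if unit not in _TO_SI:
        hint = f" (expected a {expect})" if expect else ""
        raise UnitError(f"unknown unit {unit!r} in {value!r}{hint}")
    try:
        x = float(number)
    except ValueError as exc:
        raise UnitError(f"malformed number in {value!r}") from exc
    return x * _TO_SI[unit]


def format_quantity(value_si: float, unit: str) -> str:
    """Format an SI value in the given display unit (inverse of parse)."""
    if unit not in _TO_SI:
        u = unit.replace("µ", "u")
        if u not in _TO_SI:
            raise UnitError(f"unknown unit {unit!r}")
        unit_key = u
    else:
        unit_key = unit
    return f"{value_si / _TO_SI[unit_key]:g} {unit}"
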