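"""Unit parsing at the package boundary.

Internally everything is SI (m, Pa, N/m, s). User-facing interfaces accept
values with explicit unit suffixes ("12um", "6kPa", "4mN/m") and convert
here; bare numbers are taken as SI. Mixed implicit units are the main
foreseeable bug in a workflow that quotes lengths in um, tensions in mN/m
and moduli in kPa, so suffixes are required whenever a non-SI unit is meant.
"""

from __future__ import annotations

import re

__all__ = ["parse_quantity", "Q"]

_FACTORS = {
    # length -> m
    "m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9,
    # stress -> Pa
    "pa": 1.0, "kpa": 1e3, "mpa": 1e6,
    # tension -> N/m
    "n/m": 1.0, "mn/m": 1e-3,
    # volume -> L
    "l": 1.0, "ml": 1e-3, "ul": 1e-6, "µl": 1e-6,
    # force -> N
    "n": 1.0, "mn": 1e-3,
    # time -> s
    "s": 1.0, "min": 60.0, "h": 3600.0,
}

_QUANTITY_RE = re.compile(
    r"^\s*([-+]?[0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?)\s*([a-zA-Zµ/]*)\s*$"
)


def parse_quantity(text: str | float, default_unit: str | None = None) -> float:
    """Parse "value[unit]" into SI. Bare numbers use default_unit (or SI).

    >>> parse_quantity("4mN/m")
    0.004
    >>> parse_quantity("6kPa")
    6000.0
    >>> parse_quantity(12e-6)
    1.2e-05
    """
    if isinstance(text, (int, float)):
        value, unit = float(text), (default_unit or "")
    else:
        m = _QUANTITY_RE.match(text)
        if not m:
            raise ValueError(f"cannot parse quantity {text!r}")
        value = float(m.group(1))
        unit = m.group(2) or (default_unit or "")
    if not unit:
        return value
    key = unit.lower()
    if key not in _FACTORS:
        raise ValueError(f"unknown unit {unit!r} in {text!r}")
    return value * _FACTORS[key]


Q = parse_quantity
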