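"""Unit conventions and conversions.

Everything inside the package runs in a single set of canonical units:

* time        — hours
* concentration — nanomolar (nM = nmol/L)
* amount      — nanomoles (nmol)
* volume      — litres
* mass dose   — milligrams
* molecular weight — Daltons (g/mol)

Literature parameter tables mix minutes, hours, days and weeks; all
durations are converted to hours on ingestion (see :func:`parse_duration`)
so that no other module ever sees a mixed-unit quantity.
"""

from __future__ import annotations

import math
import re

__all__ = [
    "InvalidParameterError",
    "mg_to_nmol",
    "nmol_to_mg",
    "mg_per_kg_to_mg",
    "half_life_to_rate",
    "rate_to_half_life",
    "nM_to_ug_per_ml",
    "parse_duration",
    "LN2",
    "AVOGADRO",
]

LN2 = math.log(2.0)

#: CODATA value, molecules per mole.
AVOGADRO = 6.02214076e23

_DURATION_RE = re.compile(r"^\s*([0-9eE+.\-]+)\s*([a-zA-Z]*)\s*$")

_HOURS_PER = {
    "": 1.0,
    "h": 1.0,
    "hr": 1.0,
    "hrs": 1.0,
    "hour": 1.0,
    "hours": 1.0,
    "min": 1.0 / 60.0,
    "mins": 1.0 / 60.0,
    "minute": 1.0 / 60.0,
    "minutes": 1.0 / 60.0,
    "d": 24.0,
    "day": 24.0,
    "days": 24.0,
    "w": 168.0,
    "wk": 168.0,
    "week": 168.0,
    "weeks": 168.0,
}


class InvalidParameterError(ValueError):
    """A numeric parameter violates its physical domain (named in the message)."""

    def __init__(self, field: str, message: str) -> None:
        self.field = field
        super().__init__(f"{field}: {message}")


def parse_duration(value: float | int | str) -> float:
    """Convert a duration to hours.

    Accepts a bare number (already hours) or a string such as ``"30 min"``,
    ``"20 d"``, ``"2 weeks"``.
    """
    if isinstance(value, (int, float)):
        return float(value)
    m = _DURATION_RE.match(str(value))
    if not m:
        raise InvalidParameterError("duration", f"cannot parse {value!r}")
    num, unit = m.groups()
    try:
        factor = _HOURS_PER[unit.lower()]
    except KeyError:
        raise InvalidParameterError("duration", f"unknown time unit {unit!r}") from None
    return float(num) * factor


def mg_to_nmol(dose_mg: float, mw: float) -> float:
    """Convert a mass dose (mg) to an amount (nmol) given molecular weight (Da).

    ``nmol = mg / (g/mol) * 1e6`` — exact arithmetic, no rounding.
    """
    if mw <= 0:
        raise InvalidParameterError("mw", "molecular weight must be > 0")
    if dose_mg < 0:
        raise InvalidParameterError("dose_mg", "dose must be >= 0")
    return dose_mg / mw * 1e6


def nmol_to_mg(amount_nmol: float, mw: float) -> float:
    """Inverse of :func:`mg_to_nmol`."""
    if mw <= 0:
        raise InvalidParameterError("mw", "molecular weight must be > 0")
    return amount_nmol * mw * 1e-6


def mg_per_kg_to_mg(dose_mg_per_kg: float, body_weight_kg: float) -> float:
    """Resolve a weight-based dose (mg/kg) to an absolute dose (mg)."""
    if dose_mg_per_kg < 0:
        raise InvalidParameterError("dose_mg_per_kg", "dose must be >= 0")
    if body_weight_kg < 0:
        raise InvalidParameterError("body_weight_kg", "body weight must be >= 0")
    return dose_mg_per_kg * body_weight_kg


def half_life_to_rate(t_half_hours: float) -> float:
    """First-order rate constant (1/h) for an exponential half-life (h)."""
    if t_half_hours <= 0:
        raise InvalidParameterError("t_half", "half-life must be > 0")
    return LN2 / t_half_hours


def rate_to_half_life(rate_per_hour: float) -> float:
    """Half-life (h) for a first-order rate constant (1/h)."""
    if rate_per_hour <= 0:
        raise InvalidParameterError("rate", "rate constant must be > 0")
    return LN2 / rate_per_hour


def nM_to_ug_per_ml(conc_nM: float, mw: float) -> float:
    """Convert a molar concentration (nM) to a mass concentration (µg/ml)."""
    if mw <= 0:
        raise InvalidParameterError("mw", "molecular weight must be > 0")
    return conc_nM * mw * 1e-6
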