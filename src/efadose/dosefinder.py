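"""Effective-dose search: minimal dose meeting a pharmacology criterion.

The criterion metrics (inhibition, engagement) are monotone non-decreasing
in dose, so the minimal criterion-meeting dose is the unique threshold
crossing; it is found by bisection on log-dose after an 8-point monotone
pre-scan brackets the crossing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CriterionEvaluation, FeasibilityModel
from .params import Criterion, Regimen

__all__ = ["BracketError", "MonotonicityError", "DosePrediction", "find_effective_dose", "dose_response"]

DEFAULT_BRACKET = (0.1, 1e5)  # mg; spans all plausible antibody doses

#: tolerance (percentage points) for monotonicity violations attributable to
#: integrator noise during the pre-scan
_MONO_NOISE = 0.05


class BracketError(ValueError):
    pass


class MonotonicityError(ValueError):
    pass


@dataclass
class DosePrediction:
    """Result of an effective-dose search."""

    dose_mg: float
    dose_mg_per_kg: float
    criterion: Criterion
    evaluation: str
    metric_at_dose: float
    per_target: dict[str, float]
    n_evaluations: int
    bracket: tuple[float, float]
    rel_tol: float
    at_lower_edge: bool = False

    def summary(self) -> str:
        tgt = ", ".join(f"{t}: {v:.2f}%" for t, v in self.per_target.items())
        lines = [
            f"predicted effective dose: {self.dose_mg:.4g} mg "
            f"({self.dose_mg_per_kg:.4g} mg/kg)",
            f"  criterion: {self.criterion.label()} ({self.evaluation})",
            f"  metric at dose: {self.metric_at_dose:.3f}%  [{tgt}]",
            f"  search: {self.n_evaluations} evaluations, final bracket "
            f"[{self.bracket[0]:.4g}, {self.bracket[1]:.4g}] mg, rel_tol {self.rel_tol:g}",
        ]
        if self.at_lower_edge:
            lines.append("  note: criterion already met at the lower bracket edge")
        return "\n".join(lines)


def find_effective_dose(
    model: FeasibilityModel,
    criterion: Criterion | None = None,
    regimen: Regimen | None = None,
    bracket: tuple[float, float] = DEFAULT_BRACKET,
    rel_tol: float = 0.005,
    prescan: int = 8,
) -> DosePrediction:
    """Bisect on log-dose until the criterion metric equals its threshold.

    For multi-target criteria the binding constraint is the last target to
    reach threshold (the searched metric is the per-target minimum).
    """
    crit = criterion or model.criterion
    cache: dict[float, CriterionEvaluation] = {}
    n_eval = 0

    def f(dose: float) -> float:
        nonlocal n_eval
        if dose not in cache:
            cache[dose] = model.evaluate(dose, criterion=crit, regimen=regimen)
            n_eval += 1
        return cache[dose].value

    lo, hi = bracket
    if not 0 < lo < hi:
        raise ValueError("bracket must satisfy 0 < lo < hi")
    grid = np.geomspace(lo, hi, prescan)
    vals = np.array([f(d) for d in grid])
    drops = np.diff(vals) < -_MONO_NOISE
    if drops.any():
        j = int(np.flatnonzero(drops)[0])
        raise MonotonicityError(
            f"criterion metric is not monotone over the bracket: "
            f"{vals[j]:.3f}% at {grid[j]:.4g} mg -> {vals[j + 1]:.3f}% at {grid[j + 1]:.4g} mg"
        )
    thr = crit.threshold
    if vals[0] >= thr:
        ev = cache[grid[0]]
        return _prediction(model, crit, grid[0], ev, n_eval, (lo, hi), rel_tol, at_lower_edge=True)
    if vals[-1] < thr:
        raise BracketError(
            f"threshold {thr:g}% not bracketed: metric is {vals[0]:.3f}% at "
            f"{lo:.4g} mg and {vals[-1]:.3f}% at {hi:.4g} mg"
        )
    j = int(np.flatnonzero(vals >= thr)[0])
    b_lo, b_hi = float(grid[j - 1]), float(grid[j])
    while b_hi / b_lo - 1.0 > rel_tol:
        mid = float(np.sqrt(b_lo * b_hi))
        if f(mid) >= thr:
            b_hi = mid
        else:
            b_lo = mid
    dose = float(np.sqrt(b_lo * b_hi))
    ev = model.evaluate(dose, criterion=crit, regimen=regimen)
    n_eval += 1
    return _prediction(model, crit, dose, ev, n_eval, (b_lo, b_hi), rel_tol)


def _prediction(model, crit, dose, ev, n_eval, bracket, rel_tol, at_lower_edge=False) -> DosePrediction:
    bw = model.scenario.physiology.body_weight
    return DosePrediction(
        dose_mg=dose,
        dose_mg_per_kg=dose / bw,
        criterion=crit,
        evaluation=crit.evaluation,
        metric_at_dose=ev.value,
        per_target=ev.per_target,
        n_evaluations=n_eval,
        bracket=bracket,
        rel_tol=rel_tol,
        at_lower_edge=at_lower_edge,
    )


def dose_response(
    model: FeasibilityModel,
    doses,
    criterion: Criterion | None = None,
    regimen: Regimen | None = None,
) -> pd.DataFrame:
    """Criterion metric at each dose, evaluated at the criterion's
    evaluation point.  Columns: dose_mg, metric, value, plus one column per
    target for multi-target criteria."""
    crit = criterion or model.criterion
    rows = []
    for dose in doses:
        if dose <= 0:
            raise ValueError("doses must be > 0")
        ev = model.evaluate(float(dose), criterion=crit, regimen=regimen)
        row = {"dose_mg": float(dose), "metric": crit.metric, "value": ev.value}
        if len(ev.per_target) > 1:
            row |= {f"value_{t}": v for t, v in ev.per_target.items()}
        rows.append(row)
    return pd.DataFrame(rows)
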