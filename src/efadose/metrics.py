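"""Decision metrics computed from a simulated time course.

* :func:`inhibition_pct` — percent reduction of the ligand:cognate-receptor
  complex below its pre-treatment baseline, taken at the *worst* moment of
  the dosing interval (the interval-wide maximum of the complex), so a
  reported 90% means the complex stayed ≥90% suppressed for the entire
  interval.
* :func:`engagement_pct` — percent of membrane target bound by drug in a
  compartment, again as the interval-wide minimum.  Shed soluble receptor
  and its drug complexes are excluded from both numerator and denominator:
  the pharmacology criterion concerns the membrane target.
* :func:`pk_summary` — peak/trough of total drug (all soluble
  drug-containing species, drug-molar basis) in the central compartment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import TimeCourse
from .units import nM_to_ug_per_ml

__all__ = ["UndefinedMetricError", "inhibition_pct", "engagement_pct", "pk_summary", "PKSummary"]


class UndefinedMetricError(ValueError):
    pass


def inhibition_pct(tc: TimeCourse, interval: int | None = None) -> float:
    """Worst-case percent inhibition of the baseline ligand:receptor complex
    over the dosing interval: ``100·(1 − max_t LR(t)/LR0)``."""
    net = tc.network
    if "LR@central" not in net:
        raise UndefinedMetricError("inhibition is defined only for anti-ligand models")
    lr0 = net.baselines.get("LR@central", 0.0)
    if lr0 <= 0:
        raise UndefinedMetricError("baseline ligand:receptor complex is zero")
    mask = tc.window(interval)
    lr = tc.trace("LR@central")[mask]
    return 100.0 * (1.0 - lr.max() / lr0)


def engagement_pct(
    tc: TimeCourse,
    target: str,
    compartment: str = "peripheral",
    interval: int | None = None,
) -> float:
    """Worst-case (interval minimum) percent of membrane ``target`` bound by
    drug in ``compartment``."""
    net = tc.network
    bound_w, total_w = net.membrane_weights(target, compartment)
    if total_w.sum() == 0:
        raise UndefinedMetricError(f"target {target!r} absent from compartment {compartment!r}")
    mask = tc.window(interval)
    bound = bound_w @ tc.states[:, mask]
    total = total_w @ tc.states[:, mask]
    with np.errstate(invalid="ignore", divide="ignore"):
        te = np.where(total > 0, bound / total, 0.0)
    return 100.0 * float(te.min())


@dataclass
class PKSummary:
    cmax_nM: float
    ctrough_nM: float
    cmax_ug_ml: float
    ctrough_ug_ml: float

    def __str__(self) -> str:
        return (
            f"Cmax {self.cmax_nM:.4g} nM ({self.cmax_ug_ml:.4g} ug/ml); "
            f"Ctrough {self.ctrough_nM:.4g} nM ({self.ctrough_ug_ml:.4g} ug/ml)"
        )


def pk_summary(tc: TimeCourse, interval: int | None = None) -> PKSummary:
    """Peak and trough total-drug concentration in the central compartment
    over the dosing interval, in nM and µg/ml."""
    net = tc.network
    mw = net.scenario.drug.mw
    w = net.soluble_drug_weights("central")
    mask = tc.window(interval)
    total = w @ tc.states[:, mask]
    cmax, ctrough = float(total.max()), float(total.min())
    return PKSummary(
        cmax_nM=cmax,
        ctrough_nM=ctrough,
        cmax_ug_ml=nM_to_ug_per_ml(cmax, mw),
        ctrough_ug_ml=nM_to_ug_per_ml(ctrough, mw),
    )
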