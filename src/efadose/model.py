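"""High-level model object tying a scenario to simulation and metrics.

A :class:`FeasibilityModel` is built once from a validated
:class:`~efadose.params.Scenario`: it constructs the reaction network for
the drug's modality, back-calculates synthesis/shedding rates, and holds the
drug-free initial state.  Everything else — simulation, criterion
evaluation, effective-dose prediction, PK checks, sensitivity scans — hangs
off this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .baseline import StationarityReport, solve_predose_baseline, verify_stationarity
from .metrics import PKSummary, engagement_pct, inhibition_pct, pk_summary
from .network import build_network
from .params import Criterion, Regimen, Scenario
from .simulate import TimeCourse, run_to_steady_state, simulate_regimen

__all__ = ["FeasibilityModel", "CriterionEvaluation", "default_criterion"]


def default_criterion(scenario: Scenario) -> Criterion:
    """The criterion implied by the drug's pharmacology when the scenario
    does not specify one: 90% sustained ligand-complex inhibition after 7
    doses for soluble targets, 98% sustained peripheral membrane engagement
    at periodic steady state for receptor targets."""
    if scenario.criterion is not None:
        return scenario.criterion
    if scenario.drug.modality == "anti_ligand":
        return Criterion(metric="ID", threshold=90.0, evaluation="n_doses", n_doses=7)
    return Criterion(
        metric="TE", threshold=98.0, compartment="peripheral", evaluation="steady_state"
    )


@dataclass
class CriterionEvaluation:
    """The criterion metric at one dose: the binding (worst) value and the
    per-target breakdown."""

    dose_mg: float
    value: float
    per_target: dict[str, float]
    timecourse: TimeCourse = field(repr=False)


class FeasibilityModel:
    """Mechanistic PKPD model for one drug/target/physiology scenario.

    Parameters
    ----------
    scenario : Scenario
        Validated parameter bundle.
    kon : float, optional
        Override the association rate constant (nM⁻¹h⁻¹).
    """

    def __init__(self, scenario: Scenario, kon: float | None = None) -> None:
        if kon is not None:
            scenario = scenario.model_copy(deep=True)
            scenario.kon = kon
        self.scenario = scenario
        self.network = build_network(scenario)
        self.network.validate()
        self.y0 = solve_predose_baseline(self.network)
        self.n_simulations = 0  # integration-call bookkeeping for reports

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_scenario(cls, source: "Scenario | str | Path | dict", kon: float | None = None) -> "FeasibilityModel":
        from .scenario import load_scenario

        if isinstance(source, Scenario):
            return cls(source, kon=kon)
        if isinstance(source, dict):
            return cls(Scenario.model_validate(source), kon=kon)
        return cls(load_scenario(source), kon=kon)

    @property
    def criterion(self) -> Criterion:
        return default_criterion(self.scenario)

    # -- simulation --------------------------------------------------------
    def _regimen(self, dose_mg: float | None = None, regimen: Regimen | None = None) -> Regimen:
        reg = regimen if regimen is not None else self.scenario.regimen
        if dose_mg is not None:
            reg = reg.with_dose(dose_mg)
        return reg

    def simulate(
        self,
        dose_mg: float | None = None,
        regimen: Regimen | None = None,
        dense: str = "last",
        **kwargs,
    ) -> TimeCourse:
        """Simulate the (possibly dose-overridden) regimen from the pre-dose
        steady state; dispatches to periodic-steady-state mode when the
        regimen requests it."""
        reg = self._regimen(dose_mg, regimen)
        self.n_simulations += 1
        if reg.to_steady_state:
            return run_to_steady_state(self.network, self.y0, reg, **kwargs)
        return simulate_regimen(self.network, self.y0, reg, dense=dense, **kwargs)

    def verify_stationarity(self, horizon: float = 1000.0, tol: float = 1e-3) -> StationarityReport:
        return verify_stationarity(self.network, self.y0, horizon=horizon, tol=tol)

    # -- criterion evaluation ---------------------------------------------
    def evaluate(
        self,
        dose_mg: float,
        criterion: Criterion | None = None,
        regimen: Regimen | None = None,
    ) -> CriterionEvaluation:
        """Evaluate the criterion metric at one dose.  For multi-target
        criteria the headline value is the worst (minimum) per-target
        metric."""
        crit = criterion or self.criterion
        reg = self._regimen(dose_mg, regimen)
        if crit.evaluation == "steady_state":
            reg = reg.model_copy(update={"to_steady_state": True})
        else:
            reg = reg.model_copy(update={"to_steady_state": False, "n_doses": crit.n_doses})
        tc = self.simulate(regimen=reg)
        if crit.metric == "ID":
            value = inhibition_pct(tc)
            per_target = {self.scenario.drug.arms[0].target: value}
        else:
            targets = crit.targets or [a.target for a in self.scenario.drug.arms]
            per_target = {
                t: engagement_pct(tc, t, compartment=crit.compartment) for t in targets
            }
            value = min(per_target.values())
        return CriterionEvaluation(dose_mg=dose_mg, value=value, per_target=per_target, timecourse=tc)

    # -- headline analyses -------------------------------------------------
    def predict_dose(self, criterion: Criterion | None = None, regimen: Regimen | None = None, **kwargs):
        from .dosefinder import find_effective_dose

        return find_effective_dose(self, criterion=criterion, regimen=regimen, **kwargs)

    def dose_response(self, doses, criterion: Criterion | None = None, regimen: Regimen | None = None):
        from .dosefinder import dose_response

        return dose_response(self, doses, criterion=criterion, regimen=regimen)

    def sensitivity(self, **kwargs):
        from .sensitivity import oat_scan

        return oat_scan(self.scenario, **kwargs)

    def pk_check(
        self,
        dose_mg: float | None = None,
        dose_mg_per_kg: float | None = None,
        n_doses: int | None = None,
        regimen: Regimen | None = None,
    ) -> tuple[PKSummary, TimeCourse]:
        """Peak/trough of total central drug over the final interval of a
        short fixed-dose-count simulation (PK benchmarking)."""
        reg = regimen if regimen is not None else self.scenario.regimen
        update: dict = {"to_steady_state": False}
        if dose_mg_per_kg is not None:
            update |= {"dose_mg_per_kg": dose_mg_per_kg, "dose_mg": None}
        elif dose_mg is not None:
            update |= {"dose_mg": dose_mg, "dose_mg_per_kg": None}
        if n_doses is not None:
            update["n_doses"] = n_doses
        reg = reg.model_copy(update=update)
        tc = self.simulate(regimen=reg)
        return pk_summary(tc), tc

    # -- reporting ---------------------------------------------------------
    def resolved_rates(self) -> dict[str, float]:
        """All derived/solved rate constants — full numeric provenance."""
        return dict(self.network.derived)

    def summary(self) -> str:
        sc = self.scenario
        lines = [
            f"FeasibilityModel: {sc.name}",
            f"  modality: {sc.drug.modality}  (species: {self.network.n_species}, "
            f"reactions: {len(self.network.reactions)})",
            f"  kon: {sc.kon:g} /nM/h",
            "  resolved rate constants (1/h unless noted):",
        ]
        for key, val in sorted(self.network.derived.items()):
            lines.append(f"    {key:28s} {val:.6g}")
        lines.append("  pre-dose baselines (nM):")
        for sid, val in sorted(self.network.baselines.items()):
            lines.append(f"    {sid:28s} {val:.6g}")
        return "\n".join(lines)
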