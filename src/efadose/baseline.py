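"""Pre-dose steady-state initialisation.

Target synthesis (and shedding) rate constants are not literature inputs;
they are back-calculated in closed form so that the drug-free steady state
of the network reproduces the user-specified baselines exactly:

* anti-ligand family — given free ligand ``L0``, total cognate receptor
  ``R0_total`` and the ligand:receptor Kd, the drug-free balance (with
  complex eliminating at the receptor rate) gives::

      LR0   = R0_total · kon·L0 / (koff + kdeg_R + kon·L0)
      ksyn_L = kdeg_L·L0 + kdeg_R·LR0
      ksyn_R = kdeg_R·R0_total

* anti-receptor families — membrane baselines are fixed by the compartment
  amounts; when a shed form is present, the shedding rate constant and the
  *peripheral* soluble baseline are the solution of a 2×2 linear system
  balancing shedding, elimination and transport against the specified
  central soluble baseline.  Shedding is one route within the receptor's
  measured total turnover, so ``ksyn = kdeg·R_baseline`` per compartment
  and free receptor otherwise eliminates at ``kdeg − kshed`` (baselines are
  infeasible if shedding alone would exceed the total turnover).

:func:`verify_stationarity` integrates the drug-free system and reports the
worst relative drift, guarding the algebra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import CENTRAL, PERIPHERAL, ReactionNetwork
from .params import MembraneReceptorTarget, SolubleLigandTarget
from .units import half_life_to_rate

__all__ = ["InitializationError", "solve_predose_baseline", "verify_stationarity", "StationarityReport"]


class InitializationError(ValueError):
    """Baselines are infeasible (a solved rate or concentration is negative)."""


def solve_predose_baseline(network: ReactionNetwork) -> np.ndarray:
    """Solve synthesis/shedding rates in place and return the drug-free
    initial state vector (concentrations in nM; depot in nmol)."""
    sc = network.scenario
    y0 = np.zeros(network.n_species)
    kon = network.derived["kon"]

    for t, tgt in sc.targets.items():
        if isinstance(tgt, SolubleLigandTarget):
            _init_ligand(network, y0, t, tgt, kon)
        elif isinstance(tgt, MembraneReceptorTarget):
            _init_membrane(network, y0, t, tgt)
    return y0


def _set_rate(network: ReactionNetwork, rule: tuple, value: float) -> None:
    hit = False
    for rx in network.reactions:
        if rx.meta["rule"] == rule:
            rx.rate = value
            hit = True
    if not hit:  # pragma: no cover
        raise KeyError(f"no reaction with rule {rule!r}")


def _init_ligand(network, y0, t, tgt: SolubleLigandTarget, kon: float) -> None:
    kdeg_L = half_life_to_rate(tgt.half_life)
    kdeg_R = half_life_to_rate(tgt.receptor_half_life)
    koff = kon * tgt.receptor_kd
    L0 = tgt.baseline_conc
    R_total = tgt.receptor_total

    # free receptor from the complex quasi-balance kon·L0·Rf = (koff+kdeg_R)·LR0
    R_free = R_total / (1.0 + kon * L0 / (koff + kdeg_R))
    LR0 = R_total - R_free
    ksyn_L = kdeg_L * L0 + kdeg_R * LR0
    ksyn_R = kdeg_R * R_total
    if min(R_free, LR0, ksyn_L, ksyn_R) < 0:  # pragma: no cover - params validated > 0
        raise InitializationError(f"{t}: infeasible ligand baseline (negative solved value)")

    _set_rate(network, ("syn_ligand", t, CENTRAL), ksyn_L)
    _set_rate(network, ("syn_cognate", t, CENTRAL), ksyn_R)
    network.derived[f"ksyn_L[{t}]"] = ksyn_L
    network.derived[f"ksyn_R[{t}]"] = ksyn_R
    network.derived[f"LR0[{t}]"] = LR0

    y0[network.index(f"L@{CENTRAL}")] = L0
    y0[network.index(f"R@{CENTRAL}")] = R_free
    y0[network.index(f"LR@{CENTRAL}")] = LR0
    network.baselines[f"R@{CENTRAL}"] = R_free
    network.baselines[f"LR@{CENTRAL}"] = LR0


def _init_membrane(network, y0, t, tgt: MembraneReceptorTarget) -> None:
    sc = network.scenario
    phys = sc.physiology
    v1, v2 = phys.volume_central, phys.volume_peripheral
    kdeg = half_life_to_rate(tgt.receptor_half_life)
    Rc0 = tgt.amount_central / v1
    Rp0 = tgt.amount_peripheral / v2
    y0[network.index(f"{t}@{CENTRAL}")] = Rc0
    y0[network.index(f"{t}@{PERIPHERAL}")] = Rp0

    kshed = 0.0
    if tgt.shed is not None:
        kdeg_s = half_life_to_rate(tgt.shed.soluble_half_life)
        k12, k21 = network.derived["k12"], network.derived["k21"]
        sc0 = tgt.shed.soluble_baseline_central
        # unknowns x = (kshed, sR_peripheral); shedding + elimination +
        # transport balance in each compartment:
        #   central:     kshed·Rc0 - (kdeg_s + k12)·sc0 + k21·(V2/V1)·sp = 0
        #   peripheral:  kshed·Rp0 - (kdeg_s + k21)·sp + k12·(V1/V2)·sc0 = 0
        A = np.array([[Rc0, k21 * v2 / v1], [Rp0, -(kdeg_s + k21)]])
        b = np.array([(kdeg_s + k12) * sc0, -k12 * v1 / v2 * sc0])
        try:
            kshed, sp0 = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as err:
            raise InitializationError(f"{t}: singular shed-baseline system") from err
        if kshed < 0 or sp0 < 0:
            raise InitializationError(
                f"{t}: infeasible shed baseline (kshed={kshed:.3g}, peripheral={sp0:.3g})"
            )
        if kshed > kdeg:
            raise InitializationError(
                f"{t}: shed baseline requires kshed={kshed:.3g}/h exceeding the "
                f"receptor's total turnover rate {kdeg:.3g}/h"
            )
        _set_rate(network, ("shed", t), kshed)
        # shedding is one route within the measured total receptor turnover:
        # free receptor otherwise eliminates at kdeg - kshed
        _set_rate(network, ("elim_membrane_free", t), kdeg - kshed)
        network.derived[f"kshed[{t}]"] = kshed
        network.derived[f"sR0_peripheral[{t}]"] = sp0
        y0[network.index(f"s{t}@{CENTRAL}")] = sc0
        y0[network.index(f"s{t}@{PERIPHERAL}")] = sp0
        network.baselines[f"s{t}@{PERIPHERAL}"] = sp0

    for c, R0 in ((CENTRAL, Rc0), (PERIPHERAL, Rp0)):
        ksyn = kdeg * R0  # total turnover (shedding included) balances synthesis
        _set_rate(network, ("syn_membrane", t, c), ksyn)
        network.derived[f"ksyn[{t}@{c}]"] = ksyn


@dataclass
class StationarityReport:
    passed: bool
    horizon: float
    tol: float
    worst_species: str
    worst_drift: float
    drifts: dict[str, float]

    def __str__(self) -> str:
        status = "PASS" if self.passed else "FAIL"
        return (
            f"stationarity {status}: worst relative drift {self.worst_drift:.3e} "
            f"({self.worst_species}) over {self.horizon:g} h (tol {self.tol:g})"
        )


def verify_stationarity(
    network: ReactionNetwork,
    y0: np.ndarray,
    horizon: float = 1000.0,
    tol: float = 1e-3,
) -> StationarityReport:
    """Integrate the drug-free system over ``horizon`` hours and check that
    every species stays within ``tol`` (relative, with an absolute floor of
    ``tol``·max(y0) for species starting at zero) of its initial value."""
    from .simulate import integrate_window

    ts, ys = integrate_window(network, y0, 0.0, horizon, t_eval=np.array([0.0, horizon]))
    yT = ys[:, -1]
    floor = tol * max(y0.max(), 1.0)
    drifts = {}
    for i, sp in enumerate(network.species):
        scale = max(abs(y0[i]), floor)
        drifts[sp.id] = abs(yT[i] - y0[i]) / scale
    worst = max(drifts, key=drifts.get)
    return StationarityReport(
        passed=drifts[worst] <= tol,
        horizon=horizon,
        tol=tol,
        worst_species=worst,
        worst_drift=drifts[worst],
        drifts=drifts,
    )
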