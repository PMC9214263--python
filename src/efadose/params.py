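"""Validated domain types: drug, target, physiology, regimen, criterion, scenario.

These are the user-facing parameter blocks.  All durations accept either a
number (hours) or a string with an explicit unit (``"20 d"``, ``"30 min"``,
``"2 weeks"``); they are normalised to hours at validation time.  Binding
affinities are in nM, amounts in nmol, volumes in litres, doses in mg.
"""

from __future__ import annotations

from typing import Annotated, Literal, Optional, Union

from pydantic import (
    BaseModel,
    BeforeValidator,
    ConfigDict,
    Field,
    model_validator,
)

from .units import parse_duration

#: Default antibody association rate constant, nM^-1 h^-1 (2.78e5 M^-1 s^-1).
#: Geometric middle of the typical antibody range 1e5–1e6 M^-1 s^-1; see the
#: methods note for why predictions retain some dependence on this value.
DEFAULT_KON = 1.0

Hours = Annotated[float, BeforeValidator(parse_duration)]

Modality = Literal["anti_ligand", "anti_receptor", "bispecific_receptor"]
Route = Literal["IV", "SC"]
Compartment = Literal["central", "peripheral"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class BindingArm(_Block):
    """One binding specificity of the drug: a target, its Kd, and the number
    of identical independent sites the drug carries for it."""

    target: str
    kd: float = Field(gt=0, description="equilibrium dissociation constant, nM")
    valency: int = Field(default=1, ge=1, le=2)


class DrugParams(_Block):
    name: str
    modality: Modality
    arms: list[BindingArm]
    half_life: Hours = Field(gt=0, description="elimination half-life, hours")
    mw: float = Field(gt=0, description="molecular weight, Da")
    absorption_half_life: Optional[Hours] = Field(
        default=None, gt=0, description="SC first-order absorption half-life, hours"
    )
    bioavailability: float = Field(default=1.0, gt=0, le=1.0)

    @model_validator(mode="after")
    def _check_arms(self) -> "DrugParams":
        n = len(self.arms)
        if self.modality in ("anti_ligand", "anti_receptor") and n != 1:
            raise ValueError(f"arms: modality {self.modality!r} requires exactly 1 arm, got {n}")
        if self.modality == "bispecific_receptor":
            if n != 2:
                raise ValueError(f"arms: bispecific_receptor requires exactly 2 arms, got {n}")
            if self.arms[0].target == self.arms[1].target:
                raise ValueError("arms: bispecific arms must bind distinct targets")
            for arm in self.arms:
                if arm.valency != 1:
                    raise ValueError(
                        "arms: bispecific arms with valency != 1 are not supported"
                    )
        return self


class SolubleLigandTarget(_Block):
    """A soluble ligand with a cognate receptor whose complex is the
    pharmacodynamic readout (ligand-inhibition models)."""

    kind: Literal["soluble_ligand"] = "soluble_ligand"
    baseline_conc: float = Field(gt=0, description="free ligand at pre-dose steady state, nM")
    half_life: Hours = Field(gt=0, description="ligand turnover half-life, hours")
    receptor_kd: float = Field(gt=0, description="ligand:receptor Kd, nM")
    receptor_total: float = Field(gt=0, description="total cognate receptor, nM")
    receptor_half_life: Hours = Field(gt=0)


class ShedBlock(_Block):
    soluble_baseline_central: float = Field(gt=0, description="shed receptor in plasma, nM")
    soluble_half_life: Hours = Field(gt=0)


class MembraneReceptorTarget(_Block):
    kind: Literal["membrane_receptor"] = "membrane_receptor"
    amount_central: float = Field(ge=0, description="nmol")
    amount_peripheral: float = Field(ge=0, description="nmol")
    receptor_half_life: Hours = Field(gt=0)
    shed: Optional[ShedBlock] = None

    @model_validator(mode="after")
    def _check_amounts(self) -> "MembraneReceptorTarget":
        if self.amount_central == 0 and self.amount_peripheral == 0:
            raise ValueError("amount_central/amount_peripheral: receptor amounts cannot both be zero")
        return self


TargetParams = Annotated[
    Union[SolubleLigandTarget, MembraneReceptorTarget],
    Field(discriminator="kind"),
]


class Physiology(_Block):
    volume_central: float = Field(gt=0, description="L")
    volume_peripheral: float = Field(default=0.0, ge=0, description="L (0 = 1-compartment)")
    body_weight: float = Field(default=70.0, gt=0, description="kg")
    pdist: float = Field(default=1.0, gt=0, le=1.0,
                         description="peripheral:central partition coefficient")
    tdist: Optional[Hours] = Field(default=None, gt=0,
                                   description="inter-compartmental distribution half-life, h")

    @model_validator(mode="after")
    def _check_two_compartment(self) -> "Physiology":
        if self.volume_peripheral > 0 and self.tdist is None:
            raise ValueError("tdist: required when volume_peripheral > 0")
        return self


class Regimen(_Block):
    route: Route
    dose_mg: Optional[float] = Field(default=None, ge=0)
    dose_mg_per_kg: Optional[float] = Field(default=None, ge=0)
    interval: Hours = Field(gt=0)
    n_doses: int = Field(default=1, ge=1)
    to_steady_state: bool = False

    def resolved_dose_mg(self, body_weight_kg: float) -> float:
        """Absolute dose in mg, resolving mg/kg with the given body weight."""
        if self.dose_mg is not None:
            return self.dose_mg
        if self.dose_mg_per_kg is not None:
            return self.dose_mg_per_kg * body_weight_kg
        raise ValueError("regimen has neither dose_mg nor dose_mg_per_kg")

    def with_dose(self, dose_mg: float) -> "Regimen":
        return self.model_copy(update={"dose_mg": dose_mg, "dose_mg_per_kg": None})


class Criterion(_Block):
    """Effective-dose criterion.

    ``ID`` — percent inhibition of the baseline ligand:receptor complex,
    worst case over a dosing interval.  ``TE`` — percent of membrane target
    bound by drug, worst case over a dosing interval, in ``compartment``.
    """

    metric: Literal["ID", "TE"]
    threshold: float = Field(gt=0, lt=100)
    compartment: Optional[Compartment] = None
    evaluation: Literal["n_doses", "steady_state"] = "n_doses"
    n_doses: int = Field(default=7, ge=1)
    targets: Optional[list[str]] = None  # None -> all drug arms

    @model_validator(mode="after")
    def _check(self) -> "Criterion":
        if self.metric == "TE" and self.compartment is None:
            raise ValueError("compartment: required for TE criteria")
        return self

    def label(self) -> str:
        return f"{self.metric}{self.threshold:g}"


class Scenario(_Block):
    """A complete, validated model scenario: drug + targets + physiology +
    regimen (+ optional criterion and kon override)."""

    name: str
    drug: DrugParams
    targets: dict[str, TargetParams]
    physiology: Physiology
    regimen: Regimen
    criterion: Optional[Criterion] = None
    kon: float = Field(default=DEFAULT_KON, gt=0, description="association rate, nM^-1 h^-1")

    @model_validator(mode="after")
    def _check_targets(self) -> "Scenario":
        for arm in self.drug.arms:
            if arm.target not in self.targets:
                raise ValueError(f"targets: drug arm references unknown target {arm.target!r}")
        for tid, tgt in self.targets.items():
            if self.drug.modality == "anti_ligand" and tgt.kind != "soluble_ligand":
                raise ValueError(f"targets: {tid!r} must be a soluble_ligand for anti_ligand drugs")
            if self.drug.modality in ("anti_receptor", "bispecific_receptor") and (
                tgt.kind != "membrane_receptor"
            ):
                raise ValueError(f"targets: {tid!r} must be a membrane_receptor for {self.drug.modality}")
        if self.drug.modality == "anti_ligand" and self.physiology.volume_peripheral != 0:
            raise ValueError("physiology: anti_ligand models are 1-compartment (volume_peripheral = 0)")
        if self.drug.modality in ("anti_receptor", "bispecific_receptor") and (
            self.physiology.volume_peripheral <= 0
        ):
            raise ValueError("physiology: receptor models are 2-compartment (volume_peripheral > 0)")
        return self

    def arm_for(self, target_id: str) -> BindingArm:
        for arm in self.drug.arms:
            if arm.target == target_id:
                return arm
        raise KeyError(target_id)
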