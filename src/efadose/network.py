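"""Mass-action reaction networks for the three antibody model families.

A :class:`ReactionNetwork` is the executable form of a model: an enumerated
species list (with compartment and mobility class) plus mass-action reactions
with first- or second-order rate constants.  Three builders construct the
families used throughout:

* :func:`build_anti_ligand` — 1-compartment drug vs. soluble ligand with a
  cognate receptor (the ligand:receptor complex is the pharmacodynamic
  readout).
* :func:`build_anti_receptor` — 2-compartment drug vs. membrane receptor,
  optionally with a shed soluble form acting as a decoy sink.
* :func:`build_bispecific` — 2-compartment bispecific against two membrane
  receptors, with independent per-arm affinities (no avidity enhancement).

Conventions (documented in docs/methods.md):

* Multivalent binding uses identical-independent-sites statistics: a drug
  with ``f`` free sites binds at ``f·kon`` and a complex with ``m`` copies of
  a ligand bound dissociates at ``m·koff``, with ``koff = kon·Kd``.
* Complexes containing membrane receptor eliminate at the membrane
  receptor's turnover rate; a bispecific ternary complex with two distinct
  membrane receptors eliminates at the *sum* of the two turnover rates
  (each internalisation machinery acts independently).
* Drug:soluble-receptor and drug:ligand complexes eliminate at the free
  drug's rate; all soluble species transport between compartments with the
  free drug's transport rate constants.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .params import (
    DrugParams,
    MembraneReceptorTarget,
    Physiology,
    Scenario,
    SolubleLigandTarget,
)
from .units import LN2, half_life_to_rate

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "ModelMismatchError",
    "build_anti_ligand",
    "build_anti_receptor",
    "build_bispecific",
    "build_network",
    "assign_rates",
]

DEPOT = "depot"
CENTRAL = "central"
PERIPHERAL = "peripheral"


class ModelMismatchError(ValueError):
    """Drug modality does not match the requested model family."""


@dataclass(frozen=True)
class Species:
    """One chemical species in one compartment.

    ``composition`` maps molecular constituents to copy numbers, with keys
    ``"drug"``, ``"<target>:mem"``, ``"<target>:shed"``, ``"<target>:lig"``
    and ``"<target>:rec"``; it drives mass-balance checks and metric
    bookkeeping.
    """

    id: str
    compartment: str
    mobility: str  # "soluble" | "membrane"
    composition: dict[str, int] = field(hash=False)

    def count(self, key: str) -> int:
        return self.composition.get(key, 0)


@dataclass
class Reaction:
    """A single mass-action reaction.

    ``rate`` units are 1/h (zeroth order: nM/h; second order: 1/(nM·h)).
    Synthesis and shedding rates are left ``None`` by the builders and are
    solved by the baseline initialiser.
    """

    reactants: list[str]
    products: list[str]
    kind: str  # synthesis|elimination|binding_on|binding_off|transport|absorption|shedding
    rate: float | None = None
    meta: dict = field(default_factory=dict)

    def __str__(self) -> str:
        lhs = " + ".join(self.reactants) or "∅"
        rhs = " + ".join(self.products) or "∅"
        k = "None" if self.rate is None else f"{self.rate:.6g}"
        return f"{lhs} -> {rhs}  [{self.kind}, k={k}]"


class ReactionNetwork:
    """Species + reactions + per-compartment volumes, with compiled
    mass-action arrays for the ODE right-hand side."""

    def __init__(
        self,
        species: list[Species],
        reactions: list[Reaction],
        volumes: dict[str, float],
        scenario: Scenario,
        baselines: dict[str, float] | None = None,
    ) -> None:
        self.species = species
        self.reactions = reactions
        self.volumes = volumes
        self.scenario = scenario
        #: species whose pre-dose value is a user-specified constraint
        self.baselines: dict[str, float] = baselines or {}
        #: rates solved/derived during assignment and initialisation
        self.derived: dict[str, float] = {}
        self._index = {sp.id: i for i, sp in enumerate(species)}
        if len(self._index) != len(species):
            raise ValueError("duplicate species ids")
        for rx in reactions:
            for sid in (*rx.reactants, *rx.products):
                if sid not in self._index:
                    raise ValueError(f"reaction references undeclared species {sid!r}")

    # -- basic access ------------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    def index(self, species_id: str) -> int:
        return self._index[species_id]

    def __contains__(self, species_id: str) -> bool:
        return species_id in self._index

    def get(self, species_id: str) -> Species:
        return self.species[self._index[species_id]]

    def species_in(self, compartment: str) -> list[Species]:
        return [s for s in self.species if s.compartment == compartment]

    # -- compilation -------------------------------------------------------
    def compile(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (S, r1, r2, k): stoichiometry matrix with volume-corrected
        entries for transport/absorption, reactant index arrays (-1 = none),
        and the rate-constant vector.  Raises if any rate is unassigned."""
        n_sp, n_rx = len(self.species), len(self.reactions)
        S = np.zeros((n_sp, n_rx))
        r1 = np.full(n_rx, -1, dtype=np.int64)
        r2 = np.full(n_rx, -1, dtype=np.int64)
        k = np.empty(n_rx)
        for j, rx in enumerate(self.reactions):
            if rx.rate is None:
                raise ValueError(f"unassigned rate constant in reaction: {rx}")
            k[j] = rx.rate
            if len(rx.reactants) >= 1:
                r1[j] = self._index[rx.reactants[0]]
            if len(rx.reactants) == 2:
                r2[j] = self._index[rx.reactants[1]]
            elif len(rx.reactants) > 2:
                raise ValueError("mass-action reactions have at most 2 reactants")
            if rx.kind in ("transport", "absorption"):
                (src,), (dst,) = rx.reactants, rx.products
                v_src = self.volumes[self.get(src).compartment]
                v_dst = self.volumes[self.get(dst).compartment]
                S[self._index[src], j] -= 1.0
                S[self._index[dst], j] += v_src / v_dst
            else:
                for sid in rx.reactants:
                    S[self._index[sid], j] -= 1.0
                for sid in rx.products:
                    S[self._index[sid], j] += 1.0
        return S, r1, r2, k

    # -- bookkeeping helpers ----------------------------------------------
    def constituents(self) -> list[str]:
        """Conserved molecular constituents: drug, each target (membrane and
        shed forms pooled, since shedding interconverts them), and each
        cognate receptor."""
        out: set[str] = set()
        for sp in self.species:
            for key in sp.composition:
                if key == "drug":
                    out.add("drug")
                else:
                    t, form = key.split(":")
                    out.add(f"{t}_receptor" if form == "rec" else t)
        return sorted(out)

    def constituent_weights(self, constituent: str) -> np.ndarray:
        """Per-species molar amounts of ``constituent`` carried by one unit of
        each species, scaled by compartment volume (depot volume = 1 since the
        depot state is an amount, not a concentration)."""
        w = np.zeros(len(self.species))
        for i, sp in enumerate(self.species):
            n = 0
            for key, cnt in sp.composition.items():
                if constituent == "drug" and key == "drug":
                    n += cnt
                elif key != "drug":
                    t, form = key.split(":")
                    name = f"{t}_receptor" if form == "rec" else t
                    if name == constituent:
                        n += cnt
            w[i] = n * self.volumes[sp.compartment]
        return w

    def membrane_weights(self, target: str, compartment: str) -> tuple[np.ndarray, np.ndarray]:
        """(bound, total) copy-number vectors of membrane ``target`` per
        species in ``compartment``; drives the engagement metric.  Shed forms
        are excluded from both."""
        bound = np.zeros(len(self.species))
        total = np.zeros(len(self.species))
        key = f"{target}:mem"
        for i, sp in enumerate(self.species):
            if sp.compartment != compartment:
                continue
            n = sp.count(key)
            if n:
                total[i] = n
                if sp.count("drug"):
                    bound[i] = n
        return bound, total

    def soluble_drug_weights(self, compartment: str) -> np.ndarray:
        """Drug-molar weights of soluble drug-containing species in a
        compartment (total-drug PK bookkeeping)."""
        w = np.zeros(len(self.species))
        for i, sp in enumerate(self.species):
            if (
                sp.compartment == compartment
                and sp.mobility == "soluble"
                and sp.count("drug")
            ):
                w[i] = sp.count("drug")
        return w

    def validate(self) -> None:
        """Check that every species has at least one elimination route,
        possibly by first converting into another species (binding,
        shedding, transport, absorption)."""
        eliminable = {rx.reactants[0] for rx in self.reactions if rx.kind == "elimination"}
        # breadth-first over conversion edges
        edges: dict[str, set[str]] = {sp.id: set() for sp in self.species}
        for rx in self.reactions:
            if rx.kind in ("binding_on", "binding_off", "shedding", "transport", "absorption"):
                for r in rx.reactants:
                    edges[r].update(rx.products)
        for sp in self.species:
            seen, frontier = {sp.id}, [sp.id]
            ok = sp.id in eliminable
            while frontier and not ok:
                nxt = []
                for sid in frontier:
                    for dst in edges[sid]:
                        if dst not in seen:
                            seen.add(dst)
                            nxt.append(dst)
                            if dst in eliminable:
                                ok = True
                frontier = nxt
            if not ok:
                raise ValueError(f"species {sp.id!r} has no elimination route")

    def to_table(self):
        """Human-readable reaction table as a DataFrame (one row per
        reaction) for inspection/diffing."""
        import pandas as pd

        rows = []
        for rx in self.reactions:
            rows.append(
                {
                    "reactants": " + ".join(rx.reactants) or "-",
                    "products": " + ".join(rx.products) or "-",
                    "kind": rx.kind,
                    "rate_constant": rx.rate,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def _drug_species_id(tokens: tuple[str, ...], compartment: str) -> str:
    if not tokens:
        return f"D@{compartment}"
    return f"D[{','.join(sorted(tokens))}]@{compartment}"


def build_anti_ligand(scenario: Scenario) -> ReactionNetwork:
    """1-compartment anti-ligand network: depot (if SC absorption is
    parameterised), free drug D, ligand L, cognate receptor R, complex LR and
    drug:ligand complexes up to the drug's valency.  Drug-bound ligand cannot
    bind receptor."""
    drug = scenario.drug
    if drug.modality != "anti_ligand":
        raise ModelMismatchError(f"build_anti_ligand requires anti_ligand, got {drug.modality}")
    phys = scenario.physiology
    if phys.volume_peripheral != 0:
        raise ModelMismatchError("anti_ligand model is 1-compartment (volume_peripheral = 0)")
    arm = drug.arms[0]
    t = arm.target
    target = scenario.targets[t]
    assert isinstance(target, SolubleLigandTarget)

    c = CENTRAL
    species: list[Species] = []
    if drug.absorption_half_life is not None:
        species.append(Species(DEPOT, DEPOT, "soluble", {"drug": 1}))
    species += [
        Species(f"D@{c}", c, "soluble", {"drug": 1}),
        Species(f"L@{c}", c, "soluble", {f"{t}:lig": 1}),
        Species(f"R@{c}", c, "soluble", {f"{t}:rec": 1}),
        Species(f"LR@{c}", c, "soluble", {f"{t}:lig": 1, f"{t}:rec": 1}),
    ]
    for n in range(1, arm.valency + 1):
        sid = f"D[{','.join(['L'] * n)}]@{c}"
        species.append(Species(sid, c, "soluble", {"drug": 1, f"{t}:lig": n}))

    rx: list[Reaction] = []
    if drug.absorption_half_life is not None:
        rx.append(Reaction([DEPOT], [f"D@{c}"], "absorption", meta={"rule": ("absorption",)}))
    rx += [
        Reaction([], [f"L@{c}"], "synthesis", meta={"rule": ("syn_ligand", t, c)}),
        Reaction([], [f"R@{c}"], "synthesis", meta={"rule": ("syn_cognate", t, c)}),
        Reaction([f"D@{c}"], [], "elimination", meta={"rule": ("elim_drug",)}),
        Reaction([f"L@{c}"], [], "elimination", meta={"rule": ("elim_ligand", t)}),
        Reaction([f"R@{c}"], [], "elimination", meta={"rule": ("elim_cognate", t)}),
        Reaction([f"LR@{c}"], [], "elimination", meta={"rule": ("elim_cognate", t)}),
        Reaction([f"L@{c}", f"R@{c}"], [f"LR@{c}"], "binding_on", meta={"rule": ("on_cognate", t)}),
        Reaction([f"LR@{c}"], [f"L@{c}", f"R@{c}"], "binding_off", meta={"rule": ("off_cognate", t)}),
    ]
    for n in range(1, arm.valency + 1):
        lo = f"D@{c}" if n == 1 else f"D[{','.join(['L'] * (n - 1))}]@{c}"
        hi = f"D[{','.join(['L'] * n)}]@{c}"
        free_sites = arm.valency - (n - 1)
        rx.append(
            Reaction([lo, f"L@{c}"], [hi], "binding_on",
                     meta={"rule": ("on_arm", t, free_sites)})
        )
        rx.append(
            Reaction([hi], [lo, f"L@{c}"], "binding_off",
                     meta={"rule": ("off_arm", t, n)})
        )
        rx.append(Reaction([hi], [], "elimination", meta={"rule": ("elim_drug",)}))

    volumes = {DEPOT: 1.0, c: phys.volume_central}
    baselines = {f"L@{c}": target.baseline_conc}
    net = ReactionNetwork(species, rx, volumes, scenario, baselines)
    return assign_rates(net)


def _receptor_family(scenario: Scenario, modality: str) -> ReactionNetwork:
    """Shared construction for the monospecific and bispecific 2-compartment
    receptor families: drug occupancy states are the product over arms of the
    multisets of bound forms (membrane or shed) up to each arm's valency."""
    drug = scenario.drug
    phys = scenario.physiology
    if drug.modality != modality:
        raise ModelMismatchError(f"expected modality {modality}, got {drug.modality}")
    if phys.volume_peripheral <= 0:
        raise ModelMismatchError("receptor models are 2-compartment (volume_peripheral > 0)")

    arms = drug.arms
    targets = {a.target: scenario.targets[a.target] for a in arms}
    for t, tgt in targets.items():
        if not isinstance(tgt, MembraneReceptorTarget):
            raise ModelMismatchError(f"target {t!r} must be a membrane receptor")

    # per-arm bound-form options: membrane token = target id, shed token = "s"+id
    def options(arm):
        tgt = targets[arm.target]
        opts = [arm.target]
        if tgt.shed is not None:
            opts.append("s" + arm.target)
        return opts

    def arm_states(arm):
        out = [()]
        for n in range(1, arm.valency + 1):
            out += [tuple(sorted(c)) for c in
                    itertools.combinations_with_replacement(options(arm), n)]
        return out

    def composition(tokens: tuple[str, ...]) -> dict[str, int]:
        comp: dict[str, int] = {"drug": 1}
        for tok in tokens:
            if tok.startswith("s") and tok[1:] in targets:
                key = f"{tok[1:]}:shed"
            else:
                key = f"{tok}:mem"
            comp[key] = comp.get(key, 0) + 1
        return comp

    # enumerate drug occupancy states (product over arms)
    per_arm = [arm_states(a) for a in arms]
    states = [tuple(tok for part in combo for tok in part)
              for combo in itertools.product(*per_arm)]

    species: list[Species] = []
    rx: list[Reaction] = []
    compartments = [CENTRAL, PERIPHERAL]
    baselines: dict[str, float] = {}

    for c in compartments:
        for t, tgt in targets.items():
            species.append(Species(f"{t}@{c}", c, "membrane", {f"{t}:mem": 1}))
            if tgt.shed is not None:
                species.append(Species(f"s{t}@{c}", c, "soluble", {f"{t}:shed": 1}))
        for tokens in states:
            comp = composition(tokens)
            mobility = "membrane" if any(k.endswith(":mem") and k != "drug" for k in comp if k != "drug") else "soluble"
            species.append(Species(_drug_species_id(tokens, c), c, mobility, comp))

    if drug.absorption_half_life is not None:
        species.insert(0, Species(DEPOT, DEPOT, "soluble", {"drug": 1}))
        rx.append(Reaction([DEPOT], [f"D@{CENTRAL}"], "absorption", meta={"rule": ("absorption",)}))

    membrane_tokens = set(targets)

    def elim_rule(tokens: tuple[str, ...]):
        mem = sorted({tok for tok in tokens if tok in membrane_tokens})
        if mem:
            return ("elim_membrane", tuple(mem))
        return ("elim_drug",)

    for c in compartments:
        for t, tgt in targets.items():
            rx.append(Reaction([], [f"{t}@{c}"], "synthesis", meta={"rule": ("syn_membrane", t, c)}))
            # free-receptor elimination: shedding is one route within the
            # measured total turnover, so this rate becomes kdeg - kshed once
            # kshed is solved at initialisation
            rx.append(Reaction([f"{t}@{c}"], [], "elimination", meta={"rule": ("elim_membrane_free", t)}))
            if tgt.shed is not None:
                rx.append(Reaction([f"{t}@{c}"], [f"s{t}@{c}"], "shedding", meta={"rule": ("shed", t)}))
                rx.append(Reaction([f"s{t}@{c}"], [], "elimination", meta={"rule": ("elim_shed", t)}))
        for tokens in states:
            sid = _drug_species_id(tokens, c)
            rx.append(Reaction([sid], [], "elimination", meta={"rule": elim_rule(tokens)}))
            # binding: each arm with free sites can bind each of its options
            for arm, part in zip(arms, _split_state(tokens, arms, targets)):
                free = arm.valency - len(part)
                if free <= 0:
                    continue
                for tok in options(arm):
                    new = tuple(sorted(tokens + (tok,)))
                    hi = _drug_species_id(new, c)
                    lig = f"{tok}@{c}" if tok in membrane_tokens else f"{tok}@{c}"
                    n_bound = new.count(tok)
                    rx.append(
                        Reaction([sid, lig], [hi], "binding_on",
                                 meta={"rule": ("on_arm", arm.target, free)})
                    )
                    rx.append(
                        Reaction([hi], [sid, lig], "binding_off",
                                 meta={"rule": ("off_arm", arm.target, n_bound)})
                    )

    # transport of soluble species
    sol = [sp for sp in species if sp.mobility == "soluble" and sp.compartment == CENTRAL]
    for sp in sol:
        pid = sp.id.replace(f"@{CENTRAL}", f"@{PERIPHERAL}")
        rx.append(Reaction([sp.id], [pid], "transport", meta={"rule": ("transport", "c2p")}))
        rx.append(Reaction([pid], [sp.id], "transport", meta={"rule": ("transport", "p2c")}))

    volumes = {DEPOT: 1.0, CENTRAL: phys.volume_central, PERIPHERAL: phys.volume_peripheral}
    for c, vol_attr in ((CENTRAL, "amount_central"), (PERIPHERAL, "amount_peripheral")):
        for t, tgt in targets.items():
            baselines[f"{t}@{c}"] = getattr(tgt, vol_attr) / volumes[c]
    for t, tgt in targets.items():
        if tgt.shed is not None:
            baselines[f"s{t}@{CENTRAL}"] = tgt.shed.soluble_baseline_central

    net = ReactionNetwork(species, rx, volumes, scenario, baselines)
    return assign_rates(net)


def _split_state(tokens: tuple[str, ...], arms, targets) -> list[tuple[str, ...]]:
    """Partition a drug occupancy state into per-arm bound tokens."""
    parts = []
    for arm in arms:
        mine = tuple(tok for tok in tokens if tok == arm.target or tok == "s" + arm.target)
        parts.append(mine)
    return parts


def build_anti_receptor(scenario: Scenario) -> ReactionNetwork:
    """2-compartment monospecific anti-receptor network (membrane receptor,
    optional shed soluble form; bivalent drugs use independent-identical-site
    statistics)."""
    return _receptor_family(scenario, "anti_receptor")


def build_bispecific(scenario: Scenario) -> ReactionNetwork:
    """2-compartment bispecific anti-receptor × anti-receptor network with
    independent per-arm binding; ternary complexes form with no avidity
    enhancement."""
    return _receptor_family(scenario, "bispecific_receptor")


_BUILDERS = {
    "anti_ligand": build_anti_ligand,
    "anti_receptor": build_anti_receptor,
    "bispecific_receptor": build_bispecific,
}


def build_network(scenario: Scenario) -> ReactionNetwork:
    """Dispatch to the model family matching the drug's modality."""
    return _BUILDERS[scenario.drug.modality](scenario)


# ---------------------------------------------------------------------------
# rate assignment
# ---------------------------------------------------------------------------


def assign_rates(network: ReactionNetwork, kon_default: float | None = None) -> ReactionNetwork:
    """Fill in numeric rate constants from the scenario parameter blocks.

    * ``koff = kon·Kd`` per binding step, with independent-identical-sites
      statistical factors (first of two sites on at ``2·kon``, off at
      ``koff``; second on at ``kon``, off at ``2·koff``).
    * drug non-specific elimination ``ln2/t½`` in every compartment;
    * transport ``k12 = ln2/tdist`` on central concentration and
      ``k21 = k12·V1/(pdist·V2)`` so the drug-only distribution equilibrium
      satisfies ``C_peripheral/C_central = pdist``;
    * SC absorption ``ka = ln2/absorption_half_life``.

    Synthesis and shedding rates are left for the baseline initialiser.
    """
    sc = network.scenario
    kon = sc.kon if kon_default is None else kon_default
    if kon is None or kon <= 0:
        raise ValueError("kon_default: a positive association rate constant is required")
    drug, phys = sc.drug, sc.physiology

    kel = half_life_to_rate(drug.half_life)
    network.derived["kon"] = kon
    network.derived["kel_drug"] = kel
    if drug.absorption_half_life is not None:
        network.derived["ka"] = half_life_to_rate(drug.absorption_half_life)
    if phys.volume_peripheral > 0:
        k12 = LN2 / phys.tdist
        k21 = k12 * phys.volume_central / (phys.pdist * phys.volume_peripheral)
        network.derived["k12"] = k12
        network.derived["k21"] = k21

    def kd_of(target_id: str) -> float:
        return sc.arm_for(target_id).kd

    for rx in network.reactions:
        rule = rx.meta["rule"]
        head = rule[0]
        if head in ("syn_ligand", "syn_cognate", "syn_membrane", "shed"):
            continue  # solved at initialisation
        if head == "absorption":
            rx.rate = network.derived["ka"]
        elif head == "elim_drug":
            rx.rate = kel
        elif head == "elim_ligand":
            rx.rate = half_life_to_rate(sc.targets[rule[1]].half_life)
        elif head == "elim_cognate":
            rx.rate = half_life_to_rate(sc.targets[rule[1]].receptor_half_life)
        elif head == "elim_membrane":
            rx.rate = sum(half_life_to_rate(sc.targets[t].receptor_half_life) for t in rule[1])
        elif head == "elim_membrane_free":
            # provisional: total turnover; reduced by kshed at initialisation
            rx.rate = half_life_to_rate(sc.targets[rule[1]].receptor_half_life)
        elif head == "elim_shed":
            rx.rate = half_life_to_rate(sc.targets[rule[1]].shed.soluble_half_life)
        elif head == "on_cognate":
            rx.rate = kon
        elif head == "off_cognate":
            rx.rate = kon * sc.targets[rule[1]].receptor_kd
        elif head == "on_arm":
            _, target_id, free_sites = rule
            rx.rate = free_sites * kon
        elif head == "off_arm":
            _, target_id, n_bound = rule
            rx.rate = n_bound * kon * kd_of(target_id)
        elif head == "transport":
            rx.rate = network.derived["k12"] if rule[1] == "c2p" else network.derived["k21"]
        else:  # pragma: no cover - builder/assigner mismatch
            raise ValueError(f"unknown rate rule {rule!r}")
    return network
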