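"""Network construction: species enumeration against a brute-force oracle,
rate assignment algebra, detailed balance, and structural invariants."""

import itertools
import math

import numpy as np
import pytest

import efadose as e
from efadose.network import ModelMismatchError, build_anti_ligand, build_anti_receptor

# ---------------------------------------------------------------------------
# independent brute-force enumeration of expected species
# ---------------------------------------------------------------------------


def enumerate_receptor_drug_states(arm_options: list[tuple[list[str], int]]) -> set[tuple[str, ...]]:
    """All drug occupancy states for arms given as (bindable tokens, valency),
    enumerated exhaustively and independently of the builder."""
    per_arm = []
    for tokens, valency in arm_options:
        states = {()}
        for n in range(1, valency + 1):
            states |= {
                tuple(sorted(c)) for c in itertools.combinations_with_replacement(tokens, n)
            }
        per_arm.append(sorted(states))
    out = set()
    for combo in itertools.product(*per_arm):
        out.add(tuple(sorted(tok for part in combo for tok in part)))
    return out


def drug_species_ids(network, compartment):
    return {
        sp.id
        for sp in network.species_in(compartment)
        if sp.count("drug") and sp.id != "depot"
    }


def state_id(tokens, compartment):
    if not tokens:
        return f"D@{compartment}"
    return f"D[{','.join(sorted(tokens))}]@{compartment}"


def test_anti_ligand_enumeration_valency_1(scenarios):
    net = build_anti_ligand(scenarios["adalimumab"])
    # depot + D + L + R + LR + DL
    assert {sp.id for sp in net.species} == {
        "depot", "D@central", "L@central", "R@central", "LR@central", "D[L]@central",
    }
    # absorption + 2 syntheses + 5 eliminations + 2x2 binding on/off
    kinds = [rx.kind for rx in net.reactions]
    assert len(net.reactions) == 12
    assert kinds.count("synthesis") == 2
    assert kinds.count("elimination") == 5
    assert kinds.count("binding_on") == kinds.count("binding_off") == 2
    assert kinds.count("absorption") == 1


def test_anti_ligand_enumeration_valency_2(scenarios):
    sc = scenarios["infliximab"].model_copy(deep=True)
    sc.drug.arms[0].valency = 2
    net = build_anti_ligand(sc)
    ids = {sp.id for sp in net.species}
    assert "D[L,L]@central" in ids
    assert len(ids) == 6  # no depot (IV-only drug): D, L, R, LR, DL, DL2


def test_anti_ligand_rejects_wrong_modality(scenarios):
    with pytest.raises(ModelMismatchError):
        build_anti_ligand(scenarios["panitumumab"])


def test_anti_receptor_rejects_wrong_modality(scenarios):
    with pytest.raises(ModelMismatchError):
        build_anti_receptor(scenarios["adalimumab"])


@pytest.mark.parametrize(
    "fixture, tokens, valency",
    [
        ("panitumumab", ["egfr"], 2),
        ("emibetuzumab", ["cmet", "scmet"], 2),
    ],
)
def test_monospecific_receptor_enumeration(scenarios, fixture, tokens, valency):
    net = e.build_network(scenarios[fixture])
    expected_states = enumerate_receptor_drug_states([(tokens, valency)])
    for comp in ("central", "peripheral"):
        expected = {state_id(s, comp) for s in expected_states}
        assert drug_species_ids(net, comp) == expected
    # spec sanity: panitumumab has 3 occupancy states, emibetuzumab 6
    assert len(expected_states) == (3 if fixture == "panitumumab" else 6)


def test_bispecific_enumeration(scenarios):
    net = e.build_network(scenarios["amivantamab"])
    expected_states = enumerate_receptor_drug_states([(["egfr"], 1), (["cmet", "scmet"], 1)])
    assert len(expected_states) == 6  # D, DE, DM, DsM, DEM, DEsM
    for comp in ("central", "peripheral"):
        expected = {state_id(s, comp) for s in expected_states}
        assert drug_species_ids(net, comp) == expected
        free = {f"egfr@{comp}", f"cmet@{comp}", f"scmet@{comp}"}
        assert free <= {sp.id for sp in net.species_in(comp)}
    assert "depot" not in net  # IV-only network


def test_bispecific_without_shed_has_four_drug_states(scenarios):
    sc = scenarios["amivantamab"].model_copy(deep=True)
    sc.targets["cmet"].shed = None
    net = e.build_network(sc)
    assert len(drug_species_ids(net, "central")) == 4  # D, DE, DM, DEM


def test_membrane_species_never_soluble_and_never_transport(models):
    for name in ("panitumumab", "emibetuzumab", "amivantamab"):
        net = models[name].network
        transported = {rx.reactants[0] for rx in net.reactions if rx.kind == "transport"}
        for sp in net.species:
            has_mem = any(k.endswith(":mem") for k in sp.composition)
            assert sp.mobility == ("membrane" if has_mem else "soluble")
            if has_mem:
                assert sp.id not in transported
        # all soluble species (in central/peripheral) do transport
        for sp in net.species:
            if sp.mobility == "soluble" and sp.compartment != "depot":
                assert sp.id in transported


def test_zero_peripheral_receptor_amount_is_valid(scenarios):
    sc = scenarios["panitumumab"].model_copy(deep=True)
    sc.targets["egfr"].amount_peripheral = 0.0
    model = e.FeasibilityModel(sc)
    assert model.network.derived["ksyn[egfr@peripheral]"] == 0.0
    assert model.verify_stationarity(horizon=200.0).passed


# ---------------------------------------------------------------------------
# rate assignment
# ---------------------------------------------------------------------------


def test_koff_equals_kon_times_kd(make_model):
    model = make_model("adalimumab", kon=0.36)
    net = model.network
    offs = [rx for rx in net.reactions if rx.meta["rule"][0] == "off_arm"]
    assert offs[0].rate == pytest.approx(0.36 * 0.0086, rel=1e-12)  # 3.096e-3 /h


def test_transport_rates_give_pdist_equilibrium(models):
    net = models["panitumumab"].network
    k12, k21 = net.derived["k12"], net.derived["k21"]
    assert k12 == pytest.approx(math.log(2) / 35.0, rel=1e-12)
    assert k21 == pytest.approx(k12 * 3.0 / (0.19 * 13.0), rel=1e-12)
    # drug-only transport equilibrium: Cp/Cc = pdist
    assert (k12 * 3.0) / (k21 * 13.0) == pytest.approx(0.19, rel=1e-12)


def test_bivalent_site_statistics(models):
    """First of two sites binds at 2·kon and releases at koff; the second at
    kon and 2·koff — so macroscopic Kd of the first step is Kd/2 and of the
    second 2·Kd."""
    net = models["panitumumab"].network
    kon, kd = net.derived["kon"], 0.05

    def rate(kind, lo_tokens, hi_tokens):
        lo = state_id(lo_tokens, "central")
        hi = state_id(hi_tokens, "central")
        for rx in net.reactions:
            if kind == "on" and rx.kind == "binding_on" and rx.reactants[0] == lo and rx.products == [hi]:
                return rx.rate
            if kind == "off" and rx.kind == "binding_off" and rx.reactants == [hi] and rx.products[0] == lo:
                return rx.rate
        raise AssertionError("reaction not found")

    on1, off1 = rate("on", (), ("egfr",)), rate("off", (), ("egfr",))
    on2, off2 = rate("on", ("egfr",), ("egfr", "egfr")), rate("off", ("egfr",), ("egfr", "egfr"))
    assert on1 == pytest.approx(2 * kon) and off1 == pytest.approx(kon * kd)
    assert on2 == pytest.approx(kon) and off2 == pytest.approx(2 * kon * kd)
    assert off1 / on1 == pytest.approx(kd / 2)
    assert off2 / on2 == pytest.approx(2 * kd)


def test_detailed_balance_every_binding_pair(models):
    """koff/kon of every arm binding step equals the declared site Kd after
    removing the statistical factors."""
    for name, model in models.items():
        net = model.network
        sc = model.scenario
        kon = net.derived["kon"]
        for rx in net.reactions:
            rule = rx.meta["rule"]
            if rule[0] == "on_arm":
                _, target, free = rule
                assert rx.rate == pytest.approx(free * kon, rel=1e-12)
            elif rule[0] == "off_arm":
                _, target, n_bound = rule
                assert rx.rate == pytest.approx(
                    n_bound * kon * sc.arm_for(target).kd, rel=1e-12
                ), name
            elif rule[0] == "off_cognate":
                assert rx.rate == pytest.approx(kon * sc.targets[rule[1]].receptor_kd, rel=1e-12)


def test_complex_elimination_conventions(models):
    """Membrane complexes eliminate at the membrane receptor's turnover rate;
    the bispecific ternary complex at the sum of both; drug:soluble-receptor
    complexes at the free drug's rate."""
    net = models["amivantamab"].network
    kel = net.derived["kel_drug"]
    kdeg_e = math.log(2) / 5.0
    kdeg_m = math.log(2) / 4.0

    def elim(sid):
        for rx in net.reactions:
            if rx.kind == "elimination" and rx.reactants == [sid]:
                return rx.rate
        raise AssertionError(sid)

    assert elim("D@central") == pytest.approx(kel)
    assert elim("D[scmet]@central") == pytest.approx(kel)  # soluble complex: drug rate
    assert elim("D[egfr]@central") == pytest.approx(kdeg_e)
    assert elim("D[cmet]@central") == pytest.approx(kdeg_m)
    assert elim("D[cmet,egfr]@central") == pytest.approx(kdeg_e + kdeg_m)  # ternary: sum
    assert elim("D[egfr,scmet]@central") == pytest.approx(kdeg_e)  # mixed: membrane rate


def test_every_species_has_elimination_route(models):
    for model in models.values():
        model.network.validate()  # raises on violation


def test_missing_kon_rejected(scenarios):
    net = e.build_network(scenarios["adalimumab"])
    with pytest.raises(ValueError, match="kon"):
        e.assign_rates(net, kon_default=-1.0)


def test_reaction_table_export(models):
    table = models["emibetuzumab"].network.to_table()
    assert set(table.columns) == {"reactants", "products", "kind", "rate_constant"}
    assert len(table) == len(models["emibetuzumab"].network.reactions)
    assert table["rate_constant"].notna().all()


# ---------------------------------------------------------------------------
# constituent conservation in the closed limit
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("fixture", ["emibetuzumab", "amivantamab"])
def test_constituent_conservation_closed_system(scenarios, fixture):
    """With synthesis, elimination, absorption and transport switched off,
    binding and shedding conserve the total moles of drug and of each target
    along any trajectory."""
    from efadose.simulate import integrate_window
    from tests.conftest import total_constituents

    model = e.FeasibilityModel(scenarios[fixture].model_copy(deep=True))
    net = model.network
    for rx in net.reactions:
        if rx.kind in ("synthesis", "elimination", "absorption", "transport"):
            rx.rate = 0.0
    y0 = np.full(net.n_species, 0.7)
    before = total_constituents(net, y0)
    _, ys = integrate_window(net, y0, 0.0, 200.0, np.array([0.0, 200.0]))
    after = total_constituents(net, ys[:, -1])
    assert not np.allclose(ys[:, -1], y0)  # binding/shedding actually happened
    for c in before:
        assert after[c] == pytest.approx(before[c], rel=1e-6), c
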