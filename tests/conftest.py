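import numpy as np
import pytest

import efadose as e

ALL_FIXTURES = ["adalimumab", "infliximab", "panitumumab", "emibetuzumab", "amivantamab"]


@pytest.fixture(scope="session")
def scenarios() -> dict[str, e.Scenario]:
    return {name: e.load_builtin(name) for name in ALL_FIXTURES}


@pytest.fixture(scope="session")
def models(scenarios) -> dict[str, e.FeasibilityModel]:
    """Shared read-only models; tests that mutate networks must build their
    own via make_model."""
    return {name: e.FeasibilityModel(sc) for name, sc in scenarios.items()}


@pytest.fixture()
def make_model(scenarios):
    def _make(name: str, **kwargs) -> e.FeasibilityModel:
        return e.FeasibilityModel(scenarios[name].model_copy(deep=True), **kwargs)

    return _make


def drug_only_scenario(two_compartment: bool, dose_mg: float = 100.0, route: str = "IV",
                       interval: float = 336.0, n_doses: int = 1) -> e.Scenario:
    """A scenario whose target burden is numerically negligible, so the drug
    follows pure linear 1- or 2-compartment kinetics (closed-form oracles)."""
    if two_compartment:
        drug = {
            "name": "probe",
            "modality": "anti_receptor",
            "arms": [{"target": "r", "kd": 1.0, "valency": 2}],
            "half_life": 384.0,
            "mw": 150000.0,
        }
        targets = {
            "r": {
                "kind": "membrane_receptor",
                "amount_central": 1e-12,
                "amount_peripheral": 1e-12,
                "receptor_half_life": 5.0,
            }
        }
        phys = {"volume_central": 3.0, "volume_peripheral": 13.0, "body_weight": 70.0,
                "pdist": 0.19, "tdist": 35.0}
    else:
        drug = {
            "name": "probe",
            "modality": "anti_ligand",
            "arms": [{"target": "l", "kd": 1.0, "valency": 1}],
            "half_life": 480.0,
            "mw": 148000.0,
            "absorption_half_life": 60.0,
        }
        targets = {
            "l": {
                "kind": "soluble_ligand",
                "baseline_conc": 1e-12,
                "half_life": 0.5,
                "receptor_kd": 1.0,
                "receptor_total": 1e-12,
                "receptor_half_life": 9.0,
            }
        }
        phys = {"volume_central": 5.0, "volume_peripheral": 0.0, "body_weight": 70.0}
    return e.Scenario.model_validate(
        {
            "name": "drug-only probe",
            "drug": drug,
            "targets": targets,
            "physiology": phys,
            "regimen": {"route": route, "dose_mg": dose_mg, "interval": interval,
                        "n_doses": n_doses},
        }
    )


def total_constituents(network: e.ReactionNetwork, y: np.ndarray) -> dict[str, float]:
    return {c: float(network.constituent_weights(c) @ y) for c in network.constituents()}
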