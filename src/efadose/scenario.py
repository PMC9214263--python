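"""Scenario file I/O and the built-in drug fixtures.

Scenario files are YAML documents validated against the
:class:`~efadose.params.Scenario` schema.  Five ready-made scenarios for
approved antibodies ship with the package (literature-parameterised):
adalimumab, infliximab (anti-TNFα ligand models), panitumumab (anti-EGFR),
emibetuzumab (anti-c-Met with shed soluble receptor) and amivantamab
(EGFR × c-Met bispecific).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml
from pydantic import ValidationError

from .params import Scenario

__all__ = ["ScenarioValidationError", "load_scenario", "save_scenario", "scenario_to_yaml",
           "builtin_scenarios", "load_builtin"]


class ScenarioValidationError(ValueError):
    """Scenario document violates the schema; message lists field errors."""

    def __init__(self, source: str, err: ValidationError) -> None:
        self.errors = err.errors()
        details = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in self.errors
        )
        super().__init__(f"invalid scenario {source}: {details}")


def _validate(doc: dict, source: str) -> Scenario:
    if not isinstance(doc, dict):
        raise ScenarioValidationError.__new__(ScenarioValidationError)  # pragma: no cover
    try:
        return Scenario.model_validate(doc)
    except ValidationError as err:
        raise ScenarioValidationError(source, err) from err


def load_scenario(path: "str | Path") -> Scenario:
    """Read and validate a YAML scenario file."""
    path = Path(path)
    with path.open() as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"scenario file {path} is not a mapping")
    return _validate(doc, str(path))


def scenario_to_yaml(scenario: Scenario) -> str:
    doc = scenario.model_dump(exclude_none=True)
    return yaml.safe_dump(doc, sort_keys=False)


def save_scenario(scenario: Scenario, path: "str | Path") -> None:
    Path(path).write_text(scenario_to_yaml(scenario))


def builtin_scenarios() -> list[str]:
    """Names of the scenarios shipped with the package."""
    pkg = resources.files("efadose") / "data"
    return sorted(p.name.removesuffix(".yaml") for p in pkg.iterdir() if p.name.endswith(".yaml"))


def load_builtin(name: str) -> Scenario:
    """Load a shipped scenario by name (see :func:`builtin_scenarios`)."""
    pkg = resources.files("efadose") / "data" / f"{name}.yaml"
    try:
        text = pkg.read_text()
    except FileNotFoundError:
        raise KeyError(
            f"no builtin scenario {name!r}; available: {builtin_scenarios()}"
        ) from None
    return _validate(yaml.safe_load(text), f"builtin:{name}")
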