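"""Bottom-up membrane-target expression from cell-level data.

Compartmental target amount = Σ over cell populations of
(cell count × fraction of cells expressing × receptors per cell),
converted to nanomoles via Avogadro's number and to a concentration by the
compartment's (interstitial) volume.  Receptors-per-cell values are treated
as binding sites (Scatchard-derived); no dimer correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .units import AVOGADRO, InvalidParameterError

__all__ = ["Population", "ExpressionResult", "bottom_up_expression", "expression_from_table"]


@dataclass(frozen=True)
class Population:
    """One target-expressing cell population."""

    cell_count: float
    fraction_expressing: float
    receptors_per_cell: float
    cell_type: str = ""

    def __post_init__(self) -> None:
        if self.cell_count < 0:
            raise InvalidParameterError("cell_count", "must be >= 0")
        if not 0.0 <= self.fraction_expressing <= 1.0:
            raise InvalidParameterError("fraction_expressing", "must be in [0, 1]")
        if self.receptors_per_cell < 0:
            raise InvalidParameterError("receptors_per_cell", "must be >= 0")

    @property
    def receptors(self) -> float:
        return self.cell_count * self.fraction_expressing * self.receptors_per_cell


@dataclass(frozen=True)
class ExpressionResult:
    amount_nmol: float
    concentration_nM: float
    volume_L: float

    def __str__(self) -> str:
        return (
            f"{self.amount_nmol:.4g} nmol in {self.volume_L:g} L "
            f"-> {self.concentration_nM:.4g} nM"
        )


def bottom_up_expression(populations, volume_L: float) -> ExpressionResult:
    """Total compartmental target amount and concentration from cell
    populations.  Linear and additive in every input."""
    if volume_L <= 0:
        raise InvalidParameterError("volume_L", "must be > 0")
    pops = [p if isinstance(p, Population) else Population(**p) for p in populations]
    total_receptors = sum(p.receptors for p in pops)
    amount_nmol = total_receptors / AVOGADRO * 1e9
    return ExpressionResult(
        amount_nmol=amount_nmol,
        concentration_nM=amount_nmol / volume_L,
        volume_L=volume_L,
    )


def expression_from_table(table: pd.DataFrame, volumes: dict[str, float]) -> pd.DataFrame:
    """Per-compartment expression from a population table with columns
    (cell_type, compartment, cell_count, fraction_expressing,
    receptors_per_cell); ``volumes`` maps compartment name to litres.
    Output rows are compatible with MembraneReceptorTarget amounts."""
    required = {"compartment", "cell_count", "fraction_expressing", "receptors_per_cell"}
    missing = required - set(table.columns)
    if missing:
        raise InvalidParameterError("table", f"missing columns: {sorted(missing)}")
    rows = []
    for comp, grp in table.groupby("compartment"):
        if comp not in volumes:
            raise InvalidParameterError("volumes", f"no volume for compartment {comp!r}")
        pops = [
            Population(
                cell_count=r.cell_count,
                fraction_expressing=r.fraction_expressing,
                receptors_per_cell=r.receptors_per_cell,
                cell_type=str(getattr(r, "cell_type", "")),
            )
            for r in grp.itertuples()
        ]
        res = bottom_up_expression(pops, volumes[comp])
        rows.append(
            {
                "compartment": comp,
                "amount_nmol": res.amount_nmol,
                "concentration_nM": res.concentration_nM,
                "volume_L": res.volume_L,
            }
        )
    return pd.DataFrame(rows)
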