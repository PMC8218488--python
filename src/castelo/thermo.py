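"""Relative potency from relative binding free energies.

Alchemical free-energy calculations give each compound a binding free energy
ΔΔF relative to a common chargeless probe. Assuming potency (for sweeteners,
relative sweetness RS) is a direct readout of the dissociation constant,
the computed relative potency of a compound against a reference compound is

    CRS = exp(-(ΔΔF_compound - ΔΔF_reference) / RT)

with R = 1.987e-3 kcal/(mol K). This module implements that arithmetic and
the fold-improvement form used to verify suggested modifications; running
the alchemical simulations themselves is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "GAS_CONSTANT_KCAL",
    "FreeEnergyRecord",
    "SWEETENER_TABLE",
    "log_crs",
    "fold_improvement",
    "crs_table",
]

#: Gas constant in kcal/(mol K).
GAS_CONSTANT_KCAL = 1.987e-3


@dataclass(frozen=True)
class FreeEnergyRecord:
    """Relative binding free energy of one compound.

    Parameters
    ----------
    name:
        Compound label.
    ddF:
        Binding free energy relative to the common probe (kcal/mol).
    ddF_err:
        One standard deviation on ``ddF`` (kcal/mol), non-negative.
    rs:
        Experimental relative potency (relative sweetness), if known.
    """

    name: str
    ddF: float
    ddF_err: float = 0.0
    rs: Optional[float] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.ddF):
            raise ValueError(f"ddF must be finite, got {self.ddF!r}")
        if self.ddF_err < 0:
            raise ValueError("ddF_err must be non-negative")


#: T1R2 sweetener free energies (kcal/mol, relative to muted ethane) with
#: experimental relative sweetness; sucrose is the potency reference (RS=1).
SWEETENER_TABLE: tuple[FreeEnergyRecord, ...] = (
    FreeEnergyRecord("sucrose", -6.9, 0.7, rs=1.0),
    FreeEnergyRecord("4R-Cl-sucrose", -10.2, 0.8, rs=5.0),
    FreeEnergyRecord("sucralose", -11.7, 0.8, rs=600.0),
    FreeEnergyRecord("dulcin", -10.6, 0.4, rs=250.0),
    FreeEnergyRecord("isovanillyl", -11.1, 0.8, rs=400.0),
)


def log_crs(
    compound: FreeEnergyRecord,
    reference: FreeEnergyRecord,
    temperature_K: float = 310.0,
) -> tuple[float, float]:
    """log10 of the computed relative potency of ``compound`` vs ``reference``.

    Returns ``(log10(CRS), err)`` where CRS = exp(-(ΔΔF_c - ΔΔF_r)/RT) and
    ``err`` propagates the two ddF standard deviations in quadrature onto the
    log10 scale.

    Raises
    ------
    ValueError
        If ``temperature_K`` is not positive.
    """
    if temperature_K <= 0:
        raise ValueError("temperature_K must be positive")
    rt = GAS_CONSTANT_KCAL * temperature_K
    value = -(compound.ddF - reference.ddF) / (rt * math.log(10.0))
    err = math.hypot(compound.ddF_err, reference.ddF_err) / (rt * math.log(10.0))
    return value, err


def fold_improvement(ddF_change: float, temperature_K: float = 298.15) -> float:
    """Potency fold-change implied by a binding free-energy change.

    A modification that changes the binding free energy by ``ddF_change``
    (kcal/mol; negative = stronger binding) multiplies the predicted potency
    by exp(-ΔΔF/RT).
    """
    if temperature_K <= 0:
        raise ValueError("temperature_K must be positive")
    return math.exp(-ddF_change / (GAS_CONSTANT_KCAL * temperature_K))


def crs_table(
    records: Iterable[FreeEnergyRecord] = SWEETENER_TABLE,
    reference_name: str = "sucrose",
    temperature_K: float = 310.0,
) -> pd.DataFrame:
    """Tabulate log10(CRS) ± err for every record against one reference.

    Columns: name, ddF, ddF_err, log_rs (log10 of the experimental potency
    where known), log_crs, log_crs_err.
    """
    records = list(records)
    by_name = {r.name: r for r in records}
    if reference_name not in by_name:
        raise KeyError(f"reference compound {reference_name!r} not in records")
    ref = by_name[reference_name]
    rows = []
    for r in records:
        value, err = log_crs(r, ref, temperature_K=temperature_K)
        rows.append(
            {
                "name": r.name,
                "ddF": r.ddF,
                "ddF_err": r.ddF_err,
                "log_rs": math.log10(r.rs) if r.rs is not None and r.rs > 0 else float("nan"),
                "log_crs": value,
                "log_crs_err": err,
            }
        )
    return pd.DataFrame(rows)
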