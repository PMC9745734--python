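"""Sepsis-3 reference-standard labelling.

Suspected infection is proxied by orders for antibiotics or blood
cultures; sepsis is suspected infection plus a SOFA score of at least 2
(missing SOFA components assumed normal, i.e. zero); septic shock is
operationalised per the Sepsis-3 consensus as sepsis with vasopressor use
and lactate above 2 mmol/L (the threshold is configurable because the
underlying clinical definition is a consensus choice, not a measurement).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .cohort_io import EncounterRecord

__all__ = ["SepsisLabel", "suspected_infection", "sofa_total", "sepsis3_label"]


@dataclass(frozen=True)
class SepsisLabel:
    suspected_infection: bool
    sofa_total: int
    sepsis: bool
    septic_shock: bool

    def __post_init__(self) -> None:
        if self.septic_shock and not self.sepsis:
            raise ValueError("septic shock implies sepsis")
        if self.sepsis and not (self.suspected_infection and self.sofa_total >= 2):
            raise ValueError("sepsis requires suspected infection and SOFA >= 2")


def suspected_infection(rec: EncounterRecord) -> bool:
    """Orders for antibiotics or blood cultures mark suspected infection."""
    return rec.antibiotics_ordered or rec.blood_cultures_ordered


def sofa_total(components: Sequence[Optional[int]]) -> int:
    """Total SOFA score; absent components are assumed normal (0 points)."""
    total = 0
    for score in components:
        if score is None:
            continue
        if not 0 <= score <= 4:
            raise ValueError(f"SOFA component must be in [0, 4], got {score}")
        total += score
    return total


def sepsis3_label(
    rec: EncounterRecord,
    shock_lactate_mmol_l: float = 2.0,
) -> SepsisLabel:
    """Label one encounter against the Sepsis-3 reference standard.

    A precomputed SOFA total is used only when no component score is
    present; components win when both are recorded.
    """
    if any(score is not None for score in rec.sofa_components):
        total = sofa_total(rec.sofa_components)
    elif rec.sofa_total_precomputed is not None:
        total = rec.sofa_total_precomputed
    else:
        total = 0

    suspected = suspected_infection(rec)
    sepsis = suspected and total >= 2
    shock = (
        sepsis
        and bool(rec.vasopressors)
        and rec.lactate_mmol_l is not None
        and rec.lactate_mmol_l > shock_lactate_mmol_l
    )
    return SepsisLabel(
        suspected_infection=suspected,
        sofa_total=total,
        sepsis=sepsis,
        septic_shock=shock,
    )
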