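"""Forward dosimetry: reference doses to urinary biomonitoring equivalents.

A BE (biomonitoring equivalent) is the steady-state urinary concentration an
individual would show under chronic daily intake of a reference dose (TDI,
RfD, or an estimated daily intake).  Each virtual individual is dosed daily
until their urinary excretion plateaus; the maximum daily excreted amount is
converted to ng/mL with the individual's daily urine volume.  The 5th
percentile (conservative) and median over the population summarise the BE.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .chem_params import ChemicalParameterSet
from .pbk_core import (
    MAX_STEADY_STATE_DAYS,
    DosingRegimen,
    ModelMode,
    NOT_REACHED,
    Schedule,
    assemble_model,
    daily_urine_output,
    detect_steady_state,
    simulate,
)
from .population import PhysiologyParameterSet, individual_chemical_params

logger = logging.getLogger(__name__)


class BEBasis(str, Enum):
    TDI = "TDI"
    RFD = "RFD"
    EDI = "EDI"


@dataclass
class BEResult:
    """Per-individual steady-state urinary concentrations at a reference dose."""

    chemical: str
    basis: BEBasis
    dose_mg_kg_day: float
    concentrations_ngml: np.ndarray
    not_reached: int = 0
    group_tdi_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.concentrations_ngml = np.asarray(self.concentrations_ngml, dtype=float)
        if np.any(self.concentrations_ngml < 0):
            raise ValueError("BE concentrations must be non-negative")

    @property
    def n(self) -> int:
        return len(self.concentrations_ngml)

    @property
    def p05(self) -> float:
        return float(np.percentile(self.concentrations_ngml, 5, method="linear"))

    @property
    def median(self) -> float:
        return float(np.median(self.concentrations_ngml))

    def to_record(self) -> dict:
        return {
            "chemical": self.chemical,
            "basis": self.basis.value,
            "dose_mg_kg_day": self.dose_mg_kg_day,
            "n": self.n,
            "not_reached": self.not_reached,
            "p05_ngml": self.p05,
            "median_ngml": self.median,
        }


def steady_state_urinary_concentration(
    chemical: ChemicalParameterSet,
    individual: PhysiologyParameterSet,
    dose_mg_kg_day: float,
    mode: ModelMode | str = ModelMode.LINEAR7,
    rel_tol: float = 0.01,
    max_days: int = MAX_STEADY_STATE_DAYS,
    initial_days: int = 10,
    output_step_h: float = 1.0,
) -> Optional[float]:
    """One individual's plateau urinary concentration (ng/mL) under daily dosing.

    Simulates daily boluses, extending the horizon (doubling, capped at
    ``max_days``) until day-over-day urinary excretion stabilises within
    ``rel_tol``; returns the maximum daily concentration at/after that day,
    or ``NOT_REACHED`` (None) if the cap is hit without a plateau.
    """
    model = assemble_model(chemical, individual, mode=mode)
    days = min(initial_days, max_days)
    while True:
        regimen = DosingRegimen(
            dose=dose_mg_kg_day, schedule=Schedule.DAILY_BOLUS, duration_h=days * 24.0
        )
        result = simulate(model, regimen, output_step_h=output_step_h)
        ss_day = detect_steady_state(result, rel_tol=rel_tol)
        if ss_day is not None:
            concs = [
                daily_urine_output(
                    result, d, individual.daily_urine_volume_ml, chemical.mw
                )
                for d in range(ss_day, days + 1)
            ]
            return max(concs)
        if days >= max_days:
            return NOT_REACHED
        days = min(days * 2, max_days)


def derive_be(
    chemical: ChemicalParameterSet,
    dose_mg_kg_day: float,
    population: Sequence[PhysiologyParameterSet],
    mode: ModelMode | str = ModelMode.LINEAR7,
    basis: BEBasis | str = BEBasis.TDI,
    poor_metaboliser: bool = False,
    rel_tol: float = 0.01,
    max_days: int = MAX_STEADY_STATE_DAYS,
) -> BEResult:
    """Forward-simulate a reference dose across a virtual population.

    Individuals whose urinary excretion never plateaus within ``max_days``
    are excluded from the summaries and counted, with a logged warning.
    """
    if dose_mg_kg_day < 0:
        raise ValueError("dose must be non-negative")
    if len(population) == 0:
        raise ValueError("population must be non-empty")
    basis = BEBasis(basis)
    concs: list[float] = []
    not_reached = 0
    for individual in population:
        merged = individual_chemical_params(
            individual, chemical, poor_metaboliser=poor_metaboliser
        )
        conc = steady_state_urinary_concentration(
            merged, individual, dose_mg_kg_day, mode=mode,
            rel_tol=rel_tol, max_days=max_days,
        )
        if conc is NOT_REACHED:
            not_reached += 1
        else:
            concs.append(conc)
    if not concs:
        raise RuntimeError(
            f"{chemical.name}: steady state not reached for any of "
            f"{len(population)} individuals within {max_days} days"
        )
    if not_reached:
        logger.warning(
            "%s: steady state not reached for %d/%d individuals; excluded",
            chemical.name, not_reached, len(population),
        )
    return BEResult(
        chemical=chemical.name,
        basis=basis,
        dose_mg_kg_day=dose_mg_kg_day,
        concentrations_ngml=np.array(concs),
        not_reached=not_reached,
        group_tdi_id=chemical.group_tdi_id,
    )


def pool_group_be(results: Sequence[BEResult]) -> BEResult:
    """Pool BE distributions of chemicals sharing a group reference dose.

    All per-individual urinary equivalents are concatenated and the 5th
    percentile and median recomputed over the pooled distribution (used for
    group TDIs such as the shared methyl+ethyl paraben value).
    """
    if len(results) < 2:
        raise ValueError("group pooling needs at least two BE results")
    bases = {r.basis for r in results}
    if len(bases) > 1:
        raise ValueError(f"cannot pool mixed BE bases: {sorted(b.value for b in bases)}")
    group_ids = {r.group_tdi_id for r in results}
    return BEResult(
        chemical=" + ".join(r.chemical for r in results),
        basis=results[0].basis,
        dose_mg_kg_day=results[0].dose_mg_kg_day,
        concentrations_ngml=np.concatenate([r.concentrations_ngml for r in results]),
        not_reached=sum(r.not_reached for r in results),
        group_tdi_id=group_ids.pop() if len(group_ids) == 1 else None,
    )


def average_be_edi(
    edi_mg_kg_day: float,
    population: Sequence[PhysiologyParameterSet],
    chemical: ChemicalParameterSet,
    mode: ModelMode | str = ModelMode.LINEAR7,
    **kwargs,
) -> float:
    """Arithmetic mean BE_EDI (ng/mL) over the population at one intake."""
    result = derive_be(
        chemical, edi_mg_kg_day, population, mode=mode, basis=BEBasis.EDI, **kwargs
    )
    return float(np.mean(result.concentrations_ngml))


def reverse_dose(
    urine_conc_ngml: float,
    chemical: ChemicalParameterSet,
    individual: PhysiologyParameterSet,
    mode: ModelMode | str = ModelMode.LINEAR7,
    **kwargs,
) -> float:
    """Infer the daily intake (mg/kg/day) behind a measured urinary level.

    Exploits dose-linearity of the linear model: the steady-state urinary
    concentration at a unit dose of 1 mg/kg/day scales the inversion,
    EDI = conc / BE(1 mg/kg/day).
    """
    if ModelMode(mode) is not ModelMode.LINEAR7:
        raise ValueError("reverse dosimetry requires the linear (LINEAR7) mode")
    if urine_conc_ngml < 0:
        raise ValueError("urinary concentration must be non-negative")
    merged = individual_chemical_params(individual, chemical)
    be_unit = steady_state_urinary_concentration(
        merged, individual, 1.0, mode=mode, **kwargs
    )
    if be_unit is NOT_REACHED:
        raise RuntimeError(f"{chemical.name}: no steady state at unit dose")
    if be_unit <= 0:
        raise ValueError(f"{chemical.name}: no urinary excretion path (BE at unit dose is 0)")
    return urine_conc_ngml / be_unit


def reverse_dose_population(
    urine_concs_ngml: Sequence[float],
    chemical: ChemicalParameterSet,
    population: Sequence[PhysiologyParameterSet],
    mode: ModelMode | str = ModelMode.LINEAR7,
    **kwargs,
) -> np.ndarray:
    """Per-individual reverse dosimetry: one EDI per (concentration, individual)."""
    if len(urine_concs_ngml) != len(population):
        raise ValueError("need one concentration per individual")
    return np.array(
        [
            reverse_dose(c, chemical, ind, mode=mode, **kwargs)
            for c, ind in zip(urine_concs_ngml, population)
        ]
    )


@dataclass(frozen=True)
class FoldComparison:
    """Measured-over-predicted fold deviation and order-of-magnitude class."""

    fold: float
    magnitude_class: int
    abs_log10: float


def compare_predicted_measured(predicted_ngml: float, measured_ngml: float) -> FoldComparison:
    """Fold deviation measured/predicted with its order-of-magnitude class.

    ``magnitude_class`` is floor(log10(measured/predicted)); ``abs_log10`` is
    the symmetric |log10 ratio| variant.
    """
    if predicted_ngml <= 0 or measured_ngml <= 0:
        raise ValueError("both concentrations must be positive")
    fold = measured_ngml / predicted_ngml
    return FoldComparison(
        fold=fold,
        magnitude_class=int(math.floor(math.log10(fold))),
        abs_log10=abs(math.log10(fold)),
    )


def be_table(results: Sequence[BEResult]):
    """BE summaries as a tidy DataFrame (chemical, basis, dose, n, p05, median)."""
    import pandas as pd

    return pd.DataFrame([r.to_record() for r in results])
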