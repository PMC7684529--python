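"""Synthetic human-biomonitoring cohorts.

Real mother/child cohort urine tables of this kind are typically shared under
data-transfer agreements and cannot ship with code.  This module generates
synthetic stand-ins with the statistical structure the analysis assumes:
per-chemical lognormal urinary concentrations, specific-gravity values within
observed spot-sample ranges, below-LoD censoring, and adult-female/child
strata.  A model-linked variant forward-simulates each subject's concentration
from a known daily intake through the PBK model, providing ground truth for
parameter-recovery tests.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .chem_params import ChemicalParameterSet
from .dosimetry import steady_state_urinary_concentration
from .hbm_io import CohortTable, LodRule, _impute
from .pbk_core import ModelMode, NOT_REACHED
from .population import PhysiologyParameterSet, Stratum, individual_chemical_params


class ChemicalConcSpec(BaseModel):
    """Lognormal urinary-concentration distribution for one chemical."""

    gm_ngml: float = Field(gt=0.0, description="geometric mean, ng/mL")
    gsd: float = Field(ge=1.0, description="geometric standard deviation")
    lod_ngml: float = Field(default=0.0, ge=0.0)


class CohortGeneratorSpec(BaseModel):
    """Specification of a synthetic cohort.

    ``n_adult_females``/``n_children`` set the strata sizes; ``chemicals``
    maps chemical names to lognormal concentration parameters; SG values are
    drawn uniformly within ``sg_bounds`` (defaults spanning observed
    morning-spot ranges).
    """

    n_adult_females: int = Field(default=48, ge=0)
    n_children: int = Field(default=48, ge=0)
    chemicals: dict[str, ChemicalConcSpec]
    sg_bounds: tuple[float, float] = (1.003, 1.032)
    creatinine_gl_range: tuple[float, float] = (0.3, 3.0)
    seed: int = 0
    true_edi_mg_kg_day: Optional[dict[str, float]] = None
    noise_gsd: float = Field(default=1.0, ge=1.0)

    @model_validator(mode="after")
    def _validate(self) -> "CohortGeneratorSpec":
        lo, hi = self.sg_bounds
        if not (1.000 < lo <= hi < 1.050):
            raise ValueError("SG bounds must lie within (1.000, 1.050)")
        if self.n_adult_females + self.n_children < 1:
            raise ValueError("cohort must contain at least one subject")
        return self


def _rows_for_stratum(
    rng: np.random.Generator,
    stratum: str,
    n: int,
    start: int,
    spec: CohortGeneratorSpec,
) -> list[dict]:
    rows = []
    for i in range(n):
        subject = f"{stratum.lower()}-{start + i:04d}"
        sg = rng.uniform(*spec.sg_bounds)
        creat = rng.uniform(*spec.creatinine_gl_range)
        for chem, cs in spec.chemicals.items():
            conc = cs.gm_ngml * math.exp(rng.normal(0.0, math.log(cs.gsd))) \
                if cs.gsd > 1.0 else cs.gm_ngml
            below = conc < cs.lod_ngml
            rows.append(
                {
                    "subject_id": subject,
                    "stratum": stratum,
                    "chemical": chem,
                    "conc_ngml": np.nan if below else conc,
                    "sg": sg,
                    "creatinine_gl": creat,
                    "lod_ngml": cs.lod_ngml,
                    "below_lod": below,
                }
            )
    return rows


def generate_cohort(spec: CohortGeneratorSpec,
                    lod_rule: LodRule | str = LodRule.HALF_LOD) -> CohortTable:
    """Draw a synthetic cohort table; deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    rows = _rows_for_stratum(rng, "ADULT_FEMALE", spec.n_adult_females, 0, spec)
    rows += _rows_for_stratum(rng, "CHILD", spec.n_children, spec.n_adult_females, spec)
    df = pd.DataFrame(rows)
    rule = LodRule(lod_rule)
    return CohortTable(data=_impute(df, rule), lod_rule=rule)


def generate_model_linked_cohort(
    spec: CohortGeneratorSpec,
    population: Sequence[PhysiologyParameterSet],
    chemicals: dict[str, ChemicalParameterSet],
    mode: ModelMode | str = ModelMode.LINEAR7,
    lod_rule: LodRule | str = LodRule.HALF_LOD,
) -> tuple[CohortTable, dict[str, float]]:
    """Cohort whose concentrations come from the PBK model at known intakes.

    Each subject's urinary concentration is their forward-simulated
    steady-state concentration at the true EDI, times multiplicative
    lognormal noise with GSD ``spec.noise_gsd`` (noise GSD 1 reproduces the
    simulated values exactly).  Returns the cohort and the ground-truth EDI
    record for recovery testing.
    """
    if spec.true_edi_mg_kg_day is None:
        raise ValueError("model-linked cohorts require true_edi_mg_kg_day")
    missing = set(spec.true_edi_mg_kg_day) - set(chemicals)
    if missing:
        raise ValueError(f"no chemical parameters for {sorted(missing)}")
    rng = np.random.default_rng(spec.seed)
    rows = []
    for i, individual in enumerate(population):
        stratum = (
            "ADULT_FEMALE" if individual.id.startswith("adult_female") else "CHILD"
        )
        sg = rng.uniform(*spec.sg_bounds)
        creat = rng.uniform(*spec.creatinine_gl_range)
        for chem_name, edi in spec.true_edi_mg_kg_day.items():
            chem = chemicals[chem_name]
            merged = individual_chemical_params(individual, chem)
            conc = steady_state_urinary_concentration(merged, individual, edi, mode=mode)
            if conc is NOT_REACHED:
                raise RuntimeError(
                    f"{chem_name}: steady state not reached for subject {individual.id}"
                )
            if spec.noise_gsd > 1.0:
                conc *= math.exp(rng.normal(0.0, math.log(spec.noise_gsd)))
            lod = spec.chemicals.get(chem_name, ChemicalConcSpec(gm_ngml=1.0, gsd=1.0)).lod_ngml
            below = conc < lod
            rows.append(
                {
                    "subject_id": individual.id if individual.id else f"subject-{i:04d}",
                    "stratum": stratum,
                    "chemical": chem_name,
                    "conc_ngml": np.nan if below else conc,
                    "sg": sg,
                    "creatinine_gl": creat,
                    "lod_ngml": lod,
                    "below_lod": below,
                }
            )
    rule = LodRule(lod_rule)
    table = CohortTable(data=_impute(pd.DataFrame(rows), rule), lod_rule=rule)
    return table, dict(spec.true_edi_mg_kg_day)
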