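"""Cohort urine tables: I/O, dilution normalisation and below-LoD handling.

The CSV schema (exact header) is:

    subject_id, stratum, chemical, conc_ngml, sg, creatinine_gl, lod_ngml, below_lod

One row per subject-chemical pair.  Concentrations are spot-sample values in
ng/mL; ``sg`` is urinary specific gravity, ``creatinine_gl`` (nullable) in
g/L.  Below-LoD rows carry ``below_lod=True`` and are imputed on read
according to a configurable substitution rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

#: Reference specific gravity used for dilution adjustment by default.
DEFAULT_SG_REFERENCE = 1.024

COHORT_COLUMNS = [
    "subject_id", "stratum", "chemical", "conc_ngml", "sg",
    "creatinine_gl", "lod_ngml", "below_lod",
]

_STRATA = {"ADULT_FEMALE", "CHILD"}


class LodRule(str, Enum):
    """Substitution rule for measurements below the limit of detection."""

    HALF_LOD = "HALF_LOD"
    LOD_SQRT2 = "LOD_SQRT2"
    ZERO = "ZERO"
    EXCLUDE = "EXCLUDE"


def sg_adjust(conc_ngml: float, sg: float, sg_ref: float = DEFAULT_SG_REFERENCE) -> float:
    """Normalise a urinary concentration to a reference specific gravity.

    conc × (SG_ref − 1)/(SG − 1): corrects spot-sample dilution so that
    samples of different hydration states are comparable.
    """
    if sg <= 1.000:
        raise ValueError(f"specific gravity {sg} <= 1.000: adjustment degenerates")
    if sg_ref <= 1.000:
        raise ValueError("reference specific gravity must exceed 1.000")
    if conc_ngml < 0:
        raise ValueError("concentration must be non-negative")
    return conc_ngml * (sg_ref - 1.0) / (sg - 1.0)


def creatinine_adjust(conc_ngml: float, creatinine_gl: float) -> float:
    """Express a urinary concentration per gram creatinine (µg/g).

    ng/mL ÷ g/L = µg/g numerically, so this is a plain ratio with unit
    bookkeeping.
    """
    if creatinine_gl <= 0:
        raise ValueError("creatinine must be positive")
    if conc_ngml < 0:
        raise ValueError("concentration must be non-negative")
    return conc_ngml / creatinine_gl


@dataclass
class CohortTable:
    """Measured (or synthetic) urine records plus the LoD rule applied on read."""

    data: pd.DataFrame
    lod_rule: LodRule = LodRule.HALF_LOD
    sg_ref: float = DEFAULT_SG_REFERENCE

    def __post_init__(self) -> None:
        _validate_frame(self.data)

    def concentrations(self, chemical: str, sg_adjusted: bool = False,
                       include_below_lod: bool = True) -> np.ndarray:
        """Concentration vector for one chemical, optionally SG-normalised.

        Under the EXCLUDE rule (or ``include_below_lod=False``) censored rows
        are dropped from numeric analyses; otherwise the imputed values are
        used.
        """
        rows = self.data[self.data["chemical"] == chemical]
        if len(rows) == 0:
            raise KeyError(f"no rows for chemical {chemical!r}")
        if self.lod_rule is LodRule.EXCLUDE or not include_below_lod:
            rows = rows[~rows["below_lod"]]
        concs = rows["conc_ngml"].to_numpy(dtype=float)
        if sg_adjusted:
            sgs = rows["sg"].to_numpy(dtype=float)
            concs = np.array([sg_adjust(c, s, self.sg_ref) for c, s in zip(concs, sgs)])
        return concs

    def chemicals(self) -> list[str]:
        return sorted(self.data["chemical"].unique())

    def coverage(self) -> pd.DataFrame:
        """Per-chemical row counts and below-LoD fractions (censored rows included)."""
        return (
            self.data.groupby("chemical")
            .agg(n=("subject_id", "size"), below_lod_frac=("below_lod", "mean"))
            .reset_index()
        )


def _validate_frame(df: pd.DataFrame) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing column(s): {missing}")
    problems = []
    for i, row in df.iterrows():
        if row["stratum"] not in _STRATA:
            problems.append(f"row {i}: unknown stratum {row['stratum']!r}")
        if not row["below_lod"] and (
            pd.isna(row["conc_ngml"]) or row["conc_ngml"] < 0
        ):
            problems.append(f"row {i}: negative or missing concentration")
        if not pd.isna(row["sg"]) and row["sg"] <= 1.000:
            problems.append(f"row {i}: specific gravity {row['sg']} <= 1.000")
    if problems:
        raise ValueError("malformed cohort rows:\n" + "\n".join(problems))
    dupes = df.duplicated(subset=["subject_id", "chemical"])
    if dupes.any():
        raise ValueError(
            f"duplicate subject-chemical pairs at rows {list(df.index[dupes])}"
        )


def _impute(df: pd.DataFrame, rule: LodRule) -> pd.DataFrame:
    df = df.copy()
    mask = df["below_lod"].astype(bool)
    if rule is LodRule.HALF_LOD:
        df.loc[mask, "conc_ngml"] = df.loc[mask, "lod_ngml"] / 2.0
    elif rule is LodRule.LOD_SQRT2:
        df.loc[mask, "conc_ngml"] = df.loc[mask, "lod_ngml"] / math.sqrt(2.0)
    elif rule is LodRule.ZERO:
        df.loc[mask, "conc_ngml"] = 0.0
    # EXCLUDE keeps the rows (flagged) so coverage stats still see them;
    # numeric accessors drop them.
    return df


def read_cohort(path: str | Path, lod_rule: LodRule | str = LodRule.HALF_LOD,
                sg_ref: float = DEFAULT_SG_REFERENCE) -> CohortTable:
    """Read a cohort CSV, validate the schema, and impute below-LoD rows."""
    rule = LodRule(lod_rule)
    df = pd.read_csv(path)
    if "below_lod" in df.columns:
        df["below_lod"] = df["below_lod"].astype(bool)
    _validate_frame(df)
    return CohortTable(data=_impute(df, rule), lod_rule=rule, sg_ref=sg_ref)


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write the cohort back out in the canonical column order."""
    table.data[COHORT_COLUMNS].to_csv(path, index=False)
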