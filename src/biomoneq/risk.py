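"""Single-substance and mixture risk screening against biomonitoring equivalents.

A risk quotient (RQ) divides a measured urinary concentration by the BE for
that chemical; the Hazard Index (HI) of a subject sums their RQs across
chemicals.  HI < 1 indicates low concern at screening level; HI ≥ 1 flags the
mixture for refined assessment.  Chemicals sharing a group reference dose
(e.g. methyl+ethyl paraben) enter the HI once, as the sum of member
concentrations over the pooled BE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

HI_CONCERN_THRESHOLD = 1.0

#: Chemical-group membership used for group contribution reporting.
DEFAULT_GROUPS = {
    "phenols": ["BPA", "TCS", "BP-3"],
    "parabens": ["MeP", "EtP", "n-PrP", "n-BuP"],
}


def risk_quotient(conc_ngml: float, be_ngml: float) -> float:
    """RQ = measured urinary concentration / biomonitoring equivalent."""
    if be_ngml <= 0:
        raise ValueError("BE must be positive")
    if conc_ngml < 0:
        raise ValueError("concentration must be non-negative")
    return conc_ngml / be_ngml


def hazard_index(rqs: Iterable[float]) -> float:
    """HI = sum of risk quotients; ≥ 1 flags potential mixture concern."""
    rqs = list(rqs)
    if any(rq < 0 for rq in rqs):
        raise ValueError("risk quotients must be non-negative")
    return float(sum(rqs))


def hi_concern(hi: float) -> bool:
    return hi >= HI_CONCERN_THRESHOLD


def exceedance_fraction(concs_ngml: Sequence[float], be_ngml: float) -> float:
    """Percentage of the cohort strictly exceeding the BE (ties do not exceed)."""
    concs = np.asarray(list(concs_ngml), dtype=float)
    if concs.size == 0:
        raise ValueError("empty cohort")
    if be_ngml <= 0:
        raise ValueError("BE must be positive")
    return 100.0 * float(np.count_nonzero(concs > be_ngml)) / concs.size


def group_tdi_rq(member_concs_ngml: Mapping[str, float], pooled_be_ngml: float) -> float:
    """Single RQ for a chemical group with a shared reference dose.

    The member concentrations are summed and divided by the pooled BE; the
    group RQ replaces (never duplicates) the member RQs in the HI.
    """
    if pooled_be_ngml <= 0:
        raise ValueError("pooled BE must be positive")
    total = 0.0
    for chem, conc in member_concs_ngml.items():
        if conc < 0:
            raise ValueError(f"{chem}: negative concentration")
        total += conc
    return total / pooled_be_ngml


@dataclass
class PopulationHI:
    """Population-level HI from median concentrations and median BEs."""

    hi: float
    rq_by_chemical: dict[str, float]
    group_contribution_pct: dict[str, float]

    @property
    def concern(self) -> bool:
        return hi_concern(self.hi)


def population_hazard_index(
    median_concs_ngml: Mapping[str, float],
    median_bes_ngml: Mapping[str, float],
    groups: Optional[Mapping[str, Sequence[str]]] = None,
) -> PopulationHI:
    """HI of a study population: median measured level over median BE, summed.

    ``median_concs_ngml`` and ``median_bes_ngml`` must cover the same chemical
    set (group entries such as a pooled paraben pair count as one chemical).
    Group contributions are reported as percentages of the HI.
    """
    if set(median_concs_ngml) != set(median_bes_ngml):
        raise ValueError(
            "chemical sets differ: "
            f"{sorted(set(median_concs_ngml) ^ set(median_bes_ngml))}"
        )
    rqs = {
        chem: risk_quotient(median_concs_ngml[chem], median_bes_ngml[chem])
        for chem in median_concs_ngml
    }
    hi = hazard_index(rqs.values())
    groups = groups if groups is not None else DEFAULT_GROUPS
    contrib = {}
    for gname, members in groups.items():
        gsum = sum(rq for chem, rq in rqs.items()
                   if chem in members or any(m in chem for m in members))
        contrib[gname] = 100.0 * gsum / hi if hi > 0 else 0.0
    return PopulationHI(hi=hi, rq_by_chemical=rqs, group_contribution_pct=contrib)


@dataclass
class RiskSummary:
    """Per-subject RQ matrix, HIs, and per-chemical exceedance fractions."""

    rq_table: pd.DataFrame  # index subject_id, columns chemicals (and groups)
    hi_by_subject: pd.Series
    exceedance_pct: dict[str, float]
    be_basis: str = "p05"
    groups_applied: dict[str, list[str]] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        out = self.rq_table.copy()
        out["HI"] = self.hi_by_subject
        out.to_csv(path)

    def summary_json(self) -> dict:
        return {
            "be_basis": self.be_basis,
            "n_subjects": int(len(self.hi_by_subject)),
            "hi_median": float(self.hi_by_subject.median()),
            "hi_max": float(self.hi_by_subject.max()),
            "frac_hi_above_1": float((self.hi_by_subject >= 1.0).mean()),
            "exceedance_pct": self.exceedance_pct,
        }


def screen_cohort(
    cohort,
    bes_ngml: Mapping[str, float],
    group_members: Optional[Mapping[str, Sequence[str]]] = None,
    be_basis: str = "p05",
    sg_adjusted: bool = False,
) -> RiskSummary:
    """Full per-subject screening of a cohort table against BE values.

    ``bes_ngml`` maps chemical names to BEs; ``group_members`` maps a group
    key in ``bes_ngml`` (e.g. "MeP + EtP") to the member chemicals whose
    concentrations are summed against the pooled BE and whose individual RQs
    are dropped from the HI.
    """
    group_members = dict(group_members or {})
    grouped_chems = {m for members in group_members.values() for m in members}
    df = cohort.data
    if cohort.lod_rule.value == "EXCLUDE":
        df = df[~df["below_lod"]]
    wide = df.pivot(index="subject_id", columns="chemical", values="conc_ngml")
    if sg_adjusted:
        from .hbm_io import sg_adjust

        sgs = df.pivot(index="subject_id", columns="chemical", values="sg")
        wide = pd.DataFrame(
            {
                chem: [
                    sg_adjust(c, s, cohort.sg_ref) if pd.notna(c) and pd.notna(s) else np.nan
                    for c, s in zip(wide[chem], sgs[chem])
                ]
                for chem in wide.columns
            },
            index=wide.index,
        )

    rq_cols: dict[str, pd.Series] = {}
    exceed: dict[str, float] = {}
    for chem, be in bes_ngml.items():
        if chem in group_members:
            members = [m for m in group_members[chem] if m in wide.columns]
            concs = wide[members].sum(axis=1, min_count=1)
        else:
            if chem not in wide.columns:
                raise KeyError(f"cohort has no measurements for {chem!r}")
            concs = wide[chem]
        rq_cols[chem] = concs / be
        valid = concs.dropna()
        exceed[chem] = exceedance_fraction(valid.to_numpy(), be) if len(valid) else 0.0
    rq_table = pd.DataFrame(rq_cols)
    # HI over the screened chemicals; grouped members enter via their group only
    hi = rq_table.fillna(0.0).sum(axis=1)
    return RiskSummary(
        rq_table=rq_table,
        hi_by_subject=hi,
        exceedance_pct=exceed,
        be_basis=be_basis,
        groups_applied={k: list(v) for k, v in group_members.items()},
    )


def plot_risk_summary(summary: RiskSummary, path) -> None:
    """Bar chart of per-chemical median RQs and the median HI."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    med = summary.rq_table.median()
    fig, ax = plt.subplots(figsize=(7, 4))
    labels = list(med.index) + ["HI"]
    values = list(med.values) + [float(summary.hi_by_subject.median())]
    ax.bar(labels, values, color=["#4477aa"] * len(med) + ["#cc6677"])
    ax.axhline(1.0, color="k", lw=0.8, ls="--")
    ax.set_ylabel(f"median RQ ({summary.be_basis}-based BE)")
    ax.set_yscale("log")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
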