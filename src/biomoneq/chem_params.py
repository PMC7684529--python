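"""Chemical parameters: ADME inputs, IVIVE scaling, partitioning and unit conversions.

Every quantity carries its unit in the field name or docstring.  Internal
simulation units are µmol (amount), hours (time) and litres (volume);
conversion to urinary ng/mL happens only at the output boundary.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

# Hepatic IVIVE scaling factor: mg microsomal protein per g liver.
MICROSOMAL_PROTEIN_MG_PER_G_LIVER = 40.0

# Hepatocellularity used to scale intrinsic clearance expressed per 10^6
# hepatocytes to whole-liver values (10^6 cells per g liver).
HEPATOCELLULARITY_MCELLS_PER_G_LIVER = 110.0

# Whole blood is ~0.7 % lipid; used as the denominator of the tissue:blood
# lipid/water partitioning rule.
BLOOD_LIPID_FRACTION = 0.007
BLOOD_WATER_FRACTION = 0.82

# Default human small-intestinal radius (cm) for the cylindrical-tube
# permeability-to-absorption-rate conversion ka = 2*Peff/R.
SMALL_INTESTINE_RADIUS_CM = 1.75


class MetabolicStep(BaseModel):
    """One enzymatic conversion (Michaelis–Menten) of a parent into a product.

    ``vmax_invitro`` is in µmol/h per mg microsomal protein; ``km_um`` in µM
    (µmol/L unbound in plasma water).  The product is itself a chemical that
    distributes through the body and may carry further steps.
    """

    product: "ChemicalParameterSet"
    vmax_invitro: float = Field(ge=0.0)
    km_um: float = Field(gt=0.0)


class ChemicalParameterSet(BaseModel):
    """Physicochemical + ADME parameters and metabolite links for one substance."""

    name: str
    cas: Optional[str] = None
    mw: float = Field(gt=0.0, description="molecular weight, g/mol")
    log_kow: float = Field(default=0.0, description="log10 octanol:water at pH 7.4")
    water_solubility_mgl: Optional[float] = Field(default=None, ge=0.0)
    vapour_pressure_pa: Optional[float] = Field(default=None, ge=0.0)
    density_gcm3: Optional[float] = Field(default=None, gt=0.0)
    fub: float = Field(default=1.0, ge=0.0, le=1.0, description="fraction unbound in plasma")
    clint: Optional[float] = Field(
        default=None, ge=0.0,
        description="intrinsic hepatic clearance, µL/min/10^6 hepatocytes (linear mode)",
    )
    metabolic_steps: list[MetabolicStep] = Field(default_factory=list)
    ka: float = Field(default=1.0, ge=0.0, description="oral absorption rate, 1/h")
    fabs: float = Field(default=1.0, ge=0.0, le=1.0, description="bioavailable fraction")
    enterohepatic_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    renal_resorption_fraction: float = Field(
        default=0.0, ge=0.0, lt=1.0,
        description="fraction of the primary-urine filtrate resorbed from the "
        "renal tubule (metabolite-chain mode only; forced to 0 for log Kow < -1.5)",
    )
    rblood2plasma: float = Field(default=1.0, gt=0.0)
    tdi: Optional[float] = Field(default=None, ge=0.0, description="mg/kg/day")
    rfd: Optional[float] = Field(default=None, ge=0.0, description="mg/kg/day")
    group_tdi_id: Optional[str] = None
    group_tdi: Optional[float] = Field(default=None, ge=0.0, description="mg/kg/day")

    @field_validator("name")
    @classmethod
    def _nonempty_name(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("chemical name must be non-empty")
        return v

    @model_validator(mode="after")
    def _group_tdi_consistent(self) -> "ChemicalParameterSet":
        if self.group_tdi is not None and self.group_tdi_id is None:
            raise ValueError(f"{self.name}: group_tdi given without group_tdi_id")
        return self

    def reference_dose(self, basis: str) -> float:
        """Return the TDI or RfD in mg/kg/day, raising if absent."""
        basis = basis.upper()
        if basis == "TDI":
            value = self.tdi if self.tdi is not None else self.group_tdi
        elif basis == "RFD":
            value = self.rfd
        else:
            raise ValueError(f"unknown reference-dose basis {basis!r}")
        if value is None:
            raise ValueError(f"{self.name} has no {basis} value")
        return value

    def all_species(self) -> list["ChemicalParameterSet"]:
        """Parent plus every metabolite reachable through the step chain."""
        out: list[ChemicalParameterSet] = [self]
        for step in self.metabolic_steps:
            out.extend(step.product.all_species())
        return out


MetabolicStep.model_rebuild()


def scale_vmax_ivive(vmax_invitro: float, liver_mass_g: float) -> float:
    """Scale an in vitro Vmax (µmol/h per mg microsomal protein) to whole liver.

    Uses the microsomal-protein content of liver tissue (40 mg protein per g
    liver) times the individual's liver mass, returning µmol/h in vivo.
    """
    if vmax_invitro < 0 or liver_mass_g < 0:
        raise ValueError("vmax and liver mass must be non-negative")
    return vmax_invitro * MICROSOMAL_PROTEIN_MG_PER_G_LIVER * liver_mass_g


def scale_clint(clint_ul_min_mcells: float, liver_mass_g: float) -> float:
    """Scale intrinsic clearance from µL/min/10^6 hepatocytes to whole-liver L/h."""
    if clint_ul_min_mcells < 0 or liver_mass_g < 0:
        raise ValueError("clint and liver mass must be non-negative")
    ul_per_min = clint_ul_min_mcells * HEPATOCELLULARITY_MCELLS_PER_G_LIVER * liver_mass_g
    return ul_per_min * 60.0 / 1e6  # µL/min -> L/h


def absorption_rate_from_permeability(
    peff_cm_s: float | None = None,
    log_peff: float | None = None,
    radius_cm: float = SMALL_INTESTINE_RADIUS_CM,
) -> float:
    """First-order oral absorption rate ka (1/h) from effective jejunal permeability.

    Treats the small intestine as a cylinder of radius R: ka = 2·Peff/R,
    converted from 1/s to 1/h.  Accepts either Peff (cm/s) or log10(Peff).
    """
    if (peff_cm_s is None) == (log_peff is None):
        raise ValueError("provide exactly one of peff_cm_s or log_peff")
    if peff_cm_s is None:
        peff_cm_s = 10.0 ** log_peff
    if peff_cm_s < 0:
        raise ValueError("Peff must be non-negative")
    if radius_cm <= 0:
        raise ValueError("intestinal radius must be positive")
    return 2.0 * peff_cm_s * 3600.0 / radius_cm


#: Default tissue composition (volume fractions of neutral lipid and water).
#: Values are standard human tissue-composition figures; overridable per call.
DEFAULT_TISSUE_COMPOSITION: dict[str, dict[str, float]] = {
    "gut":     {"lipid": 0.049, "water": 0.718},
    "liver":   {"lipid": 0.049, "water": 0.642},
    "kidney":  {"lipid": 0.021, "water": 0.783},
    "lung":    {"lipid": 0.013, "water": 0.811},
    "rest":    {"lipid": 0.070, "water": 0.650},
    "heart":   {"lipid": 0.025, "water": 0.758},
    "brain":   {"lipid": 0.051, "water": 0.770},
    "skin":    {"lipid": 0.028, "water": 0.718},
    "adipose": {"lipid": 0.853, "water": 0.141},
    "muscle":  {"lipid": 0.022, "water": 0.760},
    "bone":    {"lipid": 0.017, "water": 0.430},
    "marrow":  {"lipid": 0.640, "water": 0.315},
}


def tissue_partition_coefficients(
    chemical: ChemicalParameterSet,
    tissue_composition: dict[str, dict[str, float]] | None = None,
    exponent: float = 1.0,
    overrides: dict[str, float] | None = None,
) -> dict[str, float]:
    """Tissue:blood partition coefficients from a lipid/water partitioning rule.

    Kp(t) = (f_lipid,t · Kow^a + f_water,t) / (f_lipid,blood · Kow^a + f_water,blood)

    with a = ``exponent`` (default 1) and blood composition 0.7 % lipid.
    The hydrophilic limit (Kow → 0) tends to the tissue/blood water ratio;
    Kp grows monotonically with Kow in lipid-rich tissues.  User ``overrides``
    are returned verbatim for the named tissues.
    """
    comp = tissue_composition if tissue_composition is not None else DEFAULT_TISSUE_COMPOSITION
    for tissue, fracs in comp.items():
        for key in ("lipid", "water"):
            if not 0.0 <= fracs[key] <= 1.0:
                raise ValueError(f"{tissue} {key} fraction outside [0, 1]")
    kow_a = (10.0 ** chemical.log_kow) ** exponent
    denom = BLOOD_LIPID_FRACTION * kow_a + BLOOD_WATER_FRACTION
    kps = {
        tissue: (fracs["lipid"] * kow_a + fracs["water"]) / denom
        for tissue, fracs in comp.items()
    }
    if overrides:
        unknown = set(overrides) - set(comp)
        if unknown:
            raise ValueError(f"unknown tissue name(s) in overrides: {sorted(unknown)}")
        kps.update(overrides)
    return kps


def hepatic_clearance_well_stirred(
    clint_scaled_lh: float, fub: float, liver_blood_flow_lh: float, rb2p: float = 1.0
) -> float:
    """Well-stirred hepatic clearance (L/h, referenced to plasma concentration).

    CLh = Q·(fub/Rb2p)·CLint / (Q + (fub/Rb2p)·CLint).  The unbound fraction is
    taken relative to whole blood via Rb2p, converted for use with plasma
    concentrations.  Bounded above by the liver blood flow Q.
    """
    if min(clint_scaled_lh, fub) < 0 or rb2p <= 0:
        raise ValueError("inputs must be non-negative with rb2p > 0")
    if liver_blood_flow_lh <= 0:
        raise ValueError("liver blood flow must be positive")
    fu_clint = (fub / rb2p) * clint_scaled_lh
    return liver_blood_flow_lh * fu_clint / (liver_blood_flow_lh + fu_clint)


def metabolite_molar_to_mass(conc_umol_l: float, parent_mw: float) -> float:
    """Convert µmol/L to ng/mL using the parent compound's molecular weight.

    Metabolite amounts are carried in parent-equivalent moles, so reported
    mass concentrations use the parent MW: µmol/L × g/mol = µg/L = ng/mL.
    """
    if conc_umol_l < 0 or parent_mw < 0:
        raise ValueError("inputs must be non-negative")
    return conc_umol_l * parent_mw


def load_chemicals(path: str | Path) -> dict[str, ChemicalParameterSet]:
    """Load a YAML file of chemical parameter sets, keyed by chemical name."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "chemicals" not in raw:
        raise ValueError(f"{path}: expected a top-level 'chemicals' mapping")
    out: dict[str, ChemicalParameterSet] = {}
    for name, fields in raw["chemicals"].items():
        out[name] = ChemicalParameterSet(name=name, **fields)
    return out


def demo_chemicals() -> dict[str, ChemicalParameterSet]:
    """The bundled demo set: nine phenols/parabens/phthalates with TDI/RfD values."""
    return load_chemicals(Path(__file__).parent / "data" / "chemicals_demo.yaml")
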