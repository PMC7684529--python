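"""Virtual populations: physiology sampling, sample-size rules and cohort matching.

Individuals are drawn from documented parametric distributions (lognormal BMI
and normal height per stratum) rather than survey microdata; organ volumes and
blood flows are scaled allometrically from body weight so that flows always
sum to cardiac output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .chem_params import ChemicalParameterSet

ADULT_FEMALE_DAILY_URINE_ML = 1600.0
CHILD_DAILY_URINE_ML = 820.0

#: Systemic blood-flow fractions (of cardiac output) for the linear 7-compartment
#: structure; the lung receives the full cardiac output in series.
LINEAR7_FLOW_FRACTIONS = {"gut": 0.15, "liver": 0.065, "kidney": 0.19, "rest": 0.595}

#: Tissue volumes as fractions of body weight (density ~1 kg/L assumed).
LINEAR7_VOLUME_FRACTIONS = {
    "gut": 0.017, "liver": 0.026, "kidney": 0.004, "lung": 0.008,
    "rest": 0.80, "arterial_blood": 0.02, "venous_blood": 0.045,
}

METABOLITE11_FLOW_FRACTIONS = {
    "heart": 0.04, "brain": 0.12, "skin": 0.058, "adipose": 0.05,
    "muscle": 0.237, "bone": 0.042, "marrow": 0.03, "gut": 0.15,
    "liver": 0.083, "kidney": 0.19,
}

METABOLITE11_VOLUME_FRACTIONS = {
    "lung": 0.008, "heart": 0.005, "brain": 0.02, "skin": 0.037,
    "adipose": 0.21, "muscle": 0.40, "bone": 0.07, "marrow": 0.04,
    "gut": 0.017, "liver": 0.026, "kidney": 0.004, "blood": 0.065,
}


class Stratum(str, Enum):
    ADULT_FEMALE = "ADULT_FEMALE"
    CHILD = "CHILD"


class AgeGroup(str, Enum):
    ADULT = "ADULT"
    CHILD = "CHILD"


class BmiCategory(str, Enum):
    UNDERWEIGHT = "underweight"
    NORMAL = "normal"
    OVERWEIGHT = "overweight"
    OBESE = "obese"


def yamane_sample_size(population: float, error_tolerance: float) -> int:
    """Yamane sample size n = N / (1 + N·e²), rounded to the nearest integer.

    Bounded above by N and by the asymptote 1/e² as N grows; used to size
    Monte-Carlo virtual populations against a real population count.
    """
    if population < 1:
        raise ValueError("population must be >= 1")
    if not 0.0 < error_tolerance < 1.0:
        raise ValueError("error tolerance must be in (0, 1)")
    n = population / (1.0 + population * error_tolerance**2)
    return min(int(round(n)), int(population))


def bmi_category(bmi: float, group: AgeGroup) -> BmiCategory:
    """Categorise BMI (kg/m²) for adults and for children aged 6–11.

    Adults: < 18.5 underweight, < 25 normal, [25, 30) overweight, ≥ 30 obese.
    Children (age/sex-independent screening bands): < 14 underweight,
    < 22 normal, [22, 25) overweight, ≥ 25 obese.
    """
    if bmi <= 0:
        raise ValueError("BMI must be positive")
    group = AgeGroup(group)
    if group is AgeGroup.ADULT:
        if bmi < 18.5:
            return BmiCategory.UNDERWEIGHT
        if bmi < 25.0:
            return BmiCategory.NORMAL
        if bmi < 30.0:
            return BmiCategory.OVERWEIGHT
        return BmiCategory.OBESE
    if bmi < 14.0:
        return BmiCategory.UNDERWEIGHT
    if bmi < 22.0:
        return BmiCategory.NORMAL
    if bmi < 25.0:
        return BmiCategory.OVERWEIGHT
    return BmiCategory.OBESE


@dataclass
class PhysiologyParameterSet:
    """One virtual individual: anthropometry, organ volumes/flows, renal function."""

    id: str
    sex: str
    age_years: float
    bw_kg: float
    height_cm: float
    organ_volumes_l: dict[str, float] = field(default_factory=dict)
    blood_flows_lh: dict[str, float] = field(default_factory=dict)
    cardiac_output_lh: float = 0.0
    gfr_lh: float = 0.0
    liver_mass_g: float = 0.0
    daily_urine_volume_ml: float = ADULT_FEMALE_DAILY_URINE_ML
    clearance_multiplier: float = 1.0

    @property
    def bmi(self) -> float:
        return self.bw_kg / (self.height_cm / 100.0) ** 2

    def __post_init__(self) -> None:
        if self.bw_kg <= 0 or self.height_cm <= 0:
            raise ValueError("body weight and height must be positive")
        if self.gfr_lh < 0 or self.daily_urine_volume_ml <= 0:
            raise ValueError("GFR must be >= 0 and urine volume > 0")
        for name, v in {**self.organ_volumes_l, **self.blood_flows_lh}.items():
            if v < 0:
                raise ValueError(f"negative physiology value for {name}")


class PopulationSpec(BaseModel):
    """Specification of a virtual population to generate."""

    n: int = Field(ge=1)
    stratum: Stratum = Stratum.ADULT_FEMALE
    sex_mix: dict[str, float] = Field(default_factory=lambda: {"F": 1.0})
    age_range: tuple[float, float] = (32.0, 56.0)
    weight_categories: Optional[list[BmiCategory]] = None
    kidney_function: str = "normal"
    poor_metaboliser: bool = False
    ethnicity: Optional[str] = None  # recorded for provenance; no physiological effect
    urine_volume_cv: float = Field(default=0.0, ge=0.0)
    clearance_gsd: float = Field(default=1.3, ge=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "PopulationSpec":
        lo, hi = self.age_range
        if hi < lo:
            raise ValueError("age range is empty")
        if abs(sum(self.sex_mix.values()) - 1.0) > 1e-9:
            raise ValueError("sex mix must sum to 1")
        return self


# Stratum-level anthropometry: height ~ Normal(mean, sd) cm, BMI ~ Lognormal(GM, GSD).
_ANTHROPOMETRY = {
    Stratum.ADULT_FEMALE: {"height_mean": 164.0, "height_sd": 6.5, "bmi_gm": 24.5, "bmi_gsd": 1.18},
    Stratum.CHILD: {"height_mean": 131.0, "height_sd": 10.0, "bmi_gm": 16.8, "bmi_gsd": 1.13},
}


def _allometric(individual_bw: float, reference_bw: float, reference: float, power: float) -> float:
    return reference * (individual_bw / reference_bw) ** power


def _build_individual(
    ident: str,
    sex: str,
    age: float,
    bw: float,
    height: float,
    stratum: Stratum,
    urine_ml: float,
    clearance_multiplier: float,
) -> PhysiologyParameterSet:
    # Cardiac output and GFR scale with BW^0.75 from a 70-kg adult reference
    # (CO 347 L/h ~ 5.8 L/min; GFR 6.7 L/h ~ 110 mL/min).
    co = _allometric(bw, 70.0, 347.0, 0.75)
    gfr = _allometric(bw, 70.0, 6.7, 0.75)
    volumes = {t: f * bw for t, f in LINEAR7_VOLUME_FRACTIONS.items()}
    volumes.update({t: f * bw for t, f in METABOLITE11_VOLUME_FRACTIONS.items()})
    flows = {t: f * co for t, f in LINEAR7_FLOW_FRACTIONS.items()}
    return PhysiologyParameterSet(
        id=ident,
        sex=sex,
        age_years=age,
        bw_kg=bw,
        height_cm=height,
        organ_volumes_l=volumes,
        blood_flows_lh=flows,
        cardiac_output_lh=co,
        gfr_lh=gfr,
        liver_mass_g=volumes["liver"] * 1000.0,  # density ~1 g/mL
        daily_urine_volume_ml=urine_ml,
        clearance_multiplier=clearance_multiplier,
    )


def generate_population(spec: PopulationSpec) -> list[PhysiologyParameterSet]:
    """Sample ``spec.n`` virtual individuals, reproducibly under ``spec.seed``.

    Ages are uniform on the range; BMI is lognormal and height normal per
    stratum, with rejection sampling when ``weight_categories`` restricts the
    admissible BMI bands.  Daily urine volume defaults to 1600 mL (adult
    female) / 820 mL (child), optionally with lognormal variability.
    """
    rng = np.random.default_rng(spec.seed)
    anthro = _ANTHROPOMETRY[spec.stratum]
    group = AgeGroup.ADULT if spec.stratum is Stratum.ADULT_FEMALE else AgeGroup.CHILD
    base_urine = (
        ADULT_FEMALE_DAILY_URINE_ML if spec.stratum is Stratum.ADULT_FEMALE else CHILD_DAILY_URINE_ML
    )
    allowed = set(spec.weight_categories) if spec.weight_categories else None
    sexes = list(spec.sex_mix)
    sex_p = np.array([spec.sex_mix[s] for s in sexes])

    out: list[PhysiologyParameterSet] = []
    max_draws = 1000 * spec.n + 1000
    draws = 0
    while len(out) < spec.n:
        draws += 1
        if draws > max_draws:
            raise ValueError(
                f"could not realise weight categories {sorted(c.value for c in allowed)} "
                f"for stratum {spec.stratum.value} (infeasible spec?)"
            )
        age = rng.uniform(*spec.age_range)
        height = rng.normal(anthro["height_mean"], anthro["height_sd"])
        bmi = math.exp(rng.normal(math.log(anthro["bmi_gm"]), math.log(anthro["bmi_gsd"])))
        if height <= 0:
            continue
        if allowed is not None and bmi_category(bmi, group) not in allowed:
            continue
        bw = bmi * (height / 100.0) ** 2
        urine = base_urine
        if spec.urine_volume_cv > 0:
            sigma = math.sqrt(math.log(1.0 + spec.urine_volume_cv**2))
            urine = base_urine * math.exp(rng.normal(-0.5 * sigma**2, sigma))
        mult = math.exp(rng.normal(0.0, math.log(spec.clearance_gsd)))
        sex = str(rng.choice(sexes, p=sex_p))
        out.append(
            _build_individual(
                f"{spec.stratum.value.lower()}-{len(out):05d}", sex, age, bw, height,
                spec.stratum, urine, mult,
            )
        )
    return out


def individual_chemical_params(
    individual: PhysiologyParameterSet,
    chemical: ChemicalParameterSet,
    poor_metaboliser: bool = False,
    poor_metaboliser_quantile: float = 0.05,
    clearance_gsd: float = 1.3,
) -> ChemicalParameterSet:
    """Merge population-level chemical parameters with one individual's variability.

    The individual's clearance multiplier scales CLint (and every Vmax).  With
    ``poor_metaboliser`` the multiplier is replaced by a low quantile (default
    5th) of the population lognormal clearance distribution.
    """
    if poor_metaboliser:
        from scipy.stats import norm

        mult = math.exp(norm.ppf(poor_metaboliser_quantile) * math.log(clearance_gsd))
    else:
        mult = individual.clearance_multiplier
    updates: dict = {}
    if chemical.clint is not None:
        updates["clint"] = chemical.clint * mult
    if chemical.metabolic_steps:
        updates["metabolic_steps"] = [
            step.model_copy(update={"vmax_invitro": step.vmax_invitro * mult})
            for step in chemical.metabolic_steps
        ]
    return chemical.model_copy(update=updates)


def resample_to_match(
    population: Sequence[PhysiologyParameterSet],
    targets: dict[str, float],
    k: int,
    seed: int = 0,
    tolerance: float = 0.10,
    max_attempts: int = 10_000,
) -> list[PhysiologyParameterSet]:
    """Randomly select ``k`` individuals whose BW summary matches cohort targets.

    ``targets`` maps any of {"min", "max", "median", "mean"} to body-weight
    values (kg); a draw is accepted when every given statistic deviates
    relatively by less than ``tolerance``.  Raises LookupError (explicit
    NOT_FOUND) after ``max_attempts`` rejected draws.
    """
    if k > len(population):
        raise ValueError("k exceeds population size")
    known = {"min": np.min, "max": np.max, "median": np.median, "mean": np.mean}
    unknown = set(targets) - set(known)
    if unknown:
        raise ValueError(f"unknown target statistic(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    bws = np.array([ind.bw_kg for ind in population])
    for _ in range(max_attempts):
        idx = rng.choice(len(population), size=k, replace=False)
        sample = bws[idx]
        ok = all(
            abs(known[stat](sample) - value) <= tolerance * abs(value)
            for stat, value in targets.items()
        )
        if ok:
            return [population[i] for i in idx]
    raise LookupError(
        f"NOT_FOUND: no subset of size {k} matched BW targets {targets} "
        f"within {tolerance:.0%} after {max_attempts} attempts"
    )
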