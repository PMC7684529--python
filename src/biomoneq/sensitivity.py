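"""One-at-a-time (OAT) sensitivity of the dosimetry pipeline to its inputs.

Each parameter is perturbed by ±10 % around its baseline and the model output
(by default the steady-state urinary concentration) re-computed.  The
normalised sensitivity coefficient is the elasticity — the central difference
of ln(output) against ln(input) — which is exact for power-law pathways:
+1 for the dose in the linear mode, −1 for the daily urine volume, 0 for
parameters with no pathway to the urinary output.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

from .chem_params import ChemicalParameterSet
from .pbk_core import ModelMode, NOT_REACHED
from .dosimetry import steady_state_urinary_concentration
from .population import PhysiologyParameterSet


@dataclass
class SensitivityRecord:
    """Result of perturbing one parameter by ±delta."""

    parameter: str
    delta: float
    baseline_output: float
    output_up: float
    output_down: float
    coefficient: float  # Δln(output)/Δln(input), central difference
    error: Optional[str] = None


@dataclass
class _Scenario:
    chemical: ChemicalParameterSet
    individual: PhysiologyParameterSet
    dose_mg_kg_day: float
    mode: ModelMode


def _apply(scenario: _Scenario, parameter: str, factor: float) -> _Scenario:
    """Return a scenario with one named parameter scaled by ``factor``."""
    chem = scenario.chemical
    ind = copy.deepcopy(scenario.individual)
    dose = scenario.dose_mg_kg_day
    if parameter == "dose":
        dose *= factor
    elif parameter == "daily_urine_volume":
        ind.daily_urine_volume_ml *= factor
    elif parameter == "clint":
        if chem.clint is None:
            raise ValueError("chemical has no clint")
        chem = chem.model_copy(update={"clint": chem.clint * factor})
    elif parameter == "fub":
        chem = chem.model_copy(update={"fub": min(chem.fub * factor, 1.0)})
    elif parameter == "ka":
        chem = chem.model_copy(update={"ka": chem.ka * factor})
    elif parameter == "gfr":
        ind.gfr_lh *= factor
    elif parameter == "body_weight":
        ind.bw_kg *= factor
    elif parameter == "cardiac_output":
        ind.cardiac_output_lh *= factor
    elif parameter == "liver_mass":
        # metabolic capacity (CLint/Vmax scaling), distinct from the liver's
        # distribution volume below
        ind.liver_mass_g *= factor
    elif parameter.endswith("_volume"):
        organ = parameter[: -len("_volume")]
        if organ not in ind.organ_volumes_l:
            raise ValueError(f"unknown organ {organ!r}")
        ind.organ_volumes_l[organ] *= factor
    else:
        raise ValueError(f"unknown parameter {parameter!r}")
    if ind.bw_kg <= 0 or ind.daily_urine_volume_ml <= 0:
        raise ValueError(f"perturbing {parameter} produced invalid physiology")
    return _Scenario(chem, ind, dose, scenario.mode)


def _default_output(scenario: _Scenario) -> float:
    # tight plateau tolerance: coefficients should reflect the asymptotic
    # steady state, not the speed of approach to it
    conc = steady_state_urinary_concentration(
        scenario.chemical,
        scenario.individual,
        scenario.dose_mg_kg_day,
        mode=scenario.mode,
        rel_tol=1e-5,
    )
    if conc is NOT_REACHED:
        raise RuntimeError("steady state not reached in sensitivity run")
    return conc


DEFAULT_PARAMETERS = (
    "dose", "daily_urine_volume", "clint", "fub", "ka", "gfr",
    "body_weight", "liver_volume", "kidney_volume", "rest_volume",
)


def oat_sensitivity(
    chemical: ChemicalParameterSet,
    individual: PhysiologyParameterSet,
    dose_mg_kg_day: float,
    parameters: Sequence[str] = DEFAULT_PARAMETERS,
    delta: float = 0.10,
    mode: ModelMode | str = ModelMode.LINEAR7,
    output: Optional[Callable[[_Scenario], float]] = None,
) -> list[SensitivityRecord]:
    """±delta one-at-a-time perturbations, sorted by |coefficient| descending.

    Parameters whose perturbation produces invalid physiology are reported
    per-parameter in the record's ``error`` field rather than aborting the
    scan.
    """
    if not 0.0 < delta < 1.0:
        raise ValueError("delta must be a fraction in (0, 1)")
    scenario = _Scenario(chemical, individual, dose_mg_kg_day, ModelMode(mode))
    out_fn = output if output is not None else _default_output
    baseline = out_fn(scenario)
    if baseline <= 0:
        raise ValueError("baseline output must be positive for normalised coefficients")
    records: list[SensitivityRecord] = []
    for param in parameters:
        try:
            up = out_fn(_apply(scenario, param, 1.0 + delta))
            down = out_fn(_apply(scenario, param, 1.0 - delta))
            if up > 0 and down > 0:
                coeff = (math.log(up) - math.log(down)) / (
                    math.log(1.0 + delta) - math.log(1.0 - delta)
                )
            else:  # output vanished on one side: fall back to a linear slope
                coeff = (up - down) / (2.0 * delta * baseline)
            records.append(
                SensitivityRecord(param, delta, baseline, up, down, coeff)
            )
        except (ValueError, RuntimeError) as exc:
            records.append(
                SensitivityRecord(
                    param, delta, baseline, math.nan, math.nan, math.nan, error=str(exc)
                )
            )
    records.sort(key=lambda r: (math.isnan(r.coefficient), -abs(r.coefficient)))
    return records


def sensitivity_table(records: Sequence[SensitivityRecord]):
    """Records as a DataFrame ready for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "delta": r.delta,
                "baseline_ngml": r.baseline_output,
                "output_up_ngml": r.output_up,
                "output_down_ngml": r.output_down,
                "coefficient": r.coefficient,
                "error": r.error or "",
            }
            for r in records
        ]
    )
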