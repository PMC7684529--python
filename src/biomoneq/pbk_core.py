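"""Perfusion-limited compartmental PBK models and their simulation.

Two structures are supported:

* ``LINEAR7`` — a linear seven-compartment whole-body model (gut lumen, gut,
  liver, kidney, lung, rest-of-body, arterial and venous blood) with
  well-stirred hepatic clearance from scaled intrinsic clearance and renal
  filtration GFR·fub·C_plasma into a cumulative renal-tubule accumulator.
  The system is linear time-invariant between boluses, so it is propagated
  exactly by a matrix exponential: mass conservation and dose-linearity hold
  to machine precision.

* ``METABOLITE11`` — an eleven-tissue model with a single blood pool, saturable
  (Michaelis–Menten) hepatic conversion of a parent into one or more metabolite
  species that themselves distribute through the body, primary-urine formation
  at 8 % of the renal arterial blood flow, and no tubular resorption for very
  soluble substances (log Kow < −1.5).  Integrated with a stiff BDF solver
  (rtol 1e-8, atol 1e-12 µmol).

Internal units: amounts µmol, time h, volumes L.  Metabolite amounts are
carried in parent-equivalent moles; conversion to ng/mL uses the parent
molecular weight at the output boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .chem_params import (
    ChemicalParameterSet,
    scale_clint,
    scale_vmax_ivive,
    tissue_partition_coefficients,
)
from .population import (
    LINEAR7_FLOW_FRACTIONS,
    LINEAR7_VOLUME_FRACTIONS,
    METABOLITE11_FLOW_FRACTIONS,
    METABOLITE11_VOLUME_FRACTIONS,
    PhysiologyParameterSet,
)

#: Fraction of renal arterial blood flow turned into primary urine
#: (metabolite-chain mode).
PRIMARY_URINE_FRACTION = 0.08

#: log Kow below which tubular resorption is disabled (very soluble substances).
RESORPTION_LOGKOW_CUTOFF = -1.5

#: Hard cap on the daily-dosing horizon used when searching for steady state.
MAX_STEADY_STATE_DAYS = 200

NOT_REACHED = None

_LINEAR7_TISSUES = ("gut", "liver", "kidney", "lung", "rest")
_LINEAR7_COMPARTMENTS = (
    "gut_lumen", "gut", "liver", "kidney", "lung", "rest",
    "arterial_blood", "venous_blood",
)
_METABOLITE11_TISSUES = (
    "lung", "heart", "brain", "skin", "adipose", "muscle",
    "bone", "marrow", "gut", "liver", "kidney",
)
_METABOLITE11_COMPARTMENTS = ("gut_lumen",) + _METABOLITE11_TISSUES + ("blood",)


class MissingParameterError(ValueError):
    """A chemical parameter required by the chosen model mode is absent."""


class InconsistentModeError(ValueError):
    """The chemical's parameters do not fit the requested model structure."""


class SolverError(RuntimeError):
    """Integration failed or produced a materially negative state."""


class ModelMode(str, Enum):
    LINEAR7 = "LINEAR7"
    METABOLITE11 = "METABOLITE11"


class Route(str, Enum):
    ORAL = "ORAL"


class Schedule(str, Enum):
    SINGLE_BOLUS = "SINGLE_BOLUS"
    DAILY_BOLUS = "DAILY_BOLUS"


@dataclass(frozen=True)
class DosingRegimen:
    """Oral dosing: ``dose`` in mg per kg body weight per day."""

    dose: float
    schedule: Schedule = Schedule.DAILY_BOLUS
    duration_h: float = 24.0
    route: Route = Route.ORAL

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if self.duration_h <= 0:
            raise ValueError("duration must be positive")


@dataclass
class ModelStructure:
    """Compartment layout with flow/volume fractions.

    ``flows`` are fractions of cardiac output over the systemically perfused
    tissues (the lung, in series, carries the full cardiac output) and must
    sum to 1; ``volumes`` are fractions of body weight and must sum to ≤ 1.
    """

    mode: ModelMode
    compartments: tuple[str, ...]
    flows: dict[str, float]
    volumes: dict[str, float]

    def __post_init__(self) -> None:
        self.mode = ModelMode(self.mode)
        flow_sum = sum(self.flows.values())
        if abs(flow_sum - 1.0) > 1e-9:
            raise ValueError(f"perfused flow fractions sum to {flow_sum}, expected 1")
        if sum(self.volumes.values()) > 1.0 + 1e-9:
            raise ValueError("volume fractions exceed body weight")
        required = (
            set(_LINEAR7_COMPARTMENTS)
            if self.mode is ModelMode.LINEAR7
            else set(_METABOLITE11_COMPARTMENTS)
        )
        if set(self.compartments) != required:
            raise ValueError(
                f"{self.mode.value} structure must contain exactly {sorted(required)}"
            )

    @classmethod
    def linear7(cls) -> "ModelStructure":
        return cls(
            mode=ModelMode.LINEAR7,
            compartments=_LINEAR7_COMPARTMENTS,
            flows=dict(LINEAR7_FLOW_FRACTIONS),
            volumes=dict(LINEAR7_VOLUME_FRACTIONS),
        )

    @classmethod
    def metabolite11(cls) -> "ModelStructure":
        return cls(
            mode=ModelMode.METABOLITE11,
            compartments=_METABOLITE11_COMPARTMENTS,
            flows=dict(METABOLITE11_FLOW_FRACTIONS),
            volumes=dict(METABOLITE11_VOLUME_FRACTIONS),
        )

    @classmethod
    def for_mode(cls, mode: ModelMode | str) -> "ModelStructure":
        mode = ModelMode(mode)
        return cls.linear7() if mode is ModelMode.LINEAR7 else cls.metabolite11()


@dataclass
class SimulationResult:
    """Time grid plus per-species compartment trajectories (µmol).

    ``tubule_umol`` holds the cumulative renal-tubule (urinary) amount per
    species; ``absorbed_umol`` the administered-to-date amount.  Bookkeeping
    accumulators (e.g. the hepatic ``metabolized`` sink of the linear mode)
    appear among the compartments so the mass balance closes exactly.
    """

    time_h: np.ndarray
    amounts: dict[str, dict[str, np.ndarray]]
    tubule_umol: dict[str, np.ndarray]
    absorbed_umol: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("time grid must be strictly increasing")
        n = len(self.time_h)
        for species, comps in self.amounts.items():
            for comp, traj in comps.items():
                if len(traj) != n:
                    raise ValueError(f"{species}/{comp}: trajectory length mismatch")

    def total_umol(self) -> np.ndarray:
        """Parent-equivalent moles in the whole system (compartments + urine)."""
        total = np.zeros_like(self.time_h, dtype=float)
        for comps in self.amounts.values():
            for traj in comps.values():
                total = total + traj
        for traj in self.tubule_umol.values():
            total = total + traj
        return total

    def to_dataframe(self):
        """Tidy long-format table: time_h, species, compartment, amount_umol."""
        import pandas as pd

        rows = []
        for species, comps in self.amounts.items():
            for comp, traj in comps.items():
                rows.append(
                    pd.DataFrame(
                        {"time_h": self.time_h, "species": species,
                         "compartment": comp, "amount_umol": traj}
                    )
                )
        for species, traj in self.tubule_umol.items():
            rows.append(
                pd.DataFrame(
                    {"time_h": self.time_h, "species": species,
                     "compartment": "renal_tubule", "amount_umol": traj}
                )
            )
        return pd.concat(rows, ignore_index=True)

    def summary(self) -> dict:
        """JSON-ready summary: peak blood amount, daily excreted amounts."""
        daily = daily_excreted_amounts(self)
        blood_keys = [k for k in next(iter(self.amounts.values())) if "blood" in k]
        peak = 0.0
        for comps in self.amounts.values():
            for key in blood_keys:
                peak = max(peak, float(np.max(comps[key])))
        return {
            "duration_h": float(self.time_h[-1]),
            "peak_blood_amount_umol": peak,
            "daily_excreted_umol": [float(x) for x in daily],
            "steady_state_day": detect_steady_state(self) if len(daily) >= 2 else None,
        }


def _dose_umol(dose_mg_per_kg: float, bw_kg: float, mw: float, fabs: float) -> float:
    # mg -> µmol: mg / (g/mol) * 1000
    return dose_mg_per_kg * bw_kg * fabs / mw * 1000.0


def _check_negative(y: np.ndarray, scale: float) -> np.ndarray:
    floor = -1e-9 * max(scale, 1.0)
    if np.min(y) < floor:
        raise SolverError(f"negative state detected (min {np.min(y):.3e} µmol)")
    return np.clip(y, 0.0, None)


class LinearPBKModel:
    """A linear PBK system dA/dt = M·A propagated exactly via expm.

    ``state_names`` maps indices to labels; ``tubule_states`` names the
    cumulative urinary accumulator per species.  The generator matrix has
    zero column sums, so total mass (states + sinks) is conserved exactly.
    """

    mode = ModelMode.LINEAR7

    def __init__(
        self,
        state_names: Sequence[str],
        matrix: np.ndarray,
        dose_state: int,
        tubule_states: dict[str, int],
        chemical: ChemicalParameterSet,
        individual: PhysiologyParameterSet,
        sink_states: tuple[int, ...] = (),
    ) -> None:
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (len(state_names), len(state_names)):
            raise ValueError("matrix shape does not match state names")
        colsums = matrix.sum(axis=0)
        if np.max(np.abs(colsums)) > 1e-9 * max(1.0, np.max(np.abs(matrix))):
            raise ValueError("generator matrix columns must sum to zero (mass leak)")
        self.state_names = list(state_names)
        self.matrix = matrix
        self.dose_state = dose_state
        self.tubule_states = dict(tubule_states)
        self.chemical = chemical
        self.individual = individual
        self.sink_states = sink_states

    def simulate(self, regimen: DosingRegimen, duration_h: float | None = None,
                 output_step_h: float = 1.0) -> SimulationResult:
        duration = float(duration_h if duration_h is not None else regimen.duration_h)
        if not duration >= output_step_h > 0:
            raise ValueError("require duration >= output_step > 0")
        if regimen.schedule is Schedule.DAILY_BOLUS and abs(
            24.0 / output_step_h - round(24.0 / output_step_h)
        ) > 1e-9:
            raise ValueError("output step must divide 24 h for daily dosing")
        n_steps = int(np.ceil(duration / output_step_h - 1e-9))
        times = np.arange(n_steps + 1) * output_step_h
        dose = _dose_umol(
            regimen.dose, self.individual.bw_kg, self.chemical.mw, self.chemical.fabs
        )
        steps_per_day = int(round(24.0 / output_step_h))
        propagator = expm(self.matrix * output_step_h)

        n = len(self.state_names)
        traj = np.zeros((n_steps + 1, n))
        absorbed = np.zeros(n_steps + 1)
        y = np.zeros(n)
        given = 0.0
        for k in range(n_steps + 1):
            if k > 0:
                y = propagator @ y
            dosing_now = (k == 0) or (
                regimen.schedule is Schedule.DAILY_BOLUS and k % steps_per_day == 0
            )
            if dosing_now:
                y[self.dose_state] += dose
                given += dose
            y = _check_negative(y, given)
            traj[k] = y
            absorbed[k] = given

        species = self.chemical.name
        comp_amounts = {
            name: traj[:, i]
            for i, name in enumerate(self.state_names)
            if i not in self.tubule_states.values()
        }
        return SimulationResult(
            time_h=times,
            amounts={species: comp_amounts},
            tubule_umol={species: traj[:, self.tubule_states[species]]},
            absorbed_umol=absorbed,
            diagnostics={"method": "expm", "output_step_h": output_step_h},
        )


def _assemble_linear7(
    chemical: ChemicalParameterSet,
    individual: PhysiologyParameterSet,
    structure: ModelStructure,
) -> LinearPBKModel:
    if chemical.clint is None:
        raise MissingParameterError(
            f"{chemical.name}: 'clint' is required for the LINEAR7 mode"
        )
    states = list(_LINEAR7_COMPARTMENTS) + ["renal_tubule", "metabolized"]
    idx = {name: i for i, name in enumerate(states)}
    n = len(states)
    M = np.zeros((n, n))

    co = individual.cardiac_output_lh
    flows = {t: structure.flows[t] * co for t in structure.flows}
    vols = {
        c: individual.organ_volumes_l.get(c, structure.volumes[c] * individual.bw_kg)
        for c in _LINEAR7_COMPARTMENTS
        if c != "gut_lumen"
    }
    kp = tissue_partition_coefficients(chemical)
    kp.update({"arterial_blood": 1.0, "venous_blood": 1.0})
    fu_blood = chemical.fub / chemical.rblood2plasma

    def transfer(src: str, dst: str, q: float) -> None:
        # first-order flux q·A_src/(V·Kp) from src into dst
        rate = q / (vols[src] * kp[src])
        M[idx[src], idx[src]] -= rate
        M[idx[dst], idx[src]] += rate

    # oral absorption
    M[idx["gut_lumen"], idx["gut_lumen"]] -= chemical.ka
    M[idx["gut"], idx["gut_lumen"]] += chemical.ka

    # arterial supply to tissues, venous/portal returns
    transfer("arterial_blood", "gut", flows["gut"])
    transfer("arterial_blood", "liver", flows["liver"])
    transfer("arterial_blood", "kidney", flows["kidney"])
    transfer("arterial_blood", "rest", flows["rest"])
    transfer("gut", "liver", flows["gut"])  # portal flow
    transfer("liver", "venous_blood", flows["liver"] + flows["gut"])
    transfer("kidney", "venous_blood", flows["kidney"])
    transfer("rest", "venous_blood", flows["rest"])
    transfer("venous_blood", "lung", co)
    transfer("lung", "arterial_blood", co)

    # hepatic elimination: well-stirred intrinsic clearance on the unbound
    # liver outflow concentration; optional biliary recirculation to gut lumen
    clint_lh = scale_clint(chemical.clint, individual.liver_mass_g)
    elim = clint_lh * fu_blood / (vols["liver"] * kp["liver"])
    f_ehr = chemical.enterohepatic_fraction
    M[idx["liver"], idx["liver"]] -= elim
    M[idx["metabolized"], idx["liver"]] += (1.0 - f_ehr) * elim
    M[idx["gut_lumen"], idx["liver"]] += f_ehr * elim

    # renal filtration of unbound plasma from arterial blood into the tubule
    filt = individual.gfr_lh * fu_blood / vols["arterial_blood"]
    M[idx["arterial_blood"], idx["arterial_blood"]] -= filt
    M[idx["renal_tubule"], idx["arterial_blood"]] += filt

    return LinearPBKModel(
        state_names=states,
        matrix=M,
        dose_state=idx["gut_lumen"],
        tubule_states={chemical.name: idx["renal_tubule"]},
        chemical=chemical,
        individual=individual,
    )


class MetabolitePBKModel:
    """Eleven-tissue model with Michaelis–Menten metabolite chains.

    State layout: for each species (parent first, then metabolites in chain
    order): gut lumen, the 11 tissues, blood, cumulative renal tubule.
    """

    mode = ModelMode.METABOLITE11

    def __init__(
        self,
        chemical: ChemicalParameterSet,
        individual: PhysiologyParameterSet,
        structure: ModelStructure,
    ) -> None:
        self.chemical = chemical
        self.individual = individual
        self.structure = structure
        self.species = chemical.all_species()
        self.species_names = [s.name for s in self.species]
        if len(set(self.species_names)) != len(self.species_names):
            raise InconsistentModeError("duplicate species names in metabolite chain")
        self.compartments = list(_METABOLITE11_COMPARTMENTS)
        self.n_comp = len(self.compartments) + 1  # + renal tubule
        self._c = {name: i for i, name in enumerate(self.compartments)}
        self._s = {name: i for i, name in enumerate(self.species_names)}

        co = individual.cardiac_output_lh
        self.flows = {t: structure.flows[t] * co for t in structure.flows}
        self.flows["lung"] = co
        self.vols = {
            c: individual.organ_volumes_l.get(c, structure.volumes[c] * individual.bw_kg)
            for c in self.compartments
            if c != "gut_lumen"
        }
        self.kp = []
        for sp in self.species:
            kps = tissue_partition_coefficients(sp)
            kps["blood"] = 1.0
            self.kp.append(kps)
        # primary urine formation at 8 % of renal arterial flow; no tubular
        # resorption for very soluble species (log Kow < -1.5)
        self.resorption_fraction = {
            sp.name: (
                0.0
                if sp.log_kow < RESORPTION_LOGKOW_CUTOFF
                else sp.renal_resorption_fraction
            )
            for sp in self.species
        }
        # metabolic steps: (source idx, product idx, Vmax µmol/h, Km µM, f_ehr)
        self.steps: list[tuple[int, int, float, float, float]] = []
        for sp in self.species:
            for step in sp.metabolic_steps:
                self.steps.append(
                    (
                        self._s[sp.name],
                        self._s[step.product.name],
                        scale_vmax_ivive(step.vmax_invitro, individual.liver_mass_g),
                        step.km_um,
                        sp.enterohepatic_fraction,
                    )
                )

    def _index(self, species_i: int, comp: str) -> int:
        if comp == "renal_tubule":
            return species_i * self.n_comp + self.n_comp - 1
        return species_i * self.n_comp + self._c[comp]

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros_like(y)
        v_blood = self.vols["blood"]
        for si, sp in enumerate(self.species):
            off = si * self.n_comp
            kp = self.kp[si]
            fu_blood = sp.fub / sp.rblood2plasma
            c_blood = y[off + self._c["blood"]] / v_blood

            def c_out(comp: str) -> float:
                return y[off + self._c[comp]] / (self.vols[comp] * kp[comp])

            # oral absorption from the gut lumen
            abs_flux = sp.ka * y[off + self._c["gut_lumen"]]
            dy[off + self._c["gut_lumen"]] -= abs_flux
            dy[off + self._c["gut"]] += abs_flux

            blood_net = 0.0
            for tissue in _METABOLITE11_TISSUES:
                if tissue in ("gut", "liver"):
                    continue
                q = self.flows[tissue]
                inflow = q * c_blood
                outflow = q * c_out(tissue)
                dy[off + self._c[tissue]] += inflow - outflow
                blood_net += outflow - inflow
            # splanchnic loop: blood -> gut -> liver -> blood, plus hepatic artery
            q_gut, q_ha = self.flows["gut"], self.flows["liver"]
            dy[off + self._c["gut"]] += q_gut * (c_blood - c_out("gut"))
            dy[off + self._c["liver"]] += (
                q_ha * c_blood + q_gut * c_out("gut") - (q_ha + q_gut) * c_out("liver")
            )
            blood_net += (q_ha + q_gut) * c_out("liver") - (q_gut + q_ha) * c_blood

            # renal filtration into the tubule, net of tubular resorption
            filt = (
                PRIMARY_URINE_FRACTION * self.flows["kidney"] * fu_blood * c_blood
            ) * (1.0 - self.resorption_fraction[sp.name])
            blood_net -= filt
            dy[off + self.n_comp - 1] += filt
            dy[off + self._c["blood"]] += blood_net

        # hepatic Michaelis-Menten conversions (moles conserved across species)
        for src, dst, vmax, km, f_ehr in self.steps:
            sp = self.species[src]
            c_liv_out = y[self._index(src, "liver")] / (
                self.vols["liver"] * self.kp[src]["liver"]
            )
            cu = sp.fub / sp.rblood2plasma * c_liv_out  # unbound plasma, µM
            v = vmax * cu / (km + cu) if cu > 0 else 0.0
            dy[self._index(src, "liver")] -= v
            dy[self._index(dst, "liver")] += (1.0 - f_ehr) * v
            dy[self._index(dst, "gut_lumen")] += f_ehr * v
        return dy

    def simulate(self, regimen: DosingRegimen, duration_h: float | None = None,
                 output_step_h: float = 1.0) -> SimulationResult:
        duration = float(duration_h if duration_h is not None else regimen.duration_h)
        if not duration >= output_step_h > 0:
            raise ValueError("require duration >= output_step > 0")
        n_steps = int(np.ceil(duration / output_step_h - 1e-9))
        times = np.arange(n_steps + 1) * output_step_h
        dose = _dose_umol(
            regimen.dose, self.individual.bw_kg, self.chemical.mw, self.chemical.fabs
        )
        dose_times = (
            [0.0]
            if regimen.schedule is Schedule.SINGLE_BOLUS
            else list(np.arange(0.0, duration, 24.0))
        )

        n = len(self.species) * self.n_comp
        traj = np.zeros((n_steps + 1, n))
        absorbed = np.zeros(n_steps + 1)
        y = np.zeros(n)
        given = 0.0
        gl_parent = self._index(0, "gut_lumen")
        segments = sorted(set(dose_times) | {duration})
        nfev = 0
        k_out = 0
        for seg_start, seg_end in zip([0.0] + segments[:-1], segments):
            if seg_start in dose_times:
                y[gl_parent] += dose
                given += dose
            while k_out <= n_steps and times[k_out] <= seg_start + 1e-9:
                traj[k_out] = y
                absorbed[k_out] = given
                k_out += 1
            if seg_end <= seg_start:
                continue
            t_eval = times[(times > seg_start + 1e-9) & (times < seg_end + 1e-9)]
            sol = solve_ivp(
                self.rhs, (seg_start, seg_end), y, method="BDF",
                rtol=1e-8, atol=1e-12, t_eval=None if len(t_eval) == 0 else t_eval,
                dense_output=False,
            )
            if not sol.success:
                raise SolverError(f"BDF integration failed: {sol.message}")
            nfev += sol.nfev
            for j, tj in enumerate(sol.t):
                if k_out <= n_steps and abs(tj - times[k_out]) < 1e-9:
                    traj[k_out] = _check_negative(sol.y[:, j], given)
                    absorbed[k_out] = given
                    k_out += 1
            # continue from the segment endpoint
            y = _check_negative(sol.y[:, -1], given) if len(sol.t) else y
            if abs(sol.t[-1] - seg_end) > 1e-9:
                sol_end = solve_ivp(
                    self.rhs, (sol.t[-1], seg_end), y, method="BDF",
                    rtol=1e-8, atol=1e-12,
                )
                if not sol_end.success:
                    raise SolverError(f"BDF integration failed: {sol_end.message}")
                y = _check_negative(sol_end.y[:, -1], given)
        if k_out == n_steps:  # final time equals last segment end
            traj[k_out] = y
            absorbed[k_out] = given
            k_out += 1

        amounts: dict[str, dict[str, np.ndarray]] = {}
        tubule: dict[str, np.ndarray] = {}
        for si, name in enumerate(self.species_names):
            amounts[name] = {
                comp: traj[:, self._index(si, comp)] for comp in self.compartments
            }
            tubule[name] = traj[:, self._index(si, "renal_tubule")]
        return SimulationResult(
            time_h=times,
            amounts=amounts,
            tubule_umol=tubule,
            absorbed_umol=absorbed,
            diagnostics={"method": "BDF", "rtol": 1e-8, "atol": 1e-12, "nfev": nfev},
        )


PBKModel = LinearPBKModel | MetabolitePBKModel


def assemble_model(
    chemical: ChemicalParameterSet,
    individual: PhysiologyParameterSet,
    structure: ModelStructure | None = None,
    mode: ModelMode | str = ModelMode.LINEAR7,
) -> PBKModel:
    """Build a PBK model for one chemical and one virtual individual.

    The individual's clearance multiplier must already be folded into the
    chemical parameters (see ``population.individual_chemical_params``); organ
    volumes come from the individual where present, otherwise from the
    structure's body-weight fractions.
    """
    if structure is None:
        structure = ModelStructure.for_mode(mode)
    if individual.cardiac_output_lh <= 0 or individual.gfr_lh < 0:
        raise ValueError("individual must have positive cardiac output and GFR >= 0")
    if structure.mode is ModelMode.LINEAR7:
        return _assemble_linear7(chemical, individual, structure)
    return MetabolitePBKModel(chemical, individual, structure)


def simulate(
    model: PBKModel,
    regimen: DosingRegimen,
    duration_h: float | None = None,
    output_step_h: float = 1.0,
) -> SimulationResult:
    """Run a dosing regimen; non-negative trajectories on a shared time grid."""
    return model.simulate(regimen, duration_h=duration_h, output_step_h=output_step_h)


def mass_balance_residual(result: SimulationResult,
                          regimen: Optional[DosingRegimen] = None) -> float:
    """Max relative gap between administered-to-date and system-wide content.

    All species are counted in parent-equivalent moles (compartments +
    cumulative urinary amount + any bookkeeping sink); the residual is 0
    wherever nothing has been administered.
    """
    total = result.total_umol()
    absorbed = result.absorbed_umol
    mask = absorbed > 0
    if not np.any(mask):
        return 0.0
    return float(np.max(np.abs(absorbed[mask] - total[mask]) / absorbed[mask]))


def steady_state_time_rule(half_life_h: float) -> float:
    """Time to steady state under repeated dosing: five elimination half-lives."""
    if half_life_h < 0:
        raise ValueError("half-life must be non-negative")
    return 5.0 * half_life_h


def daily_excreted_amounts(result: SimulationResult) -> np.ndarray:
    """Per-day urinary (renal-tubule) increments, parent-equivalent µmol."""
    cum = np.zeros_like(result.time_h)
    for traj in result.tubule_umol.values():
        cum = cum + traj
    n_days = int(np.floor(result.time_h[-1] / 24.0 + 1e-9))
    out = np.empty(n_days)
    for d in range(1, n_days + 1):
        i0 = int(np.argmin(np.abs(result.time_h - 24.0 * (d - 1))))
        i1 = int(np.argmin(np.abs(result.time_h - 24.0 * d)))
        out[d - 1] = cum[i1] - cum[i0]
    return out


def detect_steady_state(result: SimulationResult, rel_tol: float = 0.01) -> Optional[int]:
    """First day whose urinary excretion matches the previous day within rel_tol.

    Days are numbered from 1; the earliest possible return is day 2.  Returns
    ``NOT_REACHED`` (None) when no day qualifies — e.g. when the chemical keeps
    accumulating, or when a dosed simulation never excretes anything.
    """
    daily = daily_excreted_amounts(result)
    if len(daily) < 2:
        raise ValueError("steady-state detection needs at least 2 full days")
    dosed = bool(np.any(result.absorbed_umol > 0))
    for d in range(2, len(daily) + 1):
        prev, cur = daily[d - 2], daily[d - 1]
        if prev == 0.0 and cur == 0.0:
            if not dosed:
                return d
            continue  # dosed but nothing excreted: not an informative plateau
        if prev > 0.0 and abs(cur - prev) < rel_tol * prev:
            return d
    return NOT_REACHED


def daily_urine_output(
    result: SimulationResult,
    day: int,
    daily_urine_volume_ml: float,
    mw_basis: float,
) -> float:
    """Urinary concentration (ng/mL) for one 24 h window.

    The parent-equivalent amount excreted into the renal tubule during day
    ``day`` (1-based) is converted to mass with ``mw_basis`` (the parent MW,
    also for glucuronides) and divided by the daily urine volume.
    """
    if daily_urine_volume_ml <= 0:
        raise ValueError("daily urine volume must be positive")
    daily = daily_excreted_amounts(result)
    if not 1 <= day <= len(daily):
        raise ValueError(f"day {day} outside simulated span of {len(daily)} days")
    micrograms = daily[day - 1] * mw_basis  # µmol × g/mol = µg
    return micrograms / daily_urine_volume_ml * 1000.0  # µg/mL -> ng/mL
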