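# Methods

## Model structures

Both PBK structures are perfusion-limited: tissue uptake is limited by blood
flow, with instantaneous tissue–blood equilibrium set by a partition
coefficient K_p. For tissue *t* with volume V_t (L), blood flow Q_t (L/h) and
amount A_t (µmol), the outflowing blood concentration is
C_out,t = A_t / (V_t · K_p,t), and

    dA_t/dt = Q_t · (C_in − C_out,t).

Internal units are µmol, hours and litres throughout; conversion to ng/mL
(µmol/L × g/mol = ng/mL numerically) happens only at the output boundary, and
metabolite amounts are carried in parent-equivalent moles, reported with the
parent molecular weight.

**Linear seven-compartment mode (`LINEAR7`).** Compartments: gut lumen, gut,
liver, kidney, lung, rest-of-body, arterial and venous blood, plus a
cumulative renal-tubule accumulator and a hepatic "metabolized" sink.
Systemic flow fractions (gut 0.15, hepatic artery 0.065, kidney 0.19, rest
0.595 of cardiac output) sum to 1; the lung sits in series carrying the full
cardiac output. Hepatic elimination applies the scaled intrinsic clearance to
the unbound liver-outflow concentration, CL_int·(f_ub/R_b2p)·C_liv,out, which
reproduces the well-stirred clearance CL_h = Q·fu·CL_int/(Q + fu·CL_int) at
steady state; the unbound fraction is referenced to whole blood via the
(constant) blood:plasma ratio and converted for plasma use. Renal input to
the tubule is GFR·f_ub·C_plasma from arterial blood. Metabolism is linear
(non-saturated) in this mode. An optional enterohepatic fraction reroutes
part of the hepatic elimination flux to the gut lumen as biliary output.

**Eleven-tissue metabolite-chain mode (`METABOLITE11`).** Tissues: lung,
heart, brain, skin, adipose, muscle, bone, marrow, gut, liver, kidney, with a
single blood pool, a gut-lumen dosing site and a tubule accumulator per
species. Hepatic conversion of a parent into each metabolite follows
Michaelis–Menten kinetics v = V_max·C_u/(K_m + C_u) on the unbound liver
outflow concentration; products are themselves distributed species with their
own partition coefficients and renal handling, so phthalate monoesters and
glucuronides can be simulated explicitly. Primary urine forms at 8 % of the
renal arterial blood flow (carrying the unbound plasma fraction); a
configurable fraction of the filtrate is resorbed from the tubule, and
resorption is disabled entirely for very soluble species with log K_ow <
−1.5. Urinary excretion being driven by lipophilicity in this way is a
structural assumption of the mode.

## Numerical treatment

Between boluses the linear mode is a linear time-invariant ODE system, so it
is propagated **exactly** by a matrix exponential per output step rather than
by tolerance-based stepping. The generator matrix has zero column sums by
construction (every flux leaves one state and enters another, with explicit
urinary and metabolic sinks), so mass conservation and dose-linearity hold to
machine precision — the conservation suite observes residuals ~1e-13 and the
contract is ≤ 1e-6. The nonlinear metabolite mode uses scipy's implicit BDF
integrator with rtol 1e-8 and atol 1e-12 µmol, restarted at each daily bolus;
observed mass-balance residuals are ~1e-10. States more negative than −1e-9 ×
the administered amount abort the run; smaller excursions are clipped to 0.

Daily dosing applies dose·BW (µmol via the parent MW, times the bioavailable
fraction F_abs) to the gut lumen at 24-h intervals; the administered-to-date
bookkeeping counts the absorbed (F_abs-scaled) dose. Steady state is detected
when a day's urinary excretion matches the previous day's within a relative
tolerance (default 1 %; days numbered from 1, so the earliest detection is
day 2). Simulations extend by doubling up to a hard cap of 200 days;
individuals that never plateau are excluded from BE summaries with a logged
warning and counted, rather than contributing last-day values — a chemical
that keeps accumulating has no defensible steady-state BE. Percentiles use
the inclusive linear-interpolation definition (numpy's default), noted
because percentile dialects differ at small n.

## Parameters

| parameter | unit | default | note |
|---|---|---|---|
| CL_int | µL/min/10⁶ hepatocytes | per chemical | scaled by 110×10⁶ cells/g liver × liver mass |
| V_max (in vitro) | µmol/h/mg microsomal protein | per step | scaled by 40 mg protein/g liver × liver mass |
| K_m | µM | per step | unbound plasma basis |
| k_a | 1/h | per chemical | or from permeability: k_a = 2·P_eff/R, R = 1.75 cm |
| f_ub | – | per chemical | constant; no saturable binding |
| R_blood2plasma | – | 1.0 | constant throughout the body |
| daily urine volume | mL | 1600 (adult female) / 820 (child) | optional lognormal variability |
| steady-state rel. tol. | – | 0.01 | 1e-5 inside the sensitivity module |
| horizon cap | days | 200 | |

Tissue:blood partitioning uses a single documented lipid/water rule,
K_p = (f_lip,t·K_ow^a + f_wat,t)/(f_lip,b·K_ow^a + f_wat,b) with a = 1 and a
blood composition of 0.7 % lipid / 82 % water. It is monotone in K_ow, tends
to the tissue/blood water ratio in the hydrophilic limit, and is fully
overridable per tissue, which is the intended route for chemical-specific
refinements; published tool-specific partitioning regressions are not
reproduced because their coefficients are not public.

Virtual individuals are sampled from parametric distributions (height normal,
BMI lognormal per stratum: adult females 32–56 y, BMI GM 24.5/GSD 1.18;
children 6–11 y, BMI GM 16.8/GSD 1.13), with rejection sampling when weight
categories are restricted. BMI categories follow the screening bands: adults
≥ 25 overweight, ≥ 30 obese; children < 22 normal, ≥ 25 obese, with the
[22, 25) band labelled overweight to keep the partition consistent and
testable. Cardiac output (347 L/h at 70 kg) and GFR (6.7 L/h at 70 kg) scale
as BW^0.75; organ volumes as fixed BW fractions, so flows always sum to
cardiac output. Inter-individual metabolic variability is a lognormal
clearance multiplier (GSD 1.3); the poor-metaboliser option substitutes a low
quantile of that distribution (default 5th, overridable, e.g. 0.06 for a
chemical whose clearance distribution parameter is set so). Ethnicity is
recorded for provenance but has no physiological effect.

## Synthetic cohorts: what they emulate and what they do not

Real cohort urine tables of this kind are shared under data-transfer
agreements, so the generator produces stand-ins with the structure the
analysis assumes: per-chemical lognormal concentrations (GM/GSD are
config placeholders, not measured statistics), specific gravity uniform
within the observed spot-sample range 1.003–1.032, below-LoD censoring with a
selectable substitution rule (LoD/2 default; LoD/√2, zero, or exclusion), and
adult-female/child strata. The model-linked variant forward-simulates each
subject's concentration from a known intake plus multiplicative lognormal
spot-sample noise, giving ground truth for recovery tests. Not emulated:
within-person repeat-sample correlation (ICC), between-chemical exposure
correlation (independent by default; a Gaussian-copula hook exists in design
but correlations are not quantified), diurnal void timing, or exposure-source
(food/dust/air) structure. Passing recovery tests therefore demonstrates the
internal consistency of the forward/reverse chain under the model's own
data-generating process — not predictive accuracy for real cohorts, where
evaluations of this kind find order-of-magnitude deviations.

## Sensitivity analysis

One-at-a-time ±10 % perturbations; the reported coefficient is the elasticity
Δln(output)/Δln(input) by central difference in log space, which is exact for
power-law pathways (a plain percentage ratio at ±10 % would report −1.01 for
an exactly inverse pathway). Both one-sided responses are retained. The
urinary output is evaluated at a tight plateau tolerance (1e-5) so
coefficients reflect the asymptotic steady state rather than the speed of
approach; at steady state distribution volumes have essentially no effect,
which is why intrinsic clearance dominates organ-volume parameters for
hepatically cleared chemicals. Liver *mass* (metabolic capacity) and liver
*volume* (distribution) are deliberately separate parameters.

## Problem sizes

The shipped analyses use 400 adult females (Yamane-sized) and 500–1000
children for BE tables, 200/500 subjects for the recovery studies, and
48+48-subject synthetic cohorts; the test suite uses the same machinery at
20-individual scale plus a 50-chemical × 20-individual randomized
conservation sweep in both model modes. These sizes give stable medians
(Monte-Carlo convergence checks in the suite run at n = 10 000) while keeping
a full run in minutes on one CPU.

## Known limitations

Oral route only; constant f_ub (no saturable protein binding); metabolism in
liver only; kidney function fixed at normal; the linear mode cannot represent
saturation, and the metabolite mode's resorption magnitude for log K_ow ≥
−1.5 is a user parameter (default 0) because no public value exists. BE
values are urine-based only (no blood-matrix BEs), and the screening HI sums
across all chemicals regardless of endpoint — a deliberate worst-case
convention; endpoint-specific grouping is available via configuration.
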