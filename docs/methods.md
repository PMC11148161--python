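# Methods

## Scope and model overview

`pbpkeo` couples a reduced whole-body physiologically based pharmacokinetic
(PBPK) model of osimertinib to a turnover model of covalent EGFR occupancy
(EO) in brain tissue. It predicts plasma and brain-interstitial
concentration–time profiles under repeated oral dosing, the intracranial
occupancy time course of four EGFR variants (wild-type, T790M/L858R, L858R,
C797S), local parameter sensitivities, factor sweeps with threshold
crossings against the 80 % engagement and 711 nmol/L trough-safety
thresholds, dose-regimen feasibility, and exposure changes under five CYP
perpetrators.

## PBPK structure

Amount-based ODEs (µmol) over: stomach (solid + dissolved), intestinal
lumen, venous and arterial blood, lung, liver, gut, spleen, kidney, muscle,
adipose, skin, heart, bone, a lumped rest compartment, and a
permeability-limited brain with four sub-compartments (vascular plasma,
blood cells, interstitial, intracellular). All organs except the brain are
flow-limited with Rodgers–Rowland tissue:plasma coefficients (moderate-to-
strong base branch, acidic-phospholipid association constant estimated from
blood-cell partitioning) multiplied by the global Kp scale 1.5.

**Absorption.** The dose dissolves in the stomach following a Weibull
function (t50 15 min, shape 0.92); dissolved drug empties to the intestine
first-order with mean time GET = 120 min (the source states only the mean
time, so a first-order transfer was chosen); intestinal uptake is
first-order with ka = Peff·(2/r)·SEF, r = 1.75 cm and a segment-scale
surface amplification SEF = 5 chosen once to place tmax near the clinically
observed ~6 h. No lumen loss is modeled (complete absorption; the global
hepatic calibration factor absorbs net bioavailability error).

**Elimination.** Whole-liver unbound intrinsic clearances per CYP are
CLint(µL/min/pmol) × microsomal abundance × MPPGL 40 mg/g × 1800 g liver,
applied to unbound liver concentration (well-stirred); intestinal CYP3A4
(70 nmol total) acts on unbound gut-tissue concentration; renal clearance is
GFR × fup on arterial plasma. Organ volumes, flows and abundances are a
standard-human fixture — they are not part of the source parameter table,
which is why a calibration factor exists (below).

**Brain.** Passive BBB exchange is written on unbound concentrations,
PS·fu·(C_vascular,plasma − C_interstitial); ABCB1/BCRP efflux removes
CL_e·fu·C_interstitial back to vascular plasma, with CL_e = (73.4 + 15.9)
µL/min/million cells × 1e5 million cells and the printed transporter
concentrations treated as relative-activity anchors (multiplier 1 at base).
The interstitial space is assigned the same protein-binding milieu as
plasma (interstitial albumin tracks plasma albumin), so the unbound
fraction cancels and interstitial *total* equilibrates toward vascular
total × Kp,uu, where Kp,uu = PS/(PS + CL_e) ≤ 1 on the unbound scale for
any non-negative efflux. The interstitial sub-compartment concentration is
reported as the intracranial ("free BRT") concentration — the operational
definition used in the validation data, where CSF totals are compared with
interstitial levels. One consequence, intended: intracranial exposure and
the EO drive scale with *total* plasma concentration, so albumin shifts
propagate to the brain through total plasma rather than cancelling on the
free scale. The intracellular:interstitial partition Kic is derived once in
closed form so that total brain:plasma equals K_BRT,p = 2.89 at the base
steady state, then frozen for all experiments.

**Solver.** LSODA, rtol 1e-8, atol 1e-10, event-based dosing with exact
pre-dose (trough) sampling, 0.1 h output grid. Mass balance holds to
~1e-14 relative.

## Plasma-protein scale factor and the albumin pathway

PPSF = 1/(fup + (1 − fup)·albumin_f) rescales the unbound fraction when
albumin deviates from the healthy reference. The published wording of
albumin_f is ambiguous and the two readings move fup in opposite
directions:

* *physiological* (albumin_f = patient/healthy): hypoalbuminemia raises
  fup — the standard binding-dilution relation. This is the default of the
  `ppsf()` API (PPSF = 1.444 for albumin 0.31 vs 0.45, scaled
  fup ≈ 0.0159).
* *literal* (albumin_f = healthy/patient): fup falls as albumin falls.

The shipped model configuration uses the *literal* orientation in the
albumin pathway because the source's reported factor-sweep behaviour
(falling albumin drives the plasma trough up through the safety threshold;
rising albumin erodes intracranial occupancy) follows that direction, and
reproducing those experiments is the model's purpose. Both orientations
remain selectable and every absolute albumin value enters only as a ratio,
which also neutralizes the g/dL-vs-g/L inconsistency in the printed values
(0.31 printed where the validation studies report ~3.1).

## Calibration — two factors, then freeze

Absolute physiology is not recoverable from the printed inputs, so exactly
two factors are fitted once and frozen (`data/calibration_locked.yaml`).
Because both observed targets are cohort (arithmetic) means, the fit is
finished on the population mean of the seeded n=100 reference population
rather than on the mean subject (a log-normal population's arithmetic mean
exceeds its median by exp(σ²/2) ≈ 9 % at the configured variability, and
matching a median prediction to a mean observation would build that bias
into every population-level comparison):

1. **hepatic CLint scale = 2.3619**, fitted so the population-mean day-14
   plasma AUC at 80 mg OD equals the observed development-study value
   11,930 nmol·h/L (mean-subject AUC ≈ 10,880);
2. **brain passive PS = 13.07 L/h**, fitted so the population-mean
   interstitial trough at 80 mg equals the intracranial trough level
   12.0 nmol/L (mean-subject ≈ 10.4; Kp,uu ≈ 0.024 with the fixed efflux
   clearance).

Every downstream experiment runs under the frozen pair, preserving
falsifiability of the validation ratios and threshold findings.

## EO model and drive-mode selection

Occupancy follows the binding/turnover ODE pair (kon per variant from
kinact/Ki; koff = 0.001 h⁻¹; kdeg = ln2/27.5 h; EGFR T0 = 0.299 µM) driven
one-way by a brain concentration profile; occupancy is
100·(T0 − EGFR_free)/T0 and the trough is the minimum over the final
dosing interval. With koff → 0 the true stationary state has zero
occupancy (resynthesis eventually replaces all free receptor); over 14
days the system sits on the quasi-steady plateau
kon·C/(kon·C + kdeg + koff), which the analytic oracle `qss_occupancy`
captures and the ODE reproduces to <0.1 pp at ten relaxation times.

The printed kon units (µM⁻¹s⁻¹) and the printed occupancy outcomes are not
jointly consistent under one literal reading: per-second kon with the
~0.012 µM interstitial drive puts C797S at ~83 %, not the reported ~10 %.
The package therefore carries an explicit mode switch, and a calibration
experiment selects the mode reproducing both printed outcomes:

* mode A (interstitial drive, kon s⁻¹→h⁻¹): C797S ≈ 83 % — rejected;
* mode B (total-brain drive ≈ K_BRT,p × plasma, kon numerals per hour):
  C797S ≈ 9.6 %, T790M/L858R ≈ 98.1 %, L858R ≈ 95.6 % — locked default.

Every occupancy result records the mode used.

## Known, quantified disagreements with the source results

These follow from arithmetic of the stated model, were identified before
implementation, and are reported honestly rather than tuned away:

* **Sweep crossings.** With the kon ratio 1.40/0.0026 = 538 fixed, any
  parameterization giving C797S ≈ 10 % places the T790M/L858R quasi-steady
  trough near 98 %, so the drive must fall ~16-fold before occupancy
  crosses 80 %. The reported crossings (~2-fold ABCB1, ~1.6-fold albumin)
  imply only a ~2-fold drive reduction and cannot coexist with the ~10 %
  C797S under these ODEs driven one-way by a concentration profile. The
  implemented sweeps locate the crossings at ~19.4-fold (ABCB1) and
  ~10.3-fold (albumin); the albumin→711 nmol/L crossing computes to
  ~0.55-fold vs the reported ~0.65. Consistently, the ±20 % sensitivity
  scan finds occupancy insensitive to every parameter (|SC| ≪ 1) — which
  matches the source's own sensitivity table, where ABCB1 and T0 were *not*
  sensitive for EO.
* **EGFR T0 sweep.** Without a binding-consumption feedback of the drug
  (not part of the stated equations), occupancy is independent of receptor
  abundance; the T0 sweep is flat and its threshold crossing is reported
  absent. A reported T0 effect would require the occupancy reaction to
  deplete brain drug, i.e. a coupling the stated model does not contain.
* **Dose feasibility.** The model is linear in dose, so trough exposure
  doubles from 80 to 160 mg daily. Under the frozen calibration the
  mean-subject 160 mg OD trough lands at ~709 nmol/L — marginally under the
  711 nmol/L threshold — while 80 mg BID (~833 nmol/L, BID profiles being
  flatter and higher at trough) fails it. The source calls both feasible,
  yet its own table predicts 805.5 nmol/L at 160 mg OD, above its own
  threshold; a dose-linear model cannot reconcile the two claims.

## Virtual population

Independent unit-median log-normal multipliers on hepatic CLint (CV 35 %),
Peff (30 %), brain PS (30 %), ABCB1 activity (30 %), albumin (10 %) and
body weight (15 %), chosen once so steady-state exposure spread matches the
published population CVs (achieved: AUC CV ≈ 38 %, Ctrough CV ≈ 45 % vs
published 34–46 %). Subjects are reproducible from (seed, id). The
generator emulates between-subject PK variability only — no covariate
models, no intra-subject variability, no adherence effects — so population
checks validate spread and reproducibility, not covariate physiology.
Studies without modeled demographics reuse the standard patient
(mean-value surrogate); validation predictions for other doses use the
dose-linearity of the model.

## DDI scenarios

Perpetrators are reduced exposure models (one-compartment oral, closed-form
superposition of doses) supplying unbound concentration to per-enzyme
multipliers: competitive inhibition 1/(1 + I_u/Ki_u), induction through an
enzyme-turnover Emax model (CYP3A4 turnover t½ 36 h, configurable).
Intestinal CYP3A4 receives the hepatic multiplier. Perpetrator parameters
are literature-sourced substitutes (documented per entry in
`data/perpetrators.yaml`) because the source's supplementary values are not
in the text; achieved 14-day AUC ratios: itraconazole ~2.1 (reported 2.21),
fluconazole ~1.7 (1.75), rifampicin ~0.18 (0.15), efavirenz ~0.27 (0.28).
Fluvoxamine computes to ~1.06 vs the reported 1.41: with the fixture's CYP
fractional metabolism (fm,CYP1A2 ≈ 0.14), even complete CYP1A2 inhibition
caps the AUC ratio at ~1.17, so the reported 1.41 would require a
substantially larger CYP1A2 contribution than the printed intrinsic
clearances support.

## Numerical and design choices

* Concentrations are nmol/L externally, µM internally; conversion is
  centralized through MW 499.6.
* Sweep crossings are bracketed on the evaluation grid and refined by
  geometric bisection to 1 % relative precision; a sweep without a sign
  change reports the crossing as absent. Where a crossing lies beyond the
  stated sweep window, the grid is extended upward so the value can be
  located and reported instead of silently missing.
* Sensitivity coefficients SC = (ΔY/Y)/(ΔP/P) are reported for both the
  +20 % and −20 % sides (the source does not state which side it used);
  |SC| > 1 flags a sensitive parameter.
* Weibull dissolution with shape < 1 has an integrable rate singularity at
  t = 0; the rate is regularized at 1e-6 h.
* The transwell cell count behind the efflux clearances is not printed; the
  back-calculated value (3.92 million cells with SA 1.12 cm²) reproduces
  the ABCB1 number it was solved from *and*, independently, the BCRP
  number to three figures. It is recorded in the fixture as an implied
  value, not as the authors'.
* Osimertinib's own perpetrator parameters (Ki, EC50, Emax) are stored but
  auto-inhibition/induction is off by default, as the base-model usage is
  unstated in the source.

## Problem sizes

Mean-subject simulations cover 14 days at 0.1 h output resolution (~0.8 s
each); the population validation uses n = 100 subjects; sweeps use 11–17
grid points plus bisection refinements; the recovery experiment fits one
factor against 16 noisy replicates of a 10-sample rich design.
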