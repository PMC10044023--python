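# Methods

## Scope and model

The package implements a population-pharmacokinetic and PK/PD
target-attainment analysis of ceftazidime in adult ward patients across
three renal-function strata.  The structural model is a one-compartment
disposition with first-order elimination and zero-order infusion input,
parameterised by clearance `CL` (L/h) and volume of distribution `V` (L).
Typical clearance follows a covariate model with renal function entering as
a power function and concomitant antibiotic use as a multiplicative factor:

    CL = theta_cl * (eGFR / eGFR_ref)^gamma * theta_abx^flag

with default values `theta_cl = 3.74` L/h, `theta_v = 21.8` L,
`gamma = 0.75`, `theta_abx = 1.56` and `eGFR_ref = 76.86` mL/min/1.73 m²
(the final-model estimates of the study the analysis re-implements).
Inter-individual variability is log-normal on both parameters
(`CL_i = TVCL * exp(eta)`), with default standard deviations 0.313 (CL) and
0.402 (V); residual error on measured concentrations is proportional with
default magnitude 18.6 %.  Protein binding (about 10 % for ceftazidime) is
ignored throughout: all targets are evaluated on total concentrations, as
the concentrations the model is calibrated to were measured as totals.

**%CV convention.** Reported %CV values are interpreted as `100 * omega`
(the common reporting convention for log-normal random effects).  The
alternative geometric convention `100 * sqrt(exp(omega²) − 1)` is available
via `PopulationParameters(cv_convention="geometric")` and the
`omega_from_cv` helper; at 31 %CV the two differ by about 2.5 % relative.

## Closed-form kinetics

Because every superposed dose term decays with the same rate constant
`ke = CL/V`, the concentration between any two infusion start/stop
breakpoints is exactly `A + E * exp(-ke * dt)` with `A` the running
infusion rate sum divided by CL.  Each segment is therefore monotone, and

* concentrations are evaluated exactly (no ODE solver),
* AUC is the exact segment-wise integral,
* threshold crossings (for time above MIC) are solved by a single logarithm
  per segment; a sign change of `C - MIC` across a segment guarantees
  exactly one crossing, so no root bracketing is ever needed.

Dose linearity and superposition hold to machine precision and are enforced
by tests against independent dense-grid and Runge–Kutta oracles.
Units are fixed: hours, mg, L, mg/L; time zero is the first infusion start.

## Dataset handling

The longitudinal dataset uses a NONMEM-flavoured CSV (ID/TIME/EVID/AMT/
DUR/DV/BLQ plus covariate columns).  Cleaning applies, in order and
idempotently: (1) exact duplicate observation timepoints within a subject
keep the first record; (2) observations below the 0.1 mg/L quantification
limit are imputed at half that limit (0.05 mg/L), except that a BLQ
observation directly following another BLQ observation of the same subject
is excluded.  BLQ values enter estimation as their imputed values (an
M5-style treatment); no censored likelihood is used, matching the source
analysis.  Renal grouping uses half-open intervals on eGFR (CKD-EPI):
group I ≥ 50, group II [30, 50), group III < 30 mL/min/1.73 m², with the
boundary value 50 in group I.  CKD-EPI (2009, race term optional and off by
default), MDRD (175 coefficient) and Cockcroft–Gault formulas are provided;
which variant a site's laboratory used is a configuration choice.

## Synthetic cohorts

The patient-level data behind the analysis are not publicly deposited, so
all pipeline stages run on synthetic cohorts that reproduce the published
marginal structure: 40 subjects split 25/10/5 across renal groups; group
eGFR sampled from log-normal distributions calibrated to the published
medians and IQRs (102.8 [78.1–124.8], 34.3 [30.9–48.2], 18.6 [10.6–25.9]),
truncated to the group interval by rejection; guideline dosing per group
(2000 mg q8h, 1000 mg q12h, 1000 mg q24h) with 0.5 h infusions over 72 h;
three samples per subject (one trough drawn 0–15 min before a dose, two
random samples outside infusion windows) with 12.5 % of subjects yielding
only two; concomitant-antibiotic prevalence 19/25, 6/10 and 2/5 per group;
one severe-group subject mis-dosed at 2000 mg q24h (placed on the highest-
eGFR subject of the stratum, consistent with the high mid-interval
concentration reported for that patient) and one adequate-group subject
treated during the first 24 h only.

The "extra morning dose" phenomenon is modelled via a nurse-round
mechanism: each subject's first-dose clock time is uniform over 24 h; for
the 55 % of subjects flagged as shifted, one administration is given at the
first 08:00 round of the day after initiation and subsequent doses follow
the nominal interval anchored on that round.  A round falling within an
hour of a scheduled dose coincides with it (no extra administration), and a
round less than 2 h after the first dose defers to the next day.  Note the
anchoring can displace a later nominal dose, so the shifted schedule adds
administrations in the first day but does not pointwise dominate the exact
schedule; the paired comparison therefore reports the attainment
difference rather than assuming dominance.

Covariates that do not enter the final model (age, weight, BMI, sex,
ethnicity, ward, fever, serum creatinine) are drawn independently from the
published per-group margins: no joint correlation structure (for example
age–eGFR) is available to emulate, so their only role is exercising the
covariate-selection machinery's null behaviour.  Consequently, passing
tests demonstrate correct machinery under the published margins, not
calibration to the real joint covariate distribution.

For the Monte Carlo PTA stand-in of the study's fixed covariate set, a
deterministic "representative" cohort is used instead of an iid redraw:
per group, eGFR is placed at the plotting-position quantiles (k−0.5)/n of
the calibrated log-normal (so the group median equals the published median
by construction) and antibiotic counts are matched exactly.  An iid redraw
of only five severe-group covariate vectors would inject several percentage
points of between-run PTA variance that the fixed-dataset design of the
original simulation does not have.

## Estimation

The marginal likelihood is approximated by the Laplace method.  For each
subject the joint negative log-density of observations and the 2-D
random-effect vector is minimised by a damped Newton iteration (gradient
and Hessian from a 9-point central-difference stencil, eigenvalue-floored
steps, per-subject backtracking), run batched across subjects; the
curvature at the mode supplies the Gaussian-integral correction.  If the
curvature at a mode is indefinite (a ridge point, which can occur around a
BLQ-imputed datum), its eigenvalues are floored at 1e-6 rather than letting
a vanishing determinant spuriously reward the fit.  The outer problem runs
Nelder–Mead (adaptive simplex) over log-transformed parameters, warm-
starting each inner solve from the previous one.  Freely estimated
variance components carry smooth lower floors (sigma ≥ 0.5 %, below the
assay's reported precision; omega ≥ 0.001) implemented as floored
exponentials, which close the degenerate `sigma → 0` likelihood valley
without creating flat clipped regions.  Any parameter can be fixed
(`fix={"omega_cl": 0.0, ...}`), which reduces the objective to a pooled
regression criterion — the idiom used for degenerate noise-free checks.

Convergence is the optimiser's own success flag; when the simplex exhausts
its iterations, one restart is run and the fit is declared stationary if
the objective moves by less than 0.5 and no transformed parameter moves by
more than 0.02 — a situation that arises when a subject's joint density is
multimodal and the inner mode toggling keeps the simplex function-spread
test from ever passing while the estimates are already stable.  Anything
else is reported as non-converged, never silently.

Relative standard errors come from a central-difference Hessian of the
objective at the optimum (covariance `2 H⁻¹`, delta method through the log
transform); eta shrinkage is `1 − SD(EBE)/omega`.  The inter-individual
covariance is diagonal (no CL–V correlation is estimated), and
inter-occasion variability is not implemented in the default model.

**Covariate selection.**  A univariate likelihood-ratio screen at p < 0.05
(ΔOFV ≥ 3.84, 1 df; the screen threshold is conventional and configurable)
is followed by multivariate backward elimination at p < 0.01 (ΔOFV ≥ 6.63).
Continuous covariates enter clearance as power functions normalised to the
dataset median (or an explicit reference); binary covariates as
multiplicative factors.  The four renal-function markers (serum creatinine
and three eGFR formulas) are treated as mutually collinear: only the one
with the largest univariate drop may enter the multivariate model, with
ties broken by candidate order.

**Bootstrap.**  Subjects are resampled with replacement within renal-group
strata (keeping the 25/10/5 design), the model is refitted per replicate,
and percentile 95 % intervals are reported; non-converged replicates are
dropped and counted, with a hard warning above 20 % failures.

## Targets and PTA

Three targets are evaluated on residual-error-free individual profiles
(the standard PTA convention): strictly more than 12 of the first 24 h
above the MIC (primary); at least 23.5 of the first 24 h above the MIC
(the "100 %" target, allowing for the first 0.5 h infusion); and strictly
more than 12 h above the MIC between 24 and 48 h.  The 24 h clock starts at
the first infusion start.  PTA per renal group is tabulated over the EUCAST
MIC grid (0.125–8 mg/L) with a ≥ 90 % adequacy flag.  Eligibility follows
the study's explicit per-subject flags: the mis-dosed subject counts for
the primary target but not the secondary ones, and the 24-h-only subject
additionally drops from the 24–48 h window, giving denominators 25/10/5,
25/10/4 and 24/10/4.  AUCs are computed analytically from the profile (not
by trapezoid on predicted curves) and compared across groups with the
Kruskal–Wallis test.

The Monte Carlo engine simulates the fixed covariate set 1000 times,
redrawing only the log-normal random effects per replicate (fixed-effect
uncertainty is not propagated — replicates are simulations from the final
model), under exact q8/q12/q24 guideline intervals; each subject keeps
their own dose amount, so the mis-dosed subject is simulated at 2000 mg
q24h, mirroring the "original dataset with exact intervals" design.  PTA
is pooled over subject-replicates; with equal denominators per replicate
this equals the mean of per-replicate PTAs, and both are reported.

## Diagnostics

The prediction-corrected VPC bins observations by time after the most
recent dose (quantile bins, default 6, merging bins under 5 observations),
scales each observed and simulated value by the ratio of its bin's median
population prediction to its own population prediction, and compares
observed 5th/50th/95th percentile curves with 95 % bands from (by default)
1000 simulated replicates; using fewer replicates triggers a warning.
Goodness-of-fit tables report population and individual predictions,
individual weighted residuals, and a FOCE-style conditional weighted
residual built by linearising the model in the random effects at the
empirical Bayes mode.

## Problem sizes in the test suite

The automated tests use scaled-down study designs chosen for fast, stable
runs: parameter recovery uses 6 replicate cohorts (median-error criterion
20 % on fixed effects, 40 % on variabilities), the null covariate study
uses 10 cohorts × 3 candidates with a false-retention bound derived from
the binomial at the 1 % level, VPC calibration aggregates 8 self-simulation
repeats of 300 replicates each, and the bootstrap is exercised at small
replicate counts for determinism and interval structure.  The acceptance
script runs the Monte Carlo PTA at the full scale (1000 replicates of the
40-subject cohort).

## Known limitations

* Two-compartment disposition, nonlinear elimination and protein-binding
  corrections are out of scope by design.
* Objective-function values are not comparable to NONMEM's printed OFVs
  (different constants and approximation details); only differences within
  this implementation are meaningful.
* The synthetic cohorts reproduce published margins, not the real joint
  covariate distribution; observed-data tables and figure-level results of
  the original study are not reproducible from margins alone.
* The covariate step explores clearance covariates only; volume covariates
  were tested and not retained in the source analysis and are not searched
  here.
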