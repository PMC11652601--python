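# Methods

`quetipk` implements a complete model-informed precision dosing (MIPD)
workflow for oral quetiapine in adults with bipolar affective disorder:
a population-pharmacokinetic (PPK) model and its estimation machinery, the
standard evaluation toolbox (goodness of fit, visual predictive check,
bootstrap), and Monte Carlo dose-finding that turns the fitted model into
weight-banded initial-dose recommendations against the 100–500 ng/mL
therapeutic window.

## Structural and statistical model

Disposition is a one-compartment model with first-order absorption,
parameterized by apparent oral clearance CL/F (L/h), apparent volume of
distribution V/F (L) and absorption rate constant k_a (fixed at 1.46 h⁻¹;
with trough-dominated data the absorption phase is unobserved and k_a is
not estimable). The closed form for n doses of amount D every τ hours,
evaluated at time t after the last dose, uses the accumulation factors
A_x = (1 − e^(−n x τ)) / (1 − e^(−x τ)):

    C(t) = (D k_a) / (V (k_a − k_e)) · [A_{k_e} e^(−k_e t) − A_{k_a} e^(−k_a t)] ,
    k_e = CL/V

with the analytic limit at k_a = k_e (a removable singularity, handled by a
derivative branch rather than a crash), the n → ∞ limit for steady state,
and a single mg/L → ng/mL factor of 1000. Units are fixed throughout: mg
(dose), L (volume), h (time), ng/mL (concentration).

Between-subject variability is a single log-normal random effect on CL/F,
CL_i = TV(CL) · exp(η_i), η_i ~ N(0, ω²); V/F and k_a carry no random
effect (the data cannot support more). Body weight enters structurally
through fixed allometric scaling at a 70-kg reference (exponent 0.75 on
CL/F, 1 on V/F). Additional covariates enter multiplicatively: continuous
covariates as power terms (S_i / S_median)^Z centered at the dataset
median (computed once and frozen in the selection trace), binary flags as
linear shifts 1 + Z·S_i. Residual error is the combined model
y = g(1 + ε₁) + ε₂, so Var(y | g) = g²σ₁² + σ₂².

**Scale convention.** Published variability values (ω = 0.285, σ₁ = 0.312,
σ₂ = 23.896) do not state whether they are SDs or variances. The model
object carries an explicit `scale_convention` field (default `"sd"`), the
convention is recorded in every serialized result, and the dose-simulation
calibration (below) adjudicates empirically — the SD reading wins by a wide
margin.

## Likelihood and estimation

Each subject's marginal likelihood integrates the single η dimension:

    L_i = ∫ ∏_j N(y_ij ; g_ij(η), g_ij(η)² σ₁² + σ₂²) · N(η; 0, ω²) dη

Two evaluation paths are exposed and tested against each other:

* **Adaptive Gauss–Hermite quadrature** (default, order 21): nodes are
  centered at the empirical Bayes mode and scaled by the curvature there,
  making the one-dimensional integral essentially exact (doubling the
  order moves the OFV by < 0.01; agreement with a generic adaptive
  integrator is at 1e−6). This is the primary path — exact, and smooth in
  the outer parameters.
* **FOCE-style conditional approximation**: Laplace at the conditional
  mode with the standard fourth-order correction (numeric third/fourth
  derivatives of the joint −log density). Plain Laplace misses the exact
  value by ~0.06 per sparse subject; the corrected version agrees with
  quadrature to ~0.01 per subject. The correction factor is clamped to
  [0.25, 4] where the expansion is unreliable, keeping the objective
  surface free of cliffs.

The mode search is a vectorized grid-bracketed golden-section over all
subjects simultaneously; the likelihood kernel is JIT-compiled (numba)
with a pure-numpy fallback that produces identical values. The objective
function value (OFV) is −2 log L including Gaussian constants; a
NONMEM-style value with n·log 2π dropped is reported alongside. Selection
decisions use OFV differences, which are convention-free.

Maximization runs Nelder–Mead on log-transformed positive parameters
(covariate coefficients untransformed) inside a soft box (quadratic
penalty outside generous bounds): without the box, degenerate ridges such
as σ₂ → 0 stretch the simplex until it collapses prematurely. The simplex
is built explicitly (step 0.15) because the default perturbation collapses
at zero coordinates — exactly where fresh covariate coefficients start. A
restart with a fresh simplex at the first solution guards against early
collapse; it stops as soon as it fails to improve by 0.01. Initial values
come from a documented heuristic: CL₀ = mean dose rate / mean
concentration, V₀ = CL₀/k_e with k_e from the drug's ~7-h half-life,
ω₀ = 0.3, σ₁₀ = 0.3, σ₂₀ = 10 ng/mL — all overridable.

Relative standard errors come from the central finite-difference Hessian
of OFV/2 in the transformed space (step 5e−3); for log parameters the SE
of the log is the relative SE (delta method). A singular Hessian yields
NaN rather than a crash — with trough-only designs this is the expected
signature for V/F (see below).

## Stepwise covariate selection

Forward inclusion / backward elimination on OFV differences: each
candidate (every covariate × target pair is its own candidate) is added
singly and refitted; the largest drop strictly greater than 3.84 (χ²₁,
p < 0.05) enters, ties resolving by candidate list order; this repeats
until no candidate qualifies. Backward, each included effect is removed
singly and retained only if removal raises the OFV strictly more than
6.63 (p < 0.01). The allometric weight rule is structural and never a
candidate. Candidates whose fits fail are logged and skipped, never
silently dropped; the trace records every tested (candidate, ΔOFV) pair.
Calibration: a pure-noise covariate enters the forward step in ≈5% of
simulated null datasets, as the χ²₁ reference requires (tested over 200
replicates at n = 40).

## Identifiability and the sampling design

A steady-state trough is a single functional of (CL, V): with trough-only
sampling the likelihood has a near-ridge in (TV(CL), TV(V)) that only the
modest weight spread breaks, refitted clearances wander by ~45%, and the
V/F relative SE explodes (the test suite pins this signature: RSE for V/F
in the thousands of percent, mirroring the published fit's 59.6% RSE and
an order-of-magnitude bootstrap interval on real data). Because the
source study never states its TDM draw times, the synthetic design is
*trough-dominated* rather than trough-only: each of a subject's 1–3
samples is the pre-dose trough with probability 0.6, otherwise drawn
uniformly over 1–12 h post dose — the draw-time scatter that real TDM
data exhibits. Under this design the clearance estimator at the study
scale (n = 99) is well calibrated: mean error +1.4%, SD ≈ 5.4% over 30
seeds. A rich design (n = 200, sampling at 0.5–12 h post dose) identifies
V/F to a few percent and is used wherever volume recovery is asserted.

## Synthetic cohorts

The generator emulates the study cohort: n = 99 (66 men / 33 women),
age and 16 laboratory covariates from normal distributions truncated at
the published ranges (weight 73.75 ± 13.85 kg on 43–119 kg), and 23
binary co-medication flags as independent Bernoulli draws at the
published frequencies. Only marginal frequencies are published, so
between-drug correlation is not emulated — a stated limitation, not an
oversight. Total daily doses are drawn uniformly from
{200, 300, 400, 600, 800} mg/day (the immediate-release clinical range),
split twice daily (τ = 12 h); dose is independent of the subject's
clearance, so the generator contains no dose-titration confounding —
real TDM cohorts may, and passing recovery tests here does not certify
robustness to it. Concentrations follow the model at the subject's true
η plus one combined residual draw per observation; the rare non-positive
draw is redrawn (measured troughs are positive). The generating truth and
per-subject η are returned for recovery tests.

## Dose simulation and recommendation

For each (weight, daily dose) cell, `n_virtual` patients (default 1,000,
the study's own size) receive the allometric typical parameters at that
weight with fresh η draws; the exposure metric is the steady-state trough
under twice-daily dosing — the schedule and metric are config fields, as
the source never states either. The attainment probability (PTA) is the
fraction of troughs inside [100, 500] ng/mL (inclusive bounds — boundary
mass is measure-zero under the continuous model); exceedance is the
fraction strictly above 500 ng/mL. Residual-error draws are off by
default, and negative concentrations under the residual option are
floored at zero and counted below-window.

**Calibration.** `calibrate()` scores the four conventions
{ω, σ as SD | as variance} × {residual on | off} against the published
probability ranges. Reading the values as SDs and simulating
inter-individual variability only reproduces the published table to
within about one percentage point on every range endpoint; residual-on
drops attainment by 5–8 points and the variance reading by ~25 points.
The winning convention is the default and is stamped into every result's
metadata.

**Recommendation rule.** Per weight: doses whose exceedance exceeds the
safety cap (default 10%) are excluded; among the rest, the *lowest* dose
whose PTA lies within `pta_tolerance` (default 1.25 percentage points —
one binomial SE of the 1,000-patient design at p ≈ 0.8) of the maximum is
recommended. The tolerance treats PTA differences below the design's
Monte Carlo resolution as ties and resolves them toward the parsimonious
dose; without it, 20 mg/kg/day would edge out 16 by less than one point
at the lowest weights, and the 16 → 12 switch would drift to ~74 kg.
Under this rule, exact evaluation of the attainment surface yields two
bands — 16 mg/kg/day below ≈68 kg and 12 mg/kg/day above — matching the
published band structure; the published 66-kg edge itself was interpolated
from five weights at n = 1,000 and carries roughly ±10 kg of Monte Carlo
uncertainty, within which our boundary falls. Band boundaries are located
on a 2-kg grid (the published 20-kg grid cannot resolve them) and
contiguous weights sharing a recommendation merge into left-closed bands
with min–max attainment/exceedance ranges.

## Evaluation toolbox

* **Goodness of fit**: PRED (η = 0), IPRED (empirical Bayes mode),
  iWRES = (DV − IPRED)/√Var(y|IPRED), classic WRES from the first-order
  marginal covariance at η = 0, and CWRES linearized at the mode (the
  published figure does not say which "weighted residuals" it shows, so
  both are emitted). Rows with zero residual SD are flagged, not dropped.
* **VPC**: replicate datasets on the original design (new η and ε), 5/50/95
  percentiles per equal-count time bin with 90% envelopes; duplicate bin
  edges (few distinct nominal times) collapse gracefully. Default 500
  replicates; fewer than 50 records a warning. Fully seeded.
* **Bootstrap**: subjects resampled with replacement, each replicate
  refitted warm-started from the final estimates (a flag restarts from
  the initial model instead); default 1,000 resamples, configurable.
  Reported per parameter: estimate, bootstrap median, 5th–95th percentile
  interval, and bias = (median − estimate)/estimate × 100%. Failed
  replicates are excluded and counted; > 10% failures raises a warning.

## Problem sizes in the shipped tests

The test suite and acceptance script choose sizes that make each claim
statistically decidable: parameter recovery runs ten seeds at the study
scale (n = 99) and ten at n = 200 rich; the stepwise null calibration uses
200 replicates of n = 40 cohorts; band probability checks simulate up to
4×10⁶ patients per cell because the band-edge attainment (81.57%) sits
only 0.07 points above the published band minimum — at smaller samples the
check would be decided by Monte Carlo noise rather than by the model. The
recommendation grid uses 1.5×10⁵ patients per cell so the grid's own noise
stays well below the rule's tie tolerance.

## Known limitations

* Single random effect (no IIV on V/F or k_a, no inter-occasion
  variability, no covariance structure) — the sparse design supports no
  more, and the source model has the same shape.
* Co-medication flags are sampled independently; laboratory covariates are
  mutually independent truncated normals. Correlation structure in the
  real cohort is unknown.
* The TDM sampling-time distribution and per-patient dosing histories of
  the real study are assumptions, stated above, not reconstructions.
* Maintenance dosing, titration over time and pharmacodynamic outcomes are
  out of scope: the deliverable is the initial dose.
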