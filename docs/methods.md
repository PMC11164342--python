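# Methods

`ca125kin` analyzes longitudinal serum CA-125 in high-grade serous ovarian
cancer (HGSOC): it quantifies how quickly a patient's tumor burden falls
during chemotherapy lines and regrows between them, fits mechanistic models
of sensitive/resistant cell dynamics to each patient's series, compares the
model variants, and asks whether the inferred traits predict survival after
second-line treatment. This note records the models, the estimation and
comparison procedures, the numerical choices, and what the synthetic cohort
generator does and does not emulate.

## Data model and conventions

A patient record couples CA-125 measurements `(day, value)` with a treatment
schedule — chemotherapy *cycles* (dosing events, typically 21 days apart)
grouped into *lines* — and clinical covariates. Time is days from the
patient's first CA-125 measurement, so day 0 always has an observed value;
the models use it as the initial condition C(0).

The treatment indicator α(t) is 1 on the closed interval
[first cycle day, last cycle day] of every line, including intra-line gaps,
and 0 otherwise. A measurement taken exactly on a line's boundary day counts
as on-treatment (closed-interval convention); the gap window used for
regrowth slopes is the open interval between consecutive lines. A
single-cycle line has a zero-length interval: it counts as a line for
eligibility but contributes no on-treatment slope, and a measurement exactly
on that day is omitted from slope estimation (it belongs to neither open
gap). Both conventions are arbitrary at the measure-zero boundary; they are
fixed here once and tested.

Eligibility mirrors the study design: completion of second-line treatment
(at least two lines, with the record reaching the end of line 2), strictly
more than six CA-125 values (i.e. ≥ 7), a platinum-based first-line regimen
(case-insensitive drug-label match against carboplatin/cisplatin), and a
recorded disease progression.

## Data-based traits

*Data-based resistance* for line k is the ordinary-least-squares slope of
ln CA-125 against day over the measurements inside line k's on-treatment
interval; decline during therapy makes it negative, and values drifting
toward zero across lines indicate emerging chemoresistance. *Data-based
aggressiveness* after line k is the same slope over the following gap
(regrowth while off therapy). Natural logarithms are used throughout; slopes
in another base are a constant multiple. Estimation is per patient and per
line (fixed effects); no population-level random-effects model is included.
A slope is reported only when its window holds at least two measurements
with distinct days. These slopes also initialize the model fits.

## The sensitive/resistant (SR) model

Two cell populations produce CA-125 proportionally, C = R + S. Off treatment
they grow at rates γ_S, γ_R (per day, non-negative); on treatment they die
at rates δ_S (non-negative) and δ_R (unconstrained — a negative δ_R means
resistant cells keep growing under therapy); sensitive cells convert to
resistant at rate μ ≥ 0, both on and off treatment:

    dR/dt = (1-α) γ_R R − α δ_R R + μ S
    dS/dt = (1-α) γ_S S − α δ_S S − μ S

Three scenarios are fitted: pre-existing resistance (`sr_r0`: μ = 0,
R(0) > 0 free), acquired resistance (`sr_mu`: R(0) = 0, μ > 0 free), and the
single-cell special case (`single`: μ = 0, R(0) = 0). An extended variant
lets CA-125 relax toward R + S with turnover rate δ_C
(dC/dt = δ_C (R + S − C)); it is exposed but excluded from the default
fitting menu because it produces near-identical trajectories once δ_C is
fast compared to the population rates.

Within any interval of constant α the system is linear, constant-coefficient
and triangular, so propagation uses the exact closed form (with
a = (1−α)γ_R − αδ_R, b = (1−α)γ_S − αδ_S − μ):

    S(t+dt) = S e^{b dt}
    R(t+dt) = R e^{a dt} + μ S (e^{b dt} − e^{a dt})/(b − a)

with the analytic limit R e^{a dt} + μ S dt e^{a dt} when |b − a| < 1e-12
(the secular t e^{at} term), rather than a perturbation of the coefficients.
Regime boundaries are breakpoints; propagation never crosses an α switch.
This makes a single trajectory evaluation a short scalar-exponential
recursion — important because fitting runs hundreds of thousands of them —
and is exact at machine precision, with no step-size artifacts at line
boundaries. An adaptive-step integration of the raw ODEs is kept in the test
suite as the independent oracle (agreement to < 1e-6 relative error over
randomized draws, including engineered equal-eigenvalue cases).

## The adaptive-dynamics (AD) model

A single population N carries a continuous resistance level x. Growth and
death rates interpolate logistically between the sensitive (x → −∞) and
resistant (x → +∞) extremes:

    γ(x) = γ_R + (γ_S − γ_R) / (1 + e^{B_γ x + A_γ})
    δ(x) = δ_R + (δ_S − δ_R) / (1 + e^{B_δ x + A_δ})

    dN/dt = [(1−α) γ(x) − α δ(x)] N
    dx/dt = K ∂W/∂x,   W(x) = (1−α) γ(x) − α δ(x)

Treatment pushes x up toward lower death rates; treatment-free intervals
pull it back toward higher growth rates. K (the selection-response rate) is
fixed at 0.01 per day and is not estimated. The shape parameters B_γ, B_δ
are constrained non-negative so the limits above hold as written; the
offsets A_γ, A_δ are free. The initial level x(0) is fixed at 0 and not
estimated — the offsets absorb the origin choice, keeping the free-parameter
set at {γ_R, γ_S, δ_R, δ_S, A_γ, A_δ, B_γ, B_δ}. N(0) is set to the first
observed CA-125, as in the SR models.

N is integrated in log space (it is strictly positive), with adaptive error
control (relative tolerance 1e-8; 1e-6 inside the fitting loop, where the
objective tolerance dominates), restarting at every α switch. The logistic
and its derivative are evaluated in overflow-safe form. The analytic
gradient ∂W/∂x is checked against central finite differences to 1e-8.

## Parameter estimation

For each patient, model variant, and fitting window the objective is the sum
of squared deviations between log observed CA-125 and the log model
prediction, with C(0) anchored at the first observed value. Windows: `two`,
`three`, `four` use all measurements up to (and including, for boundary
points) the start of line k+1; `all` uses everything. A window is refused
when it holds fewer measurements than free parameters + 1.

Constraints are enforced by smooth reparameterization: non-negative rates
(γ_S, γ_R, δ_S, μ, B_γ, B_δ) live on a log scale, δ_R and the A offsets are
unconstrained, and R(0) is a logit-transformed fraction of the observed
C(0) — which also enforces S(0) ≥ 0, an upper bound the model family leaves
open but that the decomposition C = R + S requires. Infeasible or
non-finite simulations return a large finite penalty (1e12) so the simplex
can contract away from them.

The local optimizer is Nelder–Mead on the unconstrained scale, with
multistart: the first start comes from the data-based traits (δ_S, γ_S from
first-line slopes; δ_R, γ_R from the latest line with an estimate, since the
resistant population dominates late; scaled copies when absent), later
starts are jittered with growing spread, 20 restarts by default with early
stop once the objective is below 1e-12. The simplex optimum is then polished
by a Gauss–Newton pass (`least_squares` on the residual vector, same
objective, same scale). The polish matters for noiseless parameter-recovery
checks: the simplex alone stalls around RSS ~ 1e-6–1e-8, which leaves
sub-percent but non-negligible parameter error; Gauss–Newton drives RSS to
~1e-29 and the parameters to machine precision. Everything is deterministic
given the configuration seed (per-patient streams are derived from the seed
and a CRC of the patient id, so cohort fits are order-independent).

**Identifiability.** With μ = 0 the SR model is exactly invariant under
relabeling the two cell types together with their rates and initial
fraction: (γ_R, δ_R, f) ↔ (γ_S, δ_S, 1−f). When the true δ_R is negative
the constraint δ_S ≥ 0 forbids the mirror; when δ_R > 0 both labelings are
admissible and the data cannot distinguish them. Parameter-recovery checks
therefore score a fit as correct if either labeling matches the truth.
Separately, parameters of a compartment that is effectively absent (e.g.
sensitive-cell rates after that population is eliminated in a
primary-resistance patient) are only weakly identified; recovery statements
are strongest for the compartment that drives the observed dynamics. AD
parameters can be ridge-identifiable (different (A, B) pairs giving nearly
identical trajectories over the observation span), so AD recovery is judged
by objective value rather than per-parameter error.

## Model comparison

* **RSS ratio** (reference-smoother RSS / model RSS) on the same log-scale
  fitting points. The reference is a variable-span local-linear smoother
  after Friedman's SuperSmoother: candidate spans {0.05, 0.2, 0.5} of n,
  per-point leave-one-out residual selects the local span, the selected
  spans are themselves smoothed at the midrange span, and the final fit
  interpolates between the candidate fits; fewer than 10 points fall back to
  the half-span fit, fewer than 5 are refused. The bass/tension enhancements
  of the original are omitted. Saturated windows (hat value 1, e.g. a
  two-point window, which interpolates) are excluded from span selection —
  otherwise the cross-validation shortcut degenerates and the smoother
  collapses to an interpolant. A ratio near 1 means the mechanistic model
  tracks the data about as well as a flexible smoother; on sparsely sampled
  sawtooth series the smoother can also be *worse* than the model
  (ratio > 1), which dense clinical sampling largely avoids.
* **AIC** = 2k − 2 ln L with a Gaussian likelihood whose variance is
  profiled out: ln L = −(n/2)(ln(2π·RSS/n) + 1). k counts the free model
  parameters plus one for the variance, uniformly across variants, so the
  +1 cancels in every comparison. RSS = 0 returns −∞ as a perfect-fit
  sentinel.
* **Three R² values** on log CA-125: over the fitted window; over the next
  line through the end of its following gap (short-term prediction); and
  over all points past the window (long-term prediction). The total sum of
  squares is centered on the evaluation subset's own mean — the convention
  under which out-of-sample R² goes negative when the prediction is worse
  than a constant. Entries with fewer than two points, or zero total sum of
  squares, are absent.

## Survival analysis

Overall survival runs from the end of second-line treatment to death or last
follow-up; starting the clock at the end of line 2 avoids the survivorship
bias of conditioning on reaching later lines. Survival rows are
complete-case over the requested covariates: clinical ones resolved from the
record (age at diagnosis, first-line modality PDS/NACT, residual-disease
category, log pre-treatment CA-125, and the progression-free interval from
the end of line 1), any others from a per-patient table of trait slopes or
fitted parameters. Kaplan–Meier median splits put values exactly at the
median in the lower group (deterministic); the rank test is log-rank by
default with Gehan–Breslow–Wilcoxon exposed. Cox proportional-hazards fits
use Efron tie handling, indicator coding against the first (alphabetical)
reference level for categoricals, and a guardrail of at least 10 complete
cases per covariate. The product-limit and partial-likelihood machinery is
`lifelines`; this module's own content is the input construction, the split
protocol, and the missing-data policy. A hand-computable partial-likelihood
grid maximization serves as the oracle in tests.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
exercised; every default is either a published summary statistic or a fixed
choice documented here.

* **Schedules.** Cycles 21 days apart. Line durations and between-line gaps
  are log-normal with medians 106 and 165 days (the published medians) and
  log-sd 0.5 — log-normal because only medians and wide positive ranges are
  reported, and the distribution is right-skewed, positive, and
  median-parameterized. Cycle counts are the rounded duration over the cycle
  interval (at least two), so realized durations are quantized to 21-day
  multiples. Lines per patient: uniform on 2–6. First-line drug labels are
  carboplatin+paclitaxel (the standard first-line doublet); later lines draw
  from common second-line agents.
* **Parameters.** Rates draw from truncated normals with the published
  per-patient estimate summaries as moments: δ_R (−0.00018, 0.0127),
  δ_S (0.04421, 0.0241), γ_S (0.0142, 0.0167), γ_R (0.01024, 0.0127), with
  the published ranges as truncation bounds. ln R(0) uses the published mean
  0.1208 with sd widened to 1.0: the printed sd (0.0127) is inconsistent
  with the printed range (−5.51, 3.78) and is treated as unreliable rather
  than silently adopted.
* **Patterns.** Three qualitative CA-125 patterns with default weights
  (0.6, 0.2, 0.2): (1) fluctuating response — decline each line, regrowth
  between (δ_S ≥ 0.02, moderate R(0) fraction); (2) primary resistance —
  δ_R forced negative and R(0) 50–90% of C(0), so CA-125 rises through later
  lines; (3) durable response — strong kill (δ_S ≥ 0.06), growth rates
  scaled to 15%, near-zero R(0). The weights are a fixed choice reflecting
  that the fluctuating pattern is the typical presentation.
* **Observation.** Baseline CA-125 is log-normal (median 300 U/mL, a typical
  pre-treatment HGSOC level; upper limit of normal 35). Measurements are
  taken at day 0, every cycle day, and evenly spaced points in each gap
  (2 by default); observed values are the model trajectory times e^ε with
  ε ~ N(0, noise_sd²), noise_sd = 0.2 by default — a fixed assumption, since
  no measurement-error model is published for CA-125.
* **Survival.** Exponential, with log hazard = intercept + 20·γ_S + 20·γ_R
  − 20·δ_R (coefficients scaled so one prior sd of a rate moves the log
  hazard by ~0.2–0.3; intercept −6.9 puts the median post-line-2 survival
  near 450 days), administratively censored at 2,500 days. Exponential
  rather than Weibull keeps the generator analytically checkable. Schedules
  and measurements are truncated at death/censoring (lines 1–2 always
  complete, preserving eligibility).
* **Drift option.** For prediction-failure experiments the generating rates
  can be multiplied by fixed factors after a chosen line (SR family only),
  emulating resistance emerging after the fitted window — which no
  constant-parameter fit can anticipate.

What the generator does **not** emulate: drug-specific and combination
effects (complete cross-resistance is implicit), surgery effects on CA-125,
non-exponential hazards, informative measurement scheduling (visits driven
by clinical deterioration), covariate correlations of a real cohort, and
CA-125 assay floor/ceiling effects. Passing tests therefore demonstrate the
pipeline's internal correctness and its behavior under the stated data
structure, not performance on real AOCS-like data.

## Problem sizes and experiment design

The validation experiments use: 200 random draws for the SR closed-form vs
integrator check; 100 random scenarios for AD gradient/monotonicity; 100
noiseless and 200 noisy four-line patients for parameter recovery (the
recovery cohorts use three gap samples per interval and negligible early
mortality so every schedule completes its four lines with ≥ 30 points); 100
noisy mixed-pattern patients for AIC discrimination; 30 drift patients for
the out-of-sample R² property; 500 patients for survival sign recovery and
100 replicates of 100 for null-covariate CI coverage. These sizes make each
experiment's Monte-Carlo error small relative to the property being
asserted while keeping the full suite's runtime modest.

## Known limitations

* Per-patient fixed-effect slopes only; no mixed-effects pooling.
* The Nelder–Mead + polish optimizer is local; multistart reduces but cannot
  eliminate the risk of missing a global optimum in pathological series.
* AD fitting is substantially slower than SR fitting (each objective
  evaluation integrates an ODE) and its parameters may be ridge-identified.
* The RSS-ratio reference smoother is a deliberately plain variable-span
  local-linear smoother; absolute ratio values depend on sampling density
  and should be compared across models, not across datasets.
* No uncertainty quantification on fitted parameters (no profile likelihood
  or bootstrap); survival analyses treat fitted parameters as known
  covariates.
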