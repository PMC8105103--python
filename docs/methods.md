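# Methods

## Model

The tumor is a set of volume compartments coupled by first-order transfer.
Each active sub-population T_m grows logistically with rate a_m (day⁻¹) and
carrying capacity K_m (mm³); the quiescent pool Q holds cells that have
suspended division and can re-enter any active pool; the non-dividing pool
ND holds dead and dying cells cleared into the blood at rate η. With
transfer rates p_ij (day⁻¹):

    dV_m /dt = a_m V_m (1 − V_m/K_m) + p_Qm V_Q − (p_mQ + p_mND) V_m
    dV_Q /dt = Σ_m p_mQ V_m − (Σ_m p_Qm + p_QND) V_Q
    dV_ND/dt = Σ_m p_mND V_m + p_QND V_Q − η V_ND

Two consequences worth knowing. First, transfers conserve volume: the
summed right-hand side equals the total logistic growth minus η·V_ND, which
the tests assert on random states. Second, with M = 1 and all couplings
zero the system is exactly the logistic law, which anchors the solver
against the closed form V(t) = K / (1 + (K/V₀ − 1)e^{−at}). The Gompertz
baseline dV/dt = aV − bV ln V (closed form V(t) = exp(a/b + (ln V₀ −
a/b)e^{−bt})) is provided alongside.

A deliberate interpretation: the compartment diagram's p_ij are labelled
transition *probabilities*, but they multiply volumes inside an ODE and
carry day⁻¹ units, so this package treats them as rate constants
throughout.

## Default parameters

Published NSCLC fits (A549-line growth data and lung-cancer
radiosensitivity estimates), all exposed as `CompartmentParams.default()`,
`RadiosensitivityParams.default()`, `DEFAULT_LOGISTIC`, `DEFAULT_GOMPERTZ`:

| block | values |
|---|---|
| logistic baseline | a = 0.502 day⁻¹, K = 1297 mm³ |
| Gompertz baseline | a = 0.743 day⁻¹, b = 0.0792 day⁻¹ |
| active types | a₁ = 0.862, a₂ = 0.501 day⁻¹; K₁ = 1397, K₂ = 1174 mm³ |
| transfers | p_Q1 = p_Q2 = 0.1, p_1Q = p_2Q = 0.2, p_1ND = p_2ND = 0.2, p_QND = 0.09 day⁻¹ |
| clearance | η = 0.4 day⁻¹ |
| radiosensitivity | α₁ = 0.194, α₂ = 0.3705, α_Q = 0.3 Gy⁻¹; β₁ = 0.063, β₂ = 0.02335, β_Q = 0.15 Gy⁻² |

T₁ is the fast-growing, radioresistant type (α₁/β₁ ≈ 3 Gy) and T₂ the
slower, radiosensitive type (α₂/β₂ ≈ 16 Gy); that contrast drives every
fractionation finding below. The core is written for general M; the
defaults use M = 2.

## Radiation kill

A dose D leaves surviving fraction S = exp(−αD − βD²) in the compartments
it reaches — the active types and the quiescent pool, each with its own
(α, β). The non-dividing pool is never irradiated-effective: radiation
kills by stopping division, and those cells have already stopped.

Fractions are applied in one of two modes:

* **Impulse (default).** Delivery takes minutes while growth acts on a
  scale of days, so each fraction instantaneously multiplies V_m and V_Q by
  their LQ survivals. This makes the per-fraction survival exactly the LQ
  formula and makes an n-way split of total dose D compose to
  exp(−αD − βD²/n) when growth is off — the fractionation-sparing closed
  form the tests verify for n ∈ {1, 4, 5, 8, 30}.
* **Window.** The kill is a concurrent ODE term −(αr + 2βr²)V at constant
  dose rate r = D/t_R over the fraction's duration t_R, integrated jointly
  with growth. With growth off this yields exponent αD + 2βD²/t_R, which
  agrees with the LQ exponent only at t_R = 2 time units; the two forms are
  mutually consistent only there, so the impulse form is taken as ground
  truth and the window form is kept for delivery-time studies. The matched
  window (t_R = 2) reproduces the impulse to 10⁻⁸ relative in the tests.

A course alternates free growth between fractions with fraction
application; an optional run-in grows the tumor from its seed state before
fraction 1, and the treatment ratio (post/pre volume per compartment and
total) compares the state at the first fraction's start with a configurable
evaluation state.

## Schedules

`build_plan` expands a prescription (total dose, n fractions,
fractions/day, treatment days/week, intra-day gap) into timed fractions.
Day 0 is a Monday-equivalent; a day d is a treatment day iff d mod 7 <
treatment_days_per_week, which makes weekend skipping and course lengths
deterministic. The intra-day gap for multiple daily fractions defaults to
6 h (0.25 day). Shipped presets are representative of the three clinical
scenarios: SBRT {48 Gy/4, 60 Gy/8, 50 Gy/5, 23.5 Gy/1}, CFRT {60 Gy/30 and
70 Gy/35 at 2 Gy, 60 Gy/24 at 2.5 Gy}, HFRT {60 Gy/30 at 2/day}. The
single-fraction SBRT dose (23.5 Gy) is the top of the commonly quoted
7–23.5 Gy per-fraction range; the 70 Gy escalation keeps the 2 Gy/fraction
convention; the 2.5 Gy variant keeps the 60 Gy total. Comparison reports
rank tumor control only — the model computes no normal-tissue toxicity, and
no such ranking is claimed.

## Evaluation conventions and the calibrated comparison

Neither the initial tumor state, the pre-treatment history, nor the
evaluation time of a treatment ratio is uniquely dictated by the model, so
they are explicit, documented knobs:

* seed state: 1 mm³ per active type, Q = ND = 0;
* run-in: free growth before fraction 1 (30 days by default in the
  config/comparison layer, which puts the default tumor near its plateau);
* evaluation: at the last fraction (plus optional follow-up), or — via
  `eval_day` — at a fixed calendar day after the course start, the way
  competing plans are read off a shared time axis. When the evaluation
  instant coincides with a scheduled fraction the state *before* that
  fraction is used (left limit).

The committed configuration `configs/cfrt_hfrt_headline.yaml` (13-day
run-in, evaluation at day 30) is the regression anchor for the
once-vs-twice-daily comparison of 60 Gy/30 Fr at 2 Gy: it yields T₁
treatment ratios of 0.238 (once daily) and 0.0070 (twice daily). Two
robust, convention-independent facts accompany it: the twice-daily plan
beats the once-daily plan by well over an order of magnitude for T₁ under
every convention examined, and raising dose per fraction to 2.5 Gy at the
same 60 Gy improves T₁ control far more than escalating the total dose to
70 Gy at 2 Gy.

## Fitting and synthetic data

`fit_growth_curve` fits logistic or Gompertz parameters to time–volume
data by nonlinear least squares on volumes (`scipy.optimize.least_squares`;
an optional log-volume objective suits multiplicative noise). The starting
volume is estimated as a nuisance parameter rather than pinned to the noisy
first observation. Non-convergence and rank-deficient Jacobians (e.g. data
sitting at carrying capacity, where the rate carries no information) are
flagged on the result, never raised.

The fixture generator evaluates a closed form and applies multiplicative
log-normal noise V·exp(σZ), Z ~ N(0,1), so σ approximates the coefficient
of variation and the noiseless curve is the median. It emulates measurement
scatter on a growing xenograft; it does not emulate irregular sampling,
measurement censoring, inter-subject variability, or model misspecification
— so passing recovery tests demonstrate estimator correctness, not
real-data robustness. A 1000-replicate Monte Carlo of the standard recipe
(20 points over 25 days, σ = 0.1) gives 99.5% bounds on the absolute
relative error of 0.43 for a and 0.17 for K; the seeded tests assert
against those frozen bounds. Seeds exist only in the fixture generator —
the simulator itself is deterministic by construction.

## Numerics

* Integrator: `solve_ivp` with DOP853 (high-order explicit Runge–Kutta),
  rtol 10⁻⁸, atol 10⁻¹⁰ — tight enough that closed forms act as exact
  oracles at the 10⁻⁶ level over 100 days.
* Courses are integrated piecewise between fraction events; impulse jumps
  appear in trajectories as duplicated sample times (pre/post state).
* Small negative solver excursions are clamped to zero at output samples;
  any component below −10⁻⁶ mm³ raises a simulation error rather than being
  masked.
* Degenerate inputs are rejected up front: non-increasing time grids,
  negative volumes or doses, Gompertz from V₀ ≤ 0 (ln V undefined — rejected,
  not clamped), overlapping fractions, window mode without durations.
* Problem sizes: acceptance-grade checks use ≤ 501-point grids over ≤ 120
  days and single courses of ≤ 35 fractions; the full test suite and the
  acceptance script each complete in a few seconds.

## Known limitations

* No spatial structure, hypoxia, cell-cycle phase or stochastic variant;
  the model is deliberately a small ODE system.
* No normal-tissue complication model: plan rankings are tumor-control
  rankings only.
* Dose rate within a fraction is constant in window mode; time-varying
  delivery is out of scope.
* The printed treatment-ratio pair for the once-vs-twice-daily comparison
  depends on the documented run-in/evaluation conventions; only the
  order-of-magnitude separation is convention-independent.
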