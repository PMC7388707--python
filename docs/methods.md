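# Methods

## Scope and intent

`tgisim` packages a computational regimen-exploration study: how does the
schedule of a fixed cisplatin budget (one bolus, a few fractions, or weekly
metronomic doses) change tumor growth in a mouse mammary-tumor model?  The
pipeline has four stages — exposure (PK), tumor dynamics, regimen
comparison, and population estimation on synthetic cohorts — each usable on
its own.

## Pharmacokinetic model

A bolus of `D` mg/kg raises the concentration instantaneously by
`s·D` and decays as `exp(−k_e t)` with `k_e = ln 2 / t_half`.  Superposition
(valid for linear kinetics) gives the multi-dose profile and closed-form
AUCs; `auc` on `[t0, t1]` evaluates the exact expression

    Σ_{i: t_i < t1} (s·D_i/k_e) (e^{−k_e·max(0, t0−t_i)} − e^{−k_e (t1−t_i)}),

with `t1 = ∞` supported (the total exposure is `total_dose·s/k_e`, schedule
independent).  Defaults: `t_half = 6.9` days (the fitted cisplatin half-life
in the treated cohort this package emulates; the weekly metronomic spacing
rounds it to 7), and `s = 1` concentration unit per mg/kg.  The volume of
distribution is unidentifiable here, so concentrations are "remaining dose"
units and the kill potency `k2` is interpreted per those units; AUC tables
are reported relative to a reference schedule anchored at a configurable
value (2.433 for the day-0 bolus reproduces the published table).

Dose literals matter at the third decimal of that table: the "1.66 mg/kg"
three-dose arms must be exactly 5/3 mg/kg, while the metronomic arms are the
literal 0.714 and 1.428 mg/kg.  Both conventions are encoded in
`build_paper_regimens` and verified by test.  The high-dose metronomic row
is reported as computed (twice the low-dose row, 4.281 after anchoring);
the differing printed source value cannot arise from first-order
superposition and is treated as a typo upstream.

## Tumor dynamics

Unperturbed growth follows the exponential-then-linear Simeoni form with
switching sharpness `psi = 20`; the switch burden is `lambda1/lambda0` and
the growth factor is evaluated in log space so large burdens cannot
overflow.  The growth denominator uses the **total** burden (all
compartments), the standard convention.

Two delay-of-kill mechanisms share one integration contract:

* **Transit chain** (`n_transit = 3` by default): drug-hit cells pass
  through first-order damage compartments at rate `k1`; the hit-to-death lag
  is Erlang(n, k1) with mean `n/k1`.
* **Fixed delay**: a hit cell is removed exactly `tau` days later.  The
  damaged pool gains `k2 c(t) x1(t)` and loses `k2 c(t−tau) x1(t−tau)`,
  integrated by the method of steps with dense interpolants of `x1` kept per
  segment.  Breakpoints at every multiple of `tau` guarantee each segment
  reaches no further back than known history; dose times are propagated
  through the lag to second order (`t_i`, `t_i+tau`, `t_i+2tau`) so the
  integrator never steps across a lagged discontinuity.  `tau = 0` is the
  degenerate instantaneous-kill limit (damaged pool identically empty).

As `n` grows with `k1 = n/tau`, the Erlang lag concentrates at `tau` and the
transit trajectory converges to the fixed-delay one; the test suite asserts
the sup-norm gap decreases over `n ∈ {1, 3, 10, 30}`.

Integration uses adaptive LSODA at `rtol 1e-8 / atol 1e-10` (simulation) and
`1e-6 / 1e-8` (inside fitting loops, where the objective tolerance dominates),
restarted at every dose time because the concentration jumps there.
Negative states within `max(1e-12, 10·atol)` of zero are clamped to zero on
output; anything worse raises `SolverError` with the last accepted time.
The eradication threshold `lambda0/k2` is exact in the exponential regime;
the sign tests run at 0.9× and 1.1× the threshold.

## Default demonstration parameters

The source study prints no fitted values, so demonstration defaults were
chosen once to make the package's simulations reproduce the qualitative
regimen findings, and are config-settable rather than hard-coded:

| parameter | value | units | rationale |
| --- | --- | --- | --- |
| lambda0 | 0.3 | 1/day | brisk exponential phase; control reaches the switch burden in ~1 week |
| lambda1 | 120 | volume/day | linear-phase cap; switch burden 400 units |
| psi | 20 | — | sharp, standard switching exponent |
| k1 | 0.5 | 1/day | mean hit-to-death lag 6 days with 3 compartments |
| k2 | 0.15 | 1/(conc·day) | eradication threshold 2.0 conc units: a 5 mg/kg bolus transiently regresses the tumor, regrowth well before day 50 |
| w0 | 50 | volume | palpable tumor at treatment start |
| tau | 6 | days | `n_transit/k1`, matching the transit chain's mean lag |

With these values the bolus arm dips to ~2% of the control burden near day
17 and returns to ~42% by day 50; the regimen ranking at day 20 (bolus
best) inverts by day 50 (both metronomic arms best).  These qualitative
statements are asserted only under this parameter set.

## Synthetic cohorts

`generate_cohort` emulates the study structure: 21 untreated controls plus
19 animals receiving 5 mg/kg on day 0, volumes recorded on weekdays over
days 0–50 (day 0 anchored to Monday by default — the true anchor is
unknown — with optional holidays), between-animal lognormal variability
`theta_i = theta_pop·exp(eta_i)`, and combined additive + proportional
residual error truncated at zero.  Defaults: `omega = 0.2` on
`lambda0, k2, w0` (the other parameters fixed, keeping 40-animal recovery
well-posed), `sigma_prop = 0.1`, `sigma_add = 5` volume units (visible only
at small burdens).  Volumes are in arbitrary units since the source figures
are not digitized.  What a green recovery test establishes is therefore
internal consistency — the estimator recovers the generator's parameters
under the stated design — not agreement with any animal dataset; dropout,
euthanasia rules and measurement-day irregularities of real studies are not
emulated.

## Two-stage estimation

Full nonlinear mixed-effects estimation (SAEM) is deliberately replaced by
the classical two-stage approach: per-animal nonlinear least squares, then a
geometric-mean population summary with the SD of log estimates as the
variability estimate.  With ~36 observations per animal the individual fits
are well-conditioned, which is the regime where two-stage estimation is an
acceptable stand-in; it inflates variability estimates (estimation noise
adds to true heterogeneity) and `omega_hat` is accordingly reported but not
held to a recovery criterion.

The objective is weighted (relative) least squares,
``sum ((y - w)/(5 + w))**2``: because measurement error is
proportional-dominant, unweighted least squares lets the large late-time
volumes swamp the objective, and for some noise realisations the degenerate
no-drug solution (``w0 -> 0``, ``k2 -> 0``, pure exponential regrowth
through the data's tail) then *genuinely* attains a lower unweighted RSS
than the true basin — we verified that Levenberg–Marquardt slides into it
even when started at the true parameters.  Scaling residuals by the
prediction (with a 5-volume-unit floor standing in for the additive error
component) restores the information in the early treatment dip and removes
the degeneracy; plain unweighted fitting remains available as
``loss="absolute"``.

Details: optimisation is Levenberg–Marquardt on log parameters (positivity
by construction), objective tolerance 1e-10, finite-difference step 1e-4 in
log space (well above the ODE solver noise floor), five starts keeping the
best final objective: the central (population) value, a data-informed
start, and lognormal jitters (sd 0.3).  The data-informed start matters:
for animals whose growth rate sits far above the population value, the true
optimum occupies a narrow basin in the joint (growth, potency, baseline)
space next to a broad degenerate one, and plain jittered multi-starts can
miss it.  For drug-exposed fits the informed start is hierarchical — fix
the potency at a small grid (0.5x and 1x the central value), fit the
remaining docile parameters, seed the full fit from the best; for
unexposed fits it uses the first observation for ``w0`` and the steepest
windowed log-volume slope for ``lambda0``.  Robustness against wild trial steps: the RHS aborts immediately
on absurd states (|x| ≥ 1e100 or non-finite, which can otherwise stall
LSODA indefinitely), each solve has a 1e5 RHS-evaluation budget, and each
start is capped at 200 objective evaluations; an aborted evaluation counts
as a huge residual, so bad starts simply lose the multi-start comparison.  Drug potency `k2` is structurally unidentifiable in untreated
animals (concentration is identically zero) and is dropped from their free
set; animals with fewer than `len(free) + 2` observations are excluded with
a logged warning.  Control animals are integrated as the exact one-state
unperturbed equation (damage compartments stay empty without drug), which
is mathematically identical and ~4× faster.

The estimator's acceptance surface is simulate-and-refit recovery: 20
replicate cohorts at the default design give median relative bias < 10% and
relative RMSE < 25% for each of `lambda0, k2, w0`.

## Numerical and design choices

* Ties in regimen rankings are broken alphabetically (deterministic reports).
* "Control achieved" at day 50 is reported as two flags, not one verdict:
  better-than-bolus, and below `2·w0` absolute; the source claim is
  qualitative.
* Post-treatment rebound is reported as the sign of `dw/dt` at the horizon,
  never asserted for arbitrary parameters.
* Comparison CSVs are written with fixed float formatting; identical
  configurations reproduce byte-identical files.
* The empty schedule is a valid control regimen (total dose 0); individual
  dose amounts must still be positive.

## Known limitations

Single-compartment PK with bolus inputs only (no infusion, saturable
elimination or protein binding); no tumor heterogeneity, acquired
resistance, cumulative toxicity or saturable kill; two-stage estimation is
not a likelihood-based mixed-effects fit and provides no standard errors;
the fixed-delay formulation (removal term `k2 c(t−tau) x1(t−tau)`) is one
reasonable reconstruction of a delay-differential variant, and the transit
defaults (`psi = 20`, three compartments) are the standard published form
rather than values fitted to the original animal data.
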