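# Methods

## The model

`twopac` implements a two-phase description of aging for cohorts of a
short-lived organism (developed for *Drosophila melanogaster* and the
"Smurf" intestinal-permeability assay, but the mathematics is generic).
Life is split into two consecutive phases separated by an abrupt,
irreversible transition:

- **Phase 1** ("non-Smurf"): individuals cannot die, but face a hazard
  of transitioning to phase 2 that rises linearly with age,

      p(t) = a·t + b   for t > t0,   t0 = −b/a,

  where `a` (per day²) is the *daily failure rate* and `t0` (days) is
  the *tolerance* — the first age at which transitions can occur.
- **Phase 2** ("Smurf"): individuals die at a constant rate `k`
  (per day), independent of the age at which they transitioned, so an
  isolated phase-2 cohort decays as `exp(−k·t)` with characteristic
  time `τ = 1/k`.

With `u = t − t0` the phase-1 count obeys `dN/du = −a·u·N`, giving
`N(u) = P0·exp(−a·u²/2)`, and the living phase-2 count obeys
`dS/du = −k·S + a·u·N(u)` with `S(0) = 0`, whose solution is the
convolution

    S(u) = P0·a·∫₀ᵘ v·exp(−a·v²/2)·exp(−k·(u−v)) dv.

The whole-population survivorship is `π = N + S`. Although every
phase-2 individual dies at the same constant rate, the *apparent*
population mortality `−(1/π)·dπ/dt` rises with age because the phase
composition shifts — the central reinterpretation the model offers for
classical demographic observations (and likewise for "progressively"
rising biomarkers, via `mixture_trajectory`).

## Numerical choices

- **S(t) by adaptive quadrature.** The convolution admits a closed form
  in scaled error functions, but it suffers catastrophic cancellation
  at double precision for realistic parameters, so `smurf_count`
  evaluates the integral with adaptive Gauss–Kronrod quadrature
  (`scipy.integrate.quad`, abs tol 1e−10, rel tol 1e−8). Tests
  cross-check it against an independent RK4 integration of the ODE and
  a fine-step iterative scheme (three-route agreement within 1e−4).
- **Fitting hot loop.** Inside `fit_2pac` the same integral is
  evaluated by fixed 128-node Gauss–Legendre quadrature, vectorized
  over ages; it agrees with the adaptive path to ~1e−10 in the
  moderate-`k` regime where fitting operates (asserted in tests).
- **T50.** `t50` brackets the root of `π(t) = 0.5` by geometric
  expansion from `t0 + 1/k`, capped at
  `t0 + 10·sqrt(2·ln 1e6/a) + 20/k` (phase-1 extinction to 1e−6 plus
  ample phase-2 decay time), then solves with Brent's method to 1e−6
  day. Beyond the cap the median provably cannot lie except when `π`
  never reaches 0.5, which raises an error (near-immortal phase 2).
- **Discrete scheme.** `evolve` generalizes the daily spreadsheet-style
  recursion `N_t = N_{t−1} − p(t−0.5)·N_{t−1}` to arbitrary step `dt`
  by evaluating the hazard at the step midpoint and using
  `p = hazard·dt` clamped to [0, 1] (a per-step *probability* must not
  exceed 1, while the continuous hazard may). Phase-2 mass decays by
  the exact factor `exp(−k·dt)` per step; deaths are accumulated so
  that `N + S + dead = P0` holds to machine precision. Cohort-resolved
  and aggregated phase-2 bookkeeping are both available and agree to
  machine precision, since a constant `k` makes cohorts exchangeable.
  Evolution stops at `t_max` or when fewer than 1e−6·P0 remain alive.
  Observed convergence to the continuous solution is first order in
  `dt` (the operator splitting dominates the midpoint rule).
- **Time convention.** All public interfaces use absolute age in days;
  the shift to the onset origin is internal. The transition hazard is a
  rate (may exceed 1/day); only the discrete scheme speaks of per-step
  probabilities.

## Fitting

The estimation pipeline mirrors the two-step procedure used with real
assay data:

1. `fit_k`: least squares of the pooled phase-2 survival fractions
   (time measured from each individual's transition) against
   `exp(−k·t)` with the amplitude fixed at 1 — every phase-2 individual
   is alive at its own onset, so no prefactor is free. An optional
   nonparametric bootstrap over individual lifetimes (B = 1000 by
   convention; seeded) gives a percentile 95% CI.
2. `fit_2pac`: with `k` fixed, maximizes R² between observed
   whole-population survival fractions and the model curve over
   `(a, t0)`. R² is computed on survival fractions (not log-survival or
   mortality), matching how longevity curves are fitted in practice. A
   deterministic coarse grid (log-spaced `a` in [1e−5, 1], `t0` from 0
   to the first observed-death age) seeds Nelder–Mead refinement in
   `(log a, t0)`; the procedure is deterministic given the data.

   The forward model defaults to the continuous solution, which is the
   right likelihood-free target for event-level or individual-based
   data. `forward_dt` switches to the discrete scheme: data that were
   themselves produced by the daily recursion carry its O(dt) bias, and
   refitting them with the continuous curve would leak that bias into
   the estimates (~6% on `a` at dt = 1). With the forward model matched
   to the generator, round trips recover parameters to ~1e−11.
3. Comparators: `fit_gompertz` (`S = exp(−(A/k)(e^{kt}−1))`) and
   `fit_weibull` (`S = exp(−a·t^k)`) by `scipy.optimize.curve_fit`,
   with a log–log linearization seeding the Weibull fit. Both recover
   noiseless generating parameters to better than 1e−4 relative.
4. `fit_shared_k` applies `fit_2pac` across genotypes under one common
   `k` — the model's signature claim that phase-2 mortality is a
   genotype-independent constant — reporting per-curve `(a, t0, R²)`
   and the implied theoretical SIR.

## Survival statistics

- `empirical_t50`: linear interpolation of pooled survival at 50%.
- `sir`: the Smurf Increase Rate, the OLS slope of the per-vial
  proportion of living phase-2 individuals against age; each
  (vial, age) pair is one regression point and the denominator is the
  *living* count only (dead individuals leave the assay). Sufficient
  statistics are retained on the result object.
- `theoretical_sir`: the same regression computed on the deterministic
  proportion `S/(N+S)`, by default on a daily grid from `t0` until
  survivorship falls below 10% of P0. The source window for this
  statistic is not standardized; the 10% floor spans the range where a
  real assay still has vials to score. The slope is invariant under
  `t0` translation (the whole solution translates) and strictly
  increasing in `a`.
- `compare_sir`: classical two-regression slope-equality t-test with
  pooled residual variance and `n1 + n2 − 4` degrees of freedom, the
  documented method behind the slope-comparison feature of common
  biostatistics GUIs.
- `compare_medians`: two-sided Wilcoxon rank-sum (Mann–Whitney) test,
  exact for small tie-free samples, normal approximation with tie
  correction otherwise; the continuity correction is disabled so that
  identical samples give p = 1 exactly.

## The synthetic-cohort generator

`sample_cohort` draws, per individual, a continuous transition age by
inverse transform from `exp(−a·u²/2)` (`u = sqrt(−2·ln U/a)`) and an
exponential phase-2 lifetime at rate `k`; vials are assigned
round-robin for deterministic balance. Defaults correspond to the
reference longitudinal assay the model was built around: n = 1146
individuals scored daily, 4 replicate vials, followed to death
(censoring supported but off by default). The generator emulates the
statistical structure the model assumes — it does **not** model dye
scoring error, escapers, accidental deaths, age-dependent `k`, or the
empirical hint that early-transitioning individuals have more variable
phase-2 lifetimes. Passing recovery tests therefore demonstrates
internal consistency of estimator and model, not robustness of the
model on real cohorts.

Problem sizes used in tests and the acceptance script — 20 cohorts of
1146 individuals for recovery studies, daily grids to ~90 days,
dt = 1e−3 for oracle cross-checks — are chosen to keep sampling error
well inside the asserted tolerances while remaining quick to run.

## Known limitations

- Two phases only; more phases (several consecutive transitions with
  their own `t0`, `k`) are a natural extension but out of scope.
- `k` is strictly age- and genotype-independent within a fit;
  `fit_shared_k` tests that assumption rather than relaxing it.
- `fit_2pac` is least-squares on survival fractions, not an
  interval-censored maximum-likelihood estimator; with very small
  cohorts the (a, t0) estimates correlate strongly along a ridge.
- The discrete scheme's fractional individuals are deterministic;
  demographic stochasticity lives entirely in `sample_cohort`.
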