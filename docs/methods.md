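# Methods

## Model

The state variable is the age density `n(a, t)` of people with substance
use disorder (SUD): `n(a, t) da` people aged in `[a, a + da)` at time
`t`, with ages in `[0, 120]` years. It obeys the transport equation

```
(∂/∂a + ∂/∂t) n = −μ(a,t) n + p(a,t),    n(a, t₀) = ρ(a),  n(0, t) = 0,
```

i.e. everyone ages at unit rate, dies at rate `μ`, and new cases arrive
at rate `p`. The zero boundary encodes that nobody is born with SUD;
there is no recovery flux (leaving the compartment only happens through
death or aging past 120), which makes `n` closer to an "ever-affected,
still-alive" density than a point prevalence. The method of
characteristics gives the solution along lines `a − t = const`; points
with `a ≥ t − t₀` carry decayed initial data plus accumulated influx,
points with `a < t − t₀` only accumulated influx.

**Toy configuration.** `ρ = 0`, constant `μ`, `p(a) = a e^{−λa}`
(new cases peak at age `1/λ`, mean entry age `2/λ`). Density, time
derivative, steady state, and the ridge of maxima are closed-form. Two
numerical hazards are handled explicitly:

* `λ → μ` degeneracy: the closed forms divide by `(λ − μ)²`. Where
  `|λ − μ|·max(a, t) < 10⁻³` (the branch condition is per evaluation
  point; a fixed gap threshold alone would still cancel catastrophically
  at small `a`) a fourth-order series in `λ − μ` is used instead. The
  filter explores parameter space stochastically, so near-degenerate
  members do occur.
* the ridge formula `a_max(t)` cancels as `λ → μ` and at `t → 0`; both
  limits are series-evaluated (`a_max(0⁺) = 1/λ`).

**Overdose configuration.** Influx `r(a) N(t)` with
`r(a) = (r₀/2)[f₁ + f₂]`, a half/half mixture of gamma densities
(shapes `αᵢ`, rates `βᵢ`, means `αᵢ/βᵢ`), so `∫r = r₀` and `r₀` is the
per-capita addiction rate of the whole population per year. Total
population is the linear fit `N(t) = 274.9·10⁶ + 2.3·10⁶ (t − 2000)`
(calendar years), extrapolated back to the 1998 simulation start. The
substitution `μ → μ + r(a)`, `p → r N` maps this onto the general model;
the influx actually drawn from the susceptible pool `N − n` is
approximated by `r N` inside the closed forms (the same recast as the
transport equation above). Cumulative overdose deaths per year of age,
`D̃(a, t) = ∫₀ᵗ μ n dt′`, are an explicit state block so that the
measurement is linear in the state.

The filter's forecast step needs `∂n/∂t` at fixed age. Differentiating
the characteristic solution (Leibniz rule; `R(x) = ∫₀ˣ r` from the gamma
CDFs) gives

```
∂n/∂t = [a ≥ t] · r(a−t) N(0) e^{−μt − [R(a) − R(a−t)]}
        + ΔN ∫_{max(a−t,0)}^{a} r(σ) e^{−μ(a−σ) − [R(a) − R(σ)]} dσ .
```

Two implementations exist and cross-validate each other: a pointwise
adaptive-quadrature version (reference; also used by the tests against
central finite differences of the density at `h = 10⁻⁴`, agreeing to
better than `10⁻⁴` relative), and a vectorised grid version used inside
the filter, which evaluates the survival-weighted integral by the
trapezoid rule on the age grid with the moving lower limit placed by
linear interpolation of the cumulative integral. On the reference grid
(Δa = 0.12 yr) the grid version is accurate to ~10⁻³ relative in the far
tails and ~10⁻⁵ near the bulk, and Euler re-integration of it at
Δt = 0.01 rebuilds the density at t = 5 within 0.5%.

**Coarse-graining.** Reported counts live on 22 irregular age groups
(widths 1, 4, then nineteen 5-year groups, then 20). Bin values are
integrals of the age-density fields: cumulative trapezoid on the model
grid, constant extension over the final part-cell to age 120, and linear
interpolation of the cumulative integral at interior bin edges. By
telescoping, the 22 bins sum to the `[0, 120]` integral exactly.

## Filter

Perturbed-observation ensemble Kalman filter with explicit-Euler
forecasts (`χ⁻ₖ₊₁ = χₖ + Δt f(χₖ, tₖ) + ε`), unbiased (`M − 1`) sample
covariances, innovation covariance `P_zz = cov(h(χ)) + R`, gain by
symmetric linear solve, and per-member perturbed observations
`z + η⁽ⁱ⁾`. Parameters are stored as logarithms (exponentiated before
each model evaluation), which keeps every reported trajectory strictly
positive. No inflation or localisation is applied.

Reference configurations (all overridable):

| quantity | toy run | overdose run |
| --- | --- | --- |
| age cells `N_a` | 1000 (Δa = 0.12 yr) | same |
| time step | 0.1 yr, horizon 10 yr | 0.1 yr, horizon = data span (+ forecast) |
| ensemble `M` | 500 | 2000 (scaled-down; 10⁴ at full scale) |
| state dim | 1002 | 2006 |
| update cadence | every 5 steps | every 10 steps (yearly) |
| `x̂₀` | density 10⁻⁵, rate guesses 0.1/yr | empty state, (7·10⁻⁴, 0.04, 15, ⅓, 15, ⅓) |
| `P₀` (diagonal) | 0.5 density, 1 log-params | 10⁻⁴ state, 10⁻² log-params |
| `Q` | 10⁻⁴ per entry | same |
| `R` | diag(10⁻⁴), all 1000 cells observed | diag(10⁻⁴), 22 scaled bins |

Initial parameter guesses are natural-scale values; the state stores
their logs, and `P₀`'s parameter block applies on the log scale (an
order-of-magnitude prior for the toy run, a ±10% prior for the overdose
run).

**Process-noise sampling.** The process covariance has entry-wise
variance 10⁻⁴. Sampling it as a rank-one, fully correlated draw (the
all-ones covariance matrix read literally) injects fresh ensemble spread
along a single state direction only; after the first update collapses
the parameter spread, the two (toy) parameters can then never be
corrected independently, and estimates freeze ~10–20% off truth. With
independent per-entry draws of the same variance the filter reproduces
the expected behaviour — λ̂ within a few percent of truth by t ≈ 2 yr,
μ̂ by t ≈ 7 yr, both within 1% at t = 10 — so diagonal sampling is the
default; `ProcessNoise.ones` / `q_mode="ones"` selects the correlated
variant for comparison.

**Observation model.** Overdose observations are running sums of annual
per-bin counts divided by 10³ (so `R = diag(10⁻⁴)` means a standard
deviation of 10 deaths). Cumulative totals rather than annual counts are
assimilated; because last year's cumulative level is part of the
assimilated record, the two parameterisations carry the same innovation
and this is a presentation choice, not a statistical one. Annual tables
for reporting are member-wise differences of consecutive cumulative
predictions, with bands from the ensemble spread (3σ inside the data
span, 2σ for pure forecasts). Predictions for year `y` are recorded
*before* the year-`y` update, so predicted-vs-observed tables genuinely
use only prior data. When assimilating real exports that begin in 1999,
deaths the model accumulates during the 1998 spin-up year are not in the
data; the compartment starts empty, so this contributes a small
first-year bias only.

## Synthetic data

The toy generator evaluates the closed-form density on the grid at the
update times and adds i.i.d. `N(0, 10⁻⁴)` noise. The overdose generator
runs the model forward at chosen "true" parameters on a fine time grid
(Δt = 0.05 yr), accumulates `μ n` by trapezoid in time, coarse-grains at
year ends, differences to annual counts, adds Gaussian noise with
σ = 10 deaths per bin-year (the low end of the plausible reporting-noise
range, and exactly consistent with the filter's `R`), rounds, and clips
at zero. Output is a tab-delimited WONDER-style table that round-trips
through the reader.

Twin defaults: μ = 9·10⁻⁴/yr, r₀ = 0.05/yr, addiction-age means 35 and
55 yr (shapes kept at 15). These are moderate, demographically plausible
offsets from the assimilation starting guesses (7·10⁻⁴, 0.04, means
45/45): the filter must raise both rates and split the two age
components apart. What the generator does *not* emulate: age-dependent
mortality, cohort effects, migration, reporting-delay artefacts,
year-to-year drift of the addiction-age profile, and count suppression —
so passing twins show the estimation machinery is self-consistent, not
that the model captures all structure in real mortality data.

**Identifiability.** With μ of order 10⁻³/yr, the survival factor
`e^{−μ·age}` is nearly flat, so binned deaths are (to ~2%) a function of
the *product* μ·r₀ and of the mixture shape: μ and r₀ are individually
near-degenerate. In twin runs the product and both age means are
recovered within a few percent; along the degenerate direction the
posterior stays near the prior, so individual-rate errors are bounded by
roughly the prior offset (both rates land within 20% at the reference
twin conditions). Real-data trends in μ̂ and r̂₀ should be read with
this ridge in mind.

## Numerical choices

* Quadrature oracles: adaptive Gauss–Kronrod (`scipy.integrate.quad`)
  at abs/rel tolerance 10⁻¹⁰ (absolute tolerance scaled by the
  population size where the integrand is population-scaled); failures
  raise with the offending `(a, t)`.
* Ages are cell left edges; grid values are point evaluations of
  densities, not cell averages.
* Death accumulation is a rectangle rule per Euler step; negative
  density excursions (possible under filter noise) are clipped to zero
  in the death increment and logged, keeping cumulative deaths
  non-decreasing.
* `exp` arguments in the vectorised model tables are clipped at ±700 to
  survive extreme parameter excursions of individual members.
* Separate, labelled RNG streams (ensemble init, process noise,
  observation perturbations, data noise) derive from one seed; runs are
  bitwise reproducible.
* Reported parameter estimates are ensemble means of the natural-scale
  (exponentiated) parameters; bands are ±kσ of the same.

## Problem sizes

The test suite and the acceptance script run the toy twin at the full
reference configuration (M = 500, state dimension 1002, 100 steps; about
20 s per seed, five seeds) and the overdose twin at M = 2000 with 20
years of data (state dimension 2006, 200 steps; a few minutes). The
full-scale overdose run of M = 10⁴ changes only the ensemble size and
runs the same code path.

## Known limitations

* Mortality `μ` is age- and time-constant within each configuration;
  age-dependent `μ(a, t)` and age-structured `N(a, t)` are out of scope.
* The influx uses `r N` rather than `r (N − n)`; fine while `n ≪ N`.
* Explicit Euler is the only forecast integrator (kept deliberately, as
  the filter is defined around it); its O(Δt) bias at Δt = 0.1 yr is
  ~0.4% in density over a 10-year run.
* No ensemble inflation, localisation, or smoother passes.
* The Gaussian observation model is used even though counts are
  integers; for thinly populated bins (old-age groups) this is crude.
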