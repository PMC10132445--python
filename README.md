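# agemort

Age-structured modelling and ensemble-Kalman-filter data assimilation of
drug-overdose mortality.

Drug-overdose deaths in the United States are reported as annual counts
over irregular age groups. `agemort` couples a mechanistic age-structured
model of the population with substance use disorder (SUD) to these counts,
jointly estimating the model parameters and the latent age-resolved state,
and producing short-term forecasts with uncertainty bands. It is aimed at
quantitative epidemiologists and data-assimilation practitioners who want a
transparent, fully testable pipeline from closed-form PDE solutions to
age-binned mortality forecasts.

## The model

The density `n(a, t)` of people with SUD aged `a` at time `t` follows a
McKendrick-type transport equation

```
(∂/∂a + ∂/∂t) n(a, t) = −μ(a, t) n(a, t) + p(a, t),
```

with no inflow at age zero. Solved along characteristics `a − t = const`,
this gives closed forms for two configurations:

* **Toy case** — constant mortality `μ` and influx `p(a) = a e^{−λa}`:
  fully analytic density, rate of change, steady state, and the ridge of
  density maxima `a_max(t) = t / (1 − e^{−(λ−μ)t}) − μ / (λ(λ−μ))`.
* **Overdose case** — addiction influx `r(a) N(t)` with
  `r(a) = (r₀/2)[f₁(a; α₁, β₁) + f₂(a; α₂, β₂)]` a mixture of two gamma
  densities, linear population `N(t) = N₀ + ΔN·t`, and cumulative death
  densities `D̃(a, t) = ∫₀ᵗ μ n(a, t′) dt′` coarse-grained over the 22
  CDC age groups.

Estimation uses a perturbed-observation **ensemble Kalman filter** with
state augmentation: the unknown parameters (log-transformed to stay
positive) ride along in the state vector

```
x = [n(a₀,t), …, n(a_{Nₐ−1},t), D̃(a₀,t), …, D̃(a_{Nₐ−1},t), μ̃, r̃₀, α̃₁, β̃₁, α̃₂, β̃₂]
```

and are corrected through their sampled correlations with the observed
death counts, `K = P_xz P_zz⁻¹`.

## Worked example

```bash
python examples/toy_twin_filter.py
```

runs a twin experiment: noisy snapshots of the analytic density are
generated at known rates (μ = 0.08/yr, λ = 0.2/yr), then the filter
re-estimates both from data alone:

```
time   mu_hat   lam_hat   (truth: 0.0800, 0.2000)
 0.5   0.1113   0.2383
 1.0   0.1121   0.1896
 2.0   0.1065   0.1960
 5.0   0.0972   0.1889
10.0   0.0781   0.2005

lambda locks into a 10% band at t = 1.0 yr; mu at t = 8.5 yr.
```

The influx-shape rate λ is identified within a year because it controls
the whole age profile; the mortality rate μ needs several years of decay
signal to separate from it. `examples/overdose_assimilation.py` does the
same on synthetic age-binned overdose counts and prints parameter
recovery plus banded annual forecasts; `examples/analytic_model.py`
explores the closed forms.

The same pipelines are available from the shell:

```bash
agemort simulate --seed 1 --years 20 --out synthetic_wonder.tsv
agemort assimilate --data synthetic_wonder.tsv --out assim_out
agemort forecast --data synthetic_wonder.tsv --horizon 3 --out fc_out
```

`assimilate` and `forecast` accept real CDC WONDER exports (tab-delimited
year / age-group / deaths tables, "Suppressed" cells allowed) in the same
way.

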