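"""Reproducible experiment drivers.

Three experiments are wired here on top of the generic filter:

* the toy twin experiment -- recover (mu, lambda) of the closed-form
  model from noisy density snapshots;
* SUD assimilation -- yearly updates of the overdose model against
  age-binned cumulative death counts (real WONDER exports or synthetic
  twins), with joint estimation of (mu, r0, alpha1, beta1, alpha2, beta2);
* pure forecasting -- assimilate through the last data year, then run
  the ensemble forward and report predicted annual deaths with bands
  from the ensemble spread.

Default settings are the reference run conditions: age interval
[0, 120] years with 1000 cells, dt = 0.1 year, Q = 1e-4 * J (all-ones),
R = diag(1e-4), toy ensemble M = 500 with updates every 5 steps, SUD
updates yearly (every 10 steps), deaths scaled by 10^3 in the
measurement, population line N(t) anchored at 274.9e6 in 2000 growing by
2.3e6/year, simulations starting in 1998.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cdc_io import MortalityTable, to_cumulative
from .enkf import (
    FilterConfig,
    FilterDiagnostics,
    NoiseSpec,
    ProcessNoise,
    StateLayout,
    run_filter,
    untransform_params,
)
from .model_core import AgeTimeGrid, ToyParams
from .sud_model import (
    AgeBinSchema,
    DEATH_SCALE,
    PopulationModel,
    SUDParams,
    coarse_grain,
    sud_rate_profile,
)
from .synthetic_data import (
    CDCLikeData,
    TwinExperimentSpec,
    generate_cdc_like_counts,
    generate_toy_observations,
)

__all__ = [
    "TOY_TRUTH",
    "SUD_INITIAL_GUESS",
    "SUD_TWIN_TRUTH",
    "default_toy_grid",
    "default_sud_grid",
    "make_toy_rate_fn",
    "make_toy_measurement",
    "make_sud_rate_fn",
    "make_sud_measurement",
    "ToyTwinResult",
    "run_toy_twin",
    "SUDRunResult",
    "run_sud_assimilation",
    "run_sud_twin",
    "annual_predictions",
]

#: data-generating parameters of the toy twin experiment
TOY_TRUTH = ToyParams(mu=0.08, lam=0.2)

#: assimilation starting guesses for the overdose model: both addiction-age
#: components start at mean 45 years (shape 15, rate 1/3)
SUD_INITIAL_GUESS = SUDParams(
    mu=7e-4, r0=0.04, alpha1=15.0, beta1=1.0 / 3.0, alpha2=15.0, beta2=1.0 / 3.0
)

#: data-generating parameters of the scaled-down SUD twin: moderate,
#: demographically plausible offsets from the starting guesses (mortality
#: and base addiction rate shifted up, addiction-age components split to
#: means 35 and 55 years)
SUD_TWIN_TRUTH = SUDParams(
    mu=9e-4, r0=0.05, alpha1=15.0, beta1=15.0 / 35.0, alpha2=15.0, beta2=15.0 / 55.0
)


def _make_process_noise(q_mode: str, q_variance: float, dim: int) -> ProcessNoise:
    if q_mode in ("diagonal", "diag"):
        return ProcessNoise.diagonal(np.full(dim, q_variance))
    if q_mode == "ones":
        return ProcessNoise.ones(q_variance)
    if q_mode == "zero":
        return ProcessNoise.zero()
    raise ValueError(f"unknown q_mode {q_mode!r}")


def default_toy_grid(n_time: int = 100) -> AgeTimeGrid:
    return AgeTimeGrid(a_max=120.0, n_age=1000, delta_t=0.1, n_time=n_time)


def default_sud_grid(n_years: int) -> AgeTimeGrid:
    return AgeTimeGrid(a_max=120.0, n_age=1000, delta_t=0.1, n_time=10 * n_years)


# ---------------------------------------------------------------------------
# toy twin experiment
# ---------------------------------------------------------------------------

def make_toy_rate_fn(grid: AgeTimeGrid, layout: StateLayout):
    """Closed-form density rate, member-wise in (mu, lambda)."""
    ages = grid.ages

    def rate(members: np.ndarray, t: float) -> np.ndarray:
        params = untransform_params(members[:, layout.params], layout)
        mu = params[:, [0]]
        lam = params[:, [1]]
        u = ages[None, :] - t
        out = np.zeros_like(members)
        out[:, layout.density] = np.where(
            u >= 0.0, u * np.exp(-lam * u - mu * t), 0.0
        )
        return out

    return rate


def make_toy_measurement(layout: StateLayout):
    """The full density block is observed (identity on that block)."""

    def h(members: np.ndarray) -> np.ndarray:
        return members[:, layout.density]

    return h


@dataclass
class ToyTwinResult:
    """Twin-run output: filter diagnostics plus the generating conditions."""

    diagnostics: FilterDiagnostics
    truth: ToyParams
    grid: AgeTimeGrid
    obs_steps: np.ndarray

    @property
    def times(self) -> np.ndarray:
        return self.diagnostics.times

    @property
    def mu_hat(self) -> np.ndarray:
        return self.diagnostics.param_mean[:, 0]

    @property
    def lam_hat(self) -> np.ndarray:
        return self.diagnostics.param_mean[:, 1]

    def final_estimates(self) -> dict[str, float]:
        return {"mu": float(self.mu_hat[-1]), "lam": float(self.lam_hat[-1])}

    def convergence_time(self, name: str, rel_tol: float = 0.1) -> float:
        """Earliest time after which the estimate stays within ``rel_tol``
        relative error of its data-generating value for the rest of the run.
        Returns inf if it never locks in."""
        truth = {"mu": self.truth.mu, "lam": self.truth.lam}[name]
        traj = {"mu": self.mu_hat, "lam": self.lam_hat}[name]
        ok = np.abs(traj - truth) / truth < rel_tol
        locked = np.flip(np.logical_and.accumulate(np.flip(ok)))
        if not locked[-1]:
            return float("inf")
        return float(self.times[np.argmax(locked)])


def run_toy_twin(
    seed: int = 0,
    m: int = 500,
    grid: AgeTimeGrid | None = None,
    truth: ToyParams = TOY_TRUTH,
    obs_noise_variance: float = 1e-4,
    update_every: int = 5,
    q_variance: float = 1e-4,
    q_mode: str = "diagonal",
    r_variance: float = 1e-4,
    x0_density: float = 1e-5,
    param_guess: float = 0.1,
    p0_density: float = 0.5,
    p0_param: float = 1.0,
) -> ToyTwinResult:
    """The toy twin experiment with the reference settings.

    Observations are noisy snapshots of the closed-form density on the
    full age grid every ``update_every`` steps; the augmented state is
    [density, log mu, log lambda].  One seed drives independent streams
    for data noise and for the filter.

    ``q_mode`` selects how the process covariance of variance
    ``q_variance`` is sampled: "diagonal" (independent per-entry noise,
    the default -- see the methods note) or "ones" (one fully correlated
    draw per member, the rank-one all-ones covariance).  The latter
    injects spread only along a single state direction and cannot
    re-explore the two parameters independently after the first update.
    """
    grid = grid or default_toy_grid()
    data_seed, filter_seed = (
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(2)
    )
    schedule = grid.t0 + grid.delta_t * np.arange(
        update_every, grid.n_time + 1, update_every
    )
    obs = generate_toy_observations(
        TwinExperimentSpec(
            true_params=truth,
            obs_noise_variance=obs_noise_variance,
            schedule=tuple(schedule),
            seed=data_seed,
        ),
        grid,
    )

    layout = StateLayout(
        n_density=grid.n_age, param_names=("mu", "lam"), log_params=(True, True)
    )
    x0 = np.concatenate(
        [np.full(grid.n_age, x0_density), np.log([param_guess, param_guess])]
    )
    p0 = np.concatenate([np.full(grid.n_age, p0_density), [p0_param, p0_param]])
    config = FilterConfig(
        layout=layout,
        x0=x0,
        p0=p0,
        m=m,
        noise=NoiseSpec(
            Q=_make_process_noise(q_mode, q_variance, layout.dim),
            R=np.full(grid.n_age, r_variance),
        ),
        delta_t=grid.delta_t,
        n_steps=grid.n_time,
        seed=filter_seed,
    )
    diag = run_filter(
        make_toy_rate_fn(grid, layout),
        make_toy_measurement(layout),
        obs.as_mapping(),
        config,
    )
    return ToyTwinResult(diagnostics=diag, truth=truth, grid=grid, obs_steps=obs.steps)


# ---------------------------------------------------------------------------
# SUD assimilation
# ---------------------------------------------------------------------------

def make_sud_rate_fn(grid: AgeTimeGrid, layout: StateLayout, pop: PopulationModel):
    """State derivative of the augmented overdose state.

    The density block follows the closed-form rate at each member's own
    parameters; the cumulative-death block grows as mu * max(n, 0); the
    parameter block has zero drift.
    """
    ages = grid.ages

    def rate(members: np.ndarray, t: float) -> np.ndarray:
        params = untransform_params(members[:, layout.params], layout)
        mu, r0, a1, b1, a2, b2 = (params[:, [j]] for j in range(6))
        out = np.zeros_like(members)
        out[:, layout.density] = sud_rate_profile(
            ages, t, mu, r0, a1, b1, a2, b2, pop
        )
        out[:, layout.deaths] = mu * np.maximum(members[:, layout.density], 0.0)
        return out

    return rate


def make_sud_measurement(
    grid: AgeTimeGrid, layout: StateLayout, schema: AgeBinSchema,
    scale: float = DEATH_SCALE,
):
    """Coarse-grained cumulative deaths, divided by the death scale."""

    def h(members: np.ndarray) -> np.ndarray:
        return coarse_grain(members[:, layout.deaths], schema, grid) / scale

    return h


@dataclass
class SUDRunResult:
    """Assimilation output and everything needed to interpret it."""

    diagnostics: FilterDiagnostics
    grid: AgeTimeGrid
    schema: AgeBinSchema
    pop: PopulationModel
    start_year: int
    data_years: np.ndarray
    observed_annual: np.ndarray = field(repr=False)
    observed_cumulative: np.ndarray = field(repr=False)
    forecast_years: np.ndarray = field(default_factory=lambda: np.array([], int))

    PARAM_NAMES = ("mu", "r0", "alpha1", "beta1", "alpha2", "beta2")

    @property
    def times(self) -> np.ndarray:
        return self.diagnostics.times

    def param_trajectory(self, name: str) -> np.ndarray:
        return self.diagnostics.param_mean[:, self.PARAM_NAMES.index(name)]

    def final_params(self) -> SUDParams:
        return SUDParams.from_array(self.diagnostics.param_mean[-1])

    def final_mean_ages(self) -> tuple[float, float]:
        p = self.final_params()
        return p.mean_age_1, p.mean_age_2

    def year_step(self, year: int) -> int:
        """Model step at which the cumulative count through ``year`` is due."""
        return 10 * (int(year) - self.start_year + 1)


def _year_steps(years: np.ndarray, start_year: int) -> np.ndarray:
    return 10 * (np.asarray(years, dtype=int) - start_year + 1)


def run_sud_assimilation(
    table: MortalityTable,
    seed: int = 0,
    m: int = 2000,
    start_year: int = 1998,
    horizon: int = 0,
    initial_guess: SUDParams = SUD_INITIAL_GUESS,
    pop: PopulationModel | None = None,
    grid: AgeTimeGrid | None = None,
    q_variance: float = 1e-4,
    q_mode: str = "diagonal",
    r_variance: float = 1e-4,
    p0_state: float = 1e-4,
    p0_param: float = 1e-2,
) -> SUDRunResult:
    """Yearly assimilation of age-binned death counts, then ``horizon``
    years of pure forecasting.

    The model clock starts at ``start_year`` with an empty SUD
    compartment; the cumulative count through calendar year ``y`` is
    assimilated at model time ``y - start_year + 1`` (data for a year
    becomes available at its end).  Observations are running sums of the
    annual counts divided by 10^3; prior predicted observations are
    recorded at every year end so annual predicted-vs-observed tables and
    forecast bands can be formed.
    """
    pop = pop or PopulationModel.from_calendar(start_year=start_year)
    schema = table.schema
    last_year = int(table.years[-1])
    n_years_total = last_year - start_year + 1 + horizon
    grid = grid or default_sud_grid(n_years_total)
    if grid.n_time < 10 * n_years_total:
        raise ValueError("grid horizon too short for the data plus forecast")

    cumulative = to_cumulative(table)  # (n_years, 22) counts
    obs_steps = _year_steps(table.years, start_year)
    if np.any(obs_steps < 1):
        raise ValueError(
            f"data years {table.years.tolist()} precede the simulation start "
            f"{start_year}"
        )
    observations = {
        int(k): cumulative[i] / DEATH_SCALE for i, k in enumerate(obs_steps)
    }

    layout = StateLayout(
        n_density=grid.n_age,
        n_deaths=grid.n_age,
        param_names=SUDRunResult.PARAM_NAMES,
        log_params=(True,) * 6,
    )
    x0 = np.concatenate(
        [np.zeros(2 * grid.n_age), np.log(initial_guess.as_array())]
    )
    p0 = np.concatenate([np.full(2 * grid.n_age, p0_state), np.full(6, p0_param)])
    config = FilterConfig(
        layout=layout,
        x0=x0,
        p0=p0,
        m=m,
        noise=NoiseSpec(
            Q=_make_process_noise(q_mode, q_variance, layout.dim),
            R=np.full(22, r_variance),
        ),
        delta_t=grid.delta_t,
        n_steps=grid.n_time,
        seed=seed,
    )
    forecast_years = last_year + 1 + np.arange(horizon, dtype=int)
    report_steps = _year_steps(
        np.concatenate([table.years, forecast_years]), start_year
    )
    diag = run_filter(
        make_sud_rate_fn(grid, layout, pop),
        make_sud_measurement(grid, layout, schema),
        observations,
        config,
        report_obs_steps=report_steps,
    )
    return SUDRunResult(
        diagnostics=diag,
        grid=grid,
        schema=schema,
        pop=pop,
        start_year=start_year,
        data_years=table.years.copy(),
        observed_annual=table.deaths.copy(),
        observed_cumulative=cumulative,
        forecast_years=forecast_years,
    )


def annual_predictions(result: SUDRunResult) -> dict[int, dict[str, np.ndarray]]:
    """Per-year predicted annual deaths (counts) with ensemble spread.

    For each year the prediction uses only data through the previous year
    (the prior ensemble at the year's end, before its update).  Annual
    member-level predictions are differences of cumulative predictions at
    consecutive year ends; for the first reported year the previous
    cumulative level is the assimilated observation when available.
    Returns ``{year: {"mean": (22,), "sigma": (22,), "observed": (22,)|None}}``.
    """
    out: dict[int, dict[str, np.ndarray]] = {}
    members = result.diagnostics.reported_obs_members
    all_years = np.concatenate([result.data_years, result.forecast_years])
    cum_by_year = {
        int(y): result.observed_cumulative[i]
        for i, y in enumerate(result.data_years)
    }
    for year in map(int, all_years):
        step = result.year_step(year)
        if step not in members:
            continue
        z_now = members[step] * DEATH_SCALE  # (M, 22) cumulative counts
        prev_year = year - 1
        prev_step = result.year_step(prev_year)
        if prev_year in cum_by_year:
            z_prev = cum_by_year[prev_year][None, :]
        elif prev_step in members:
            z_prev = members[prev_step] * DEATH_SCALE
        else:  # first data year: cumulative equals annual
            z_prev = np.zeros((1, result.schema.n_bins))
        annual = z_now - z_prev
        observed = None
        idx = np.nonzero(result.data_years == year)[0]
        if idx.size:
            observed = result.observed_annual[idx[0]]
        out[year] = {
            "mean": annual.mean(axis=0),
            "sigma": annual.std(axis=0, ddof=1),
            "observed": observed,
        }
    return out


def run_sud_twin(
    seed: int = 0,
    m: int = 2000,
    n_years: int = 20,
    truth: SUDParams = SUD_TWIN_TRUTH,
    obs_noise_variance: float = 1e-4,
    start_year: int = 1998,
    horizon: int = 0,
    grid: AgeTimeGrid | None = None,
    **filter_kwargs,
) -> tuple[SUDRunResult, CDCLikeData]:
    """Scaled-down SUD twin: synthetic WONDER-style counts at known
    parameters, then yearly assimilation from the standard starting
    guesses (plus ``horizon`` years of pure forecasting).  One seed
    drives independent data and filter streams."""
    data_seed, filter_seed = (
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(2)
    )
    grid = grid or default_sud_grid(n_years)
    pop = PopulationModel.from_calendar(start_year=start_year)
    data = generate_cdc_like_counts(
        TwinExperimentSpec(
            true_params=truth,
            obs_noise_variance=obs_noise_variance,
            seed=data_seed,
        ),
        schema=AgeBinSchema.cdc_22(),
        grid=grid,
        pop=pop,
        start_year=start_year,
        n_years=n_years,
    )
    filter_grid = grid if horizon == 0 else default_sud_grid(n_years + horizon)
    result = run_sud_assimilation(
        data.table,
        seed=filter_seed,
        m=m,
        start_year=start_year,
        horizon=horizon,
        pop=pop,
        grid=filter_grid,
        **filter_kwargs,
    )
    return result, data
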