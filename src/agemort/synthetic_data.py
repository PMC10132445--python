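"""Twin-experiment observation generators.

A twin experiment generates observations from the model itself at known
("true") parameters, then checks that the filter recovers them.  Two
generators are provided:

* :func:`generate_toy_observations` -- noisy snapshots of the closed-form
  toy density on the age grid (the density itself is observed);
* :func:`generate_cdc_like_counts` -- age-binned annual overdose death
  counts in the WONDER export dialect, produced by running the SUD model
  forward, coarse-graining cumulative deaths at year ends, differencing
  to annual counts and adding rounded Gaussian observation noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate

from .cdc_io import MortalityTable
from .model_core import AgeTimeGrid, ToyParams, toy_density
from .sud_model import (
    AgeBinSchema,
    DEATH_SCALE,
    PopulationModel,
    SUDParams,
    coarse_grain,
    sud_density_profile,
)

__all__ = [
    "TwinExperimentSpec",
    "ToyObservations",
    "CDCLikeData",
    "generate_toy_observations",
    "generate_cdc_like_counts",
]


@dataclass(frozen=True)
class TwinExperimentSpec:
    """Study conditions of a twin experiment.

    true_params        -- data-generating ToyParams or SUDParams
    obs_noise_variance -- Gaussian observation-noise variance on the
                          observed scale: (persons/year)^2 for the toy
                          density, scaled-deaths^2 (counts / 10^3) for the
                          binned counts
    schedule           -- observation times in years (within the horizon)
    seed               -- RNG seed for the noise draws
    """

    true_params: ToyParams | SUDParams
    obs_noise_variance: float = 1e-4
    schedule: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.obs_noise_variance < 0:
            raise ValueError("obs_noise_variance must be >= 0")


@dataclass
class ToyObservations:
    """Truth and noisy observations of the toy density on the age grid."""

    grid: AgeTimeGrid
    steps: np.ndarray                  # observation step indices
    times: np.ndarray                  # observation times (years)
    truth: np.ndarray = field(repr=False)      # (n_obs, n_age)
    observed: np.ndarray = field(repr=False)   # (n_obs, n_age)

    def as_mapping(self) -> dict[int, np.ndarray]:
        return {int(k): self.observed[i] for i, k in enumerate(self.steps)}


def _schedule_steps(schedule: Sequence[float], grid: AgeTimeGrid) -> np.ndarray:
    times = np.asarray(schedule, dtype=float)
    if times.size == 0:
        raise ValueError("observation schedule is empty")
    steps = (times - grid.t0) / grid.delta_t
    rounded = np.rint(steps)
    if np.any(np.abs(steps - rounded) > 1e-9) or np.any(rounded < 1) or np.any(
        rounded > grid.n_time
    ):
        raise ValueError(
            f"schedule {times.tolist()} must lie on the time grid "
            f"(dt={grid.delta_t}, horizon={grid.horizon})"
        )
    return rounded.astype(int)


def generate_toy_observations(
    spec: TwinExperimentSpec, grid: AgeTimeGrid
) -> ToyObservations:
    """Closed-form toy density plus i.i.d. Gaussian observation noise.

    Zero noise variance returns the analytic field exactly; different
    seeds change the noise but never the truth.
    """
    if not isinstance(spec.true_params, ToyParams):
        raise TypeError("toy observations need ToyParams truth")
    steps = _schedule_steps(spec.schedule, grid)
    times = grid.t0 + grid.delta_t * steps
    truth = np.stack([toy_density(grid.ages, t, spec.true_params) for t in times])
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, np.sqrt(spec.obs_noise_variance), size=truth.shape)
    return ToyObservations(
        grid=grid, steps=steps, times=times, truth=truth, observed=truth + noise
    )


@dataclass
class CDCLikeData:
    """Synthetic WONDER-style counts plus the noise-free model truth."""

    table: MortalityTable
    truth_annual: np.ndarray = field(repr=False)       # (n_years, 22), deaths
    truth_cumulative: np.ndarray = field(repr=False)   # (n_years, 22), deaths
    params: SUDParams = None
    pop: PopulationModel = None
    start_year: int = 1998


def generate_cdc_like_counts(
    spec: TwinExperimentSpec,
    schema: AgeBinSchema,
    grid: AgeTimeGrid,
    pop: PopulationModel,
    start_year: int = 1998,
    n_years: int = 20,
    dt_data: float = 0.05,
) -> CDCLikeData:
    """Age-binned annual death counts from a forward SUD-model run.

    The SUD density starts empty at ``start_year`` (model time 0); the
    cumulative death density ``mu * int n dt`` is built on a fine time
    grid (``dt_data``), coarse-grained over the 22 bins at year ends and
    differenced to annual counts.  Gaussian noise with standard deviation
    ``sqrt(obs_noise_variance) * 1000`` deaths is added, then counts are
    rounded and clipped at zero (real counts are integers; the Gaussian
    observation model is kept for assimilation regardless).
    """
    if not isinstance(spec.true_params, SUDParams):
        raise TypeError("CDC-like counts need SUDParams truth")
    p = spec.true_params
    steps_per_year = int(round(1.0 / dt_data))
    times = dt_data * np.arange(n_years * steps_per_year + 1)
    profiles = np.stack(
        [sud_density_profile(grid, t, p, pop).values for t in times]
    )  # (n_times, n_age)
    death_density = p.mu * integrate.cumulative_trapezoid(
        profiles, times, axis=0, initial=0.0
    )
    year_index = steps_per_year * np.arange(1, n_years + 1)
    cumulative_bins = coarse_grain(death_density[year_index], schema, grid)
    annual = np.diff(np.vstack([np.zeros(schema.n_bins), cumulative_bins]), axis=0)

    rng = np.random.default_rng(spec.seed)
    sd_counts = np.sqrt(spec.obs_noise_variance) * DEATH_SCALE
    noisy = annual + rng.normal(0.0, sd_counts, size=annual.shape)
    counts = np.maximum(np.rint(noisy), 0.0)

    years = start_year + np.arange(n_years)
    table = MortalityTable(
        years=years,
        schema=schema,
        deaths=counts,
        suppressed=np.zeros_like(counts, dtype=bool),
    )
    return CDCLikeData(
        table=table,
        truth_annual=annual,
        truth_cumulative=cumulative_bins,
        params=p,
        pop=pop,
        start_year=start_year,
    )
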