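"""Drug-overdose adaptation of the age-structured model.

A population of size ``N(t)`` (linear in time) feeds a substance-use-
disorder (SUD) compartment through an age-dependent addiction rate

    r(a) = (r0 / 2) [ f1(a; alpha1, beta1) + f2(a; alpha2, beta2) ],

a half/half mixture of two gamma densities (shape ``alpha_i``, rate
``beta_i``), so that ``r`` integrates to the base modulating rate ``r0``
over all ages.  The SUD density obeys the transport model with effective
mortality ``mu + r(a)`` and influx ``r(a) N(t)``; overdose deaths
accumulate per age cell as ``Dtilde(a, t) = int_0^t mu n(a, t') dt'``
(a density in age: deaths per year of age).  Reported mortality data are
age-binned, so a coarse-graining operator integrates ``Dtilde`` over the
22 irregular CDC age groups.

Closed forms used throughout (``R(x) = int_0^x r``, available through the
gamma CDFs; population start value ``N(0)`` and slope ``dN``):

    n(a, t)     = int_{max(a-t,0)}^{a} r(s) N(s + t - a)
                      e^{-mu (a - s) - [R(a) - R(s)]} ds
    dn/dt(a,t)  = [a >= t] r(a-t) N(0) e^{-mu t - [R(a) - R(a-t)]}
                  + dN int_{max(a-t,0)}^{a} r(s) e^{-mu (a-s) - [R(a)-R(s)]} ds

The second line is the rate of change driving the filter forecast; like
the density itself it follows from differentiating the characteristic
solution and does not depend on the current density state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate, special

from .model_core import AgeTimeGrid, DensityField, QuadratureError

__all__ = [
    "SUDParams",
    "PopulationModel",
    "CumulativeDeathField",
    "AgeBinSchema",
    "addiction_rate",
    "cumulative_addiction_integral",
    "sud_density",
    "sud_rate_of_change",
    "sud_density_profile",
    "sud_rate_profile",
    "accumulate_deaths",
    "coarse_grain",
    "DEATH_SCALE",
]

logger = logging.getLogger(__name__)

#: cumulative deaths are divided by this inside the measurement so the
#: assimilated numbers are O(1)-O(100)
DEATH_SCALE = 1e3

_EXP_CLIP = 700.0  # exp() overflow guard for extreme filter excursions


@dataclass(frozen=True)
class SUDParams:
    """Estimands of the overdose model (all strictly positive).

    mu      -- per-year overdose mortality rate of the SUD population
    r0      -- per-year base modulating addiction rate
    alpha1, beta1, alpha2, beta2 -- gamma shape (dimensionless) and rate
               (per year) parameters of the two addiction-age components;
               component means are alpha_i / beta_i years.
    """

    mu: float
    r0: float
    alpha1: float
    beta1: float
    alpha2: float
    beta2: float

    def __post_init__(self) -> None:
        for name in ("mu", "r0", "alpha1", "beta1", "alpha2", "beta2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    @property
    def mean_age_1(self) -> float:
        return self.alpha1 / self.beta1

    @property
    def mean_age_2(self) -> float:
        return self.alpha2 / self.beta2

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.mu, self.r0, self.alpha1, self.beta1, self.alpha2, self.beta2]
        )

    @classmethod
    def from_array(cls, v: Sequence[float]) -> "SUDParams":
        return cls(*map(float, v))


@dataclass(frozen=True)
class PopulationModel:
    """Total population N(t) = n0 + delta_n * t, in model time (years).

    ``from_calendar`` maps census-style anchored values onto a model clock
    that starts at ``start_year``; the line is extrapolated linearly
    outside the anchored range.
    """

    n0: float
    delta_n: float

    def __post_init__(self) -> None:
        if self.n0 <= 0:
            raise ValueError("n0 must be positive")

    def __call__(self, t):
        return self.n0 + self.delta_n * np.asarray(t, dtype=float)

    @classmethod
    def from_calendar(
        cls,
        n_anchor: float = 274.9e6,
        delta_n: float = 2.3e6,
        anchor_year: float = 2000.0,
        start_year: float = 1998.0,
    ) -> "PopulationModel":
        return cls(n0=n_anchor + delta_n * (start_year - anchor_year), delta_n=delta_n)


# ---------------------------------------------------------------------------
# addiction rate and its integral
# ---------------------------------------------------------------------------

def _mixture_pdf(a, p_or_arrays):
    """0.5 (f1 + f2) with non-finite values (shape < 1 at a = 0) zeroed."""
    if isinstance(p_or_arrays, SUDParams):
        a1, b1, a2, b2 = (
            p_or_arrays.alpha1,
            p_or_arrays.beta1,
            p_or_arrays.alpha2,
            p_or_arrays.beta2,
        )
    else:
        a1, b1, a2, b2 = p_or_arrays
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        pdf = 0.5 * (
            _gamma_pdf(a, a1, b1) + _gamma_pdf(a, a2, b2)
        )
    return np.where(np.isfinite(pdf), pdf, 0.0)


def _gamma_pdf(x, shape, rate):
    x = np.asarray(x, dtype=float)
    logpdf = (
        shape * np.log(rate)
        - special.gammaln(shape)
        + special.xlogy(shape - 1.0, x)
        - rate * x
    )
    return np.exp(np.clip(logpdf, -_EXP_CLIP, _EXP_CLIP))


def addiction_rate(a, p: SUDParams):
    """r(a) = (r0/2) [f1(a) + f2(a)]; integrates to r0 over a in [0, inf)."""
    return p.r0 * _mixture_pdf(np.asarray(a, dtype=float), p)


def cumulative_addiction_integral(a_lo, a_hi, p: SUDParams):
    """Closed form of int_{a_lo}^{a_hi} r(s) ds via the gamma CDFs."""
    a_lo = np.asarray(a_lo, dtype=float)
    a_hi = np.asarray(a_hi, dtype=float)
    if np.any(a_lo < 0) or np.any(a_hi < a_lo):
        raise ValueError("need 0 <= a_lo <= a_hi")

    def cdf(x):
        x = np.where(np.isinf(x), np.inf, x)
        return 0.5 * (
            special.gammainc(p.alpha1, p.beta1 * x)
            + special.gammainc(p.alpha2, p.beta2 * x)
        )

    out = p.r0 * (cdf(a_hi) - cdf(a_lo))
    return out if out.ndim else float(out)


def _cumulative_rate(a, p: SUDParams):
    """R(a) = int_0^a r, vectorised, a >= 0."""
    a = np.asarray(a, dtype=float)
    return p.r0 * 0.5 * (
        special.gammainc(p.alpha1, p.beta1 * a)
        + special.gammainc(p.alpha2, p.beta2 * a)
    )


# ---------------------------------------------------------------------------
# pointwise density and rate (quadrature; the trustworthy reference path)
# ---------------------------------------------------------------------------

def _quad(fn, lo, hi, where, epsabs=1e-10, epsrel=1e-10):
    if hi <= lo:
        return 0.0
    val, err = integrate.quad(fn, lo, hi, epsabs=epsabs, epsrel=epsrel, limit=200)
    if not np.isfinite(val):
        raise QuadratureError(f"quadrature failed at (a, t) = {where}")
    return val


def sud_density(
    a: float, t: float, p: SUDParams, pop: PopulationModel, tol: float = 1e-10
) -> float:
    """SUD density n(a, t) from the characteristic solution (scalar).

    Starts from an empty compartment, n(a, 0) = 0.  The exponent uses the
    closed-form cumulative addiction integral; one adaptive quadrature
    remains over the influx along the characteristic.
    """
    a, t = float(a), float(t)
    if a < 0 or t < 0:
        raise ValueError("need a >= 0 and t >= 0")
    if t == 0.0 or a == 0.0:
        return 0.0
    r_a = _cumulative_rate(a, p)

    def integrand(s):
        return (
            addiction_rate(s, p)
            * pop(s + t - a)
            * np.exp(-p.mu * (a - s) - (r_a - _cumulative_rate(s, p)))
        )

    lo = max(a - t, 0.0)
    # the scale of n is set by pop ~ 1e8, so scale the absolute tolerance
    return _quad(
        integrand, lo, a, (a, t), epsabs=tol * max(1.0, float(pop(t))), epsrel=tol
    )


def sud_rate_of_change(
    a: float, t: float, p: SUDParams, pop: PopulationModel, tol: float = 1e-10
) -> float:
    """dn/dt at fixed age for the SUD model (scalar).

    Obtained by Leibniz differentiation of the characteristic solution:
    a boundary term from the moving lower limit (only when ``a >= t``)
    plus the population-growth term ``delta_n`` times the survival-weighted
    addiction integral.  Matches central finite differences of
    :func:`sud_density` to O(h^2).
    """
    a, t = float(a), float(t)
    if a < 0 or t < 0:
        raise ValueError("need a >= 0 and t >= 0")
    if a == 0.0:
        return 0.0
    r_a = _cumulative_rate(a, p)
    lo = max(a - t, 0.0)

    boundary = 0.0
    if a >= t:
        boundary = float(
            addiction_rate(a - t, p)
            * pop(0.0)
            * np.exp(-p.mu * t - (r_a - _cumulative_rate(a - t, p)))
        )

    def integrand(s):
        return addiction_rate(s, p) * np.exp(
            -p.mu * (a - s) - (r_a - _cumulative_rate(s, p))
        )

    growth = pop.delta_n * _quad(integrand, lo, a, (a, t), epsabs=tol, epsrel=tol)
    return boundary + growth


# ---------------------------------------------------------------------------
# vectorised grid evaluators (filter forecast path and data generation)
# ---------------------------------------------------------------------------

def _grid_tables(ages: np.ndarray, mu, r0, a1, b1, a2, b2):
    """Per-member mixture tables on the age grid.

    Parameters may be scalars or column vectors of shape (M, 1); returns
    r(a), R(a) and the exp-weighted integrand G = r e^{mu a + R(a)}
    broadcast to (M, n_age).
    """
    pdf = _mixture_pdf(ages, (a1, b1, a2, b2))
    r = r0 * pdf
    big_r = r0 * 0.5 * (
        special.gammainc(a1, b1 * ages) + special.gammainc(a2, b2 * ages)
    )
    expo = np.clip(mu * ages + big_r, -_EXP_CLIP, _EXP_CLIP)
    g = r * np.exp(expo)
    return r, big_r, g


def _interp_columns(table: np.ndarray, ages: np.ndarray, positions: np.ndarray):
    """Linear interpolation of per-member row tables at shared positions."""
    delta_a = ages[1] - ages[0]
    pos = np.clip((positions - ages[0]) / delta_a, 0.0, len(ages) - 1.0)
    i0 = np.minimum(pos.astype(int), len(ages) - 2)
    w = pos - i0
    return (1.0 - w) * table[..., i0] + w * table[..., i0 + 1]


def sud_rate_profile(
    ages: np.ndarray,
    t: float,
    mu,
    r0,
    a1,
    b1,
    a2,
    b2,
    pop: PopulationModel,
) -> np.ndarray:
    """dn/dt on the whole age grid, vectorised over ensemble members.

    Scalar parameters give a (n_age,) profile; (M, 1) column parameters a
    (M, n_age) array.  The survival-weighted integral is evaluated by the
    trapezoid rule on the grid, with the moving lower limit ``a - t``
    placed by linear interpolation of the cumulative integral.
    """
    ages = np.asarray(ages, dtype=float)
    r, big_r, g = _grid_tables(ages, mu, r0, a1, b1, a2, b2)
    c = integrate.cumulative_trapezoid(g, ages, axis=-1, initial=0.0)

    lo = np.maximum(ages - t, 0.0)
    c_lo = _interp_columns(c, ages, lo)
    decay = np.exp(np.clip(-mu * ages - big_r, -_EXP_CLIP, _EXP_CLIP))
    growth = pop.delta_n * decay * (c - c_lo)

    entered = ages >= t
    r_lo = _interp_columns(r, ages, lo)
    big_r_lo = _interp_columns(big_r, ages, lo)
    survival = np.exp(np.clip(-mu * t - (big_r - big_r_lo), -_EXP_CLIP, _EXP_CLIP))
    boundary = np.where(entered, r_lo * pop(0.0) * survival, 0.0)
    return boundary + growth


def sud_density_profile(
    grid: AgeTimeGrid, t: float, p: SUDParams, pop: PopulationModel
) -> DensityField:
    """n(a, t) on the whole age grid from the characteristic solution.

    Splits the influx integral into its population-level and growth parts,
    both cumulative-trapezoid integrals of time-independent tables, so a
    full time series costs one table build plus O(n_age) per time point.
    """
    ages = grid.ages
    r, big_r, g = _grid_tables(ages, p.mu, p.r0, p.alpha1, p.beta1, p.alpha2, p.beta2)
    c0 = integrate.cumulative_trapezoid(g, ages, axis=-1, initial=0.0)
    c1 = integrate.cumulative_trapezoid(ages * g, ages, axis=-1, initial=0.0)

    lo = np.maximum(ages - t, 0.0)
    c0_lo = _interp_columns(c0, ages, lo)
    c1_lo = _interp_columns(c1, ages, lo)
    decay = np.exp(np.clip(-p.mu * ages - big_r, -_EXP_CLIP, _EXP_CLIP))
    n_base = pop(t - ages)  # N(t - a); the sigma-weighted part carries delta_n
    values = decay * (n_base * (c0 - c0_lo) + pop.delta_n * (c1 - c1_lo))
    return DensityField(grid=grid, t=t, values=np.maximum(values, 0.0))


# ---------------------------------------------------------------------------
# cumulative deaths and coarse-graining
# ---------------------------------------------------------------------------

@dataclass
class CumulativeDeathField:
    """Cumulative overdose deaths per year of age since t = 0.

    ``values[j]`` approximates Dtilde(a_j, t) = int_0^t mu n(a_j, t') dt';
    like the density it is an age density, and bin-level counts follow by
    integrating it over age windows (:func:`coarse_grain`).
    """

    grid: AgeTimeGrid
    t: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_age,):
            raise ValueError(
                f"values must have shape ({self.grid.n_age},), got {self.values.shape}"
            )

    @classmethod
    def zeros(cls, grid: AgeTimeGrid) -> "CumulativeDeathField":
        return cls(grid=grid, t=0.0, values=np.zeros(grid.n_age))


def accumulate_deaths(
    d_prev: CumulativeDeathField,
    n_now: DensityField,
    mu: float,
    delta_t: float,
) -> CumulativeDeathField:
    """One rectangle-rule step of the cumulative death integral,

        Dtilde(a_j, t + dt) = Dtilde(a_j, t) + dt * mu * max(n(a_j, t), 0).

    Negative density values (possible under filter noise) are clipped to
    zero for the death increment so the field stays non-decreasing.
    """
    if d_prev.grid is not n_now.grid and d_prev.grid != n_now.grid:
        raise ValueError("death and density fields must share one grid")
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    n = n_now.values
    if np.any(n < 0):
        logger.warning(
            "clipping %d negative density values in death accumulation",
            int(np.sum(n < 0)),
        )
        n = np.maximum(n, 0.0)
    return CumulativeDeathField(
        grid=d_prev.grid, t=d_prev.t + delta_t, values=d_prev.values + delta_t * mu * n
    )


@dataclass(frozen=True)
class AgeBinSchema:
    """The 22 irregular age groups of the mortality data.

    Edges are 23 ascending ages covering [0, 120] years with widths
    exactly (1, 4, 5 x 19, 20): <1, 1-4, 5-9, ..., 95-99, 100+.
    """

    edges: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        if edges.shape != (23,) or len(self.labels) != 22:
            raise ValueError("schema needs 23 edges and 22 labels")
        expected = np.array([1.0, 4.0] + [5.0] * 19 + [20.0])
        if edges[0] != 0.0 or not np.array_equal(np.diff(edges), expected):
            raise ValueError(
                "bin widths must be exactly (1, 4, 5 x 19, 20) covering [0, 120]"
            )

    @property
    def n_bins(self) -> int:
        return 22

    @property
    def widths(self) -> np.ndarray:
        return np.diff(np.asarray(self.edges))

    @classmethod
    def cdc_22(cls) -> "AgeBinSchema":
        edges = [0.0, 1.0] + [5.0 * k for k in range(1, 21)] + [120.0]
        labels = ["< 1 year", "1-4 years"]
        labels += [f"{5 * k}-{5 * k + 4} years" for k in range(1, 20)]
        labels += ["100+ years"]
        return cls(edges=tuple(edges), labels=tuple(labels))


def coarse_grain(
    d_tilde: CumulativeDeathField | np.ndarray,
    schema: AgeBinSchema,
    grid: AgeTimeGrid | None = None,
) -> np.ndarray:
    """Integrate an age-density field over the 22 age groups.

    Trapezoid rule on the model grid; the last cell is extended at
    constant value to the domain edge, and bin edges falling inside a
    cell are apportioned by linear interpolation of the cumulative
    integral.  By telescoping, the bin values sum exactly to the
    integral over [0, 120].
    """
    if isinstance(d_tilde, CumulativeDeathField):
        values, grid = d_tilde.values, d_tilde.grid
    else:
        if grid is None:
            raise ValueError("grid is required when passing a bare array")
        values = np.asarray(d_tilde, dtype=float)
    if grid.delta_a > float(np.min(np.asarray(schema.widths))):
        raise ValueError(
            f"age grid (delta_a={grid.delta_a}) is coarser than the finest "
            f"bin ({np.min(np.asarray(schema.widths))} years)"
        )
    if grid.a0 > schema.edges[0] or grid.a_max < schema.edges[-1]:
        raise ValueError("age grid does not cover the bin schema's range")
    one_dim = values.ndim == 1
    vals = np.atleast_2d(values)
    nodes = np.append(grid.ages, grid.a_max)
    vals = np.concatenate([vals, vals[:, -1:]], axis=1)
    cum = integrate.cumulative_trapezoid(vals, nodes, axis=-1, initial=0.0)
    edges = np.asarray(schema.edges, dtype=float)
    at_edges = _interp_columns(cum, nodes, edges)
    out = np.diff(at_edges, axis=-1)
    return out[0] if one_dim else out
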