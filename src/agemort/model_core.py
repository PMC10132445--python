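"""Age-structured mortality model and its characteristic-line solutions.

The population density ``n(a, t)`` (individuals per year of age) obeys a
transport equation in age and time,

    (d/da + d/dt) n(a, t) = -mu(a, t) n(a, t) + p(a, t),

with initial condition ``n(a, t0) = rho(a)`` and boundary condition
``n(0, t) = 0`` (no inflow at age zero).  Because information propagates
along the characteristic lines ``a - t = const``, the solution splits into
two branches: points with ``a >= t - t0`` trace back to the initial
condition, points with ``a < t - t0`` trace back to the (empty) age-zero
boundary.

This module provides

* :func:`characteristic_solution` -- the general solution evaluated by
  nested adaptive quadrature, for arbitrary ``mu``, ``p`` and ``rho``;
* closed forms for the analytically solvable case ``rho = 0``,
  ``mu(a, t) = mu`` and ``p(a) = a exp(-lambda a)``:
  :func:`toy_density`, :func:`toy_rate_of_change`, :func:`toy_steady_state`
  and the ridge of density maxima :func:`peak_trajectory`.

All rates are per year, ages and times in years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import integrate

__all__ = [
    "AgeTimeGrid",
    "ToyParams",
    "GeneralModelSpec",
    "DensityField",
    "QuadratureError",
    "characteristic_solution",
    "toy_density",
    "toy_rate_of_change",
    "toy_steady_state",
    "peak_trajectory",
]

#: |lambda - mu| * max(a, t) below which the series limit of the closed
#: forms is used instead of the raw expression (which divides by
#: (lambda - mu)^2 and suffers catastrophic cancellation).
DEGENERATE_GAP = 1e-3

#: default absolute/relative tolerance for the quadrature oracles
QUAD_TOL = 1e-10


class QuadratureError(RuntimeError):
    """Raised when adaptive quadrature fails to converge at some (a, t)."""


@dataclass(frozen=True)
class AgeTimeGrid:
    """Shared discretisation of age [a0, a_max] and time [t0, t0 + N_t*dt].

    Ages are cell left edges ``a_j = a0 + j*delta_a`` for
    ``0 <= j <= n_age - 1``; grid values are point evaluations of the
    density at those edges.
    """

    a_max: float = 120.0
    n_age: int = 1000
    delta_t: float = 0.1
    n_time: int = 100
    a0: float = 0.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.n_age < 2:
            raise ValueError(f"n_age must be >= 2, got {self.n_age}")
        if self.a_max <= self.a0:
            raise ValueError("a_max must exceed a0")
        if self.delta_t <= 0:
            raise ValueError("delta_t must be positive")
        if self.n_time < 1:
            raise ValueError("n_time must be >= 1")

    @property
    def delta_a(self) -> float:
        return (self.a_max - self.a0) / self.n_age

    @property
    def ages(self) -> np.ndarray:
        """Cell left edges, length ``n_age``."""
        return self.a0 + self.delta_a * np.arange(self.n_age)

    @property
    def times(self) -> np.ndarray:
        """Time levels ``t_k = t0 + k*delta_t``, length ``n_time + 1``."""
        return self.t0 + self.delta_t * np.arange(self.n_time + 1)

    @property
    def horizon(self) -> float:
        return self.t0 + self.delta_t * self.n_time


@dataclass(frozen=True)
class ToyParams:
    """Parameters of the analytically solvable case.

    mu   -- constant per-year mortality rate (> 0)
    lam  -- per-year shape rate of the influx p(a) = a exp(-lam a); the
            influx peaks at age 1/lam and has mean entry age 2/lam.
    """

    mu: float
    lam: float

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError(f"mu must be positive, got {self.mu}")
        if self.lam <= 0:
            raise ValueError(f"lam must be positive, got {self.lam}")


@dataclass(frozen=True)
class GeneralModelSpec:
    """Arbitrary coefficients of the transport model.

    mortality(a, t)        -> per-year rate, >= 0
    influx(a, t)           -> persons / year^2, >= 0
    initial_density(a)     -> persons / year at t = t0, >= 0

    The age-zero boundary is fixed at zero.
    """

    mortality: Callable[[float, float], float]
    influx: Callable[[float, float], float]
    initial_density: Callable[[float], float]
    t0: float = 0.0

    @classmethod
    def toy(cls, p: ToyParams) -> "GeneralModelSpec":
        """The closed-form case: rho = 0, mu constant, p(a) = a e^{-lam a}."""
        return cls(
            mortality=lambda a, t: p.mu,
            influx=lambda a, t: a * np.exp(-p.lam * a),
            initial_density=lambda a: 0.0,
        )


@dataclass
class DensityField:
    """Density values on the age grid at one time level."""

    grid: AgeTimeGrid
    t: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_age,):
            raise ValueError(
                f"values must have shape ({self.grid.n_age},), "
                f"got {self.values.shape}"
            )


# ---------------------------------------------------------------------------
# closed forms for the toy case
# ---------------------------------------------------------------------------

def toy_density(a, t, p: ToyParams):
    """Closed-form density of the toy model (zero initial condition).

    For ``a >= t`` the characteristic starts at t = 0:

        n = e^{-lam(a-t)} / d^2 * [e^{-mu t}(1 + (a-t) d) - (1 + a d) e^{-lam t}]

    with ``d = lam - mu``; for ``a < t`` it starts at the empty age-zero
    boundary and the density is already at its time-independent form

        n = [e^{-mu a} - (1 + a d) e^{-lam a}] / d^2.

    Where ``|d| * max(a, t)`` is small the raw expressions cancel
    catastrophically, so a series expansion in ``d`` is evaluated instead.
    Accepts scalars or broadcastable arrays; returns non-negative values.
    """
    a = np.asarray(a, dtype=float)
    t = np.asarray(t, dtype=float)
    a, t = np.broadcast_arrays(a, t)
    mu, lam = p.mu, p.lam
    d = lam - mu
    # cancellation in the raw brackets is governed by |d|*t (a >= t branch)
    # and |d|*a (a < t branch) respectively
    degenerate_ge = np.abs(d) * np.abs(t) < DEGENERATE_GAP
    degenerate_lt = np.abs(d) * np.abs(a) < DEGENERATE_GAP
    d_safe = d if d != 0.0 else 1.0

    u = a - t  # age at entry for the a >= t branch

    # a >= t branch -------------------------------------------------------
    with np.errstate(over="ignore"):
        direct_ge = (
            np.exp(-lam * u - mu * t)
            / d_safe**2
            * ((1.0 + u * d) - (1.0 + a * d) * np.exp(-d * t))
        )
    # series of the bracket / d^2 about d = 0
    series_ge = np.exp(-lam * u - mu * t) * (
        t * (a - t / 2.0)
        + d * (t**3 / 6.0 - a * t**2 / 2.0)
        + d**2 * (a * t**3 / 6.0 - t**4 / 24.0)
        + d**3 * (t**5 / 120.0 - a * t**4 / 24.0)
    )

    # a < t branch (time independent) ------------------------------------
    with np.errstate(over="ignore"):
        direct_lt = (
            np.exp(-mu * a) / d_safe**2 * (1.0 - (1.0 + a * d) * np.exp(-d * a))
        )
    series_lt = np.exp(-mu * a) * (
        a**2 / 2.0 - d * a**3 / 3.0 + d**2 * a**4 / 8.0 - d**3 * a**5 / 30.0
    )

    ge = np.where(degenerate_ge, series_ge, direct_ge)
    lt = np.where(degenerate_lt, series_lt, direct_lt)
    out = np.where(a >= t, ge, lt)
    out = np.maximum(out, 0.0)  # clip round-off-level negatives
    return out if out.ndim else float(out)


def toy_steady_state(a, p: ToyParams):
    """Long-time limit n(a, t -> inf); equals toy_density(a, t) once t > a."""
    a = np.asarray(a, dtype=float)
    big_t = np.max(a, initial=0.0) + 1.0
    return toy_density(a, np.full_like(a, big_t) if a.ndim else big_t, p)


def toy_rate_of_change(a, t, p: ToyParams):
    """Time derivative of the toy density at fixed age,

        dn/dt = (a - t) e^{-lam (a - t) - mu t}   for a >= t,   0 otherwise.

    This is the closed-form rate used in the filter forecast step; it does
    not depend on the current density value.
    """
    a = np.asarray(a, dtype=float)
    t = np.asarray(t, dtype=float)
    a, t = np.broadcast_arrays(a, t)
    u = a - t
    out = np.where(u >= 0.0, u * np.exp(-p.lam * u - p.mu * t), 0.0)
    return out if out.ndim else float(out)


def peak_trajectory(t, p: ToyParams):
    """Age a_max(t) at which the a >= t branch of the toy density peaks:

        a_max(t) = t / (1 - e^{-(lam - mu) t}) - mu / (lam (lam - mu)),

    with the limits a_max(0+) = 1/lam and, for lam -> mu, the series
    a_max = 1/lam + t/2 + (lam - mu) t^2 / 12 + ...  a_max(t) > t and is
    increasing in t.
    """
    t = np.asarray(t, dtype=float)
    mu, lam = p.mu, p.lam
    d = lam - mu
    x = d * t
    small = np.abs(x) < 1e-4

    # phi(x) = x / (1 - e^{-x}), with series for small arguments
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_direct = np.where(small, 1.0, x / (-np.expm1(-x)))
    phi_series = 1.0 + x / 2.0 + x**2 / 12.0 - x**4 / 720.0
    phi = np.where(small, phi_series, phi_direct)

    if abs(d) * np.max(np.abs(t), initial=0.0) < 1e-4 or abs(d) < 1e-8:
        # (phi(d t) - mu/lam) / d, expanded about d = 0
        out = 1.0 / lam + t / 2.0 + d * t**2 / 12.0 - d**3 * t**4 / 720.0
    else:
        d_safe = d
        out = np.where(
            small,
            1.0 / lam + t / 2.0 + d * t**2 / 12.0,
            (phi - mu / lam) / d_safe,
        )
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# general solution by nested quadrature
# ---------------------------------------------------------------------------

def _quad(fn, lo, hi, tol, where):
    if hi <= lo:
        return 0.0
    val, err = integrate.quad(fn, lo, hi, epsabs=tol, epsrel=tol, limit=200)
    if not np.isfinite(val) or (err > max(tol, 100 * tol * abs(val)) and err > 1e-6):
        raise QuadratureError(
            f"quadrature failed at (a, t) = {where}: value={val}, err={err}"
        )
    return val


def characteristic_solution(
    spec: GeneralModelSpec, a: float, t: float, tol: float = QUAD_TOL
) -> float:
    """Evaluate the general solution at one point by nested quadrature.

    For ``a >= t - t0`` the characteristic starts on the initial condition:

        n(a, t) = rho(a - t + t0) exp(-int_{t0}^{t} mu(a - t + s, s) ds)
                  + int_{t0}^{t} p(s + a - t, s)
                      exp(-int_{s}^{t} mu(a - t + s', s') ds') ds

    otherwise it starts on the empty age-zero boundary:

        n(a, t) = int_{0}^{a} p(s, s + t - a)
                      exp(-int_{s}^{a} mu(s', s' + t - a) ds') ds.

    Intended as the slow-but-trustworthy oracle; ``tol`` is the quadrature
    abs/rel tolerance.  Raises :class:`QuadratureError` on non-convergence.
    """
    a = float(a)
    t = float(t)
    t0 = spec.t0
    if a < 0 or t < t0:
        raise ValueError(f"need a >= 0 and t >= t0, got (a, t) = ({a}, {t})")
    mu, p, rho = spec.mortality, spec.influx, spec.initial_density

    if a >= t - t0:
        def survival(s):  # exp(-int_s^t mu along the characteristic)
            return np.exp(-_quad(lambda sp: mu(a - t + sp, sp), s, t, tol, (a, t)))

        initial = rho(a - t + t0) * survival(t0)
        influx = _quad(
            lambda s: p(s + a - t, s) * survival(s), t0, t, tol, (a, t)
        )
        return initial + influx

    def survival_b(s):
        return np.exp(-_quad(lambda sp: mu(sp, sp + t - a), s, a, tol, (a, t)))

    return _quad(lambda s: p(s, s + t - a) * survival_b(s), 0.0, a, tol, (a, t))


def toy_density_field(grid: AgeTimeGrid, t: float, p: ToyParams) -> DensityField:
    """Toy density evaluated on the whole age grid at time ``t``."""
    return DensityField(grid=grid, t=t, values=toy_density(grid.ages, t, p))
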