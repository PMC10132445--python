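"""Perturbed-observation ensemble Kalman filter with state augmentation.

The filter tracks an ensemble of ``M`` augmented state vectors

    x = [ density block | cumulative-death block | transformed parameters ]

and alternates explicit-Euler forecast steps

    chi_{k+1}^(i-) = chi_k^(i) + dt * f(chi_k^(i), t_k) + eps_k^(i),
    eps ~ N(0, Q),

with perturbed-observation updates on an observation schedule

    chi_{k+1}^(i) = chi_{k+1}^(i-) + K [z + eta^(i) - h(chi_{k+1}^(i-))],
    eta ~ N(0, R),  K = P_xz P_zz^{-1},

where the cross- and innovation covariances are unbiased (M-1 denominator)
sample covariances of the forecast ensemble and ``P_zz`` carries the
additive ``R`` term.  Unknown model parameters are appended to the state
(state augmentation) and, when flagged, stored as logarithms so that the
additive Gaussian machinery cannot push them negative.

The module is model-agnostic: the model enters only through the state
derivative ``rate_fn(members, t)`` and measurement ``h(members)``, both
vectorised over ensemble members (arrays of shape ``(M, dim)``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import linalg

__all__ = [
    "StateLayout",
    "ProcessNoise",
    "NoiseSpec",
    "Ensemble",
    "FilterConfig",
    "FilterDiagnostics",
    "init_ensemble",
    "forecast",
    "ensemble_stats",
    "predict_observations",
    "kalman_gain",
    "update",
    "transform_params",
    "untransform_params",
    "run_filter",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StateLayout:
    """Declared layout of the flat augmented state vector.

    Blocks appear in the order density, cumulative deaths, parameters.
    ``log_params[i]`` flags whether parameter ``param_names[i]`` is stored
    as its logarithm inside the state (the usual positivity transform).
    """

    n_density: int
    n_deaths: int = 0
    param_names: tuple[str, ...] = ()
    log_params: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        if not self.log_params:
            object.__setattr__(self, "log_params", (True,) * len(self.param_names))
        if len(self.log_params) != len(self.param_names):
            raise ValueError("log_params and param_names lengths differ")

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def dim(self) -> int:
        return self.n_density + self.n_deaths + self.n_params

    @property
    def density(self) -> slice:
        return slice(0, self.n_density)

    @property
    def deaths(self) -> slice:
        return slice(self.n_density, self.n_density + self.n_deaths)

    @property
    def params(self) -> slice:
        return slice(self.n_density + self.n_deaths, self.dim)


def transform_params(values: np.ndarray, layout: StateLayout) -> np.ndarray:
    """Natural-scale parameter sub-vector -> stored scale (log where flagged)."""
    values = np.asarray(values, dtype=float)
    flags = np.asarray(layout.log_params, dtype=bool)
    if np.any(values[..., flags] <= 0):
        bad = np.asarray(layout.param_names)[flags][
            np.any(np.atleast_2d(values[..., flags]) <= 0, axis=0)
        ]
        raise ValueError(f"log-transformed parameters must be positive: {list(bad)}")
    out = values.copy()
    out[..., flags] = np.log(values[..., flags])
    return out


def untransform_params(values: np.ndarray, layout: StateLayout) -> np.ndarray:
    """Stored-scale parameter sub-vector -> natural scale (exp where flagged)."""
    values = np.asarray(values, dtype=float)
    flags = np.asarray(layout.log_params, dtype=bool)
    out = values.copy()
    out[..., flags] = np.exp(values[..., flags])
    return out


@dataclass(frozen=True)
class ProcessNoise:
    """Process noise specification, sampled once per member per step.

    kind = "ones"  -- Q = variance * J (J the all-ones matrix): rank one,
                      fully correlated; one scalar draw is added to every
                      state entry of a member.
    kind = "diag"  -- Q = diag(diag); independent per-entry draws.
    kind = "zero"  -- no process noise.
    """

    kind: str = "zero"
    variance: float = 0.0
    diag: np.ndarray | None = None

    @classmethod
    def ones(cls, variance: float) -> "ProcessNoise":
        return cls(kind="ones", variance=variance)

    @classmethod
    def diagonal(cls, diag: Sequence[float]) -> "ProcessNoise":
        d = np.asarray(diag, dtype=float)
        if np.any(d < 0):
            raise ValueError("diagonal process covariance must be >= 0")
        return cls(kind="diag", diag=d)

    @classmethod
    def zero(cls) -> "ProcessNoise":
        return cls(kind="zero")

    def sample(self, rng: np.random.Generator, m: int, dim: int) -> np.ndarray:
        if self.kind == "zero":
            return np.zeros((m, dim))
        if self.kind == "ones":
            xi = rng.standard_normal((m, 1))
            return np.sqrt(self.variance) * np.broadcast_to(xi, (m, dim)).copy()
        if self.kind == "diag":
            if self.diag is None or self.diag.shape != (dim,):
                raise ValueError("diagonal Q has wrong dimension")
            return rng.standard_normal((m, dim)) * np.sqrt(self.diag)
        raise ValueError(f"unknown process-noise kind {self.kind!r}")


@dataclass(frozen=True)
class NoiseSpec:
    """Bundle of process noise Q and observation covariance R.

    ``R`` may be a 1-D diagonal or a full symmetric matrix; it must be
    strictly positive definite for the gain computation.
    """

    Q: ProcessNoise
    R: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "R", np.asarray(self.R, dtype=float))

    @property
    def R_matrix(self) -> np.ndarray:
        return np.diag(self.R) if self.R.ndim == 1 else self.R

    def sample_obs_noise(self, rng: np.random.Generator, m: int) -> np.ndarray:
        if self.R.ndim == 1:
            return rng.standard_normal((m, self.R.size)) * np.sqrt(self.R)
        chol = np.linalg.cholesky(self.R)
        return rng.standard_normal((m, self.R.shape[0])) @ chol.T


@dataclass
class Ensemble:
    """M augmented-state members (rows), sharing one layout."""

    members: np.ndarray
    layout: StateLayout

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=float)
        if self.members.ndim != 2 or self.members.shape[1] != self.layout.dim:
            raise ValueError(
                f"members must have shape (M, {self.layout.dim}), "
                f"got {self.members.shape}"
            )
        if self.members.shape[0] < 2:
            raise ValueError("ensemble needs at least 2 members")

    @property
    def m(self) -> int:
        return self.members.shape[0]

    def natural_params(self) -> np.ndarray:
        """(M, n_params) parameter block on the natural scale."""
        return untransform_params(self.members[:, self.layout.params], self.layout)


def init_ensemble(
    x0: np.ndarray,
    p0: np.ndarray,
    m: int,
    layout: StateLayout,
    rng: np.random.Generator | int,
) -> Ensemble:
    """Draw M members from N(x0, P0) on the stored scale.

    ``p0`` is a 1-D diagonal or full covariance.  A full ``p0`` must be
    symmetric positive semidefinite; violations are reported with the
    offending eigenvalue.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    x0 = np.asarray(x0, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    if m < 2:
        raise ValueError("ensemble size M must be >= 2")
    if p0.ndim == 1:
        if np.any(p0 < 0):
            j = int(np.argmin(p0))
            raise ValueError(f"P0 diagonal entry {j} is negative: {p0[j]}")
        draws = x0 + rng.standard_normal((m, x0.size)) * np.sqrt(p0)
    else:
        if not np.allclose(p0, p0.T):
            raise ValueError("P0 must be symmetric")
        eigvals = np.linalg.eigvalsh(p0)
        if eigvals[0] < -1e-12 * max(1.0, eigvals[-1]):
            raise ValueError(f"P0 is not PSD: smallest eigenvalue {eigvals[0]}")
        root = linalg.cholesky(p0 + 1e-14 * np.eye(p0.shape[0]), lower=True)
        draws = x0 + rng.standard_normal((m, x0.size)) @ root.T
    return Ensemble(members=draws, layout=layout)


def forecast(
    e: Ensemble,
    rate_fn: Callable[[np.ndarray, float], np.ndarray],
    t_k: float,
    delta_t: float,
    q: ProcessNoise,
    rng: np.random.Generator,
) -> Ensemble:
    """One explicit-Euler forecast step plus a process-noise draw per member.

    ``rate_fn(members, t)`` must return the stored-scale state derivative
    with zeros in the parameter block (parameters have no deterministic
    drift under state augmentation).
    """
    deriv = rate_fn(e.members, t_k)
    if not np.all(np.isfinite(deriv)):
        i, j = np.argwhere(~np.isfinite(deriv))[0]
        raise FloatingPointError(
            f"non-finite state derivative for member {i}, state entry {j} "
            f"at t = {t_k}"
        )
    members = e.members + delta_t * deriv + q.sample(rng, e.m, e.layout.dim)
    return Ensemble(members=members, layout=e.layout)


def ensemble_stats(e: Ensemble | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sample mean and unbiased (M-1 denominator) sample covariance."""
    x = e.members if isinstance(e, Ensemble) else np.asarray(e, dtype=float)
    mean = x.mean(axis=0)
    anom = x - mean
    cov = anom.T @ anom / (x.shape[0] - 1)
    return mean, cov


def predict_observations(
    e: Ensemble,
    h: Callable[[np.ndarray], np.ndarray],
    r: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predicted observation mean and covariances of the forecast ensemble.

    Returns ``(z_hat, P_zz, P_xz)`` with ``P_zz`` carrying the additive
    observation covariance ``R`` and both covariances using the unbiased
    M-1 denominator.
    """
    r = np.asarray(r, dtype=float)
    z = np.asarray(h(e.members), dtype=float)
    if z.ndim != 2 or z.shape[0] != e.m:
        raise ValueError("h must map (M, dim) members to (M, obs_dim)")
    r_mat = np.diag(r) if r.ndim == 1 else r
    if r_mat.shape != (z.shape[1], z.shape[1]):
        raise ValueError(
            f"R has shape {r_mat.shape} but h returns {z.shape[1]} observables"
        )
    z_hat = z.mean(axis=0)
    z_anom = z - z_hat
    x_anom = e.members - e.members.mean(axis=0)
    p_zz = z_anom.T @ z_anom / (e.m - 1) + r_mat
    p_xz = x_anom.T @ z_anom / (e.m - 1)
    return z_hat, p_zz, p_xz


def kalman_gain(p_xz: np.ndarray, p_zz: np.ndarray) -> np.ndarray:
    """K = P_xz P_zz^{-1}, computed by a symmetric linear solve."""
    try:
        return linalg.solve(p_zz, p_xz.T, assume_a="pos").T
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rare path
        raise np.linalg.LinAlgError(
            "innovation covariance P_zz is singular; use strictly positive "
            "observation noise R"
        ) from exc


@dataclass
class UpdateInfo:
    """Per-update diagnostics (all stored-scale)."""

    z_hat: np.ndarray
    p_zz: np.ndarray
    p_xz: np.ndarray
    gain: np.ndarray
    prior_cov_diag: np.ndarray
    post_cov_diag: np.ndarray


def update(
    e: Ensemble,
    z: np.ndarray,
    h: Callable[[np.ndarray], np.ndarray],
    r: np.ndarray,
    rng: np.random.Generator,
    return_info: bool = False,
) -> Ensemble | tuple[Ensemble, UpdateInfo]:
    """Perturbed-observation update of every member.

    Each member is corrected with an independently perturbed copy of the
    observation, ``z + eta^(i)``, ``eta ~ N(0, R)``, which keeps the
    posterior ensemble spread statistically consistent.  The reported
    posterior covariance diagonal follows the closed-form identity
    ``P = P^- - K P_zz K^T``.
    """
    z = np.asarray(z, dtype=float)
    z_hat, p_zz, p_xz = predict_observations(e, h, r)
    gain = kalman_gain(p_xz, p_zz)
    noise = NoiseSpec(Q=ProcessNoise.zero(), R=np.asarray(r, dtype=float))
    eta = noise.sample_obs_noise(rng, e.m)
    innovations = z + eta - np.asarray(h(e.members), dtype=float)
    members = e.members + innovations @ gain.T
    out = Ensemble(members=members, layout=e.layout)
    if not return_info:
        return out
    prior_diag = np.sum((e.members - e.members.mean(axis=0)) ** 2, axis=0) / (
        e.m - 1
    )
    post_diag = prior_diag - np.einsum("ij,jk,ik->i", gain, p_zz, gain)
    info = UpdateInfo(
        z_hat=z_hat,
        p_zz=p_zz,
        p_xz=p_xz,
        gain=gain,
        prior_cov_diag=prior_diag,
        post_cov_diag=post_diag,
    )
    return out, info


@dataclass(frozen=True)
class FilterConfig:
    """Everything a filter run needs besides the model and the data."""

    layout: StateLayout
    x0: np.ndarray          # stored-scale initial mean (params transformed)
    p0: np.ndarray          # stored-scale covariance (1-D diagonal or full)
    m: int
    noise: NoiseSpec
    delta_t: float
    n_steps: int
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "x0", np.asarray(self.x0, dtype=float))
        object.__setattr__(self, "p0", np.asarray(self.p0, dtype=float))
        if self.x0.shape != (self.layout.dim,):
            raise ValueError("x0 dimension does not match the state layout")


@dataclass
class FilterDiagnostics:
    """Per-step filter output.

    Parameter trajectories are reported on the natural scale as the
    ensemble mean and standard deviation of the untransformed parameters;
    +/- 3 sigma bands follow as ``param_mean +/- 3 * param_std``.
    """

    layout: StateLayout
    times: np.ndarray
    mean: np.ndarray                    # (n_steps + 1, dim), stored scale
    std: np.ndarray                     # (n_steps + 1, dim), stored scale
    param_mean: np.ndarray              # (n_steps + 1, n_params), natural
    param_std: np.ndarray               # (n_steps + 1, n_params), natural
    update_steps: list[int] = field(default_factory=list)
    gain_norms: list[float] = field(default_factory=list)
    update_info: dict[int, UpdateInfo] = field(default_factory=dict)
    predicted_obs: dict[int, np.ndarray] = field(default_factory=dict)
    predicted_obs_var: dict[int, np.ndarray] = field(default_factory=dict)
    reported_obs_members: dict[int, np.ndarray] = field(default_factory=dict)
    final_ensemble: Ensemble | None = None

    def param_band(self, n_sigma: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
        lo = self.param_mean - n_sigma * self.param_std
        hi = self.param_mean + n_sigma * self.param_std
        return lo, hi


def run_filter(
    rate_fn: Callable[[np.ndarray, float], np.ndarray],
    h: Callable[[np.ndarray], np.ndarray],
    observations: Mapping[int, np.ndarray],
    config: FilterConfig,
    keep_update_info: bool = False,
    report_obs_steps: Sequence[int] = (),
) -> FilterDiagnostics:
    """Run the forecast/update cycle over ``n_steps`` Euler steps.

    ``observations`` maps a step index ``k`` (state time ``t0 + k*dt``,
    ``1 <= k <= n_steps``) to an observation vector; steps beyond the last
    observation are pure forecasts, which is how forward projections past
    the final data year are produced.  At every step listed in
    ``report_obs_steps`` the member-level predicted observations
    ``h(members)`` are recorded *before* any update at that step, so
    forecast bands can be formed from the prior ensemble spread.
    Separate, labelled RNG streams are used for ensemble initialisation,
    process noise and observation perturbations, so runs are bitwise
    reproducible for a fixed seed.
    """
    layout = config.layout
    obs = {int(k): np.asarray(v, dtype=float) for k, v in observations.items()}
    bad = [k for k in obs if not (1 <= k <= config.n_steps)]
    if bad:
        raise ValueError(
            f"observation steps {bad} fall outside the prediction grid "
            f"1..{config.n_steps}"
        )

    seq = np.random.SeedSequence(config.seed)
    rng_init, rng_proc, rng_obs = (
        np.random.default_rng(s) for s in seq.spawn(3)
    )

    e = init_ensemble(config.x0, config.p0, config.m, layout, rng_init)

    n_rec = config.n_steps + 1
    diag = FilterDiagnostics(
        layout=layout,
        times=config.delta_t * np.arange(n_rec),
        mean=np.empty((n_rec, layout.dim)),
        std=np.empty((n_rec, layout.dim)),
        param_mean=np.empty((n_rec, layout.n_params)),
        param_std=np.empty((n_rec, layout.n_params)),
    )

    def record(k: int, ens: Ensemble) -> None:
        diag.mean[k] = ens.members.mean(axis=0)
        diag.std[k] = ens.members.std(axis=0, ddof=1)
        if layout.n_params:
            nat = ens.natural_params()
            diag.param_mean[k] = nat.mean(axis=0)
            diag.param_std[k] = nat.std(axis=0, ddof=1)

    record(0, e)
    report = {int(s) for s in report_obs_steps}
    for k in range(config.n_steps):
        t_k = config.delta_t * k
        e = forecast(e, rate_fn, t_k, config.delta_t, config.noise.Q, rng_proc)
        step = k + 1
        if step in report:
            diag.reported_obs_members[step] = np.asarray(
                h(e.members), dtype=float
            ).copy()
        if step in obs:
            e, info = update(
                e, obs[step], h, config.noise.R, rng_obs, return_info=True
            )
            diag.update_steps.append(step)
            diag.gain_norms.append(float(np.linalg.norm(info.gain)))
            diag.predicted_obs[step] = info.z_hat
            diag.predicted_obs_var[step] = np.diag(info.p_zz).copy()
            if keep_update_info:
                diag.update_info[step] = info
            logger.debug(
                "step %d (t=%.2f): update, |K|=%.3g", step, t_k, diag.gain_norms[-1]
            )
        record(step, e)
    diag.final_ensemble = e
    return diag
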