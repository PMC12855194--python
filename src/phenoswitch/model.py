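"""Two-phenotype switching dynamics of bistable multicellular yeast.

Settling-selected multicellular *Saccharomyces cerevisiae* genotypes carrying a
loss-of-function ACE2 allele maintain two coexisting morphotypes within a single
isogenic population: large multicellular clusters (abundance ``M``) and small
ancestral-like clusters of one to a few cells (abundance ``U``).  The population
dynamics are modelled by a pair of coupled ODEs::

    dM/dt = alpha * log2(M) + eta(t) + gamma * U
    dU/dt = S(t) * beta * M  - gamma * U

with

* ``alpha`` — growth-rate coefficient of large clusters (1/h); growth is
  expressed through the doubling time via ``log2(M)``,
* ``beta``  — switching rate at which large clusters shed small propagules (1/h),
* ``gamma`` — reversion rate of small clusters back into the large morphotype
  (1/h); the best-fit regime observed empirically has ``gamma = 0``,
* ``S(t) = 1 / (1 + exp(-k (t - t_switch)))`` — a logistic switch with
  steepness ``k`` (1/h) and midpoint ``t_switch`` (h) gating the production of
  small clusters around the post-diauxic transition (~20 h of batch growth),
* ``eta(t)`` — additive random fluctuation in M growth, integrated
  Euler–Maruyama style with per-step standard deviation ``sigma_eta * sqrt(dt)``
  (``sigma_eta = 0`` gives the deterministic model).

Model fitting is a deterministic grid search: for every parameter tuple the
model is simulated, the predicted small-cluster fraction ``U/(U+M)`` is compared
with observed fractions at the experiment's observation times, and the tuple
minimising the RMSE prediction error is returned together with the full
objective surface, R^2, and residual diagnostics.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import FitError, StepSizeError, ValidationError

__all__ = [
    "SwitchingParams",
    "Trajectory",
    "FitResult",
    "sigmoid_switch",
    "simulate",
    "predicted_fractions",
    "fit_grid",
    "goodness_of_fit",
    "M_FLOOR",
]

#: Lower clamp applied to M after every Euler step. M = 1 is a fixed point of
#: the alpha*log2(M) growth law, so trajectories are kept strictly above it.
M_FLOOR = 1.0 + 1e-9


@dataclass(frozen=True)
class SwitchingParams:
    """Parameters of the two-phenotype switching model.

    Defaults are the best-fit tuple of the deterministic model (alpha = 1,
    beta = 0.005, gamma = 0, k = 0.001) with the post-diauxic midpoint
    t_switch = 20 h and initial conditions m0 = 2, u0 = 0.
    """

    alpha: float = 1.0
    beta: float = 0.005
    gamma: float = 0.0
    k: float = 0.001
    t_switch: float = 20.0
    sigma_eta: float = 0.0
    m0: float = 2.0
    u0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "k", "sigma_eta"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v}")
        if not self.m0 > 1.0:
            raise ValidationError(
                f"m0 must be > 1 (growth term log2(M) degenerates at M <= 1), got {self.m0}"
            )
        if self.u0 < 0:
            raise ValidationError(f"u0 must be >= 0, got {self.u0}")


@dataclass(frozen=True)
class Trajectory:
    """Simulated abundances on a uniform time grid (hours)."""

    times: np.ndarray
    M: np.ndarray
    U: np.ndarray

    @property
    def fraction_small(self) -> np.ndarray:
        """Small-cluster fraction U / (U + M) along the trajectory."""
        return self.U / (self.U + self.M)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "M": self.M,
                "U": self.U,
                "fraction_small": self.fraction_small,
            }
        )


def sigmoid_switch(t, k: float, t_switch: float):
    """Logistic switch probability S(t) = 1 / (1 + exp(-k (t - t_switch))).

    Strictly increasing in ``t`` for ``k > 0``, identically 0.5 for ``k = 0``,
    and saturates without overflow at extreme arguments.
    """
    if k < 0:
        raise ValidationError(f"steepness k must be >= 0, got {k}")
    out = expit(k * (np.asarray(t, dtype=float) - t_switch))
    return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out


def _euler_batch(
    alpha: np.ndarray,
    beta: np.ndarray,
    gamma: np.ndarray,
    k: np.ndarray,
    *,
    t_switch: float,
    m0: float,
    u0: float,
    t_end: float,
    dt: float,
    sigma_eta: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Explicit Euler integration of the model, vectorised over parameter tuples.

    Returns (times, M, U, bad) where M and U have shape (n_steps+1, n_tuples)
    and ``bad`` flags tuples for which a single step changed M by more than 50%
    (or which produced non-finite values).  A single integration loop backs both
    :func:`simulate` and :func:`fit_grid`, so a trajectory generated by one is
    bitwise identical to the corresponding column of the other.
    """
    if not 0.0 < dt <= 0.1:
        raise ValidationError(f"dt must satisfy 0 < dt <= 0.1 h, got {dt}")
    if t_end < dt:
        raise ValidationError(f"t_end must be >= dt, got t_end={t_end}, dt={dt}")
    n_steps = int(round(t_end / dt))
    times = np.arange(n_steps + 1) * dt
    n_tup = alpha.shape[0]

    # switch probabilities for every (step, tuple) in one call
    S = expit(np.multiply.outer(times[:-1] - t_switch, k))

    noise = None
    if sigma_eta > 0:
        if rng is None:
            raise ValidationError("stochastic run (sigma_eta > 0) requires a seeded rng")
        noise = rng.standard_normal((n_steps, n_tup)) * (sigma_eta * math.sqrt(dt))

    Ms = np.empty((n_steps + 1, n_tup))
    Us = np.empty((n_steps + 1, n_tup))
    M = np.full(n_tup, float(m0))
    U = np.full(n_tup, float(u0))
    bad = np.zeros(n_tup, dtype=bool)
    with np.errstate(all="ignore"):
        for i in range(n_steps):
            Ms[i] = M
            Us[i] = U
            dM = dt * (alpha * np.log2(M) + gamma * U)
            if noise is not None:
                dM = dM + noise[i]
            dU = dt * (S[i] * beta * M - gamma * U)
            bad |= np.abs(dM) > 0.5 * M
            M = np.maximum(M + dM, M_FLOOR)
            U = np.maximum(U + dU, 0.0)
        Ms[n_steps] = M
        Us[n_steps] = U
    bad |= ~np.isfinite(Ms).all(axis=0) | ~np.isfinite(Us).all(axis=0)
    return times, Ms, Us, bad


def simulate(
    params: SwitchingParams,
    t_end: float = 48.0,
    dt: float = 0.01,
    seed: int | None = None,
) -> Trajectory:
    """Integrate the switching model with explicit Euler steps of size ``dt``.

    Deterministic when ``params.sigma_eta == 0`` (the seed is ignored);
    otherwise the fluctuation term draws ``sigma_eta * sqrt(dt) * N(0,1)`` per
    step from a generator seeded with ``seed``.

    Raises :class:`StepSizeError` if any step changes M by more than 50%,
    which indicates ``dt`` is too coarse for the requested parameters.
    """
    rng = np.random.default_rng(seed) if params.sigma_eta > 0 else None
    times, Ms, Us, bad = _euler_batch(
        np.array([params.alpha]),
        np.array([params.beta]),
        np.array([params.gamma]),
        np.array([params.k]),
        t_switch=params.t_switch,
        m0=params.m0,
        u0=params.u0,
        t_end=t_end,
        dt=dt,
        sigma_eta=params.sigma_eta,
        rng=rng,
    )
    if bad[0]:
        raise StepSizeError(
            f"Euler step dt={dt} changed M by more than 50% in one step; reduce dt"
        )
    return Trajectory(times=times, M=Ms[:, 0], U=Us[:, 0])


def predicted_fractions(traj: Trajectory, observation_times) -> np.ndarray:
    """Small-cluster fraction linearly interpolated at each observation time."""
    t = np.atleast_1d(np.asarray(observation_times, dtype=float))
    lo, hi = traj.times[0], traj.times[-1]
    if t.size == 0:
        return t
    if t.min() < lo - 1e-12 or t.max() > hi + 1e-12:
        raise ValidationError(
            f"observation times must lie within the simulated grid [{lo}, {hi}]"
        )
    return np.interp(t, traj.times, traj.fraction_small)


def goodness_of_fit(observed, predicted) -> tuple[float, float]:
    """Return (R^2, residual SD) of predicted vs observed fractions.

    R^2 = 1 - SS_res / SS_tot with SS_tot about the observed mean; the residual
    SD is the sample standard deviation (ddof=1) of observed - predicted.
    R^2 is invariant under rescaling fractions to percentages.
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1 or o.size < 2:
        raise ValidationError("observed and predicted must be equal-length 1-d, length >= 2")
    ss_tot = float(((o - o.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValidationError("R^2 undefined: observed values are constant (SS_tot = 0)")
    resid = o - p
    r2 = 1.0 - float((resid**2).sum()) / ss_tot
    return r2, float(np.std(resid, ddof=1))


@dataclass
class FitResult:
    """Outcome of the grid search over (alpha, beta, gamma, k)."""

    best_params: SwitchingParams
    objective_best: float
    grid_table: pd.DataFrame
    r_squared: float
    residuals: np.ndarray
    residual_sd: float
    observation_times: np.ndarray
    observed: np.ndarray
    predicted: np.ndarray

    def to_dict(self) -> dict:
        """JSON-ready summary (the grid table is serialised separately)."""
        p = self.best_params
        return {
            "best_params": {
                "alpha": p.alpha,
                "beta": p.beta,
                "gamma": p.gamma,
                "k": p.k,
                "t_switch": p.t_switch,
                "sigma_eta": p.sigma_eta,
                "m0": p.m0,
                "u0": p.u0,
            },
            "objective_best": self.objective_best,
            "r_squared": self.r_squared,
            "residual_sd": self.residual_sd,
            "observation_times": list(map(float, self.observation_times)),
            "observed": list(map(float, self.observed)),
            "predicted": list(map(float, self.predicted)),
            "residuals": list(map(float, self.residuals)),
        }


def _as_grid(name: str, values) -> np.ndarray:
    g = np.unique(np.asarray(list(values), dtype=float))
    if g.size == 0:
        raise ValidationError(f"{name} grid must be non-empty")
    return g


def fit_grid(
    observations,
    alpha_grid,
    beta_grid,
    gamma_grid,
    k_grid,
    *,
    t_end: float = 48.0,
    dt: float = 0.01,
    t_switch: float = 20.0,
    m0: float = 2.0,
    u0: float = 0.0,
) -> FitResult:
    """Grid-search fit of the deterministic model to observed fractions.

    ``observations`` is a DataFrame (or mapping) with columns ``time_h`` and
    ``fraction_small``; alternatively ``count_small``/``count_large`` columns
    from which the fraction is derived.  The objective is the RMSE between
    predicted and observed small-cluster fractions over all observation times;
    every grid tuple is simulated deterministically (sigma_eta = 0).  Ties in
    the argmin are broken lexicographically by (alpha, beta, gamma, k)
    ascending.  A tuple whose simulation is unstable at ``dt`` is recorded with
    an infinite objective rather than aborting the search.
    """
    obs = pd.DataFrame(observations)
    if "fraction_small" not in obs.columns:
        if {"count_small", "count_large"} <= set(obs.columns):
            total = obs["count_small"] + obs["count_large"]
            obs = obs.assign(fraction_small=obs["count_small"] / total)
        else:
            raise ValidationError(
                "observations need a fraction_small column or count_small/count_large"
            )
    if "time_h" not in obs.columns:
        raise ValidationError("observations need a time_h column")
    times = obs["time_h"].to_numpy(dtype=float)
    fr_obs = obs["fraction_small"].to_numpy(dtype=float)
    if times.size < 2:
        raise ValidationError("need at least 2 observation timepoints")
    if np.any(fr_obs < 0) or np.any(fr_obs > 1):
        raise ValidationError("observed fractions must lie in [0, 1]")

    grids = [
        _as_grid("alpha", alpha_grid),
        _as_grid("beta", beta_grid),
        _as_grid("gamma", gamma_grid),
        _as_grid("k", k_grid),
    ]
    tuples = np.array(list(itertools.product(*grids)))  # lexicographic order
    A, B, G, K = tuples.T

    grid_times, Ms, Us, bad = _euler_batch(
        A, B, G, K, t_switch=t_switch, m0=m0, u0=u0, t_end=t_end, dt=dt
    )
    if times.max() > grid_times[-1] + 1e-12 or times.min() < -1e-12:
        raise ValidationError(
            f"observation times must lie within the simulated range [0, {grid_times[-1]}]"
        )
    with np.errstate(invalid="ignore"):
        frac = Us / (Us + Ms)

    n_tup = tuples.shape[0]
    pred = np.empty((n_tup, times.size))
    for j in range(n_tup):
        pred[j] = np.interp(times, grid_times, frac[:, j])
    with np.errstate(invalid="ignore"):
        obj = np.sqrt(np.mean((pred - fr_obs) ** 2, axis=1))
    obj[bad | ~np.isfinite(obj)] = np.inf

    if np.isinf(obj).all():
        raise FitError("every grid tuple failed to simulate; refine grids or reduce dt")

    best = int(np.argmin(obj))  # first occurrence = lexicographically smallest tie
    best_params = SwitchingParams(
        alpha=float(A[best]),
        beta=float(B[best]),
        gamma=float(G[best]),
        k=float(K[best]),
        t_switch=t_switch,
        sigma_eta=0.0,
        m0=m0,
        u0=u0,
    )
    residuals = fr_obs - pred[best]
    try:
        r2, resid_sd = goodness_of_fit(fr_obs, pred[best])
    except ValidationError:
        r2, resid_sd = float("nan"), float(np.std(residuals, ddof=1))
    grid_table = pd.DataFrame(
        {"alpha": A, "beta": B, "gamma": G, "k": K, "objective": obj}
    )
    return FitResult(
        best_params=best_params,
        objective_best=float(obj[best]),
        grid_table=grid_table,
        r_squared=r2,
        residuals=residuals,
        residual_sd=resid_sd,
        observation_times=times,
        observed=fr_obs,
        predicted=pred[best],
    )
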