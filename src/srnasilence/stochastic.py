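"""Noise layer: linearized stationary covariance and an exact simulator.

In the weak-noise limit the stationary covariance ``C`` of (m, s, p)
solves the fluctuation-dissipation (Lyapunov) relation

    J C + C J^T + N = 0

with ``J`` the Jacobian of the mass-action system at steady state and
``N`` the diffusion matrix assembled from the stoichiometry of the seven
elementary reactions: mRNA birth/decay, sRNA birth/decay, sRNA-mRNA
codegradation (removes one of each, hence the positive off-diagonal
coupling), protein birth/decay.  A direct-method Gillespie simulator over
the same seven reactions serves as an independent oracle.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import linalg

from .model_core import (
    KineticParameters,
    SteadyState,
    effective_rates,
    steady_state_closed_form,
)

__all__ = [
    "CovarianceResult",
    "SSAConfig",
    "SSAResult",
    "jacobian",
    "diffusion_matrix",
    "solve_covariance",
    "covariance",
    "noise_curve",
    "gillespie_simulate",
    "detect_local_maximum",
]

_SPECIES = ("m", "s", "p")


class UnstableJacobianError(ValueError):
    """The Jacobian has a nonnegative eigenvalue; no stationary covariance."""


@dataclass(frozen=True)
class CovarianceResult:
    """Stationary covariance of (m, s, p) and derived noise measures."""

    C: np.ndarray
    J: np.ndarray
    N: np.ndarray
    eta_p: float
    eta_m: float
    fano_p: float

    def to_json(self, path=None) -> str:
        payload = {
            "species": list(_SPECIES),
            "C": self.C.tolist(),
            "J": self.J.tolist(),
            "N": self.N.tolist(),
            "eta_p": self.eta_p,
            "eta_m": self.eta_m,
            "fano_p": self.fano_p,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass(frozen=True)
class SSAConfig:
    seed: int
    t_burn_in: float = 200.0
    t_sample: float = 2000.0
    sample_interval: float = 5.0
    n_trajectories: int = 8

    def __post_init__(self) -> None:
        if self.t_burn_in <= 0 or self.t_sample <= 0 or self.sample_interval <= 0:
            raise ValueError("times must be positive")
        if self.n_trajectories < 1:
            raise ValueError("need at least one trajectory")


@dataclass(frozen=True)
class SSAResult:
    """Stationary moments with trajectory-batched standard errors."""

    mean: dict
    var: dict
    se_mean: dict
    eta_p: float
    se_eta_p: float
    n_samples: int
    event_count: int
    seed: int
    per_trajectory: dict = field(repr=False, default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "mean": self.mean,
            "var": self.var,
            "se_mean": self.se_mean,
            "eta_p": self.eta_p,
            "se_eta_p": self.se_eta_p,
            "n_samples": self.n_samples,
            "event_count": self.event_count,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def jacobian(params: KineticParameters, ss: SteadyState) -> np.ndarray:
    """Jacobian of the mass-action right-hand side at the steady state."""
    eff = effective_rates(params)
    m, s = ss.m, ss.s
    return np.array(
        [
            [-eff.beta_m - eff.k * s, -eff.k * m, 0.0],
            [-eff.k * s, -params.beta_s - eff.k * m, 0.0],
            [eff.gamma, 0.0, -params.beta_p],
        ]
    )


def diffusion_matrix(params: KineticParameters, ss: SteadyState) -> np.ndarray:
    """Diffusion matrix from the stoichiometry of the elementary reactions.

    Codegradation consumes one mRNA *and* one sRNA per event, which puts
    ``+k*s*m`` on the (m, s) off-diagonal; at steady state the diagonal
    entries reduce to 2*alpha_m, 2*alpha_s and 2*gamma*m.
    """
    eff = effective_rates(params)
    m, s, p = ss.m, ss.s, ss.p
    codeg = eff.k * s * m
    N = np.zeros((3, 3))
    N[0, 0] = params.alpha_m + eff.beta_m * m + codeg
    N[1, 1] = params.alpha_s + params.beta_s * s + codeg
    N[0, 1] = N[1, 0] = codeg
    N[2, 2] = eff.gamma * m + params.beta_p * p
    return N


def solve_covariance(
    J: np.ndarray, N: np.ndarray, ss: Optional[SteadyState] = None
) -> CovarianceResult:
    """Solve J C + C J^T + N = 0 for the stationary covariance.

    Noise measures (eta, Fano) are filled in when the steady state is
    supplied; they are NaN where the corresponding mean vanishes.
    """
    J = np.asarray(J, dtype=float)
    N = np.asarray(N, dtype=float)
    eigs = np.linalg.eigvals(J)
    if np.any(eigs.real >= 0):
        raise UnstableJacobianError(f"Jacobian eigenvalues not all stable: {eigs}")
    C = linalg.solve_continuous_lyapunov(J, -N)
    C = 0.5 * (C + C.T)
    eta_p = eta_m = fano_p = math.nan
    if ss is not None:
        if ss.p > 0:
            eta_p = C[2, 2] / ss.p**2
            fano_p = C[2, 2] / ss.p
        if ss.m > 0:
            eta_m = C[0, 0] / ss.m**2
    return CovarianceResult(C=C, J=J, N=N, eta_p=eta_p, eta_m=eta_m, fano_p=fano_p)


def covariance(params: KineticParameters) -> CovarianceResult:
    """Steady state + Lyapunov solve in one call."""
    ss = steady_state_closed_form(params)
    return solve_covariance(jacobian(params, ss), diffusion_matrix(params, ss), ss)


def noise_curve(
    params: KineticParameters,
    axis_kind: str,
    grid: Sequence[float],
    include_no_srna: bool = True,
):
    """Protein noise eta_p along an axis, with and without the sRNA.

    Returns a DataFrame with columns ``axis_value``, ``eta_p`` and (when
    requested) ``eta_p_no_srna``.  Grid points with zero expression are
    flagged undefined (NaN eta).
    """
    import pandas as pd

    from .model_core import _x_from_axis, unregulated_expression

    grid = np.asarray(grid, dtype=float)
    if not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    rows = []
    for g in grid:
        if axis_kind == "alpha_s":
            pt = params.with_(alpha_s=float(g))
            axis_value = float(g)
        else:
            pt = params.with_(x=_x_from_axis(axis_kind, float(g)))
            axis_value = unregulated_expression(pt) if axis_kind == "unregulated_expression" else float(g)
        row = {"axis_value": axis_value}
        row["eta_p"] = covariance(pt).eta_p if pt.x > 0 else math.nan
        if include_no_srna:
            pt0 = pt.with_(alpha_s=0.0)
            row["eta_p_no_srna"] = covariance(pt0).eta_p if pt0.x > 0 else math.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _simulate_one(
    alpha_m: float,
    beta_m: float,
    alpha_s: float,
    beta_s: float,
    k: float,
    gamma: float,
    beta_p: float,
    m: int,
    s: int,
    p: int,
    t_burn_in: float,
    t_end: float,
    interval: float,
    rng: random.Random,
):
    """Direct-method SSA for one trajectory; fixed-interval state samples."""
    t = 0.0
    next_sample = t_burn_in
    samples_m = []
    samples_s = []
    samples_p = []
    events = 0
    rnd = rng.random
    log = math.log
    while next_sample <= t_end:
        a1 = alpha_m
        a2 = beta_m * m
        a3 = alpha_s
        a4 = beta_s * s
        a5 = k * s * m
        a6 = gamma * m
        a7 = beta_p * p
        a0 = a1 + a2 + a3 + a4 + a5 + a6 + a7
        if a0 <= 0.0:
            # absorbing state: emit samples up to the horizon
            while next_sample <= t_end:
                samples_m.append(m)
                samples_s.append(s)
                samples_p.append(p)
                next_sample += interval
            break
        t += -log(1.0 - rnd()) / a0
        while next_sample <= t_end and t >= next_sample:
            samples_m.append(m)
            samples_s.append(s)
            samples_p.append(p)
            next_sample += interval
        if next_sample > t_end:
            break
        events += 1
        u = rnd() * a0
        if u < a1:
            m += 1
        elif u < a1 + a2:
            m -= 1
        elif u < a1 + a2 + a3:
            s += 1
        elif u < a1 + a2 + a3 + a4:
            s -= 1
        elif u < a1 + a2 + a3 + a4 + a5:
            m -= 1
            s -= 1
        elif u < a1 + a2 + a3 + a4 + a5 + a6:
            p += 1
        else:
            p -= 1
    return samples_m, samples_s, samples_p, events


def gillespie_simulate(params: KineticParameters, config: SSAConfig) -> SSAResult:
    """Exact stochastic simulation of the seven elementary reactions.

    Each trajectory uses an independent deterministic child seed; standard
    errors come from batch means over trajectories.  Runs are bitwise
    reproducible for a given config.
    """
    eff = effective_rates(params)
    m0 = int(round(params.alpha_m / eff.beta_m))
    s0 = int(round(params.alpha_s / params.beta_s))
    p0 = int(round(eff.gamma * m0 / params.beta_p))
    t_end = config.t_burn_in + config.t_sample

    ss_seq = np.random.SeedSequence(config.seed)
    child_seeds = [int(s.generate_state(1)[0]) for s in ss_seq.spawn(config.n_trajectories)]

    traj_mean = {k: [] for k in _SPECIES}
    traj_var = {k: [] for k in _SPECIES}
    traj_eta = []
    n_samples = 0
    event_count = 0
    for seed in child_seeds:
        rng = random.Random(seed)
        sm, ssamp, sp, events = _simulate_one(
            params.alpha_m, eff.beta_m, params.alpha_s, params.beta_s,
            eff.k, eff.gamma, params.beta_p,
            m0, s0, p0, config.t_burn_in, t_end, config.sample_interval, rng,
        )
        event_count += events
        n_samples += len(sm)
        arrs = {"m": np.asarray(sm, float), "s": np.asarray(ssamp, float), "p": np.asarray(sp, float)}
        for kname, arr in arrs.items():
            traj_mean[kname].append(arr.mean())
            traj_var[kname].append(arr.var(ddof=1) if arr.size > 1 else 0.0)
        mp = arrs["p"].mean()
        traj_eta.append(arrs["p"].var(ddof=1) / mp**2 if mp > 0 else math.nan)

    nt = config.n_trajectories

    def batch(vals):
        vals = np.asarray(vals, float)
        mu = float(np.mean(vals))
        se = float(np.std(vals, ddof=1) / math.sqrt(nt)) if nt > 1 else math.nan
        return mu, se

    mean, se_mean, var = {}, {}, {}
    for kname in _SPECIES:
        mean[kname], se_mean[kname] = batch(traj_mean[kname])
        var[kname] = float(np.mean(traj_var[kname]))
    eta_p, se_eta_p = batch(traj_eta)
    return SSAResult(
        mean=mean,
        var=var,
        se_mean=se_mean,
        eta_p=eta_p,
        se_eta_p=se_eta_p,
        n_samples=n_samples,
        event_count=event_count,
        seed=config.seed,
        per_trajectory={"mean_p": traj_mean["p"], "eta_p": traj_eta},
    )


def detect_local_maximum(
    values: Sequence[float],
    errors: Optional[Sequence[float]] = None,
    sigma_mult: float = 1.0,
) -> Optional[int]:
    """Index of an interior point exceeding both neighbors beyond noise.

    A candidate ``i`` must satisfy
    ``values[i] > values[j] + sigma_mult * sqrt(err[i]^2 + err[j]^2)`` for
    both neighbors ``j``; among candidates the largest value wins.  Returns
    ``None`` for monotone profiles.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 5:
        raise ValueError("need at least 5 grid points")
    e = np.zeros_like(v) if errors is None else np.asarray(errors, dtype=float)
    if np.any(e < 0):
        raise ValueError("errors must be nonnegative")
    best: Optional[int] = None
    for i in range(1, v.size - 1):
        lo = sigma_mult * math.hypot(e[i], e[i - 1])
        hi = sigma_mult * math.hypot(e[i], e[i + 1])
        if v[i] > v[i - 1] + lo and v[i] > v[i + 1] + hi:
            if best is None or v[i] > v[best]:
                best = i
    return best
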