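"""Deterministic layer of the three-state silencing model.

An sRNA pairs with the 5'UTR of a target mRNA whose interaction region can
be naked, ribosome-bound or sRNA-bound.  After coarse-graining the fast
binding/unbinding steps, the mean-field kinetics of mRNA ``m``, sRNA ``s``
and protein ``p`` are

    dm/dt = alpha_m - beta_m * m - k * s * m
    ds/dt = alpha_s - beta_s * s - k * s * m
    dp/dt = gamma * m - beta_p * p

where the effective rates ``beta_m``, ``k`` and ``gamma`` depend on the
ribosome-RBS affinity ``x`` (see :func:`effective_rates`).  This module
provides the effective-rate map, closed-form and numeric steady states,
silencing efficacy (fold repression), response curves over several axes,
and regime classification.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import yaml
from scipy import optimize
from scipy.integrate import solve_ivp

__all__ = [
    "KineticParameters",
    "EffectiveRates",
    "SteadyState",
    "ResponseCurve",
    "RegimeLabel",
    "MaxEfficacyResult",
    "ParameterError",
    "UndefinedEfficacyError",
    "ConvergenceError",
    "PARAM_KEYS",
    "PRESETS",
    "get_preset",
    "load_params",
    "dump_params",
    "effective_rates",
    "steady_state_closed_form",
    "steady_state_numeric",
    "efficacy",
    "unregulated_expression",
    "response_curve",
    "find_max_efficacy",
    "classify_regime",
]

PARAM_KEYS = (
    "alpha_m",
    "alpha_s",
    "beta_m0",
    "beta_s",
    "beta_p",
    "k0",
    "gamma0",
    "x",
    "w",
    "y",
    "z",
)

AXIS_KINDS = ("x", "translational_activity", "unregulated_expression", "alpha_s")


class ParameterError(ValueError):
    """A kinetic parameter violates its domain constraint."""


class UndefinedEfficacyError(ValueError):
    """Efficacy is undefined (zero unregulated expression)."""


class ConvergenceError(RuntimeError):
    """The iterative steady-state solver failed to converge."""


@dataclass(frozen=True)
class KineticParameters:
    """All rates (per minute, molecule counts) and dimensionless ratios.

    ``x`` is the ribosome-RBS binding affinity, ``w`` the ratio of
    ribosome-bound to naked mRNA degradation rates, ``y`` the ratio of
    sRNA-mRNA interaction rates with versus without a bound ribosome and
    ``z`` the ratio of sRNA-mRNA complex dissociation to degradation.
    """

    alpha_m: float
    alpha_s: float
    beta_m0: float
    beta_s: float
    beta_p: float
    k0: float
    gamma0: float
    x: float
    w: float
    y: float
    z: float

    def __post_init__(self) -> None:
        strictly_positive = ("alpha_m", "beta_m0", "beta_s", "beta_p", "k0", "gamma0", "w", "y")
        for name in strictly_positive:
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ParameterError(f"{name} must be finite and > 0, got {v!r}")
        for name in ("alpha_s", "x", "z"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ParameterError(f"{name} must be finite and >= 0, got {v!r}")

    def with_(self, **kwargs: float) -> "KineticParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class EffectiveRates:
    """Coarse-grained rates at a given ribosome affinity ``x``.

    ``lam`` is the leakage rate ``beta_m * beta_s / k`` controlling how
    sharp the threshold-linear silencing response is, and ``b`` the protein
    burst size ``gamma / beta_m``.
    """

    beta_m: float
    k: float
    gamma: float
    lam: float
    b: float


@dataclass(frozen=True)
class SteadyState:
    m: float
    s: float
    p: float
    residual_norm: float


@dataclass(frozen=True)
class RegimeLabel:
    label: str  # expressed | crossover | silenced
    ratio: float


@dataclass(frozen=True)
class MaxEfficacyResult:
    x_opt: float
    efficacy_opt: float
    at_boundary: bool


@dataclass(frozen=True)
class ResponseCurve:
    axis_kind: str
    axis_values: np.ndarray
    efficacy: np.ndarray
    expression_on: np.ndarray
    expression_off: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "axis_kind": self.axis_kind,
                "axis_value": self.axis_values,
                "expression_off": self.expression_off,
                "expression_on": self.expression_on,
                "efficacy": self.efficacy,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# Two bundled reference parameter sets.  They differ only in the naked mRNA
# degradation rate (0.40 vs 0.42 /min) and correspondingly in k0, which in
# the second set is pinned by a unit basal leakage rate beta_m0*beta_s/k0 = 1.
_FIG2 = dict(
    alpha_m=1.0, alpha_s=1.0, beta_m0=0.4, beta_s=0.1, beta_p=1.0 / 60.0,
    k0=0.04, gamma0=1.0, x=1.0, w=1.0, y=100.0, z=0.001,
)
_FIG5 = dict(
    alpha_m=1.0, alpha_s=1.0, beta_m0=0.42, beta_s=0.1, beta_p=1.0 / 60.0,
    k0=0.042, gamma0=1.0, x=1.0, w=1.0, y=100.0, z=0.001,
)
PRESETS = {"fig2": _FIG2, "fig5": _FIG5}


def get_preset(name: str, **overrides: float) -> KineticParameters:
    """Return a named preset parameter set, optionally overriding fields."""
    try:
        base = dict(PRESETS[name])
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    base.update(overrides)
    return KineticParameters(**base)


def load_params(path) -> KineticParameters:
    """Read a flat key/value (YAML) parameter file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ParameterError(f"parameter file {path} must hold a flat mapping")
    unknown = set(raw) - set(PARAM_KEYS)
    if unknown:
        raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
    missing = set(PARAM_KEYS) - set(raw)
    if missing:
        raise ParameterError(f"missing parameter keys: {sorted(missing)}")
    return KineticParameters(**{k: float(raw[k]) for k in PARAM_KEYS})


def dump_params(params: KineticParameters, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: float(getattr(params, k)) for k in PARAM_KEYS}, fh, sort_keys=False)


def effective_rates(params: KineticParameters) -> EffectiveRates:
    """Map microscopic parameters to the effective coarse-grained rates.

    beta_m = beta_m0 (1 + w x)/(1 + x)
    k      = k0 (1 + x y) / ((1 + x)(1 + z + x y z))
    gamma  = gamma0 x/(1 + x)
    """
    x, w, y, z = params.x, params.w, params.y, params.z
    beta_m = params.beta_m0 * (1.0 + w * x) / (1.0 + x)
    k = params.k0 * (1.0 + x * y) / ((1.0 + x) * (1.0 + z + x * y * z))
    gamma = params.gamma0 * x / (1.0 + x)
    lam = beta_m * params.beta_s / k
    return EffectiveRates(beta_m=beta_m, k=k, gamma=gamma, lam=lam, b=gamma / beta_m)


def _rhs(params: KineticParameters, eff: EffectiveRates, m: float, s: float, p: float):
    dm = params.alpha_m - eff.beta_m * m - eff.k * s * m
    ds = params.alpha_s - params.beta_s * s - eff.k * s * m
    dp = eff.gamma * m - params.beta_p * p
    return dm, ds, dp


def _residual_norm(params: KineticParameters, eff: EffectiveRates, m, s, p) -> float:
    return max(abs(v) for v in _rhs(params, eff, m, s, p))


def steady_state_closed_form(params: KineticParameters) -> SteadyState:
    """Unique nonnegative steady state of the mass-action system.

    Substituting the sRNA balance into the mRNA balance yields a quadratic
    in ``m`` whose positive root is

        m = [(alpha_m - alpha_s - lam) + sqrt((...)^2 + 4 lam alpha_m)] / (2 beta_m)

    evaluated in a cancellation-safe form.
    """
    eff = effective_rates(params)
    lam = eff.lam

    def positive_root(alpha_this: float, alpha_other: float, beta: float) -> float:
        # the eliminated system is symmetric under (m, alpha_m, beta_m) <->
        # (s, alpha_s, beta_s); evaluate the positive quadratic root in a
        # cancellation-safe form
        a = alpha_this - alpha_other - lam
        disc = math.hypot(a, 2.0 * math.sqrt(lam * alpha_this))  # overflow-safe
        if a >= 0.0:
            return (a + disc) / (2.0 * beta)
        return 2.0 * lam * alpha_this / (beta * (disc - a))

    m = positive_root(params.alpha_m, params.alpha_s, eff.beta_m)
    s = positive_root(params.alpha_s, params.alpha_m, params.beta_s)
    p = eff.gamma * m / params.beta_p
    return SteadyState(m=m, s=s, p=p, residual_norm=_residual_norm(params, eff, m, s, p))


def steady_state_numeric(params: KineticParameters, tol: float = 1e-10) -> SteadyState:
    """Iterative root of the mass-action system (oracle for the closed form).

    Starts from the no-interaction fixed point and polishes with a hybrid
    Newton method; falls back to integrating the ODEs toward equilibrium if
    the first attempt leaves the positive orthant or fails.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    eff = effective_rates(params)

    def fun(v):
        return _rhs(params, eff, v[0], v[1], v[2])

    m0 = params.alpha_m / eff.beta_m
    s0 = params.alpha_s / params.beta_s
    start = np.array([m0, s0, eff.gamma * m0 / params.beta_p])
    sol = optimize.root(fun, start, method="hybr", tol=1e-13)
    ok = sol.success and np.all(sol.x >= -tol)
    if ok:
        ok = _residual_norm(params, eff, *sol.x) <= tol * max(1.0, params.alpha_m)
    if not ok:
        t_end = 60.0 / min(eff.beta_m, params.beta_s, params.beta_p)
        ivp = solve_ivp(
            lambda t, v: fun(v), (0.0, t_end), [0.0, 0.0, 0.0],
            method="LSODA", rtol=1e-10, atol=1e-12,
        )
        sol = optimize.root(fun, ivp.y[:, -1], method="hybr", tol=1e-13)
        if not sol.success:
            raise ConvergenceError(
                f"steady-state solver did not converge: {sol.message}; params={params}"
            )
    m, s, p = (max(v, 0.0) for v in sol.x)
    res = _residual_norm(params, eff, m, s, p)
    if res > tol * max(1.0, params.alpha_m):
        raise ConvergenceError(f"residual {res:.3e} exceeds tolerance {tol:.3e}")
    return SteadyState(m=m, s=s, p=p, residual_norm=res)


def unregulated_expression(params: KineticParameters) -> float:
    """Mean protein level with the sRNA absent: gamma * alpha_m / (beta_m * beta_p)."""
    eff = effective_rates(params)
    return eff.gamma * params.alpha_m / (eff.beta_m * params.beta_p)


def efficacy(params: KineticParameters, as_ratio: bool = False) -> float:
    """Fold repression p(alpha_s=0) / p(alpha_s), always >= 1.

    With ``as_ratio=True`` the reciprocal (regulated/unregulated, <= 1) is
    returned instead.  Translation and protein turnover cancel, so this is
    a pure mRNA-level ratio.
    """
    if params.alpha_s <= 0:
        raise ParameterError("efficacy requires alpha_s > 0")
    if params.x == 0:
        raise UndefinedEfficacyError("unregulated expression is zero at x = 0")
    m_off = params.alpha_m / effective_rates(params).beta_m
    m_on = steady_state_closed_form(params).m
    fold = m_off / m_on
    return 1.0 / fold if as_ratio else fold


def _x_from_axis(axis_kind: str, value: float) -> float:
    if axis_kind == "x" or axis_kind == "unregulated_expression":
        return value
    if axis_kind == "translational_activity":
        if not 0.0 < value < 1.0:
            raise ValueError("translational activity gamma/gamma0 must lie in (0, 1)")
        return value / (1.0 - value)
    raise ValueError(f"unknown axis kind {axis_kind!r}")


def response_curve(
    params: KineticParameters, axis_kind: str, grid: Sequence[float]
) -> ResponseCurve:
    """Efficacy and on/off expression along a parameter axis.

    ``axis_kind`` selects the swept quantity: the affinity ``x`` itself, the
    translational activity ``gamma/gamma0 = x/(1+x)``, the unregulated
    expression level (the grid is then an ``x`` grid mapped through
    :func:`unregulated_expression`), or the sRNA transcription rate
    ``alpha_s``.
    """
    if axis_kind not in AXIS_KINDS:
        raise ValueError(f"axis_kind must be one of {AXIS_KINDS}")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    if grid.size < 3:
        raise ValueError("grid must have at least 3 points")
    if not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")

    axis_values = np.empty_like(grid)
    eff_vals = np.empty_like(grid)
    p_on = np.empty_like(grid)
    p_off = np.empty_like(grid)
    for i, g in enumerate(grid):
        if axis_kind == "alpha_s":
            pt = params.with_(alpha_s=float(g))
            axis_values[i] = g
        else:
            pt = params.with_(x=_x_from_axis(axis_kind, float(g)))
            axis_values[i] = unregulated_expression(pt) if axis_kind == "unregulated_expression" else g
        p_off[i] = unregulated_expression(pt)
        p_on[i] = steady_state_closed_form(pt).p
        if pt.alpha_s <= 0:
            eff_vals[i] = 1.0
        else:
            eff_vals[i] = efficacy(pt) if pt.x > 0 else np.nan
    return ResponseCurve(
        axis_kind=axis_kind,
        axis_values=axis_values,
        efficacy=eff_vals,
        expression_on=p_on,
        expression_off=p_off,
    )


def find_max_efficacy(
    params: KineticParameters,
    x_range: tuple[float, float],
    n_scan: int = 80,
) -> MaxEfficacyResult:
    """Maximize fold repression over log-spaced ``x`` in ``x_range``.

    A log-grid pre-scan locates the basin; an interior maximum is refined by
    bounded scalar optimization, while a maximum at a range endpoint is
    returned with ``at_boundary=True`` (the monotone case).
    """
    x_lo, x_hi = x_range
    if not (0 < x_lo < x_hi < math.inf):
        raise ValueError("x_range must be positive, finite and increasing")

    def neg_log_eff(u: float) -> float:
        return -math.log(efficacy(params.with_(x=math.exp(u))))

    u_grid = np.linspace(math.log(x_lo), math.log(x_hi), n_scan)
    vals = np.array([-neg_log_eff(u) for u in u_grid])
    i = int(np.argmax(vals))
    if i == 0 or i == n_scan - 1:
        x_opt = float(np.exp(u_grid[i]))
        return MaxEfficacyResult(x_opt=x_opt, efficacy_opt=float(np.exp(vals[i])), at_boundary=True)
    res = optimize.minimize_scalar(
        neg_log_eff, bounds=(u_grid[i - 1], u_grid[i + 1]), method="bounded",
        options={"xatol": 1e-10},
    )
    return MaxEfficacyResult(
        x_opt=float(math.exp(res.x)),
        efficacy_opt=float(math.exp(-res.fun)),
        at_boundary=False,
    )


def classify_regime(
    params: KineticParameters, t_lo: float = 0.5, t_hi: float = 2.0
) -> RegimeLabel:
    """Classify the transcription-ratio regime of the sRNA/target pair."""
    if not (0 < t_lo < 1 < t_hi):
        raise ValueError("thresholds must satisfy 0 < t_lo < 1 < t_hi")
    ratio = params.alpha_s / params.alpha_m
    if ratio < t_lo:
        label = "expressed"
    elif ratio >= t_hi:
        label = "silenced"
    else:
        label = "crossover"
    return RegimeLabel(label=label, ratio=ratio)
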