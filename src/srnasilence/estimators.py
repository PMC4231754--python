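"""Measurement estimators for the three assay modalities.

Expression is the slope of total fluorescence versus OD inside the linear
detection window.  Biological repeats are combined with the aggregation
formulas

    g = n^-1 * sum_r g_r
    sigma_g = n^-1 * sqrt( sum_r [ (g_r - g)^2 + sigma_{g_r}^2 ] )

(note the n^-1 prefactor applied to the combined spread, not the usual
SEM; a conventional SEM is available behind a flag but is never the
default).  The same repeat-combination rule is used for the CV^2 noise
estimator.  Half-lives come from an efficiency-corrected relative
quantification of the Cq series followed by a nonlinear fit of
f(t) = f0 * 2^(-t/tau).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "LinearWindowRule",
    "SlopeEstimate",
    "ExpressionEstimate",
    "EfficacyEstimate",
    "NoiseEstimate",
    "HalfLifeEstimate",
    "slope_expression",
    "aggregate_expression",
    "estimate_expression",
    "efficacy_estimate",
    "cv2_estimate",
    "fit_half_life",
    "ddcq_relative_quantity",
]


@dataclass(frozen=True)
class LinearWindowRule:
    """Linear-window selection: central OD band plus ceiling masking."""

    od_lower_frac: float = 0.2
    od_upper_frac: float = 0.8
    fluor_ceiling: Optional[float] = None
    min_points: int = 4


@dataclass(frozen=True)
class SlopeEstimate:
    slope: float
    se: float
    n_points: int
    flagged: bool = False


@dataclass(frozen=True)
class ExpressionEstimate:
    g: float
    sigma_g: float
    n_repeats: int
    g_r: tuple = ()
    sigma_gr: tuple = ()
    flagged: bool = False


@dataclass(frozen=True)
class EfficacyEstimate:
    ratio: float            # expression(on)/expression(off), <= 1 under repression
    fold_repression: float  # reciprocal, >= 1 under repression
    se_ratio: float
    se_fold: float
    flagged: bool = False


@dataclass(frozen=True)
class NoiseEstimate:
    eta: float
    se_eta: float
    mean_gfp: float
    se_mean: float
    n_repeats: int
    flagged: bool = False


@dataclass(frozen=True)
class HalfLifeEstimate:
    tau_half: float
    f0: float
    fit_rss: float
    n_used: int
    excluded_points: tuple = ()


def slope_expression(
    od: Sequence[float],
    fluor: Sequence[float],
    rule: Optional[LinearWindowRule] = None,
) -> SlopeEstimate:
    """OLS slope of fluorescence vs OD restricted to the linear window."""
    rule = rule or LinearWindowRule()
    od = np.asarray(od, dtype=float)
    fluor = np.asarray(fluor, dtype=float)
    lo = od.min() + rule.od_lower_frac * (od.max() - od.min())
    hi = od.min() + rule.od_upper_frac * (od.max() - od.min())
    mask = (od >= lo) & (od <= hi)
    if rule.fluor_ceiling is not None:
        mask &= fluor < rule.fluor_ceiling
    n = int(mask.sum())
    if n < rule.min_points:
        # fall back to whatever un-saturated points exist, flagged
        mask = np.ones_like(od, dtype=bool)
        if rule.fluor_ceiling is not None:
            mask &= fluor < rule.fluor_ceiling
        n = int(mask.sum())
        if n < 2:
            return SlopeEstimate(slope=math.nan, se=math.nan, n_points=n, flagged=True)
        x, y = od[mask], fluor[mask]
        slope, se = _ols(x, y)
        return SlopeEstimate(slope=slope, se=se, n_points=n, flagged=True)
    slope, se = _ols(od[mask], fluor[mask])
    return SlopeEstimate(slope=slope, se=se, n_points=n, flagged=False)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xbar = x.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    slope = float(np.sum((x - xbar) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * xbar)
    resid = y - intercept - slope * x
    dof = x.size - 2
    se = math.sqrt(float(np.sum(resid**2)) / dof / sxx) if dof > 0 else 0.0
    return slope, se


def aggregate_expression(
    per_repeat: Sequence[tuple[float, float]],
    autofluor: Optional[ExpressionEstimate] = None,
    conventional_sem: bool = False,
) -> ExpressionEstimate:
    """Combine per-repeat slopes into a mean expression with its error.

    Autofluorescence (when given) is subtracted from every repeat and its
    uncertainty folded into the per-repeat errors in quadrature.  Negative
    corrected means are flagged, never clipped.
    """
    if len(per_repeat) < 1:
        raise ValueError("need at least one repeat")
    g_r = np.array([g for g, _ in per_repeat], dtype=float)
    s_r = np.array([s for _, s in per_repeat], dtype=float)
    if autofluor is not None:
        g_r = g_r - autofluor.g
        s_r = np.sqrt(s_r**2 + autofluor.sigma_g**2)
    n = g_r.size
    g = float(g_r.mean())
    if conventional_sem:
        sigma_g = float(g_r.std(ddof=1) / math.sqrt(n)) if n > 1 else float(s_r[0])
    else:
        sigma_g = float(math.sqrt(float(np.sum((g_r - g) ** 2 + s_r**2))) / n)
    return ExpressionEstimate(
        g=g,
        sigma_g=sigma_g,
        n_repeats=n,
        g_r=tuple(g_r.tolist()),
        sigma_gr=tuple(s_r.tolist()),
        flagged=bool(g <= 0),
    )


def estimate_expression(
    plate: pd.DataFrame,
    rule: Optional[LinearWindowRule] = None,
    autofluor_variant: str = "autofluor",
) -> dict[tuple[str, str], ExpressionEstimate]:
    """Per-(variant, induction) expression estimates from a plate dataset.

    Expects the long CSV layout of the plate generator (columns ``variant,
    induction, replicate, repeat, od, fluor``).  Technical replicates are
    averaged within each repeat; the autofluorescence strain provides the
    correction sample and is returned uncorrected under key
    ``(autofluor_variant, "none")``.
    """
    rule = rule or LinearWindowRule()

    def per_repeat_slopes(group: pd.DataFrame) -> tuple[float, float]:
        slopes = [
            slope_expression(rep["od"].to_numpy(), rep["fluor"].to_numpy(), rule).slope
            for _, rep in group.groupby("replicate")
        ]
        slopes = np.asarray(slopes, dtype=float)
        se = float(slopes.std(ddof=1) / math.sqrt(slopes.size)) if slopes.size > 1 else 0.0
        return float(slopes.mean()), se

    by_sample: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for (variant, induction, _repeat), grp in plate.groupby(["variant", "induction", "repeat"]):
        by_sample.setdefault((variant, induction), []).append(per_repeat_slopes(grp))

    af_key = next((k for k in by_sample if k[0] == autofluor_variant), None)
    autofluor = aggregate_expression(by_sample[af_key]) if af_key else None

    out: dict[tuple[str, str], ExpressionEstimate] = {}
    for key, repeats in by_sample.items():
        if key == af_key:
            out[key] = autofluor
        else:
            out[key] = aggregate_expression(repeats, autofluor=autofluor)
    return out


def efficacy_estimate(on: ExpressionEstimate, off: ExpressionEstimate) -> EfficacyEstimate:
    """on/off expression ratio with first-order (delta-method) error."""
    if off.g <= 0:
        return EfficacyEstimate(
            ratio=math.nan, fold_repression=math.nan, se_ratio=math.nan, se_fold=math.nan,
            flagged=True,
        )
    ratio = on.g / off.g
    rel = math.sqrt((on.sigma_g / on.g) ** 2 + (off.sigma_g / off.g) ** 2) if on.g > 0 else math.inf
    se_ratio = abs(ratio) * rel
    fold = 1.0 / ratio if ratio > 0 else math.nan
    se_fold = se_ratio / ratio**2 if ratio > 0 else math.nan
    return EfficacyEstimate(
        ratio=ratio, fold_repression=fold, se_ratio=se_ratio, se_fold=se_fold,
        flagged=bool(on.g <= 0),
    )


def _mean_var(x: np.ndarray) -> tuple[float, float]:
    return float(x.mean()), float(x.var(ddof=1))


def cv2_estimate(
    flow: pd.DataFrame,
    autofluor_sample,
    min_cells: int = 1000,
) -> NoiseEstimate:
    """Autofluorescence-corrected CV^2 of a flow sample.

    ``flow`` holds the cells of one (variant, induction) sample with
    ``repeat``/``replicate``/``cell_fluor`` columns; ``autofluor_sample``
    is either an array of background cells or a precomputed
    ``(mean, variance)`` pair.  Within each repeat, replicate means and
    variances are averaged, the background mean and variance subtracted,
    and eta_r = var/mean^2 formed; repeats are then combined with the same
    n^-1 * sqrt(sum[...]) rule as expression.
    """
    if isinstance(autofluor_sample, tuple):
        af_mean, af_var = float(autofluor_sample[0]), float(autofluor_sample[1])
    else:
        af = np.asarray(autofluor_sample, dtype=float)
        af_mean, af_var = _mean_var(af)

    eta_r, se_eta_r, mean_r, se_mean_r = [], [], [], []
    flagged = False
    for _repeat, grp in flow.groupby("repeat"):
        rep_means, rep_vars, rep_etas = [], [], []
        for _rep, cells in grp.groupby("replicate"):
            vals = cells["cell_fluor"].to_numpy(dtype=float)
            if vals.size < min_cells:
                flagged = True
            mu, var = _mean_var(vals)
            rep_means.append(mu)
            rep_vars.append(var)
            mu_c, var_c = mu - af_mean, var - af_var
            rep_etas.append(var_c / mu_c**2 if mu_c > 0 else math.nan)
        mu_c = float(np.mean(rep_means)) - af_mean
        var_c = float(np.mean(rep_vars)) - af_var
        if mu_c <= 0:
            flagged = True
            eta_r.append(math.nan)
            se_eta_r.append(math.nan)
        else:
            eta_r.append(var_c / mu_c**2)
            rep_etas = np.asarray(rep_etas, dtype=float)
            se_eta_r.append(
                float(np.nanstd(rep_etas, ddof=1) / math.sqrt(rep_etas.size))
                if rep_etas.size > 1
                else 0.0
            )
        mean_r.append(mu_c)
        rep_means = np.asarray(rep_means, dtype=float)
        se_mean_r.append(
            float(rep_means.std(ddof=1) / math.sqrt(rep_means.size)) if rep_means.size > 1 else 0.0
        )

    n = len(eta_r)
    eta_arr, mean_arr = np.asarray(eta_r), np.asarray(mean_r)
    eta = float(np.mean(eta_arr))
    mean_gfp = float(np.mean(mean_arr))
    if np.any(np.isnan(eta_arr)):
        return NoiseEstimate(eta=math.nan, se_eta=math.nan, mean_gfp=mean_gfp,
                             se_mean=math.nan, n_repeats=n, flagged=True)
    se_eta = float(math.sqrt(float(np.sum((eta_arr - eta) ** 2 + np.asarray(se_eta_r) ** 2))) / n)
    se_mean = float(
        math.sqrt(float(np.sum((mean_arr - mean_gfp) ** 2 + np.asarray(se_mean_r) ** 2))) / n
    )
    return NoiseEstimate(
        eta=eta, se_eta=se_eta, mean_gfp=mean_gfp, se_mean=se_mean, n_repeats=n, flagged=flagged
    )


def ddcq_relative_quantity(
    cq_target: Sequence[float],
    cq_ref: Sequence[float],
    ref_point: int = 0,
    efficiencies: tuple[float, float] = (2.0, 2.0),
) -> np.ndarray:
    """Efficiency-corrected relative abundance against an internal control.

    relative = E_t^(dCq_t) / E_r^(dCq_r) with dCq = Cq(ref_point) - Cq(sample).
    """
    e_t, e_r = efficiencies
    for e in (e_t, e_r):
        if not 1.0 < e <= 2.0:
            raise ValueError("amplification efficiencies must lie in (1, 2]")
    cq_t = np.asarray(cq_target, dtype=float)
    cq_r = np.asarray(cq_ref, dtype=float)
    dcq_t = cq_t[ref_point] - cq_t
    dcq_r = cq_r[ref_point] - cq_r
    return e_t**dcq_t / e_r**dcq_r


def fit_half_life(
    decay: pd.DataFrame,
    snr_threshold: float = 1.0,
    efficiencies: tuple[float, float] = (2.0, 2.0),
) -> HalfLifeEstimate:
    """Half-life from a Cq decay series via f(t) = f0 * 2^(-t/tau).

    Time points whose replicate Cq spread (max - min) exceeds
    ``snr_threshold`` cycles are excluded as low signal-to-noise and logged;
    at least three usable points are required.
    """
    excluded = []
    times, cq_t_mean, cq_r_mean = [], [], []
    for t, grp in decay.groupby("t_min"):
        spread = float(grp["cq_target"].max() - grp["cq_target"].min())
        if spread > snr_threshold:
            excluded.append((float(t), f"replicate Cq spread {spread:.2f} > {snr_threshold}"))
            continue
        times.append(float(t))
        cq_t_mean.append(float(grp["cq_target"].mean()))
        cq_r_mean.append(float(grp["cq_ref"].mean()))
    if len(times) < 3:
        raise ValueError(
            f"only {len(times)} usable time points after exclusions {excluded}; need >= 3"
        )
    t = np.asarray(times)
    rel = ddcq_relative_quantity(cq_t_mean, cq_r_mean, ref_point=0, efficiencies=efficiencies)

    def model(tt, f0, tau):
        return f0 * 2.0 ** (-tt / tau)

    # crude slope-based start for tau
    if rel[-1] > 0 and rel[0] > rel[-1]:
        tau0 = (t[-1] - t[0]) / math.log2(rel[0] / rel[-1])
    else:
        tau0 = 2.0
    popt, _ = curve_fit(
        model, t, rel, p0=(float(rel[0] * 2.0 ** (t[0] / tau0)), tau0),
        bounds=([0.0, 1e-6], [np.inf, np.inf]), maxfev=10000,
    )
    f0, tau = float(popt[0]), float(popt[1])
    rss = float(np.sum((rel - model(t, f0, tau)) ** 2))
    return HalfLifeEstimate(
        tau_half=tau, f0=f0, fit_rss=rss, n_used=len(times), excluded_points=tuple(excluded)
    )
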