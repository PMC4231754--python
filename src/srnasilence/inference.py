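"""Pipeline head: affinity inversion, mode fitting and noise signature.

The discriminating question is whether ribosome occupancy at the RBS
hinders (y/w < 1, "competition") or effectively enhances (y/w > 1,
"recruitment") sRNA action.  Per-variant affinities are inverted from
unregulated expression, the interaction parameters are fitted by weighted
least squares on log fold-repression, and a residual bootstrap yields a
confidence interval for log10(y/w) whose sign decides the mode label.
The published analysis argued the mode from curve shapes; the explicit
bootstrap classification here is a formalization of that argument.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import estimators as est
from . import synthetic_data as synth
from .model_core import KineticParameters, efficacy, get_preset, unregulated_expression
from .stochastic import detect_local_maximum

__all__ = [
    "InversionError",
    "ModeFitResult",
    "NoiseSignatureVerdict",
    "PipelineConfig",
    "PipelineReport",
    "invert_x_from_expression",
    "fit_interaction_mode",
    "noise_signature_test",
    "run_pipeline",
]


class InversionError(ValueError):
    """Expression at or above the saturation level; affinity unbounded."""


def invert_x_from_expression(
    expr_off: float,
    params: KineticParameters,
    max_fraction: Optional[float] = None,
) -> float:
    """Ribosome affinity implied by an unregulated expression level.

    Unregulated expression is p0 * x / (1 + w x) with
    p0 = gamma0 * alpha_m / (beta_m0 * beta_p), so
    x = expr / (p0 - w * expr), valid below the saturation level p0 / w.
    ``max_fraction`` (e.g. 0.99) optionally clamps noisy measurements to
    that fraction of saturation instead of raising.
    """
    if expr_off <= 0:
        raise InversionError(f"expression must be positive, got {expr_off!r}")
    p0 = params.gamma0 * params.alpha_m / (params.beta_m0 * params.beta_p)
    p_sat = p0 / params.w
    if expr_off >= p_sat:
        if max_fraction is None:
            raise InversionError(
                f"expression {expr_off:.4g} is at or above saturation {p_sat:.4g}"
            )
        expr_off = max_fraction * p_sat
    elif max_fraction is not None:
        expr_off = min(expr_off, max_fraction * p_sat)
    return expr_off / (p0 - params.w * expr_off)


@dataclass(frozen=True)
class ModeFitResult:
    y_hat: float
    w_hat: float
    k0_hat: float
    x_hat: dict
    loss: float
    mode_label: str  # competition | recruitment | indeterminate
    ci_log10_y_over_w: tuple
    n_boot: int
    seed: int
    converged: bool = True
    warnings: tuple = ()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ci_log10_y_over_w"] = list(self.ci_log10_y_over_w)
        d["warnings"] = list(self.warnings)
        return d


_FREE_ALLOWED = ("y", "k0", "w")


def fit_interaction_mode(
    dataset: pd.DataFrame,
    known_params: KineticParameters,
    free: Sequence[str] = ("y", "k0"),
    n_boot: int = 200,
    seed: int = 0,
    max_fraction: float = 0.99,
) -> ModeFitResult:
    """Fit the interaction mode from per-variant efficacy measurements.

    ``dataset`` needs columns ``variant, expr_off, fold, fold_se`` where
    ``expr_off`` is in protein-molecule units (fluorescence divided by the
    gain).  Residuals are taken on log fold-repression with
    inverse-variance weights; ``w`` stays fixed unless explicitly freed.
    The mode label follows the sign of a residual-bootstrap percentile CI
    for log10(y/w).
    """
    for name in free:
        if name not in _FREE_ALLOWED:
            raise ValueError(f"free parameter must be among {_FREE_ALLOWED}")
    warnings: list[str] = []
    df = dataset.reset_index(drop=True)
    if len(df) < 4:
        raise ValueError("need at least 4 variants")

    x_hat = {
        str(row.variant): invert_x_from_expression(
            float(row.expr_off), known_params, max_fraction=max_fraction
        )
        for row in df.itertuples()
    }
    xs = np.array([x_hat[str(v)] for v in df["variant"]])
    span = df["expr_off"].max() / df["expr_off"].min()
    if span < 10:
        warnings.append(f"expression span {span:.1f}-fold < 10-fold; fit may be degenerate")

    log_fold = np.log(df["fold"].to_numpy(dtype=float))
    se_log = df["fold_se"].to_numpy(dtype=float) / df["fold"].to_numpy(dtype=float)
    if not np.all(np.isfinite(se_log)) or np.all(se_log == 0):
        se_log = np.ones_like(log_fold)
    se_log = np.maximum(se_log, 1e-6)

    def model_log_fold(theta: np.ndarray) -> np.ndarray:
        over = dict(zip(free, np.exp(theta)))
        out = np.empty_like(xs)
        for i, x in enumerate(xs):
            out[i] = math.log(efficacy(known_params.with_(x=float(x), **over)))
        return out

    def resid(theta: np.ndarray, target: np.ndarray) -> np.ndarray:
        return (model_log_fold(theta) - target) / se_log

    lo, hi = math.log(1e-6), math.log(1e6)  # generous log-parameter box

    def fit_once(target: np.ndarray, starts: list[np.ndarray]):
        best = None
        for x0 in starts:
            sol = least_squares(
                resid, np.clip(x0, lo, hi), args=(target,), method="trf",
                bounds=(lo, hi), max_nfev=2000,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        return best

    base = {"y": known_params.y, "k0": known_params.k0, "w": known_params.w}
    # multi-start over y to avoid the competition/recruitment saddle
    starts = []
    for y0 in (0.01, 1.0, 100.0):
        s = np.array([math.log(y0) if f == "y" else math.log(base[f]) for f in free])
        starts.append(s)
    sol = fit_once(log_fold, starts)
    theta_hat = sol.x
    fitted = dict(zip(free, np.exp(theta_hat)))
    y_hat = float(fitted.get("y", known_params.y))
    w_hat = float(fitted.get("w", known_params.w))
    k0_hat = float(fitted.get("k0", known_params.k0))
    converged = bool(sol.status > 0)

    model_at_hat = model_log_fold(theta_hat)
    resid_log = log_fold - model_at_hat

    rng = np.random.default_rng(seed)
    stats = []
    n = len(df)
    for _ in range(n_boot):
        target = model_at_hat + rng.choice(resid_log, size=n, replace=True)
        try:
            b = fit_once(target, [theta_hat])
        except Exception:
            continue
        fb = dict(zip(free, np.exp(b.x)))
        stats.append(
            math.log10(fb.get("y", known_params.y) / fb.get("w", known_params.w))
        )
    if len(stats) >= max(10, n_boot // 2) and converged:
        lo, hi = np.percentile(stats, [2.5, 97.5])
        if lo > 0:
            mode = "recruitment"
        elif hi < 0:
            mode = "competition"
        else:
            mode = "indeterminate"
        ci = (float(lo), float(hi))
    else:
        mode = "indeterminate"
        ci = (math.nan, math.nan)
        if not converged:
            warnings.append(f"fit did not converge: {sol.message}")

    return ModeFitResult(
        y_hat=y_hat,
        w_hat=w_hat,
        k0_hat=k0_hat,
        x_hat=x_hat,
        loss=float(2.0 * sol.cost),
        mode_label=mode,
        ci_log10_y_over_w=ci,
        n_boot=len(stats),
        seed=seed,
        converged=converged,
        warnings=tuple(warnings),
    )


@dataclass(frozen=True)
class NoiseSignatureVerdict:
    verdict: str  # declining | non-declining | inconclusive
    slope: float
    slope_se: float
    peak_index: Optional[int]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def noise_signature_test(
    noise_by_variant: pd.DataFrame,
    sigma_mult: float = 1.0,
    z_crit: float = 2.0,
) -> NoiseSignatureVerdict:
    """Classify the eta-vs-expression trend of a variant series.

    Expects columns ``expression, eta, se`` ordered by expression (>= 5
    rows).  An interior local maximum beyond the combined errors, or a
    significantly positive weighted slope of eta against log expression,
    is recruitment-consistent ("non-declining"); a significantly negative
    slope with no peak is competition-consistent ("declining"); otherwise
    the verdict is "inconclusive".
    """
    df = noise_by_variant.sort_values("expression").reset_index(drop=True)
    if len(df) < 5:
        raise ValueError("need at least 5 variants")
    eta = df["eta"].to_numpy(dtype=float)
    se = df["se"].to_numpy(dtype=float)
    peak = detect_local_maximum(eta, se, sigma_mult=sigma_mult)

    x = np.log10(df["expression"].to_numpy(dtype=float))
    w = 1.0 / np.maximum(se, 1e-12) ** 2
    X = np.column_stack([np.ones_like(x), x])
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    beta = cov @ (XtW @ eta)
    slope = float(beta[1])
    slope_se = float(math.sqrt(cov[1, 1]))

    if peak is not None:
        verdict = "non-declining"
    elif slope + z_crit * slope_se < 0:
        verdict = "declining"
    elif slope - z_crit * slope_se > 0:
        verdict = "non-declining"
    else:
        verdict = "inconclusive"
    return NoiseSignatureVerdict(verdict=verdict, slope=slope, slope_se=slope_se, peak_index=peak)


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass(frozen=True)
class PipelineConfig:
    preset: str = "fig2"
    truth_mode: str = "recruitment"  # recruitment | competition
    alpha_s_ratio: float = 1.0
    n_variants: int = 10
    x_span: tuple = (0.005, 50.0)
    plate: synth.PlateReaderConfig = field(default_factory=synth.PlateReaderConfig)
    flow: synth.FlowConfig = field(default_factory=synth.FlowConfig)
    n_boot: int = 200
    free: tuple = ("y", "k0")
    max_fraction: float = 0.99

    @property
    def truth_y(self) -> float:
        return {"recruitment": 100.0, "competition": 0.01}[self.truth_mode]


@dataclass(frozen=True)
class PipelineReport:
    config: dict
    seed: int
    expression: dict
    efficacy: dict
    noise: dict
    mode_fit: dict
    noise_signature: dict
    truths: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _expr_to_dict(e: est.ExpressionEstimate) -> dict:
    return {"g": e.g, "sigma_g": e.sigma_g, "n_repeats": e.n_repeats, "flagged": e.flagged}


def run_pipeline(config: PipelineConfig, seed: int) -> PipelineReport:
    """Generate -> estimate -> fit -> classify, fully seeded.

    Every random stage draws its own child seed from the master seed, so a
    report is byte-identical across re-runs with the same (config, seed).
    """
    seq = np.random.SeedSequence(seed)
    seed_plate, seed_flow, seed_boot = (int(s.generate_state(1)[0]) for s in seq.spawn(3))

    base = get_preset(config.preset, y=config.truth_y, alpha_s=config.alpha_s_ratio)
    library = synth.make_variant_library(base, config.n_variants, tuple(config.x_span))

    plate = synth.simulate_plate_reader(library, config.plate, seed_plate)
    expr = est.estimate_expression(plate.data)

    gain = config.plate.gain
    rows = []
    eff_out = {}
    for v in library:
        on, off = expr[(v.name, "on")], expr[(v.name, "off")]
        eff = est.efficacy_estimate(on, off)
        eff_out[v.name] = {
            "ratio": eff.ratio,
            "fold_repression": eff.fold_repression,
            "se_fold": eff.se_fold,
            "flagged": eff.flagged,
        }
        rows.append(
            {
                "variant": v.name,
                "expr_off": off.g / gain,
                "expr_off_se": off.sigma_g / gain,
                "fold": eff.fold_repression,
                "fold_se": eff.se_fold,
            }
        )
    dataset = pd.DataFrame(rows)

    known = base.with_(y=1.0)  # truth y is what the fit must recover
    mode_fit = fit_interaction_mode(
        dataset,
        known,
        free=tuple(config.free),
        n_boot=config.n_boot,
        seed=seed_boot,
        max_fraction=config.max_fraction,
    )

    flow = synth.simulate_flow_library(library, config.flow, seed_flow)
    af_cells = flow.data.loc[flow.data["variant"] == synth.AUTOFLUOR_VARIANT, "cell_fluor"]
    af_stats = (float(af_cells.mean()), float(af_cells.var(ddof=1)))
    noise_out = {}
    sig_rows = []
    for v in library:
        for ind in ("off", "on"):
            sample = flow.data[(flow.data["variant"] == v.name) & (flow.data["induction"] == ind)]
            ne = est.cv2_estimate(sample, af_stats)
            noise_out[f"{v.name}|{ind}"] = {
                "eta": ne.eta, "se_eta": ne.se_eta, "mean_gfp": ne.mean_gfp,
                "se_mean": ne.se_mean, "flagged": ne.flagged,
            }
        ne_on = noise_out[f"{v.name}|on"]
        sig_rows.append(
            {
                "variant": v.name,
                "expression": expr[(v.name, "off")].g,
                "eta": ne_on["eta"],
                "se": ne_on["se_eta"],
            }
        )
    signature = noise_signature_test(pd.DataFrame(sig_rows))

    return PipelineReport(
        config=dataclasses.asdict(config),
        seed=seed,
        expression={f"{k[0]}|{k[1]}": _expr_to_dict(v) for k, v in expr.items()},
        efficacy=eff_out,
        noise=noise_out,
        mode_fit=mode_fit.to_dict(),
        noise_signature=signature.to_dict(),
        truths={"plate": plate.truth, "flow": flow.truth},
    )
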