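"""Seeded generators for the three measurement modalities.

Every generator is a pure function of (config, seed) and returns both the
dataset (a tidy DataFrame) and a "truth" sidecar recording every quantity
the generator used, so downstream estimators can be scored in closed loop.

Modalities
----------
* plate reader: growth (OD) plus total-fluorescence time series per well,
  with autofluorescence background, multiplicative detector noise, an
  optional saturation ceiling and a lognormal biological-repeat factor;
* flow cytometry: per-cell fluorescence drawn from a gamma distribution
  whose CV^2 is the model's intrinsic noise plus an additive extrinsic
  constant, with additive autofluorescence;
* transcription-shutoff qPCR: Cq series for target and reference channels
  under exponential mRNA decay with configurable amplification
  efficiencies.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model_core import (
    KineticParameters,
    effective_rates,
    steady_state_closed_form,
    unregulated_expression,
)
from .stochastic import covariance

__all__ = [
    "VariantSpec",
    "PlateReaderConfig",
    "FlowConfig",
    "DecayDesign",
    "DecayTruth",
    "PlateReaderDataset",
    "FlowDataset",
    "DecayDataset",
    "make_variant_library",
    "simulate_plate_reader",
    "simulate_flow_cytometry",
    "simulate_flow_library",
    "simulate_decay_qpcr",
]

AUTOFLUOR_VARIANT = "autofluor"


@dataclass(frozen=True)
class VariantSpec:
    """One RBS variant: shared kinetics except for the ribosome affinity."""

    name: str
    x_true: float
    params: KineticParameters


def make_variant_library(
    base_params: KineticParameters,
    n_variants: int = 10,
    x_span: tuple[float, float] = (0.005, 50.0),
) -> list[VariantSpec]:
    """Log-spaced ribosome-affinity library sharing all other parameters."""
    if n_variants < 2:
        raise ValueError("need at least 2 variants")
    x_lo, x_hi = x_span
    if not (0 < x_lo < x_hi):
        raise ValueError("x_span must satisfy 0 < x_lo < x_hi")
    xs = np.logspace(math.log10(x_lo), math.log10(x_hi), n_variants)
    return [
        VariantSpec(name=f"v{i + 1:02d}", x_true=float(x), params=base_params.with_(x=float(x)))
        for i, x in enumerate(xs)
    ]


def _config_dict(cfg) -> dict:
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in dataclasses.asdict(cfg).items()}


# ---------------------------------------------------------------------------
# plate reader


@dataclass(frozen=True)
class PlateReaderConfig:
    od0: float = 0.005
    doubling_time_min: float = 40.0
    t_max_min: float = 120.0
    dt_min: float = 10.0
    gain: float = 20.0            # RFU per protein molecule
    autofluor_rate: float = 100.0  # RFU/OD of the un-induced background
    noise_sd: float = 0.01         # multiplicative detector noise
    fluor_ceiling: float = math.inf
    n_tech: int = 3
    n_repeats: int = 4
    repeat_log_sd: float = 0.1     # lognormal biological-repeat factor


@dataclass(frozen=True)
class PlateReaderDataset:
    data: pd.DataFrame
    truth: dict


def simulate_plate_reader(
    library: Sequence[VariantSpec],
    config: PlateReaderConfig,
    seed: int,
) -> PlateReaderDataset:
    """Plate-reader time series for a variant library plus blank wells.

    Wells span variant x induction {off, on} x technical replicate x
    biological repeat.  Induction "on" uses the regulated (sRNA-present)
    protein level, "off" the unregulated one.  A set of ``autofluor``
    wells (reporter fully un-induced) carries only the background rate and
    defines the correction sample for the estimators.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, config.t_max_min + 0.5 * config.dt_min, config.dt_min)
    od = config.od0 * 2.0 ** (t / config.doubling_time_min)

    g_true: dict[str, dict[str, float]] = {}
    slope_true: dict[str, float] = {}
    rows = []

    def emit(variant: str, induction: str, g_cell: float) -> None:
        for repeat in range(1, config.n_repeats + 1):
            factor = float(np.exp(rng.normal(0.0, config.repeat_log_sd))) if g_cell > 0 else 1.0
            slope = g_cell * factor
            slope_true[f"{variant}|{induction}|r{repeat}"] = slope
            for tech in range(1, config.n_tech + 1):
                eps = rng.normal(0.0, config.noise_sd, size=t.size)
                fluor = (slope + config.autofluor_rate) * od * (1.0 + eps)
                fluor = np.minimum(fluor, config.fluor_ceiling)
                well = f"{variant}-{induction}-r{repeat}-t{tech}"
                for ti, oi, fi in zip(t, od, fluor):
                    rows.append((well, variant, induction, tech, repeat, ti, oi, fi))

    for v in library:
        p_off = unregulated_expression(v.params)
        p_on = steady_state_closed_form(v.params).p
        g_true[v.name] = {"off": config.gain * p_off, "on": config.gain * p_on}
        emit(v.name, "off", g_true[v.name]["off"])
        emit(v.name, "on", g_true[v.name]["on"])
    emit(AUTOFLUOR_VARIANT, "none", 0.0)

    data = pd.DataFrame(
        rows,
        columns=["well", "variant", "induction", "replicate", "repeat", "t_min", "od", "fluor"],
    )
    truth = {
        "seed": int(seed),
        "config": _config_dict(config),
        "g_true": g_true,
        "slope_true": slope_true,
        "x_true": {v.name: v.x_true for v in library},
    }
    return PlateReaderDataset(data=data, truth=truth)


# ---------------------------------------------------------------------------
# flow cytometry


@dataclass(frozen=True)
class FlowConfig:
    n_cells: int = 50_000
    n_repeats: int = 3
    n_replicates: int = 3
    gain: float = 20.0
    eta_ext: float = 0.05      # additive extrinsic CV^2
    af_mean: float = 100.0     # additive autofluorescence, RFU
    af_sd: float = 30.0


@dataclass(frozen=True)
class FlowDataset:
    data: pd.DataFrame
    truth: dict


def simulate_flow_cytometry(
    variant: VariantSpec,
    induction: str,
    config: FlowConfig,
    seed: int,
) -> FlowDataset:
    """Per-cell fluorescence for one variant/induction sample.

    Cells are gamma-distributed with mean ``gain * <p>`` and total
    CV^2 = intrinsic eta_p + extrinsic constant (the gamma family is fully
    determined by mean and CV^2, which is all downstream analysis uses),
    plus an additive Gaussian autofluorescence draw per cell.
    """
    if induction not in ("on", "off"):
        raise ValueError("induction must be 'on' or 'off'")
    params = variant.params if induction == "on" else variant.params.with_(alpha_s=0.0)
    ss = steady_state_closed_form(params)
    if ss.p <= 0:
        raise ValueError(f"variant {variant.name} has zero expression")
    eta_int = covariance(params).eta_p
    cv2 = eta_int + config.eta_ext
    if cv2 <= 0:
        raise ValueError("total CV^2 must be positive")
    mean_fluor = config.gain * ss.p

    rng = np.random.default_rng(seed)
    shape = 1.0 / cv2
    scale = mean_fluor * cv2
    rows = []
    for repeat in range(1, config.n_repeats + 1):
        for rep in range(1, config.n_replicates + 1):
            cells = rng.gamma(shape, scale, size=config.n_cells)
            cells = cells + rng.normal(config.af_mean, config.af_sd, size=config.n_cells)
            rows.append(
                pd.DataFrame(
                    {
                        "variant": variant.name,
                        "induction": induction,
                        "repeat": repeat,
                        "replicate": rep,
                        "cell_fluor": cells,
                    }
                )
            )
    data = pd.concat(rows, ignore_index=True)
    truth = {
        "seed": int(seed),
        "config": _config_dict(config),
        "variant": variant.name,
        "induction": induction,
        "mean_fluor": mean_fluor,
        "eta_int": eta_int,
        "eta_ext": config.eta_ext,
        "cv2_total": cv2,
    }
    return FlowDataset(data=data, truth=truth)


def simulate_flow_library(
    library: Sequence[VariantSpec],
    config: FlowConfig,
    seed: int,
    inductions: Iterable[str] = ("off", "on"),
) -> FlowDataset:
    """Flow samples for every (variant, induction), plus autofluorescence cells."""
    seq = np.random.SeedSequence(seed)
    combos = [(v, ind) for v in library for ind in inductions]
    children = seq.spawn(len(combos) + 1)
    frames, truths = [], {}
    for (v, ind), child in zip(combos, children[:-1]):
        ds = simulate_flow_cytometry(v, ind, config, int(child.generate_state(1)[0]))
        frames.append(ds.data)
        truths[f"{v.name}|{ind}"] = {k: ds.truth[k] for k in ("mean_fluor", "eta_int", "eta_ext", "cv2_total")}
    af_rng = np.random.default_rng(int(children[-1].generate_state(1)[0]))
    n_af = config.n_cells * config.n_replicates
    af = pd.DataFrame(
        {
            "variant": AUTOFLUOR_VARIANT,
            "induction": "none",
            "repeat": 1,
            "replicate": np.repeat(np.arange(1, config.n_replicates + 1), config.n_cells),
            "cell_fluor": af_rng.normal(config.af_mean, config.af_sd, size=n_af),
        }
    )
    frames.append(af)
    data = pd.concat(frames, ignore_index=True)
    truth = {"seed": int(seed), "config": _config_dict(config), "samples": truths}
    return FlowDataset(data=data, truth=truth)


# ---------------------------------------------------------------------------
# transcription-shutoff qPCR


@dataclass(frozen=True)
class DecayTruth:
    strain: str = "wt"
    tau_half: float = 1.6  # minutes
    cq0_target: float = 20.0
    cq0_ref: float = 12.0


@dataclass(frozen=True)
class DecayDesign:
    times_min: tuple[float, ...] = (1.0, 2.0, 3.0, 5.0, 7.0)
    n_replicates: int = 3
    cq_sd: float = 0.1
    e_target: float = 2.0
    e_ref: float = 2.0

    def __post_init__(self) -> None:
        if not all(b > a for a, b in zip(self.times_min, self.times_min[1:])):
            raise ValueError("times must be strictly increasing")
        if self.cq_sd < 0:
            raise ValueError("cq_sd must be >= 0")
        for e in (self.e_target, self.e_ref):
            if not 1.0 < e <= 2.0:
                raise ValueError("amplification efficiencies must lie in (1, 2]")


@dataclass(frozen=True)
class DecayDataset:
    data: pd.DataFrame
    truth: dict


def simulate_decay_qpcr(
    strain_truth: DecayTruth,
    design: DecayDesign = DecayDesign(),
    seed: int = 0,
) -> DecayDataset:
    """Cq series under f(t) = f0 * 2^(-t / tau_half) target decay.

    The target channel gains ``1 / (tau_half * log2(E))`` cycles per minute
    (one cycle per halving time when E = 2); the reference channel is flat
    in expectation.  Replicate noise is iid Gaussian on Cq.
    """
    if strain_truth.tau_half <= 0:
        raise ValueError("tau_half must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    slope = 1.0 / (strain_truth.tau_half * math.log2(design.e_target))
    for t in design.times_min:
        cq_t = strain_truth.cq0_target + slope * t
        for rep in range(1, design.n_replicates + 1):
            rows.append(
                (
                    strain_truth.strain,
                    t,
                    rep,
                    cq_t + rng.normal(0.0, design.cq_sd),
                    strain_truth.cq0_ref + rng.normal(0.0, design.cq_sd),
                )
            )
    data = pd.DataFrame(rows, columns=["strain", "t_min", "replicate", "cq_target", "cq_ref"])
    truth = {
        "seed": int(seed),
        "design": _config_dict(design),
        "strain": strain_truth.strain,
        "tau_half": strain_truth.tau_half,
        "cq0_target": strain_truth.cq0_target,
        "cq0_ref": strain_truth.cq0_ref,
    }
    return DecayDataset(data=data, truth=truth)


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
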