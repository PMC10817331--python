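"""Synthetic expression datasets with the structure of the measured courses.

The generator emulates the qualitative shape of the empirical data -- a
vernalization-induced FTa1 pulse peaking near day 20 in wild type, delayed
saturating rises of the SOC1 genes and PIM, strong suppression in the
fta1-1 mutant, and low flat expression without vernalization -- without
encoding any published values.  Curve families (a gamma-shaped pulse for
FTa1, logistic rises for SOC1/PIM) are an implementation choice and are
fully config-exposed.

Two PIM modes exist: ``phenomenological`` (a delayed logistic rise) and
``mechanistic`` (PIM means produced by simulating one of the hypothesis
models from known parameters, with the generating truth returned), which
enables parameter-recovery and model-selection experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import numpy as np

from .core_data import (
    CONDITIONS,
    Condition,
    ExpressionDataset,
    read_dataset,
)
from .pim_models import SOC1_GENES, get_hypothesis, simulate_pim

__all__ = ["SynthConfig", "SynthResult", "generate_dataset", "load_digitized"]


@dataclass
class SynthConfig:
    """Shape, suppression and noise parameters of the generator.

    Noise is independent per cell with sd = cv * mean + floor; the reported
    sd equals the generating sd, so downstream weighted fitting sees
    correctly specified weights.  When the generating sd is zero (noise-free
    configurations) a tiny positive placeholder ``sd_min`` is reported to
    satisfy the dataset invariant sd > 0.
    """

    timepoints: Tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0)

    # FTa1 pulse (wild type, vernalized): baseline + amplitude * gamma pulse
    fta1_peak_day: float = 20.0
    fta1_amplitude: float = 8.0
    fta1_baseline: float = 0.05
    fta1_shape: float = 4.0  # larger -> narrower pulse

    # SOC1 logistic rises, onset later than the FTa1 rise
    soc1_midpoints: Mapping[str, float] = field(
        default_factory=lambda: {"SOC1a": 16.0, "SOC1b": 18.0, "SOC1c": 20.0}
    )
    soc1_amplitudes: Mapping[str, float] = field(
        default_factory=lambda: {"SOC1a": 3.0, "SOC1b": 2.0, "SOC1c": 1.5}
    )
    soc1_baselines: Mapping[str, float] = field(
        default_factory=lambda: {"SOC1a": 0.1, "SOC1b": 0.1, "SOC1c": 0.1}
    )
    soc1_width: float = 2.5

    # phenomenological PIM: latest rise of all
    pim_midpoint: float = 21.0
    pim_amplitude: float = 2.5
    pim_baseline: float = 0.05
    pim_width: float = 1.5

    # condition scalings
    mutant_suppression: float = 0.1  # overall level in fta1-1 (<< 1)
    mutant_residual_induction: float = 0.1  # induction largely removed
    nonvern_factor: float = 0.1  # induced amplitude remaining without cold

    # noise model
    cv: float = 0.1
    sd_floor: float = 0.02
    sd_min: float = 1e-6
    seed: int = 0

    # PIM generation mode
    pim_mode: str = "phenomenological"  # or "mechanistic"
    pim_hypothesis: Optional[str] = None
    pim_params: Optional[Dict[str, float]] = None
    n_steps: int = 200  # ODE grid for mechanistic PIM

    def __post_init__(self) -> None:
        if len(self.timepoints) < 2 or any(
            a >= b for a, b in zip(self.timepoints, self.timepoints[1:])
        ):
            raise ValueError("timepoints must be strictly increasing, length >= 2")
        positives = [
            self.fta1_amplitude,
            self.fta1_baseline,
            self.fta1_shape,
            self.pim_amplitude,
            self.pim_baseline,
            self.pim_width,
            self.soc1_width,
            self.mutant_suppression,
            self.nonvern_factor,
            *self.soc1_amplitudes.values(),
            *self.soc1_baselines.values(),
        ]
        if any(p <= 0 for p in positives):
            raise ValueError("amplitudes, baselines and factors must be positive")
        if self.cv < 0 or self.sd_floor < 0 or self.sd_min <= 0:
            raise ValueError("cv and sd_floor must be >= 0; sd_min > 0")
        if self.pim_mode not in ("phenomenological", "mechanistic"):
            raise ValueError(f"unknown pim_mode {self.pim_mode!r}")
        if self.pim_mode == "mechanistic":
            if self.pim_hypothesis is None or self.pim_params is None:
                raise ValueError("mechanistic mode needs pim_hypothesis and pim_params")
            get_hypothesis(self.pim_hypothesis).validate_params(self.pim_params)


@dataclass
class SynthResult:
    """Generated dataset plus, in mechanistic mode, the generating truth."""

    dataset: ExpressionDataset
    truth: Optional[Dict] = None


def _gamma_pulse(t: np.ndarray, peak: float, shape: float) -> np.ndarray:
    """Unimodal pulse equal to 1 at ``t == peak``, 0 at ``t == 0``."""
    r = np.maximum(t, 0.0) / peak
    return r**shape * np.exp(shape * (1.0 - r))


def _logistic(t: np.ndarray, mid: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(t - mid) / width))


def _wt_vplus_means(config: SynthConfig, t: np.ndarray) -> Dict[str, np.ndarray]:
    means = {
        "FTa1": config.fta1_baseline
        + config.fta1_amplitude * _gamma_pulse(t, config.fta1_peak_day, config.fta1_shape)
    }
    for g in SOC1_GENES:
        means[g] = config.soc1_baselines[g] + config.soc1_amplitudes[g] * _logistic(
            t, config.soc1_midpoints[g], config.soc1_width
        )
    means["PIM"] = config.pim_baseline + config.pim_amplitude * _logistic(
        t, config.pim_midpoint, config.pim_width
    )
    return means


def _condition_means(
    config: SynthConfig, wt_vplus: Dict[str, np.ndarray]
) -> Dict[Condition, Dict[str, np.ndarray]]:
    """Scale the wild-type vernalized shapes into all four conditions.

    The vernalization-induced part (value minus baseline) is damped by
    ``nonvern_factor`` in V- conditions; mutant courses are suppressed
    overall and keep only ``mutant_residual_induction`` of the induction.
    """
    out: Dict[Condition, Dict[str, np.ndarray]] = {}
    for cond in CONDITIONS:
        means = {}
        for gene, wt in wt_vplus.items():
            base = wt[0] * np.ones_like(wt)  # day-5 (pre-induction) level
            induced = wt - base
            if not cond.vernalized:
                induced = induced * config.nonvern_factor
            if cond.genotype == "fta1-1":
                means[gene] = config.mutant_suppression * (
                    base + config.mutant_residual_induction * induced
                )
            else:
                means[gene] = base + induced
        out[cond] = means
    return out


def generate_dataset(config: SynthConfig) -> SynthResult:
    """Deterministically generate a dataset from the given config."""
    t = np.asarray(config.timepoints, dtype=float)
    by_cond = _condition_means(config, _wt_vplus_means(config, t))

    truth: Optional[Dict] = None
    if config.pim_mode == "mechanistic":
        # regulators must be in place (noise-free) before PIM is simulated
        clean = _assemble(config, by_cond, noise=False, rng=None).dataset
        truth = {
            "hypothesis": config.pim_hypothesis,
            "params": dict(config.pim_params),
            "pim_means": {},
        }
        for cond in CONDITIONS:
            pim = simulate_pim(
                config.pim_hypothesis,
                config.pim_params,
                clean,
                cond,
                t,
                n_steps=config.n_steps,
            )
            by_cond[cond]["PIM"] = pim
            truth["pim_means"][cond.label] = pim.copy()

    rng = np.random.default_rng(config.seed)
    result = _assemble(config, by_cond, noise=True, rng=rng)
    result.truth = truth
    return result


def _assemble(
    config: SynthConfig,
    by_cond: Dict[Condition, Dict[str, np.ndarray]],
    noise: bool,
    rng: Optional[np.random.Generator],
) -> SynthResult:
    mean: Dict = {}
    sd: Dict = {}
    for cond in CONDITIONS:
        for gene, clean in by_cond[cond].items():
            true_sd = config.cv * clean + config.sd_floor
            if noise and rng is not None and np.any(true_sd > 0):
                noisy = np.maximum(clean + rng.normal(size=clean.shape) * true_sd, 0.0)
            else:
                noisy = clean.copy()
            mean[(gene, cond)] = noisy
            sd[(gene, cond)] = np.maximum(true_sd, config.sd_min)
    dataset = ExpressionDataset(config.timepoints, mean, sd, source="synthetic")
    return SynthResult(dataset=dataset)


def load_digitized(path: str | Path) -> ExpressionDataset:
    """Load a user-digitized dataset (long CSV/JSON) and flag it empirical.

    The package never produces digitized values itself; this entry point
    exists so externally extracted tables can flow into the same pipeline.
    """
    dataset = read_dataset(path)
    dataset.source = "digitized"
    return dataset
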