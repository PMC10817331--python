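"""Candidate single-state ODE models of PIM activation.

Four hypotheses (H1--H4) describe how the leaf signal FTa1 (subject to a
transport delay tau) and the three SOC1 factors drive PIM synthesis.  All
production terms are non-cooperative saturating functions v*S/(K+S) and
combine additively; PIM decays linearly with rate lambda:

    H1: v0*F/(K0+F) + v1*S/(K1+S) - lambda*PIM      F = FTa1(t - tau),
    H2: v1*S/(K1+S) - lambda*PIM                    S = sum of SOC1a/b/c
    H3: sum_i vi*SOC1i/(Ki+SOC1i) - lambda*PIM
    H4: v0*F/(K0+F) + sum_i vi*SOC1i/(Ki+SOC1i) - lambda*PIM

Regulators enter as continuous trajectories interpolated from the measured
time courses; mRNA level stands in for protein concentration (the
proportionality constant is absorbed into the K's).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator
from scipy.signal import lfilter

from .core_data import Condition, ExpressionDataset

__all__ = [
    "SOC1_GENES",
    "RegulatorTrajectory",
    "HypothesisSchema",
    "HYPOTHESES",
    "get_hypothesis",
    "count_free_params",
    "make_trajectory",
    "make_regulators",
    "delayed_value",
    "production_rate",
    "pim_rhs",
    "simulate_pim",
]

SOC1_GENES: Tuple[str, ...] = ("SOC1a", "SOC1b", "SOC1c")

#: Parameter bounds used by the fitter.  Rates and the degradation constant
#: live in (0, 10]; dissociation constants in (0, 1000]; the transport delay
#: in [0, 15] days so that t - tau stays meaningful within the sampled window.
RATE_BOUNDS = (1e-6, 10.0)
K_BOUNDS = (1e-6, 1000.0)
TAU_BOUNDS = (0.0, 15.0)


class RegulatorTrajectory:
    """Continuous-time regulator level interpolated from discrete knots.

    Evaluation is piecewise linear by default (``kind="linear"``), with
    monotone cubic (``kind="pchip"``) available for sensitivity checks.
    Outside the knot range the value is clamped to the nearest knot.
    """

    def __init__(
        self,
        gene: str,
        condition: Condition | None,
        knot_times: Sequence[float],
        knot_values: Sequence[float],
        kind: str = "linear",
    ) -> None:
        self.gene = gene
        self.condition = condition
        self.knot_times = np.asarray(knot_times, dtype=float)
        self.knot_values = np.asarray(knot_values, dtype=float)
        if self.knot_times.ndim != 1 or self.knot_times.shape != self.knot_values.shape:
            raise ValueError("knot times and values must be 1-D and aligned")
        if len(self.knot_times) < 2:
            raise ValueError("need at least two knots")
        if np.any(np.diff(self.knot_times) <= 0):
            raise ValueError("knot times must be strictly increasing")
        if np.any(self.knot_values < 0):
            raise ValueError("knot values must be nonnegative")
        if kind not in ("linear", "pchip"):
            raise ValueError(f"unknown interpolation kind {kind!r}")
        self.kind = kind
        self._pchip = PchipInterpolator(self.knot_times, self.knot_values) if kind == "pchip" else None

    def __call__(self, t):
        tc = np.clip(t, self.knot_times[0], self.knot_times[-1])
        if self.kind == "linear":
            return np.interp(tc, self.knot_times, self.knot_values)
        return self._pchip(tc)

    def delayed(self, t, tau: float):
        """Evaluate at ``t - tau`` with the same clamping rule."""
        if tau < 0:
            raise ValueError("delay tau must be nonnegative")
        return self(np.asarray(t, dtype=float) - tau)


def make_trajectory(
    dataset: ExpressionDataset,
    gene: str,
    condition: Condition,
    kind: str = "linear",
) -> RegulatorTrajectory:
    """Trajectory through the measured means of `gene` in `condition`."""
    return RegulatorTrajectory(
        gene, condition, dataset.timepoints, dataset.mean(gene, condition), kind=kind
    )


def make_regulators(
    dataset: ExpressionDataset, condition: Condition, kind: str = "linear"
) -> Dict[str, RegulatorTrajectory]:
    """All regulator trajectories (FTa1 and the SOC1 genes) for a condition."""
    return {
        gene: make_trajectory(dataset, gene, condition, kind=kind)
        for gene in ("FTa1",) + SOC1_GENES
    }


def delayed_value(traj: RegulatorTrajectory, t: float, tau: float) -> float:
    return float(traj.delayed(t, tau))


@dataclass(frozen=True)
class HypothesisSchema:
    """Identity and parameter schema of one candidate model."""

    id: str
    param_names: Tuple[str, ...]
    bounds: Mapping[str, Tuple[float, float]]
    uses_fta1: bool
    soc1_mode: str  # "summed" | "separate"

    def validate_params(self, params: Mapping[str, float]) -> None:
        missing = set(self.param_names) - set(params)
        if missing:
            raise KeyError(
                f"{self.id}: missing parameters {sorted(missing)}"
            )

    def check_bounds(self, params: Mapping[str, float]) -> bool:
        return all(
            self.bounds[name][0] <= params[name] <= self.bounds[name][1]
            for name in self.param_names
        )

    def lower(self) -> np.ndarray:
        return np.array([self.bounds[p][0] for p in self.param_names])

    def upper(self) -> np.ndarray:
        return np.array([self.bounds[p][1] for p in self.param_names])


def _schema(id: str, names: Sequence[str], uses_fta1: bool, soc1_mode: str) -> HypothesisSchema:
    bounds = {}
    for name in names:
        if name == "tau":
            bounds[name] = TAU_BOUNDS
        elif name.startswith("K"):
            bounds[name] = K_BOUNDS
        else:  # v0..v3, lambda
            bounds[name] = RATE_BOUNDS
    return HypothesisSchema(id, tuple(names), bounds, uses_fta1, soc1_mode)


HYPOTHESES: Dict[str, HypothesisSchema] = {
    "H1": _schema("H1", ("v0", "K0", "v1", "K1", "lambda", "tau"), True, "summed"),
    "H2": _schema("H2", ("v1", "K1", "lambda"), False, "summed"),
    "H3": _schema(
        "H3", ("v1", "K1", "v2", "K2", "v3", "K3", "lambda"), False, "separate"
    ),
    "H4": _schema(
        "H4",
        ("v0", "K0", "v1", "K1", "v2", "K2", "v3", "K3", "lambda", "tau"),
        True,
        "separate",
    ),
}


def get_hypothesis(hypothesis: "str | HypothesisSchema") -> HypothesisSchema:
    if isinstance(hypothesis, HypothesisSchema):
        return hypothesis
    try:
        return HYPOTHESES[hypothesis]
    except KeyError:
        raise KeyError(
            f"unknown hypothesis {hypothesis!r}; expected one of {sorted(HYPOTHESES)}"
        ) from None


def count_free_params(hypothesis: "str | HypothesisSchema") -> int:
    """Number of optimized parameters in the model."""
    return len(get_hypothesis(hypothesis).param_names)


def production_rate(
    hypothesis: "str | HypothesisSchema",
    params: Mapping[str, float],
    t,
    regulators: Mapping[str, RegulatorTrajectory],
):
    """Total PIM synthesis rate at time(s) ``t`` (vectorized over t).

    This is the production part of the right-hand side; it does not depend
    on the PIM level itself.
    """
    schema = get_hypothesis(hypothesis)
    schema.validate_params(params)
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    if schema.uses_fta1:
        F = regulators["FTa1"].delayed(t, params["tau"])
        out = out + params["v0"] * F / (params["K0"] + F)
    if schema.soc1_mode == "summed":
        S = sum(regulators[g](t) for g in SOC1_GENES)
        out = out + params["v1"] * S / (params["K1"] + S)
    else:
        for i, g in enumerate(SOC1_GENES, start=1):
            s = regulators[g](t)
            out = out + params[f"v{i}"] * s / (params[f"K{i}"] + s)
    return out


def pim_rhs(
    hypothesis: "str | HypothesisSchema",
    params: Mapping[str, float],
    t: float,
    pim: float,
    regulators: Mapping[str, RegulatorTrajectory],
) -> float:
    """d(PIM)/dt at time ``t`` and level ``pim``."""
    if pim < 0:
        raise ValueError("PIM concentration must be nonnegative")
    g = production_rate(hypothesis, params, t, regulators)
    return float(g - params["lambda"] * pim)


def _integrate_linear_decay(p0: float, lam: float, g: np.ndarray, h: float) -> np.ndarray:
    """March dP/dt = g(t) - lam*P with classical RK4 on a uniform grid.

    ``g`` holds production sampled at grid nodes *and* midpoints
    (length 2*n_steps + 1).  Because the ODE is linear in P with constant
    decay, each RK4 step is an affine recurrence P_{k+1} = a*P_k + b_k; the
    whole march is one first-order IIR filter, evaluated in C.
    """
    g0, gh, g1 = g[0:-1:2], g[1::2], g[2::2]
    u = h * lam
    a = 1.0 - u + u * u / 2.0 - u**3 / 6.0 + u**4 / 24.0
    b = (h / 6.0) * (
        g0 * (1.0 - u + u * u / 2.0 - u**3 / 4.0)
        + gh * (4.0 - 2.0 * u + u * u / 2.0)
        + g1
    )
    rest = lfilter([1.0], [1.0, -a], b, zi=np.array([a * p0]))[0]
    return np.concatenate(([p0], rest))


def simulate_pim(
    hypothesis: "str | HypothesisSchema",
    params: Mapping[str, float],
    dataset: ExpressionDataset,
    condition: Condition,
    t_grid: Sequence[float],
    n_steps: int = 200,
    method: str = "rk4",
    interp_kind: str = "linear",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    regulators: Mapping[str, RegulatorTrajectory] | None = None,
) -> np.ndarray:
    """PIM time course under one hypothesis in one condition.

    The initial condition is the measured PIM mean at the first dataset
    timepoint.  ``t_grid`` must lie within the sampled window.  The default
    integrator is fixed-step RK4 on ``n_steps`` sub-intervals (fast and
    deterministic, used by the fitter); ``method="lsoda"`` cross-checks with
    an adaptive solver.
    """
    schema = get_hypothesis(hypothesis)
    schema.validate_params(params)
    t_grid = np.asarray(t_grid, dtype=float)
    t0, t_last = dataset.timepoints[0], dataset.timepoints[-1]
    if t_grid.size == 0:
        raise ValueError("empty time grid")
    if t_grid.min() < t0 - 1e-12 or t_grid.max() > t_last + 1e-12:
        raise ValueError(
            f"t_grid must lie within [{t0}, {t_last}] (the sampled window)"
        )
    if regulators is None:
        regulators = make_regulators(dataset, condition, kind=interp_kind)
    p0 = dataset.value("PIM", condition, t0)
    t_end = float(max(t_grid.max(), t0 + 1e-9))

    if method == "rk4":
        tt = np.linspace(t0, t_end, n_steps + 1)
        ts = np.linspace(t0, t_end, 2 * n_steps + 1)  # nodes + midpoints
        g = production_rate(schema, params, ts, regulators)
        h = (t_end - t0) / n_steps
        pim = _integrate_linear_decay(p0, params["lambda"], g, h)
        return np.interp(t_grid, tt, pim)
    if method == "lsoda":
        def rhs(t, y):
            g = production_rate(schema, params, t, regulators)
            return [float(g) - params["lambda"] * y[0]]

        order = np.argsort(t_grid)
        t_sorted = t_grid[order]
        sol = solve_ivp(
            rhs,
            (t0, t_end),
            [p0],
            method="LSODA",
            t_eval=np.unique(np.concatenate(([t0], t_sorted))),
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"PIM integration failed: {sol.message}")
        return np.interp(t_grid, sol.t, sol.y[0])
    raise ValueError(f"unknown method {method!r}")
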