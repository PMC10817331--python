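"""Coherent feed-forward loop with a configurable number of activator branches.

An upstream input X activates a target Z directly and through ``n_branches``
intermediate activators Y_i.  All regulatory terms are saturating
(Michaelis--Menten, no cooperativity) and combine additively (OR logic):

    dY_i/dt = a_y[i] * X / (K_y[i] + X) - b_y * Y_i
    dZ/dt   = a_xz * X / (K_xz + X)
              + sum_i a_yz[i] * Y_i / (K_yz[i] + Y_i)
              - b_z * Z

The module provides the right-hand side, a time-course simulator, the
closed-form steady state, and steady-state branch-perturbation analysis
(the buffering property of multi-branch loops).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence, Union

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "FFLConfig",
    "FFLState",
    "FFLSolution",
    "ffl_rhs",
    "simulate_ffl",
    "steady_state",
    "perturb_branch",
    "IntegrationError",
]


class IntegrationError(RuntimeError):
    """The ODE solver failed to produce a solution."""


def _as_branch_vector(value: Union[float, Sequence[float]], n: int) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.full(n, arr[0])
    if arr.shape != (n,):
        raise ValueError(f"per-branch vector has shape {arr.shape}, expected ({n},)")
    return arr


@dataclass
class FFLConfig:
    """Kinetic parameters of the loop.

    Scalars passed for per-branch parameters are broadcast to all branches.
    ``rtol``/``atol`` are forwarded to the adaptive solver.
    """

    n_branches: int = 1
    a_y: Union[float, Sequence[float]] = 1.0
    K_y: Union[float, Sequence[float]] = 1.0
    a_xz: float = 1.0
    K_xz: float = 1.0
    a_yz: Union[float, Sequence[float]] = 1.0
    K_yz: Union[float, Sequence[float]] = 1.0
    b_y: float = 1.0
    b_z: float = 1.0
    rtol: float = 1e-6
    atol: float = 1e-9

    def __post_init__(self) -> None:
        if int(self.n_branches) != self.n_branches or self.n_branches < 1:
            raise ValueError("n_branches must be a positive integer")
        self.n_branches = int(self.n_branches)
        self.a_y = _as_branch_vector(self.a_y, self.n_branches)
        self.K_y = _as_branch_vector(self.K_y, self.n_branches)
        self.a_yz = _as_branch_vector(self.a_yz, self.n_branches)
        self.K_yz = _as_branch_vector(self.K_yz, self.n_branches)
        for name in ("a_xz", "K_xz", "b_y", "b_z"):
            setattr(self, name, float(getattr(self, name)))
        vals = np.concatenate(
            [self.a_y, self.K_y, self.a_yz, self.K_yz,
             [self.a_xz, self.K_xz, self.b_y, self.b_z]]
        )
        if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
            raise ValueError("all rates and coefficients must be strictly positive")

    @classmethod
    def ones(cls, n_branches: int, normalize_total: bool = False, **kwargs) -> "FFLConfig":
        """All-ones parameters (the default theoretical setting).

        With ``normalize_total=True`` each branch synthesis rate ``a_y`` is
        scaled by ``1/n_branches`` so that the summed intermediate
        concentration matches the single-branch loop, for comparisons at
        equal total regulator level.
        """
        kwargs.setdefault("a_y", 1.0 / n_branches if normalize_total else 1.0)
        return cls(n_branches=n_branches, **kwargs)


@dataclass
class FFLState:
    """Instantaneous state: branch concentrations Y and target Z at time t."""

    t: float
    Y: np.ndarray
    Z: float

    def __post_init__(self) -> None:
        self.Y = np.atleast_1d(np.asarray(self.Y, dtype=float))
        self.Z = float(self.Z)
        if np.any(self.Y < 0) or self.Z < 0:
            raise ValueError("concentrations must be nonnegative")


@dataclass
class FFLSolution:
    """Dense time course: ``Y`` has shape (n_out, n_branches)."""

    t: np.ndarray
    Y: np.ndarray
    Z: np.ndarray

    def state(self, index: int) -> FFLState:
        return FFLState(t=float(self.t[index]), Y=self.Y[index], Z=float(self.Z[index]))

    @property
    def final(self) -> FFLState:
        return self.state(-1)


def ffl_rhs(state: FFLState, x: float, config: FFLConfig) -> tuple[np.ndarray, float]:
    """Time derivatives ``(dY, dZ)`` at input level ``x``."""
    if x < 0:
        raise ValueError(f"input concentration must be nonnegative, got {x}")
    if np.any(state.Y < 0) or state.Z < 0:
        raise ValueError("state concentrations must be nonnegative")
    dY = config.a_y * x / (config.K_y + x) - config.b_y * state.Y
    dZ = (
        config.a_xz * x / (config.K_xz + x)
        + float(np.sum(config.a_yz * state.Y / (config.K_yz + state.Y)))
        - config.b_z * state.Z
    )
    return dY, float(dZ)


def simulate_ffl(
    config: FFLConfig,
    x_signal: Union[float, Callable[[float], float]],
    t_span: tuple[float, float],
    initial: FFLState | None = None,
    n_out: int = 201,
) -> FFLSolution:
    """Integrate the loop over ``t_span`` under input ``x_signal``.

    ``x_signal`` may be a constant or a callable ``t -> x(t)``.  For a
    constant input the solution converges to :func:`steady_state`.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not t1 > t0:
        raise ValueError("t_span must be a nonempty forward interval")
    if initial is None:
        initial = FFLState(t=t0, Y=np.zeros(config.n_branches), Z=0.0)
    if initial.Y.shape != (config.n_branches,):
        raise ValueError("initial state has wrong number of branches")

    if callable(x_signal):
        x_of_t = x_signal
    else:
        x_const = float(x_signal)
        x_of_t = lambda t: x_const  # noqa: E731

    n = config.n_branches

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        x = max(float(x_of_t(t)), 0.0)
        Y = np.maximum(y[:n], 0.0)
        dY = config.a_y * x / (config.K_y + x) - config.b_y * y[:n]
        dZ = (
            config.a_xz * x / (config.K_xz + x)
            + np.sum(config.a_yz * Y / (config.K_yz + Y))
            - config.b_z * y[n]
        )
        return np.concatenate([dY, [dZ]])

    t_eval = np.linspace(t0, t1, int(n_out))
    sol = solve_ivp(
        rhs,
        (t0, t1),
        np.concatenate([initial.Y, [initial.Z]]),
        method="LSODA",
        t_eval=t_eval,
        rtol=config.rtol,
        atol=config.atol,
    )
    if not sol.success:
        raise IntegrationError(f"FFL integration failed: {sol.message}")
    return FFLSolution(t=sol.t, Y=sol.y[:n].T, Z=sol.y[n])


def steady_state(config: FFLConfig, x: float) -> FFLState:
    """Closed-form fixed point under constant input ``x``."""
    if x < 0:
        raise ValueError("input concentration must be nonnegative")
    Y = config.a_y / config.b_y * x / (config.K_y + x)
    Z = (
        config.a_xz * x / (config.K_xz + x)
        + np.sum(config.a_yz * Y / (config.K_yz + Y))
    ) / config.b_z
    return FFLState(t=math.inf, Y=Y, Z=float(Z))


def perturb_branch(
    config: FFLConfig,
    branch: Union[int, str],
    fold: float,
    x: float,
) -> float:
    """Relative steady-state change of Z under a fold perturbation.

    ``branch`` selects one intermediate branch (0-based index), ``"all"``
    (every branch at once), or ``"upstream"`` (scale the input x itself).
    A branch perturbation multiplies that branch's synthesis rate ``a_y``,
    which changes its steady level Y_i* by exactly ``fold``.

    Returns ``|Z*_perturbed - Z*_baseline| / Z*_baseline``.
    """
    if fold <= 0:
        raise ValueError("fold must be strictly positive")
    base = steady_state(config, x)
    if base.Z == 0:
        raise ValueError("baseline Z* is zero; relative change undefined")

    if branch == "upstream":
        pert = steady_state(config, fold * x)
    else:
        a_y = np.array(config.a_y, dtype=float)
        if branch == "all":
            a_y *= fold
        else:
            idx = int(branch)
            if not 0 <= idx < config.n_branches:
                raise IndexError(
                    f"branch {idx} out of range for {config.n_branches}-branch loop"
                )
            a_y[idx] *= fold
        pert_config = FFLConfig(
            n_branches=config.n_branches,
            a_y=a_y,
            K_y=np.array(config.K_y),
            a_xz=config.a_xz,
            K_xz=config.K_xz,
            a_yz=np.array(config.a_yz),
            K_yz=np.array(config.K_yz),
            b_y=config.b_y,
            b_z=config.b_z,
        )
        pert = steady_state(pert_config, x)
    return abs(pert.Z - base.Z) / base.Z
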