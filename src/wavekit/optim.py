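"""Gradient machinery: the Adam optimizer and finite-difference checking.

The library-wide differentiability contract is that every gradient fed
to a driver agrees with central finite differences; whether it came from
a hand-written adjoint or anything else is an implementation detail.
:func:`gradcheck_fd` measures exactly that agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "OptimizerConfig",
    "GradientReport",
    "run_gradient_descent",
    "gradcheck_fd",
    "NonFiniteLossError",
]

_LOSS_TAGS = ("mse", "neg-pearson", "accuracy", "neg-ssim")


class NonFiniteLossError(RuntimeError):
    """Raised when the loss becomes NaN/Inf mid-run; carries the iteration."""

    def __init__(self, iteration: int):
        self.iteration = iteration
        super().__init__(f"non-finite loss at iteration {iteration}")


@dataclass(frozen=True)
class OptimizerConfig:
    """Adam hyperparameters plus a loss tag and a seed.

    The step size is in the units of the optimized parameter per
    iteration (Adam's bias-corrected first step has this magnitude).
    """

    step_size: float
    iterations: int
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0
    loss: str = "mse"

    def __post_init__(self):
        if self.step_size <= 0:
            raise ValueError("step size must be positive")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("beta1, beta2 must lie in [0, 1)")
        if self.iterations < 1:
            raise ValueError("at least one iteration required")
        if self.loss not in _LOSS_TAGS:
            raise ValueError(f"loss must be one of {_LOSS_TAGS}")


def run_gradient_descent(
    value_and_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    init: np.ndarray,
    config: OptimizerConfig,
    projection: Callable[[np.ndarray], np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Adam with bias correction; deterministic given init and config.

    ``projection`` (e.g. a nonnegativity clip) is applied after every
    update.  Returns the final iterate and the loss trace (one entry per
    iteration, evaluated at the pre-update point).
    """
    x = np.array(init, dtype=float, copy=True)
    m = np.zeros_like(x)
    v = np.zeros_like(x)
    trace = np.empty(config.iterations)
    for it in range(config.iterations):
        val, g = value_and_grad(x)
        if not np.isfinite(val):
            raise NonFiniteLossError(it)
        trace[it] = val
        m = config.beta1 * m + (1 - config.beta1) * g
        v = config.beta2 * v + (1 - config.beta2) * g * g
        mhat = m / (1 - config.beta1 ** (it + 1))
        vhat = v / (1 - config.beta2 ** (it + 1))
        x = x - config.step_size * mhat / (np.sqrt(vhat) + config.eps)
        if projection is not None:
            x = projection(x)
    return x, trace


@dataclass(frozen=True)
class GradientReport:
    """Outcome of a finite-difference gradient check."""

    max_rel_error: float
    rel_step: float
    n_coordinates: int

    def passed(self, tol: float) -> bool:
        return self.max_rel_error <= tol


def gradcheck_fd(
    loss: Callable[[np.ndarray], float],
    grad: Callable[[np.ndarray], np.ndarray],
    point: np.ndarray,
    rel_step: float = 1e-6,
    max_coordinates: int = 32,
    seed: int = 0,
    floor: float = 1e-8,
) -> GradientReport:
    """Compare a supplied gradient with central finite differences.

    For parameter blocks larger than ``max_coordinates`` a seeded random
    subset of coordinates (at least 32) is probed.  The per-coordinate
    relative error is ``|g_impl - g_fd| / max(|g_fd|, floor)``.
    """
    if not (0 < rel_step <= 1e-2):
        raise ValueError("rel_step must lie in (0, 1e-2]")
    x = np.array(point, dtype=float, copy=True)
    f0 = loss(x)
    if not np.isfinite(f0):
        raise ValueError("loss is not finite at the evaluation point")
    g_impl = np.asarray(grad(x), dtype=float)
    if g_impl.shape != x.shape:
        raise ValueError("gradient shape must match the parameter shape")

    flat = x.ravel()
    n = flat.size
    if n <= max(max_coordinates, 32):
        coords = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        coords = rng.choice(n, size=max(max_coordinates, 32), replace=False)

    scale = max(float(np.max(np.abs(flat))), 1.0)
    err = 0.0
    for i in coords:
        h = rel_step * max(abs(flat[i]), scale)
        xp = flat.copy(); xp[i] += h
        xm = flat.copy(); xm[i] -= h
        g_fd = (loss(xp.reshape(x.shape)) - loss(xm.reshape(x.shape))) / (2 * h)
        denom = max(abs(g_fd), floor)
        err = max(err, abs(g_impl.ravel()[i] - g_fd) / denom)
    return GradientReport(max_rel_error=float(err), rel_step=rel_step,
                          n_coordinates=len(coords))
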