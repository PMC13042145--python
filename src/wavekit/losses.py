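"""Scalar image losses with analytic gradients.

Every loss returns ``(value, d value / d sim)`` so that the inverse
drivers can chain it onto the hand-written adjoints of the forward
models.  Tags accepted by :class:`wavekit.optim.OptimizerConfig`:

``mse``
    mean squared error.
``neg-pearson``
    negative Pearson correlation coefficient between the flattened
    images (mean-removed cosine similarity); minimizing it maximizes the
    correlation of the simulated pattern with the target.
``accuracy``
    one minus the (uncentered) cosine similarity between flattened
    simulated and target intensities.
``neg-ssim``
    one minus the mean structural similarity index, computed with a
    uniform window and zero padding (so the windowing operator is
    self-adjoint and the gradient is exact).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = ["mse", "neg_pearson", "accuracy_loss", "neg_ssim", "get_loss"]


def mse(sim: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    d = sim - target
    n = d.size
    return float(np.mean(d * d)), 2.0 * d / n


def neg_pearson(sim: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    s = sim - sim.mean()
    t = target - target.mean()
    ns = np.linalg.norm(s)
    nt = np.linalg.norm(t)
    if ns == 0 or nt == 0:
        raise ValueError("Pearson correlation undefined for constant images")
    r = float(np.vdot(s, t).real / (ns * nt))
    g = -(t / (ns * nt) - r * s / ns ** 2)
    g -= g.mean()  # project onto the mean-free subspace the loss lives in
    return -r, g


def accuracy_loss(sim: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    ns = np.linalg.norm(sim)
    nt = np.linalg.norm(target)
    if ns == 0 or nt == 0:
        raise ValueError("cosine similarity undefined for all-zero images")
    c = float(np.vdot(sim, target).real / (ns * nt))
    g = -(target / (ns * nt) - c * sim / ns ** 2)
    return 1.0 - c, g


def _win(x: np.ndarray, size: int) -> np.ndarray:
    return uniform_filter(x, size=size, mode="constant")


def neg_ssim(sim: np.ndarray, target: np.ndarray, *, window: int = 7,
             data_range: float | None = None) -> tuple[float, np.ndarray]:
    """1 − mean SSIM with a uniform window; exact analytic gradient.

    Zero ("constant") padding makes the window operator symmetric, so
    backpropagation through the local means and covariances is the same
    uniform filter applied to the partial derivatives.
    """
    x, y = np.asarray(sim, float), np.asarray(target, float)
    if data_range is None:
        rng = float(y.max() - y.min())
        data_range = rng if rng > 0 else 1.0
    C1 = (0.01 * data_range) ** 2
    C2 = (0.03 * data_range) ** 2
    w = window

    mx, my = _win(x, w), _win(y, w)
    sxx = _win(x * x, w) - mx * mx
    syy = _win(y * y, w) - my * my
    sxy = _win(x * y, w) - mx * my

    A1 = 2 * mx * my + C1
    A2 = 2 * sxy + C2
    B1 = mx * mx + my * my + C1
    B2 = sxx + syy + C2
    S = (A1 * A2) / (B1 * B2)
    n = S.size
    value = 1.0 - float(S.mean())

    # dS/d(mx, sxx, sxy) then pull each back through the uniform filter
    d_mx = (2 * my * A2 * B1 * B2 - A1 * A2 * (2 * mx * B2)) / (B1 * B2) ** 2
    d_sxx = -(A1 * A2) / (B1 * B2 ** 2)
    d_sxy = 2 * A1 / (B1 * B2)

    g_mx = d_mx - 2 * mx * d_sxx - my * d_sxy  # mean enters sxx, sxy too
    grad = _win(g_mx, w) + 2 * x * _win(d_sxx, w) + y * _win(d_sxy, w)
    return value, -grad / n


def get_loss(tag: str):
    table = {
        "mse": mse,
        "neg-pearson": neg_pearson,
        "accuracy": accuracy_loss,
        "neg-ssim": neg_ssim,
    }
    try:
        return table[tag]
    except KeyError:
        raise ValueError(f"unknown loss tag {tag!r}; choose from {sorted(table)}")
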