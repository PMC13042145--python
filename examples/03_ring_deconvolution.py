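"""Spatially-varying blur and ring deconvolution.

Point sources across the field of view are blurred with the
radially-varying Seidel PSFs of a miniature widefield microscope
(coefficients 0.85/0.56/0.25/0.29/0 waves), then recovered by gradient
descent under the ring-convolution forward model.
"""

import numpy as np

import wavekit as wk
from wavekit.inverse import ring_deconvolve
from wavekit.optim import OptimizerConfig

patch = wk.SamplingGrid(64, 64, 1.0, 1.0)
seidel = wk.SeidelSpec((0.85, 0.56, 0.25, 0.29, 0.0))
fov_radius = float(np.hypot(32, 32))
radii = np.arange(0.0, np.ceil(np.sqrt(2) * 32) + 2, 2.0)
psfs = wk.radial_psf_line(seidel, patch, 0.05, 0.55, radii, fov_radius)

rng = np.random.default_rng(0)
sample = np.zeros((64, 64))
points = []
while len(points) < 10:
    iy, ix = rng.integers(8, 56, 2)
    if all(abs(iy - a) + abs(ix - b) > 6 for a, b in points):
        points.append((iy, ix))
        sample[iy, ix] = rng.uniform(0.5, 1.0)

measured = wk.sv_superposition_oracle(sample, psfs)
config = OptimizerConfig(step_size=0.005, iterations=200, loss="mse")
estimate, trace = ring_deconvolve(measured, psfs, config)

hits = sum(
    estimate[iy - 1:iy + 2, ix - 1:ix + 2].max()
    >= estimate[iy - 3:iy + 4, ix - 3:ix + 4].max() - 1e-12
    for iy, ix in points)
print(f"data loss: {trace[0]:.3e} -> {trace[-1]:.3e} over {len(trace)} iters")
print(f"point sources re-localized within 1 pixel: {hits}/{len(points)}")
# All ten peaks should sit within one pixel of their true positions —
# the spatially-varying model undoes blur that a single-PSF deconvolution
# cannot represent at the field edge.
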