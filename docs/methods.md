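# Methods

This note records the physical models, numerical conventions, and design
choices behind `wavekit`, and what its synthetic-data tests do and do
not demonstrate.

## Conventions

All lengths are micrometres and all phases radians.  Pixel index `i` on
an axis of length `N` sits at physical coordinate `(i − N//2)·pitch`, so
the origin is the central sample for both even and odd rasters and
on-axis symmetry tests are exact.  All computation is double precision;
field amplitude is in arbitrary units (the library never asserts
absolute radiometric values), and intensity is the spectral-weighted sum
of |u|² over wavelengths.

Multi-wavelength fields share one pixel raster; the pitch is carried per
wavelength as metadata because lens Fourier transforms produce
wavelength-dependent output pitches (`λf/(nN d)`).

## Free-space propagation

The angular spectrum kernel is
`H = exp(i 2π z √((n/λ)² − fx² − fy²))`; the Fresnel transfer kernel is
its paraxial expansion `exp(ikz)·exp(−iπλz(fx²+fy²)/n)` with
`k = 2πn/λ`.  Two deliberate choices:

- **Evanescent components are zeroed by default.**  This keeps both
  kernels unitary on the propagating subspace, so power conservation is
  exact and `propagate(z)∘propagate(−z)` is the identity.  The Fresnel
  kernel is truncated to the same propagating support so the two methods
  share these invariants bit-for-bit.
- **The piston phase `exp(ikz)` is included.**  Composition over z1 then
  z2 then equals one propagation over z1+z2 with no phase bookkeeping.

Transforms run on a zero-padded raster (default pad factor 2, central
crop afterwards) to suppress periodic wrap-around; pad factor 1 is exact
for unitarity measurements on compact fields.  An optional band limit
caps `|f|` at `1/(λ√((2z/L)²+1))` per axis (L the padded width), the
standard anti-aliasing cap for long transfer-function distances.  The
padding and band-limit policies are this library's own and are exposed
in `PropagationSettings`.

The single-transform Fresnel propagator requires the input chirp to be
Nyquist sampled, i.e. `z ≥ N d² n/λ`; closer planes are rejected with
the violated bound.  Its amplitude scale `d²/(iλz)` conserves power
exactly (discrete Parseval), as does the Fourier-lens scale `d²/(iλf)`.
A far-field cross-check against the angular spectrum method on a shared
raster is impractical (matching rasters at far-field distances would
need enormous padding), so the single-transform path is validated
against the Gaussian-beam closed form `w(z) = w0√(1+(z/zR)²)` and
Parseval instead.

## Aberrations

Zernike polynomials use ANSI single-index ordering,
`j = (n(n+2)+m)/2`, **unnormalized**, with coefficients in waves; the
pupil phase is `2π Σ c_j Z_j(ρ,θ)` inside ρ ≤ 1 and zero outside.  The
pupil lives on the centered frequency raster of the image grid with
ρ = 1 at transverse frequency NA/λ (vacuum wavelength; NA includes the
medium index, the standard microscopy convention).

The Seidel wavefront is the classical five-term expansion

    W = W040 ρ⁴ + W131 h ρ³ cosθ' + W222 h² ρ² cos²θ'
      + W220 h² ρ² + W311 h³ ρ cosθ'   (waves),

with h the normalized field height and θ' the pupil azimuth measured
**from the field-point direction** — the convention forced by rotational
invariance (rotating the field point must rotate the pupil map).  The
coefficient order `[sphere, coma, astigmatism, field curvature,
distortion]` is pinned for config files.  Field coordinates are
normalized to magnitude 1 at a stated calibration radius and scale
beyond 1 outside it.

SLM phases wrap to [0, 2π) before rounding to `2^bits` uniform levels
(device convention); quantization is idempotent with half-step error
bound `π/2^bits`.

## Multislice scattering

Each slice applies the phase screen `exp(i 2π Δn dz/λ)` (vacuum
wavenumber times contrast) at the slice **entrance**, then diffracts
over dz in the background medium.  Screen-first ordering is a pinned
convention; the slice-refinement consistency test (halving dz changes
smooth-phantom outputs by ≤ 1%) is what makes the choice benign.
Complex Δn is accepted — the imaginary part attenuates amplitude — in
which case unitarity no longer holds.

## Image formation

The coherent 4f PSF is the centered inverse FFT of aperture ×
aberration phase × paraxial defocus `exp(−iπ(λ/n)z f²)`; the intensity
stack is normalized so the in-focus page (smallest |z|) sums to one,
with the same factor on every page so relative defocus energy is
preserved.  Incoherent imaging is linear (zero-padded) convolution —
never circular, since physical image formation has no wrap-around —
cropped to the sample raster with offset `kernel_shape//2`, which makes
a centered impulse reproduce the kernel exactly.

### Ring convolution

The defining model (`sv_superposition_oracle`): every sample pixel adds
its intensity times the PSF at the nearest calibrated radius, rotated to
the pixel's azimuth (bilinear rotation about the patch center).  The
efficient path scatters the sample bilinearly onto a polar raster
(radius step one pixel, `n_phi` azimuthal samples, default the next
power of two ≥ 8× the radial count), evaluates for each input radius a
circular convolution over azimuth against the azimuthal Fourier
transforms of the radially-indexed PSFs, and gathers back bilinearly.
Cost per radius is `O(n_phi log n_phi)` — linear rather than quadratic
in image rows.  The contract is agreement with the oracle (≤ 5%
relative L2 under the strong miniature-microscope aberrations used in tests;
the residual is polar-interpolation error, which decreases with
azimuthal density).  When all PSFs in the set are identical the model
is spatially invariant and the operator reduces to a single FFT
convolution, which is exact — this degenerate fast path is what makes
the zero-aberration case agree with plain convolution to ≤ 1e−4.
Because scatter/gather are sparse matrices and the per-radius kernel
products are diagonal in the azimuthal Fourier basis, the exact adjoint
is available by transposition, which ring deconvolution uses.

## Gradients

No autodiff framework is used: every inverse driver carries a
hand-written adjoint in Wirtinger calculus (`g = ∂L/∂u*`; complex-linear
operators pull back as `Aᴴg`; the adjoint of a padded transfer-function
propagation is the same propagation with the conjugate kernel; a phase
θ in `u·e^{iθ}` receives `2 Im(conj(u_out)·g)`).  The contract is purely
behavioral: agreement with central finite differences to ≤ 1e−5
(element chains) and ≤ 1e−4 (multislice) in double precision, checked
by `gradcheck_fd` on seeded coordinate subsets (≥ 32 coordinates).

Losses: MSE; negative Pearson correlation; an "accuracy" loss defined as
1 − cosine similarity of flattened intensities (pinned here, since the
original formulation is not spelled out in the literature the model
follows); and 1 − SSIM with a uniform window and zero padding (chosen so
the windowing operator is self-adjoint and the SSIM gradient is exact).
Zernike estimation defaults to MSE — the neural-representation losses
used with real data add nothing at desk scale — with neg-SSIM available.

## Inverse drivers: conditions and tunables

- **Adam** (`run_gradient_descent`): bias-corrected; the first update
  magnitude per coordinate equals the step size.  Deterministic given
  init and seed; NaN loss aborts with the iteration index.
- **Gerchberg–Saxton**: alternating projections between unit SLM
  amplitude and target focal amplitude; the target is pre-scaled to the
  SLM power so the constraint sets can intersect.  The amplitude-error
  trace is non-increasing.  From an independent random start the error
  plateaus slowly (≈ 0.05 at 50 rounds, ≤ 0.01 by 1000 rounds on a
  64² speckle target); tests use 1000 rounds.
- **CGH** (`optimize_cgh_phase`): plane wave → phase mask → Fourier lens
  → per-plane angular-spectrum propagation (or multislice through a
  given scattering volume, with targets matched to the nearest slice
  plane); Adam on the configured loss; the canonical three-plane
  configuration puts targets at −10/0/+10 mm around the focal plane of
  a 200 mm lens with 10 µm SLM pixels.  Quantization (8-bit default at
  evaluation) is applied outside the optimization loop, not through a
  straight-through estimator.
- **Zernike estimation**: coefficients start at zero; step size 0.02
  waves with 100–200 iterations recovers 0.3/−0.2/0.15 waves on ANSI
  5/6/7 to ≈ 1 milliwave RMS noiselessly (32×64×64 volume, 0.8 NA,
  513 nm, 0.2 µm pixels, 0.5 µm z-step).
- **TV proximal operator**: dual projection iteration (step 1/(4·ndim))
  for isotropic TV in any dimension, stopped at relative iterate change
  1e−4 (the stated operating tolerance) or 500 iterations.
- **Refractive-index tomography**: per epoch, one plain gradient step
  per illumination angle on the exit-plane intensity MSE (the
  measurement plane is the volume exit face — a relay to the objective
  focal plane would add no tested behavior at desk scale), then TV
  smoothing, then Nesterov momentum between smoothed iterates with
  `t_{k+1} = (1+√(1+4t_k²))/2`.  Default conditions: 16×48×48 volume,
  0.5 µm pixels, 1 µm slices, 660 nm, Δn = 0.02 sphere, 8 tilts up to
  ±30°, step 0.01, TV weight 3e−5, 50 epochs → Pearson ≈ 0.9 against
  the true sphere.  Angle order is fixed (no stochastic shuffling), so
  the driver is deterministic independent of the seed.
- **Ring deconvolution**: estimate initialized to the measurement, Adam
  on MSE under the ring operator with a clip-at-zero projection
  (intensities are nonnegative; no other regularizer is added).

## What the synthetic data does and does not show

The phantoms (seeded point sources, dot target planes, index-contrast
spheres, bead volumes) are pure functions of their configuration and
emulate geometry only: they have no sensor noise, no background, no
aberration mismatch between simulation and "measurement", and no sample
motion.  Passing recovery tests therefore demonstrates the correctness
and self-consistency of the forward models, adjoints and optimizers —
not performance on real microscope data, where noise, calibration error
and model mismatch dominate.  Conversely, the closed-form and
conservation tests (Gaussian beams, Airy radii, Parseval, reciprocity)
are genuine physics checks independent of any generator.

Problem sizes in tests and in `scripts/acceptance.py` (64–1024 pixel
rasters, ≤ 32-plane volumes, ≤ 8 angles) were chosen as the smallest
instances on which each property is cleanly measurable; every driver
scales to larger rasters unchanged.

## Known limitations

Scalar fields only (no polarization or vectorial diffraction); fully
coherent or fully incoherent models (no partial coherence); forward
multislice without backscattering; paraxial thin lenses and defocus;
no sensor model (noise, pixel response, vignetting).  The single-index
Zernike path assumes the unnormalized ANSI convention throughout —
coefficients from normalized conventions must be converted before use.
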