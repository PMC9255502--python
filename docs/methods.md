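# Methods

This note records the physical model, the numerical choices, and the known
limits of the simulation and reconstruction pipeline.  Everything stated
here is computed by the test suite or by `scripts/acceptance.py`; nothing is
quoted from elsewhere.

## Scalar field model and propagation

Fields are scalar complex arrays on uniform grids (pitch in µm, axial
distances in mm, wavelength 0.532 µm by default; the experimental linear
polarizer justifies a single scalar channel).  Free-space propagation is the
angular spectrum method (ASM): multiply the FFT of the field by
`exp(i 2π z sqrt(1/λ² − fx² − fy²))` and invert; evanescent frequencies are
always zeroed.

Two ASM variants coexist, on purpose:

* **Band-limited ASM** (`bandlimit=True`, the default of the standalone
  `angular_spectrum_propagate`): the Matsushima criterion
  `f_lim = 1/(λ sqrt((2 Δf z)² + 1))` caps the usable frequency so that the
  wrapped replicas of a finite grid cannot alias into the result, and
  distances beyond the point where fewer than 4 frequency samples survive
  raise an error naming the safe maximum.  Use this when a propagated image
  is the end product.
* **Periodic unitary ASM** (`bandlimit=False`): the grid is treated as
  periodic, |H| = 1 on every propagating frequency, and the discrete
  operator is exactly unitary and exactly invertible.  The entire
  simulation ↔ retrieval ↔ refocusing loop uses this variant, because the
  0.8 µm core modes fill the Nyquist band at 1 µm pitch: a band limit would
  discard 20 %+ of the energy, while the periodic operator keeps the
  forward and inverse models perfectly consistent (energy conservation to
  machine precision, `refocus(refocus(E, z), −z) = E` exactly).  The cost is
  physically spurious wrap-around of light leaving the window — harmless
  here, since the same operator generates and inverts it.

Zero-padding (`pad=2`) is available for scenes near the grid edge but is off
by default: padding + cropping breaks strict unitarity, and the periodic
convention makes it unnecessary at the problem sizes used.

## The fiber bundle as a phase encoder

The bundle is a hexagonal lattice of Gaussian single-mode cores (1/e
amplitude radius 0.8 µm for a 2 µm core, spacing 3.2 µm, clipped to a
circular aperture of 350 µm by default → ~10,870 cores).  Each core centre
is jittered uniformly within a disc of radius `jitter × spacing`
(default jitter 0.1) — drawn imaging bundles are visibly disordered, and
the jitter also diffuses the lattice diffraction orders that a perfect
grating would produce.  The minimum pairwise distance is therefore
`spacing (1 − 2 jitter)`.  Intrinsic phases are i.i.d. uniform on [0, 2π)
and static; per-core transmission is 1.0 by default with an optional
log-normal spread for robustness studies.  There is no inter-core coupling
and no multi-mode behaviour.

Coupling uses the mode-weighted mean `⟨g, E⟩ / ⟨g, 1⟩`, normalized so a unit
plane wave couples at amplitude exactly 1 into every core — the discrete
statement of "amplitude is maintained".  The detection facet field is the
superposition of the same Gaussian modes with the coupled amplitudes,
core transmissions and intrinsic phases applied; `transmit` is linear in
the incident field.  With ≥1,000 cores under uniform illumination the
far-field intensity is fully developed speckle (Kolmogorov–Smirnov distance
to a fitted exponential < 0.05 in the suite).

Camera model: Poisson shot noise at a stated mean photon count per pixel
(noiseless by default for oracle tests; 10⁴ photons/pixel for realism
runs), then min–max normalization and round-half-up quantization to 8 or
16 bits.  A 4-f relay (magnification + camera pitch + Nyquist warning) is
modelled by `resample_to_camera`; the reconstruction is invariant to
magnification, so the default pipeline works in facet-plane coordinates.

## Retrieval

**Reference (two planes).**  Amplitude replacement alternating projections
between the measured planes at z₀ = 3 mm and z₁ = 5 mm, with a facet-plane
aperture support (disc of 1.05 × bundle diameter).  Pure projection onto
the support stagnates when the bundle fills a sizeable fraction of the grid
(measured: residual plateau ≈ 0.29 and phase error ≈ 1.5 rad for a 180 µm
bundle on a 256² grid), so the support step uses Fienup hybrid input–output
feedback (`u_outside ← u_prev − β u`, β = 0.8) followed by a strict
projection tail (60 iterations) to land on a feasible point; with it the
same problem reaches residual ~10⁻⁹ and exact phase recovery (modulo the
global piston, which intensity-only data cannot fix).  With
`support_feedback = 0` the classic error-reduction scheme is recovered,
whose residual is provably non-increasing — the property test uses that
configuration.  Stopping: relative residual change < `tol` over a 10-
iteration window, or `max_iter` (700 by default); `converged` means the
final normalized amplitude misfit is below `residual_tol` (0.05, about the
shot-noise floor at 10⁴ photons/pixel).

**Sample (one plane).**  Initialized at the reference facet field
(amplitude A₀, phase φ₀), iterating between the facet prior and the
measured amplitude at z₁.  A disc support alone leaves this single-plane
problem underdetermined whenever the scene lights up only part of the
bundle (a mostly-opaque negative target: amplitude correlation with truth
0.44).  The facet prior is therefore the **core-mode projection**: the
physical facet field lies in the span of the Gaussian core modes, and
projecting each iterate onto that span (least-squares, core geometry
treated as calibration data — it is recoverable from the reference
amplitude map; the intrinsic phases are *not* used) reduces the unknowns to
one complex number per core and makes the problem well-posed (correlation
0.99999 on the same scene).  The projection is strict; the disc-support HIO
feedback still applies outside it.

**Decoding.**  `φ′ₛ = wrap(φ₁ − φ₀)` in (−π, π], `E′ₛ = A₁ exp(iφ′ₛ)`.  The
decoded field is the core-sampled incident field; its spectrum carries
replicas at the reciprocal lattice frequency (1/3.2 µm⁻¹) that refocus into
speckle-like crosstalk.  `suppress_core_lattice` removes them with a
Gaussian low-pass of 1/e cutoff `0.5 / spacing` — at the lattice Nyquist,
i.e. exactly the information limit of the sampling — and is applied by the
pipeline before refocusing, autofocus and phase maps (configurable off).

A global piston survives decoding (each retrieval fixes its own gauge).
The OPD pipeline removes it as the circular mean over the background region
*before* median filtering and plane fitting, so the background sits near
zero and the sample phase stays clear of the ±π wrap where elementwise
filters break down.  All phase comparisons in the tests are circular and
modulo piston (and, where a single-plane ambiguity could arise, the
conjugate solution is also scored and the better gauge reported).

## Quantitative analysis

* **Refocusing**: `refocus(E, d)` propagates by −d (positive d toward the
  sample), exactly inverting scene composition.  Autofocus maximizes the
  normalized intensity variance (Tamura coefficient as alternative) over a
  uniform distance sweep, optionally within an ROI; ties break toward
  smaller z, and a metric range below 10⁻⁶ (relative) or an absolute
  contrast below 10⁻⁶ reports "no focus".  Note the physics: focus
  localization is limited by the depth of field λ/NA², so one-step
  (0.02 mm) precision needs the full 350 µm aperture; small test bundles
  localize to ~0.1 mm only.
* **Tilt correction**: least-squares plane (piston + two tilts) on a
  background mask (user-supplied, or the lowest-gradient quartile of the
  map), subtracted everywhere.
* **Denoising**: total-variation (Chambolle) on amplitude, 2D median
  (reflective boundary) on phase; both identity at weight 0 / kernel 1.
* **OPD**: `OPD = (Δφ/2π + k) λ` in nm, fringe order k = 0 by default (the
  intended samples stay within one fringe); an optional reliability-ordered
  2D unwrapping pass handles thicker objects.
* **Bead fit**: robust (soft-L1) least squares of the spherical-chord model
  `OPD(ρ) = 2000 Δn sqrt(r² − ρ²)` over centre, radius and contrast, after
  blob detection restricted to the valid field of view.  The model is
  blurred with the *known* reconstruction resolution before comparison
  (`blur_sigma` = quadrature sum of the two core-mode blurs and the lattice
  low-pass, ≈1.65 µm at the defaults), which removes the systematic
  broadening/flattening a finite PSF otherwise imprints on d and Δn.  The
  10 %-threshold support width is reported as an independent diameter
  cross-check.
* **Resolution sweep**: two parallel phase lines through the full pipeline;
  a separation is resolved when the mid-profile dips by ≥ 26.4 %
  (Rayleigh-equivalent) below the line peaks.  The criterion is this
  package's own choice and is configurable.
* **Off-axis holography oracle**: an independent field-recovery route used
  only for cross-checks — synthesize `|U + R|²` with a tilted reference,
  window the order term at −f_c in the Fourier plane (the `U R*` term),
  demodulate, divide by the reference amplitude.  The carrier must exceed
  3× the field's 98 %-energy spectral radius or the oracle refuses.  A
  full-bandwidth facet field leaves no carrier headroom on its own grid, so
  the comparison runs on a 4× sinc-upsampled copy (the numerical analogue
  of the magnified interferometric recording) with the carrier at 3.3× the
  measured bandwidth along the grid diagonal, then downsamples.

## Benchmark problem sizes and conditions

* Holography cross-check: 512² grid, full 350 µm bundle (~10,870 cores),
  negative bar target (22.1 and 11.05 µm groups) at 1.6 mm, noiseless.
* Bead: 256² grid, 180 µm bundle (~2,870 cores), 16.7 µm bead with
  Δn = 0.008 in n = 1.335 medium at 0.5 mm, Poisson 10⁴ photons/pixel +
  16-bit quantization.
* Two-layer: 512² grid, full bundle, positive bar targets at 1.26 mm
  (22.1 µm) and 2.66 mm (11.05/9.84/8.77 µm), laterally offset; same noise;
  autofocus sweep 0.5–3.5 mm in 0.02 mm steps with per-layer ROIs taken
  from the generator's ground truth (the experimenter knows where the bars
  are); FWHM linewidths measured on each group's central bar with half a
  linewidth of clear background on either side.

All randomness flows through named seeds (bundle disorder, shot noise,
optional random initialization); identical configuration + seeds give
bitwise-identical outputs.

## What the synthetic data does and does not show

The generator reproduces the features the reconstruction depends on —
single-mode amplitude-preserving cores with static uniform phase disorder,
fully developed far-field speckle, shot noise and quantization, thin
multi-layer samples — so passing tests demonstrate the *algorithmic* chain:
calibration, single-speckle decoding, refocusing and OPD quantification
under realistic photon budgets.  They do not probe effects absent from the
model: fiber bending between calibration and measurement, inter-core
coupling and multi-mode cores, per-core mode-shape variation,
polarization/birefringence, chromatic effects, camera read noise and fixed
pattern, volumetric scattering in thick samples, and mechanical drift.
Real bundles also have larger, correlated disorder in core size and
spacing than the uniform jitter used here.  The mode-projection prior
assumes the core geometry is known to sub-micron accuracy; with a real
fiber it would first have to be estimated from the reference amplitude
image.
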