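"""Intensity-only recovery of the fiber-facet complex field (FAST).

The far-field amplitude-only speckle transfer (FAST) scheme decodes the
incident complex field from intensity-only far-field speckle images:

* **Reference retrieval** — with plane-wave (or point-source) illumination
  and no sample, two speckle images at distinct detection-plane distances
  ``z0`` and ``z1`` determine the bundle's intrinsic phase map ``phi_0`` by
  alternating projections (two-plane Gerchberg-Saxton / Misell iteration
  with amplitude replacement), optionally with a support constraint at the
  fiber facet.  Two distinct planes break the conjugate (twin) ambiguity.
* **Sample retrieval** — with a sample in place only a single speckle at
  ``z1`` is needed: the iteration runs between the facet plane (support
  constraint) and ``z1`` (amplitude constraint), initialized with the
  reference facet field, and returns ``phi_1``, ``A_1``.
* **Decoding** — ``phi_s' = phi_1 - phi_0`` (wrapped) removes the intrinsic
  disorder, and ``E_s' = A_1 * exp(i * phi_s')`` is the incident field at
  the measurement facet, since each single-mode core preserves the coupled
  amplitude.

All phases are recovered up to a global piston (and the comparison helpers
here remove it); fixed seeds and inputs give bitwise-identical results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field
from typing import Optional

import numpy as np

from .field_optics import (
    ComplexField,
    OpticalConfig,
    SpeckleImage,
    angular_spectrum_propagate,
    grid_coords,
)

__all__ = [
    "IterationOptions",
    "RetrievalResult",
    "retrieve_reference",
    "retrieve_sample",
    "subtract_reference",
    "compose_incident",
    "decode_incident",
    "wrap_phase",
    "circular_mean",
    "remove_piston",
    "gauge_phase_error",
    "support_mask",
    "ModeProjector",
]


def wrap_phase(x: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    w = (np.asarray(x, dtype=float) + np.pi) % (2.0 * np.pi) - np.pi
    return np.where(w == -np.pi, np.pi, w)


def circular_mean(phases: np.ndarray) -> float:
    """Mean direction of a set of angles (radians)."""
    return float(np.angle(np.mean(np.exp(1j * np.asarray(phases)))))


def remove_piston(phase: np.ndarray, mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Subtract the circular mean (over ``mask`` if given) and re-wrap."""
    sel = phase[mask] if mask is not None else phase
    return wrap_phase(phase - circular_mean(sel))


def gauge_phase_error(estimate: np.ndarray, truth: np.ndarray,
                      mask: Optional[np.ndarray] = None, *,
                      allow_conjugate: bool = True) -> tuple[float, int]:
    """Circular mean absolute phase error modulo the global piston.

    Intensity-only retrieval is blind to a global phase constant and (for a
    single plane) to complex conjugation; this helper removes the piston and,
    if ``allow_conjugate``, also scores the conjugate solution, returning
    ``(error, sign)`` with ``sign`` in {+1, -1} for whichever matched.
    """
    est = estimate[mask] if mask is not None else np.ravel(estimate)
    tru = truth[mask] if mask is not None else np.ravel(truth)
    best = (np.inf, 1)
    signs = (1, -1) if allow_conjugate else (1,)
    for s in signs:
        d = wrap_phase(s * est - tru)
        err = float(np.mean(np.abs(wrap_phase(d - circular_mean(d)))))
        if err < best[0]:
            best = (err, s)
    return best


def support_mask(grid_size: int, pitch: float, diameter: float,
                 margin: float = 1.05) -> np.ndarray:
    """Boolean disc of ``diameter * margin`` centred on the grid."""
    x = grid_coords(grid_size, pitch)
    r2 = x[np.newaxis, :] ** 2 + x[:, np.newaxis] ** 2
    return r2 <= (margin * diameter / 2.0) ** 2


class ModeProjector:
    """Least-squares projection of a facet field onto the core modes.

    The physical detection-facet field lives in the span of the bundle's
    Gaussian core modes; projecting each iterate onto that span is a far
    stronger facet-plane constraint than the aperture disc, and it is what
    makes single-speckle (sample) retrieval well-posed for scenes that only
    light up part of the bundle.  The core geometry is calibration
    information (recoverable from the reference amplitude map); intrinsic
    phases are not used.
    """

    def __init__(self, mcf, grid_size: int, pitch: float,
                 halfwidth_modes: float = 4.0) -> None:
        from .mcf_forward import _core_windows

        idx = []
        weights = []
        for _k, sy, sx, g in _core_windows(mcf, grid_size, grid_size, pitch,
                                           halfwidth_modes):
            rows = np.arange(sy.start, sy.stop)
            cols = np.arange(sx.start, sx.stop)
            flat = (rows[:, np.newaxis] * grid_size + cols[np.newaxis, :]).ravel()
            idx.append(flat)
            weights.append(g.ravel())
        self._idx = np.stack(idx)
        self._g = np.stack(weights)
        self._gg = (self._g**2).sum(axis=1)
        self._shape = (grid_size, grid_size)

    def coefficients(self, field_values: np.ndarray) -> np.ndarray:
        """Per-core complex amplitudes of the least-squares projection."""
        flat = field_values.ravel()
        return (flat[self._idx] * self._g).sum(axis=1) / self._gg

    def __call__(self, field_values: np.ndarray) -> np.ndarray:
        coeff = self.coefficients(field_values)
        out = np.zeros(self._shape[0] * self._shape[1], dtype=np.complex128)
        np.add.at(out, self._idx.ravel(), (coeff[:, np.newaxis] * self._g).ravel())
        return out.reshape(self._shape)


@dataclass
class IterationOptions:
    """Controls for the alternating-projection iteration.

    ``beta`` is the amplitude-replacement relaxation (1.0 = pure
    replacement).  ``support_diameter`` (um) enables a facet-plane support
    constraint (a disc of ``1.05 x`` that diameter).  The support step uses
    hybrid input-output feedback with parameter ``support_feedback``: the
    field outside the support is updated as ``u_prev - feedback * u`` rather
    than simply damped, which avoids the stagnation of pure error reduction
    when the bundle fills a sizeable fraction of the grid; the final
    ``polish_iter`` iterations switch to a strict projection (field outside
    the support multiplied by ``support_soft``) to settle on a feasible
    point.  Set ``support_feedback=0`` for the classic projection-only
    scheme.  ``tol`` stops the iteration when the relative residual change
    over ``tol_window`` iterations falls below it.
    """

    max_iter: int = 500
    tol: float = 1e-6
    tol_window: int = 10
    residual_tol: float = 0.05
    beta: float = 1.0
    support_diameter: Optional[float] = None
    support_soft: float = 0.0
    support_feedback: float = 0.8
    polish_iter: int = 60
    init: str = "flat"  # 'flat' or 'random'
    init_seed: Optional[int] = None
    init_phase: Optional[np.ndarray] = None  # explicit phase at the z0 plane
    mode_projector: Optional["ModeProjector"] = None


@dataclass
class RetrievalResult:
    """Reconstructed facet-plane field plus iteration diagnostics."""

    facet_field: ComplexField
    residual_history: np.ndarray
    iterations: int
    converged: bool
    diagnostics: dict = dataclass_field(default_factory=dict)

    @property
    def phase(self) -> np.ndarray:
        return self.facet_field.phase

    @property
    def amplitude(self) -> np.ndarray:
        return self.facet_field.amplitude


def _amplitudes_from_speckles(*speckles: SpeckleImage) -> list[np.ndarray]:
    """Square-root amplitudes, rescaled to a common (first image's) energy.

    Quantization destroys the absolute intensity scale per image; free-space
    propagation conserves energy, so the measured planes are renormalized to
    the first plane's total energy.
    """
    ref_energy = None
    out = []
    for sp in speckles:
        img = np.asarray(sp.pixels, dtype=float)
        e = img.sum()
        if e <= 0:
            raise ValueError("all-dark speckle image")
        if ref_energy is None:
            ref_energy = e
        out.append(np.sqrt(img * (ref_energy / e)))
    return out


def _replace_amplitude(u: np.ndarray, target: np.ndarray, beta: float) -> np.ndarray:
    mag = np.abs(u)
    new_mag = mag + beta * (target - mag)
    with np.errstate(invalid="ignore", divide="ignore"):
        phase_factor = np.where(mag > 0, u / np.where(mag > 0, mag, 1.0), 1.0)
    return new_mag * phase_factor


def _residual(u: np.ndarray, target: np.ndarray) -> float:
    return float(np.linalg.norm(np.abs(u) - target) / np.linalg.norm(target))


def _converged(history: list[float], tol: float, window: int) -> bool:
    if len(history) < window + 1:
        return False
    prev, cur = history[-window - 1], history[-1]
    return abs(prev - cur) <= tol * max(cur, 1e-30)


def _prop(values: np.ndarray, pitch: float, wavelength: float,
          distance_mm: float) -> np.ndarray:
    f = ComplexField(values, pitch, wavelength)
    return angular_spectrum_propagate(f, distance_mm, bandlimit=False).values


def _facet_constraint(uf: np.ndarray, sup: Optional[np.ndarray],
                      options: IterationOptions, polishing: bool, it: int,
                      state: dict) -> np.ndarray:
    """Apply the facet-plane prior: core-mode projection and/or aperture support.

    The disc support uses hybrid input-output feedback outside the polish
    tail; the mode projection is always a strict projection (it is already
    the dominant constraint and needs no relaxation).
    """
    if options.mode_projector is not None:
        uf = options.mode_projector(uf)
    if sup is not None:
        use_hio = (options.support_feedback > 0 and not polishing
                   and it <= options.max_iter - options.polish_iter)
        if use_hio:
            if state.get("uf_prev") is None:
                state["uf_prev"] = uf.copy()
            uf = np.where(sup, uf, state["uf_prev"] - options.support_feedback * uf)
            state["uf_prev"] = uf
        else:
            uf = np.where(sup, uf, uf * options.support_soft)
    return uf


def retrieve_reference(speckle_z0: SpeckleImage, speckle_z1: SpeckleImage,
                       config: OpticalConfig,
                       options: Optional[IterationOptions] = None) -> RetrievalResult:
    """Two-plane alternating-projection retrieval of the reference facet field.

    Initializes at ``z0`` with the measured amplitude and a flat (or seeded
    random) phase, then alternates amplitude replacement between the two
    measured planes; when a support diameter is configured, each cycle also
    back-propagates to the facet and damps the field outside the bundle
    aperture.  The returned field is the final iterate back-propagated to
    the facet plane (``A_0``, ``phi_0``).
    """
    options = options or IterationOptions()
    z0 = speckle_z0.plane_distance
    z1 = speckle_z1.plane_distance
    if z0 == z1:
        raise ValueError("two distinct reference planes required (z0 != z1)")
    if speckle_z0.shape != speckle_z1.shape:
        raise ValueError("speckle images must share a shape")
    a0, a1 = _amplitudes_from_speckles(speckle_z0, speckle_z1)
    pitch = speckle_z0.pitch
    lam = config.wavelength
    n = a0.shape[0]
    if options.init_phase is not None:
        theta = np.asarray(options.init_phase, dtype=float)
        if theta.shape != a0.shape:
            raise ValueError("init_phase must match the speckle shape")
    elif options.init == "random":
        rng = np.random.default_rng(options.init_seed)
        theta = rng.uniform(-np.pi, np.pi, a0.shape)
    elif options.init == "flat":
        theta = np.zeros(a0.shape)
    else:
        raise ValueError("init must be 'flat' or 'random'")
    sup = None
    if options.support_diameter is not None:
        sup = support_mask(n, pitch, options.support_diameter)
    u0 = a0 * np.exp(1j * theta)
    history: list[float] = []
    it = 0
    hio_state: dict = {"uf_prev": None}
    polish_left = options.polish_iter if sup is not None else 0
    polishing = False
    for it in range(1, options.max_iter + 1):
        u1 = _prop(u0, pitch, lam, z1 - z0)
        history.append(_residual(u1, a1))
        u1 = _replace_amplitude(u1, a1, options.beta)
        u0 = _prop(u1, pitch, lam, z0 - z1)
        u0 = _replace_amplitude(u0, a0, options.beta)
        if sup is not None or options.mode_projector is not None:
            uf = _prop(u0, pitch, lam, -z0)
            uf = _facet_constraint(uf, sup, options, polishing, it, hio_state)
            u0 = _prop(uf, pitch, lam, z0)
            u0 = _replace_amplitude(u0, a0, options.beta)
        if not polishing and _converged(history, options.tol, options.tol_window):
            if polish_left > 0 and options.support_feedback > 0:
                polishing = True  # settle on a feasible point with strict support
            else:
                break
        elif polishing:
            polish_left -= 1
            if polish_left <= 0:
                break
    converged = history[-1] <= options.residual_tol
    if not converged:
        warnings.warn("reference retrieval did not converge: residual "
                      f"{history[-1]:.3g} > {options.residual_tol:g} after "
                      f"{it} iterations", RuntimeWarning)
    uf = _prop(u0, pitch, lam, -z0)
    if options.mode_projector is not None:
        uf = options.mode_projector(uf)
    if sup is not None:
        uf = np.where(sup, uf, uf * options.support_soft)
    facet = ComplexField(uf, pitch, lam, z_label=0.0)
    return RetrievalResult(facet, np.asarray(history), it, converged,
                           {"z0": z0, "z1": z1, "mode": "reference",
                            "options": options})


def retrieve_sample(speckle_z1: SpeckleImage, reference: RetrievalResult,
                    config: OpticalConfig,
                    options: Optional[IterationOptions] = None) -> RetrievalResult:
    """Single-speckle retrieval of the sample facet field (``A_1``, ``phi_1``).

    The facet field is initialized at the reference solution (amplitude
    ``A_0``, phase ``phi_0``) and iterated between the facet plane (support
    constraint, if configured) and the measured plane at ``z1`` (amplitude
    constraint).
    """
    options = options or IterationOptions(max_iter=100)
    if speckle_z1.shape != reference.facet_field.shape:
        raise ValueError("speckle grid does not match the reference grid")
    if not reference.converged:
        warnings.warn("reference retrieval had not converged; sample "
                      "retrieval may be unreliable", RuntimeWarning)
    (a1,) = _amplitudes_from_speckles(speckle_z1)
    # keep amplitude scales commensurate with the reference facet energy
    ref_energy = np.linalg.norm(np.abs(reference.facet_field.values))
    a1 = a1 * (ref_energy / np.linalg.norm(a1))
    z1 = speckle_z1.plane_distance
    pitch = speckle_z1.pitch
    lam = config.wavelength
    n = a1.shape[0]
    sup = None
    if options.support_diameter is not None:
        sup = support_mask(n, pitch, options.support_diameter)
    uf = reference.facet_field.values.copy()
    history: list[float] = []
    it = 0
    hio_state: dict = {"uf_prev": None}
    polish_left = options.polish_iter if sup is not None else 0
    polishing = False
    for it in range(1, options.max_iter + 1):
        u1 = _prop(uf, pitch, lam, z1)
        history.append(_residual(u1, a1))
        u1 = _replace_amplitude(u1, a1, options.beta)
        uf = _prop(u1, pitch, lam, -z1)
        if sup is not None or options.mode_projector is not None:
            uf = _facet_constraint(uf, sup, options, polishing, it, hio_state)
        if not polishing and _converged(history, options.tol, options.tol_window):
            if polish_left > 0 and options.support_feedback > 0:
                polishing = True
            else:
                break
        elif polishing:
            polish_left -= 1
            if polish_left <= 0:
                break
    converged = history[-1] <= options.residual_tol
    if not converged:
        warnings.warn("sample retrieval did not converge: residual "
                      f"{history[-1]:.3g} > {options.residual_tol:g} after "
                      f"{it} iterations", RuntimeWarning)
    facet = ComplexField(uf, pitch, lam, z_label=0.0)
    return RetrievalResult(facet, np.asarray(history), it, converged,
                           {"z1": z1, "mode": "sample", "options": options})


def subtract_reference(phi_1: np.ndarray, phi_0: np.ndarray) -> np.ndarray:
    """Decode the sample-induced phase: ``phi_s' = phi_1 - phi_0``, wrapped."""
    phi_1 = np.asarray(phi_1, dtype=float)
    phi_0 = np.asarray(phi_0, dtype=float)
    if phi_1.shape != phi_0.shape:
        raise ValueError("phase maps must share a shape")
    return wrap_phase(phi_1 - phi_0)


def compose_incident(amplitude_1: np.ndarray, phi_s_prime: np.ndarray, *,
                     pitch: float, wavelength: float) -> ComplexField:
    """The decoded incident field ``E_s' = A_1 * exp(i * phi_s')``."""
    amplitude_1 = np.asarray(amplitude_1, dtype=float)
    if np.any(amplitude_1 < 0):
        raise ValueError("amplitude must be nonnegative")
    if amplitude_1.shape != np.shape(phi_s_prime):
        raise ValueError("amplitude and phase must share a shape")
    return ComplexField(amplitude_1 * np.exp(1j * np.asarray(phi_s_prime)),
                        pitch, wavelength, z_label=0.0)


def decode_incident(sample: RetrievalResult,
                    reference: RetrievalResult) -> ComplexField:
    """Reference subtraction + composition in one step, carrying geometry."""
    phi = subtract_reference(sample.phase, reference.phase)
    f = sample.facet_field
    return compose_incident(sample.amplitude, phi, pitch=f.pitch,
                            wavelength=f.wavelength)
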