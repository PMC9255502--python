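"""Forward model of a multi-core fiber bundle (MCF) as a random phase encoder.

A coherent imaging fiber bundle carries the incident field through thousands
of independent single-mode cores.  Each core transmits the local complex
amplitude faithfully but adds a fixed intrinsic phase (the optical-path-length
disorder of that core).  At the detection side the superposition of the
phase-scrambled core modes diffracts into a far-field speckle pattern, which
is what the camera records.  This module builds the core lattice, couples an
incident field into the cores, renders the detection-facet field, and
simulates noisy speckle images at arbitrary detection-plane distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Optional

import numpy as np

from .field_optics import (
    ComplexField,
    OpticalConfig,
    SpeckleImage,
    angular_spectrum_propagate,
    grid_coords,
    intensity,
    quantize,
    resample_to_camera,
)

__all__ = [
    "MCFModel",
    "NoiseSpec",
    "SpeckleImage",
    "build_mcf",
    "couple_field",
    "transmit",
    "render_cores",
    "simulate_speckle",
    "save_mcf",
    "load_mcf",
]


@dataclass
class MCFModel:
    """The fiber bundle: core positions, mode size and intrinsic disorder.

    ``mode_radius`` is the 1/e *amplitude* radius of the Gaussian core mode.
    ``intrinsic_phase`` is the static per-core phase map (radians, [0, 2pi))
    accumulated along each core — the quantity the reference measurement
    recovers.
    """

    core_centers: np.ndarray  # (N, 2) um, physical coordinates
    mode_radius: float  # um
    intrinsic_phase: np.ndarray  # (N,) radians in [0, 2pi)
    core_transmission: np.ndarray  # (N,) amplitude factors in (0, 1]
    bundle_diameter: float  # um
    core_spacing: float  # um
    jitter: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.core_centers = np.asarray(self.core_centers, dtype=float)
        self.intrinsic_phase = np.asarray(self.intrinsic_phase, dtype=float)
        self.core_transmission = np.asarray(self.core_transmission, dtype=float)
        n = len(self.core_centers)
        if n == 0:
            raise ValueError("bundle has no cores")
        if self.core_centers.shape != (n, 2):
            raise ValueError("core_centers must be an (N, 2) array")
        if self.intrinsic_phase.shape != (n,) or self.core_transmission.shape != (n,):
            raise ValueError("per-core arrays must match the number of cores")
        radii = np.hypot(*self.core_centers.T)
        if np.any(radii > self.bundle_diameter / 2 + 1e-9):
            raise ValueError("all core centers must lie within the bundle aperture")
        if np.any(self.intrinsic_phase < 0) or np.any(self.intrinsic_phase >= 2 * np.pi):
            raise ValueError("intrinsic phases must lie in [0, 2pi)")
        if np.any(self.core_transmission <= 0) or np.any(self.core_transmission > 1):
            raise ValueError("core transmissions must lie in (0, 1]")

    @property
    def n_cores(self) -> int:
        return len(self.core_centers)


@dataclass
class NoiseSpec:
    """Camera noise model: Poisson shot noise and quantization.

    ``photons`` is the mean photon count per pixel over the image (None =
    noiseless, continuous output); ``bit_depth`` quantizes to 8 or 16 bits
    after min-max normalization (None = no quantization).
    """

    photons: Optional[float] = None
    bit_depth: Optional[int] = None
    seed: int = 0


def build_mcf(core_spacing: float = 3.2,
              bundle_diameter: Optional[float] = 350.0,
              core_count: Optional[int] = None,
              mode_radius: float = 0.8,
              jitter: float = 0.0,
              seed: int = 0,
              transmission_sigma: float = 0.0) -> MCFModel:
    """Build a jittered hexagonal core lattice clipped to a circular aperture.

    Exactly one of ``bundle_diameter`` (um) or ``core_count`` fixes the size:
    with ``core_count`` the innermost N lattice sites are kept and the
    aperture shrinks to fit.  ``jitter`` displaces each core uniformly within
    a disc of radius ``jitter * core_spacing`` (so the minimum pairwise
    distance is at least ``core_spacing * (1 - 2*jitter)``); intrinsic phases are
    i.i.d. uniform on [0, 2pi).  ``transmission_sigma`` > 0 adds a log-normal
    spread of per-core amplitude transmission (clipped to (0, 1]).
    Deterministic for a given seed.
    """
    if not 0 <= jitter < 0.5:
        raise ValueError("jitter must be in [0, 0.5) of the core spacing")
    if (bundle_diameter is None) == (core_count is None):
        raise ValueError("specify exactly one of bundle_diameter or core_count")
    if core_count is not None:
        # aperture large enough to contain core_count sites at hex density
        bundle_diameter = 2.0 * core_spacing * np.sqrt(
            core_count * np.sqrt(3.0) / (2.0 * np.pi)) + 2.0 * core_spacing
    radius = bundle_diameter / 2.0
    # hexagonal lattice: a1 = (s, 0), a2 = (s/2, s*sqrt(3)/2)
    m = int(np.ceil(radius / (core_spacing * np.sqrt(3.0) / 2.0))) + 2
    i, j = np.meshgrid(np.arange(-m, m + 1), np.arange(-m, m + 1), indexing="ij")
    x = core_spacing * (i + 0.5 * j).ravel()
    y = core_spacing * (np.sqrt(3.0) / 2.0) * j.ravel()
    r = np.hypot(x, y)
    keep = r <= radius
    x, y, r = x[keep], y[keep], r[keep]
    # stable enumeration order: by radius, then angle
    order = np.lexsort((np.arctan2(y, x), np.round(r, 9)))
    x, y = x[order], y[order]
    if core_count is not None:
        if core_count > x.size:  # pragma: no cover - aperture formula has margin
            raise ValueError("aperture formula produced too few lattice sites")
        x, y = x[:core_count], y[:core_count]
        if x.size == 0:
            raise ValueError("requested geometry yields zero cores")
        bundle_diameter = 2.0 * float(np.hypot(x, y).max()) + 1e-9 + core_spacing * 0.1
    if x.size == 0:
        raise ValueError("requested geometry yields zero cores")
    rng = np.random.default_rng(seed)
    if jitter > 0:
        # uniform in a disc of radius jitter * spacing
        rad = jitter * core_spacing * np.sqrt(rng.uniform(0.0, 1.0, x.size))
        ang = rng.uniform(0.0, 2.0 * np.pi, x.size)
        x = x + rad * np.cos(ang)
        y = y + rad * np.sin(ang)
        # keep jittered cores inside the aperture
        rr = np.hypot(x, y)
        out = rr > bundle_diameter / 2.0
        if np.any(out):
            scale = (bundle_diameter / 2.0) / rr[out]
            x[out] *= scale
            y[out] *= scale
    phases = rng.uniform(0.0, 2.0 * np.pi, x.size)
    if transmission_sigma > 0:
        t = np.exp(rng.normal(0.0, transmission_sigma, x.size))
        t = np.clip(t / t.max(), 1e-6, 1.0)
    else:
        t = np.ones(x.size)
    return MCFModel(np.column_stack([x, y]), mode_radius, phases, t,
                    bundle_diameter, core_spacing, jitter, seed)


def _core_windows(mcf: MCFModel, ny: int, nx: int, pitch: float,
                  halfwidth_modes: float = 4.0):
    """Yield per-core (iy, ix, gauss) index windows and mode profiles."""
    w = mcf.mode_radius
    hw = max(1, int(np.ceil(halfwidth_modes * w / pitch)))
    cy, cx = ny // 2, nx // 2
    for k in range(mcf.n_cores):
        xc, yc = mcf.core_centers[k]
        jc = xc / pitch + cx  # column
        ic = yc / pitch + cy  # row
        i0, i1 = int(np.floor(ic)) - hw, int(np.floor(ic)) + hw + 1
        j0, j1 = int(np.floor(jc)) - hw, int(np.floor(jc)) + hw + 1
        i0c, i1c = max(i0, 0), min(i1, ny)
        j0c, j1c = max(j0, 0), min(j1, nx)
        if i0c >= i1c or j0c >= j1c:
            continue
        yy = (np.arange(i0c, i1c) - cy) * pitch - yc
        xx = (np.arange(j0c, j1c) - cx) * pitch - xc
        g = np.exp(-(yy[:, np.newaxis] ** 2 + xx[np.newaxis, :] ** 2) / w**2)
        yield k, slice(i0c, i1c), slice(j0c, j1c), g


def _check_grid_covers(incident: ComplexField, mcf: MCFModel) -> None:
    ny, nx = incident.shape
    half_extent = min(ny // 2, nx // 2) * incident.pitch
    if half_extent < mcf.bundle_diameter / 2.0:
        raise ValueError(
            f"incident grid (half-extent {half_extent:g} um) does not cover "
            f"the bundle aperture (radius {mcf.bundle_diameter / 2:g} um)")


def couple_field(incident: ComplexField, mcf: MCFModel, *,
                 method: str = "overlap") -> np.ndarray:
    """Single-mode coupling: one complex amplitude per core.

    ``method='overlap'`` uses the mode-weighted mean of the incident field
    over each core's Gaussian mode, normalized so that a unit plane wave
    couples with amplitude exactly 1 into every core (this is the discrete
    statement of per-core amplitude preservation).  ``method='point'``
    bilinearly samples the field at the core centre instead.
    """
    _check_grid_covers(incident, mcf)
    ny, nx = incident.shape
    pitch = incident.pitch
    amps = np.zeros(mcf.n_cores, dtype=np.complex128)
    if method == "point":
        from scipy.ndimage import map_coordinates

        cy, cx = ny // 2, nx // 2
        rows = mcf.core_centers[:, 1] / pitch + cy
        cols = mcf.core_centers[:, 0] / pitch + cx
        re = map_coordinates(incident.values.real, [rows, cols], order=1)
        im = map_coordinates(incident.values.imag, [rows, cols], order=1)
        return re + 1j * im
    if method != "overlap":
        raise ValueError("method must be 'overlap' or 'point'")
    for k, sy, sx, g in _core_windows(mcf, ny, nx, pitch):
        gsum = g.sum()
        amps[k] = np.sum(incident.values[sy, sx] * g) / gsum
    return amps


def render_cores(amplitudes: np.ndarray, mcf: MCFModel, grid_size: int,
                 pitch: float, wavelength: float) -> ComplexField:
    """Superpose Gaussian core modes with the given complex amplitudes."""
    out = np.zeros((grid_size, grid_size), dtype=np.complex128)
    for k, sy, sx, g in _core_windows(mcf, grid_size, grid_size, pitch):
        out[sy, sx] += amplitudes[k] * g
    return ComplexField(out, pitch, wavelength, z_label=0.0)


def transmit(incident: ComplexField, mcf: MCFModel, *,
             grid_size: Optional[int] = None,
             method: str = "overlap") -> ComplexField:
    """Carry an incident field through the bundle to the detection facet.

    Each core's coupled amplitude is preserved, multiplied by the core
    transmission, and phase-shifted by the core's intrinsic phase; the
    detection-facet field is the superposition of the resulting Gaussian
    modes.  Linear in the incident field.
    """
    amps = couple_field(incident, mcf, method=method)
    amps = amps * mcf.core_transmission * np.exp(1j * mcf.intrinsic_phase)
    n = grid_size if grid_size is not None else incident.shape[0]
    return render_cores(amps, mcf, n, incident.pitch, incident.wavelength)


def apply_noise(image: np.ndarray, noise: NoiseSpec) -> tuple[np.ndarray, dict]:
    """Apply Poisson shot noise at a stated mean photon level, then quantize."""
    meta: dict = {"photons": noise.photons, "bit_depth": noise.bit_depth,
                  "seed": noise.seed}
    out = np.asarray(image, dtype=float)
    if noise.photons is not None:
        rng = np.random.default_rng(noise.seed)
        mean = out.mean()
        if mean <= 0:
            raise ValueError("cannot apply shot noise to a dark image")
        scale = noise.photons / mean
        out = rng.poisson(out * scale).astype(float) / scale
    if noise.bit_depth is not None:
        q, vmin, vmax = quantize(out, noise.bit_depth)
        meta.update({"norm_min": vmin, "norm_max": vmax})
        out = q
    return out, meta


def simulate_speckle(scene_field_at_facet: ComplexField, mcf: MCFModel,
                     plane_distance: float, config: OpticalConfig,
                     noise: Optional[NoiseSpec] = None, *,
                     resample: bool = False) -> SpeckleImage:
    """Far-field speckle image at a detection plane ``plane_distance`` mm away.

    Composition of :func:`transmit`, unitary angular-spectrum propagation to
    the detection plane, optional 4-f relay resampling onto the camera grid,
    and the camera noise model.  Deterministic given the bundle and noise
    seeds.  The noiseless, un-resampled image conserves the facet-field
    energy exactly (periodic-grid propagator).
    """
    if not plane_distance > 0:
        raise ValueError("plane_distance must be positive")
    facet = transmit(scene_field_at_facet, mcf)
    if facet.energy() < 1e-30:
        raise ValueError("no light: facet field energy below machine epsilon")
    far = angular_spectrum_propagate(facet, plane_distance, bandlimit=False)
    img = intensity(far)
    meta: dict = {"n_cores": mcf.n_cores, "mcf_seed": mcf.seed}
    if resample and (config.magnification != 1.0
                     or config.camera_pitch != facet.pitch):
        sp = resample_to_camera(img, config.magnification, config.camera_pitch,
                                16, pitch=facet.pitch,
                                plane_distance=plane_distance)
        img = np.asarray(sp.pixels, dtype=float)
        meta.update(sp.meta)
    if noise is not None:
        img, noise_meta = apply_noise(img, noise)
        meta.update(noise_meta)
    return SpeckleImage(img, plane_distance=plane_distance,
                        pitch=scene_field_at_facet.pitch, meta=meta)


# ---------------------------------------------------------------------------
# Persistence: YAML with explicit arrays.
# ---------------------------------------------------------------------------

def save_mcf(path: str, mcf: MCFModel) -> None:
    import yaml

    doc = {
        "core_centers": np.round(mcf.core_centers, 9).tolist(),
        "mode_radius": float(mcf.mode_radius),
        "intrinsic_phase": np.round(mcf.intrinsic_phase, 12).tolist(),
        "core_transmission": np.round(mcf.core_transmission, 12).tolist(),
        "bundle_diameter": float(mcf.bundle_diameter),
        "core_spacing": float(mcf.core_spacing),
        "jitter": float(mcf.jitter),
        "seed": mcf.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def load_mcf(path: str) -> MCFModel:
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return MCFModel(np.array(doc["core_centers"]), doc["mode_radius"],
                    np.array(doc["intrinsic_phase"]),
                    np.array(doc["core_transmission"]),
                    doc["bundle_diameter"], doc["core_spacing"],
                    doc.get("jitter", 0.0), doc.get("seed"))
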