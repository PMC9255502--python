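"""Scalar complex optical fields and free-space propagation.

Conventions used throughout the package:

* Lengths transverse to the optical axis (grid pitch, wavelength, core
  geometry) are in micrometres; axial distances between planes are in
  millimetres and converted internally.
* Pixel ``(0, 0)`` is the top-left sample; the physical origin sits at the
  grid centre (index ``n // 2``), which is also the DC sample of the FFT.
* A positive propagation distance moves the field along the direction of
  travel of the light; negative distances back-propagate.
* Propagation is performed by the angular spectrum method (ASM).  Evanescent
  spatial frequencies are always suppressed.  With ``bandlimit=True`` the
  Matsushima band-limit additionally caps the usable spatial frequency so
  that long-distance propagation on a finite grid does not alias; with
  ``bandlimit=False`` the grid is treated as periodic and the discrete
  operator is exactly unitary, which is the convention the simulation and
  retrieval pipeline relies on (forward and inverse use the same operator).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from numpy.fft import fft2, fftfreq, fftshift, ifft2, ifftshift
from scipy import ndimage

__all__ = [
    "ComplexField",
    "OpticalConfig",
    "SpeckleImage",
    "AliasingError",
    "angular_spectrum_propagate",
    "intensity",
    "correlation2d",
    "resample_to_camera",
    "fourier_upsample",
    "fourier_downsample",
    "grid_coords",
    "max_alias_free_distance",
    "save_field",
    "load_field",
    "save_speckle",
    "load_speckle",
]

MM = 1000.0  # micrometres per millimetre


class AliasingError(ValueError):
    """Requested propagation distance is unsafe for the grid geometry."""


@dataclass
class ComplexField:
    """A sampled scalar complex field on a uniform 2D grid.

    Parameters
    ----------
    values:
        2D complex array (dimensionless amplitude).
    pitch:
        Grid spacing in micrometres.
    wavelength:
        Vacuum wavelength in micrometres.
    z_label:
        Axial position of the plane in millimetres (bookkeeping only).
    """

    values: np.ndarray
    pitch: float
    wavelength: float
    z_label: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("field values must be a non-empty 2D array")
        if not self.pitch > 0:
            raise ValueError("pitch must be positive")
        if not self.wavelength > 0:
            raise ValueError("wavelength must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)

    def energy(self) -> float:
        """Total energy sum(|U|^2) * pitch^2 in um^2 units."""
        return float(np.sum(np.abs(self.values) ** 2)) * self.pitch**2

    def copy(self) -> "ComplexField":
        return replace(self, values=self.values.copy())


@dataclass
class OpticalConfig:
    """Geometry of the measurement: wavelength, plane distances and sampling.

    ``z0`` and ``z1`` are the two detection-side speckle plane distances from
    the fiber facet; ``z2`` is the sample distance on the measurement side.
    The working (facet-plane) pitch is ``camera_pitch / magnification``.
    """

    wavelength: float = 0.532  # um
    z0: float = 3.0  # mm
    z1: float = 5.0  # mm
    z2: float = 1.6  # mm
    camera_pitch: float = 1.0  # um
    magnification: float = 1.0
    grid_size: int = 512  # pixels

    def __post_init__(self) -> None:
        for name in ("wavelength", "camera_pitch", "magnification"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.z0 == self.z1:
            raise ValueError("two distinct reference planes required (z0 != z1)")
        if self.grid_size < 2:
            raise ValueError("grid_size must be at least 2")

    @property
    def pitch(self) -> float:
        """Facet-plane sampling pitch in micrometres."""
        return self.camera_pitch / self.magnification


@dataclass
class SpeckleImage:
    """A nonnegative intensity image recorded at a stated plane distance."""

    pixels: np.ndarray
    plane_distance: float  # mm from the facet, detection side
    pitch: float = 1.0  # um, in facet-plane coordinates
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("speckle image must be a non-empty 2D array")
        if np.any(self.pixels < 0):
            raise ValueError("speckle intensities must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def grid_coords(n: int, pitch: float) -> np.ndarray:
    """Physical 1D coordinates (um) with the origin at index ``n // 2``."""
    return (np.arange(n) - n // 2) * pitch


def max_alias_free_distance(n: int, pitch: float, wavelength: float,
                            min_band_samples: int = 4) -> float:
    """Largest |distance| (mm) for which the band-limited ASM keeps at least
    ``min_band_samples`` frequency samples of usable bandwidth."""
    df = 1.0 / (n * pitch)
    a = 1.0 / (min_band_samples * df * wavelength)
    if a <= 1.0:  # pragma: no cover - requires n * pitch < min_band_samples * wavelength
        return 0.0
    return np.sqrt(a**2 - 1.0) / (2.0 * df) / MM


def _asm_transfer(ny: int, nx: int, pitch: float, wavelength: float,
                  z_um: float, bandlimit: bool) -> np.ndarray:
    fx = fftfreq(nx, d=pitch)
    fy = fftfreq(ny, d=pitch)
    fx2 = fx[np.newaxis, :] ** 2
    fy2 = fy[:, np.newaxis] ** 2
    arg = 1.0 / wavelength**2 - fx2 - fy2
    propagating = arg > 0
    kz = np.sqrt(np.where(propagating, arg, 0.0))
    h = np.exp(2j * np.pi * z_um * kz)
    h[~propagating] = 0.0  # evanescent components suppressed
    if bandlimit and z_um != 0.0:
        # Matsushima band limit, applied separably in fx and fy.
        dfx = 1.0 / (nx * pitch)
        dfy = 1.0 / (ny * pitch)
        flim_x = 1.0 / (wavelength * np.sqrt((2.0 * dfx * z_um) ** 2 + 1.0))
        flim_y = 1.0 / (wavelength * np.sqrt((2.0 * dfy * z_um) ** 2 + 1.0))
        h[:, np.abs(fx) > flim_x] = 0.0
        h[np.abs(fy) > flim_y, :] = 0.0
    return h


def angular_spectrum_propagate(field: ComplexField, distance: float, *,
                               bandlimit: bool = True,
                               pad: int = 1) -> ComplexField:
    """Propagate ``field`` by ``distance`` millimetres (negative = backward).

    With ``bandlimit=True`` (default) evanescent and alias-prone frequencies
    are zeroed per the Matsushima criterion, and distances beyond the safe
    bound raise :class:`AliasingError`.  With ``bandlimit=False`` the grid is
    treated as periodic and the operator is exactly unitary (Parseval), which
    is what the end-to-end simulation and retrieval pipeline uses.

    ``pad`` >= 2 zero-pads the field by that factor before propagating and
    crops afterwards, for scenes with structure near the grid edge; note that
    cropping discards energy that diffracts outside the original window.
    """
    if not np.all(np.isfinite(field.values)):
        raise ValueError("field contains non-finite values")
    if not (isinstance(pad, (int, np.integer)) and pad >= 1):
        raise ValueError("pad must be an integer >= 1")
    if distance == 0.0:
        out = field.copy()
        return out
    z_um = distance * MM
    vals = field.values
    ny, nx = vals.shape
    if pad > 1:
        py, px = ny * (pad - 1) // 2, nx * (pad - 1) // 2
        vals = np.pad(vals, ((py, ny * pad - ny - py), (px, nx * pad - nx - px)))
    nyp, nxp = vals.shape
    if bandlimit:
        zmax = max_alias_free_distance(max(nyp, nxp), field.pitch, field.wavelength)
        if abs(distance) > zmax:
            raise AliasingError(
                f"propagation distance {distance:g} mm exceeds the alias-safe "
                f"maximum of {zmax:.3g} mm for a {nyp}x{nxp} grid at "
                f"{field.pitch:g} um pitch; enlarge the grid or reduce |distance|"
            )
    h = _asm_transfer(nyp, nxp, field.pitch, field.wavelength, z_um, bandlimit)
    out = ifft2(fft2(vals) * h)
    if pad > 1:
        out = out[py:py + ny, px:px + nx]
    return ComplexField(out, field.pitch, field.wavelength,
                        z_label=field.z_label + distance)


def intensity(field: ComplexField) -> np.ndarray:
    """Camera observable |U|^2, elementwise."""
    if not np.all(np.isfinite(field.values)):
        raise ValueError("field contains non-finite values")
    return np.abs(field.values) ** 2


def correlation2d(image_a: np.ndarray, image_b: np.ndarray) -> float:
    """Pearson correlation coefficient between two images, in [-1, 1]."""
    a = np.asarray(image_a, dtype=float).ravel()
    b = np.asarray(image_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("correlation undefined for a constant image")
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


def _bandwidth_estimate(image: np.ndarray, pitch: float,
                        energy_fraction: float = 0.95) -> float:
    """Radial spatial frequency (1/um) containing ``energy_fraction`` of the
    spectral energy of ``image`` (DC excluded)."""
    spec = np.abs(fftshift(fft2(image - image.mean()))) ** 2
    ny, nx = image.shape
    fx = fftshift(fftfreq(nx, d=pitch))
    fy = fftshift(fftfreq(ny, d=pitch))
    rr = np.hypot(fx[np.newaxis, :], fy[:, np.newaxis]).ravel()
    order = np.argsort(rr)
    cum = np.cumsum(spec.ravel()[order])
    if cum[-1] == 0.0:
        return 0.0
    idx = int(np.searchsorted(cum, energy_fraction * cum[-1]))
    return float(rr[order][min(idx, rr.size - 1)])


def quantize(image: np.ndarray, bit_depth: int) -> tuple[np.ndarray, float, float]:
    """Min-max normalize to full scale and quantize with round-half-up.

    Returns (quantized integer array, vmin, vmax) so callers can invert the
    normalization if needed.
    """
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    levels = 2**bit_depth - 1
    vmin = float(image.min())
    vmax = float(image.max())
    if vmax == vmin:
        q = np.full(image.shape, levels)
    else:
        norm = (image - vmin) / (vmax - vmin)
        q = np.floor(norm * levels + 0.5)  # round half up
    dtype = np.uint16 if bit_depth == 16 else np.uint8
    return np.clip(q, 0, levels).astype(dtype), vmin, vmax


def resample_to_camera(image: np.ndarray, magnification: float,
                       camera_pitch: float, bit_depth: int, *,
                       pitch: float = 1.0,
                       plane_distance: float = 0.0) -> SpeckleImage:
    """Project a facet-plane intensity image onto the camera grid.

    Models the 4-f relay: the image is magnified by ``magnification`` and
    sampled at ``camera_pitch``, then min-max normalized to full scale and
    quantized to ``bit_depth``.  An undersampling (Nyquist) warning is
    recorded in the metadata when the camera cannot resolve the speckle
    grain.  ``pitch`` is the pitch of the input image in micrometres.
    """
    if not magnification > 0:
        raise ValueError("magnification must be positive")
    image = np.asarray(image, dtype=float)
    warnings: list[str] = []
    scale = pitch * magnification / camera_pitch
    if abs(scale - 1.0) < 1e-12:
        resampled = image
    else:
        resampled = ndimage.zoom(image, scale, order=3, mode="nearest")
        resampled = np.clip(resampled, 0.0, None)
    cam_nyquist_facet = magnification / (2.0 * camera_pitch)  # 1/um at facet
    bw = _bandwidth_estimate(image, pitch)
    if bw > cam_nyquist_facet:
        warnings.append(
            f"camera undersamples the speckle grain: image bandwidth "
            f"{bw:.3g} 1/um exceeds camera Nyquist {cam_nyquist_facet:.3g} 1/um"
        )
    q, vmin, vmax = quantize(resampled, bit_depth)
    meta = {"bit_depth": bit_depth, "norm_min": vmin, "norm_max": vmax,
            "magnification": magnification, "warnings": warnings}
    return SpeckleImage(q, plane_distance=plane_distance,
                        pitch=camera_pitch / magnification, meta=meta)


def fourier_upsample(field: ComplexField, factor: int) -> ComplexField:
    """Sinc-interpolate a field onto a ``factor`` x finer grid.

    Zero-pads the centred spectrum; amplitude values are preserved.  Used to
    give the off-axis holography oracle carrier headroom, emulating a
    magnified interferometric recording.
    """
    if factor == 1:
        return field.copy()
    ny, nx = field.shape
    spec = fftshift(fft2(field.values))
    py, px = (ny * (factor - 1)) // 2, (nx * (factor - 1)) // 2
    spec = np.pad(spec, ((py, ny * factor - ny - py), (px, nx * factor - nx - px)))
    vals = ifft2(ifftshift(spec)) * factor**2
    return ComplexField(vals, field.pitch / factor, field.wavelength, field.z_label)


def fourier_downsample(field: ComplexField, factor: int) -> ComplexField:
    """Inverse of :func:`fourier_upsample`: crop the centred spectrum."""
    if factor == 1:
        return field.copy()
    ny, nx = field.shape
    my, mx = ny // factor, nx // factor
    spec = fftshift(fft2(field.values))
    py, px = (ny - my) // 2, (nx - mx) // 2
    spec = spec[py:py + my, px:px + mx]
    vals = ifft2(ifftshift(spec)) / factor**2
    return ComplexField(vals, field.pitch * factor, field.wavelength, field.z_label)


# ---------------------------------------------------------------------------
# Persistence: two-page float32 TIFF for complex fields, single-page TIFF for
# intensity images; geometry carried in the TIFF image description as JSON.
# ---------------------------------------------------------------------------

def save_field(path: str, field_: ComplexField) -> None:
    import tifffile

    pages = np.stack([field_.values.real, field_.values.imag]).astype(np.float32)
    desc = json.dumps({"pitch": field_.pitch, "wavelength": field_.wavelength,
                       "z_label": field_.z_label})
    tifffile.imwrite(path, pages, description=desc)


def load_field(path: str) -> ComplexField:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        pages = tf.asarray()
        desc = json.loads(tf.pages[0].description)
    values = pages[0].astype(np.float64) + 1j * pages[1].astype(np.float64)
    return ComplexField(values, desc["pitch"], desc["wavelength"], desc["z_label"])


def save_speckle(path: str, speckle: SpeckleImage) -> None:
    import tifffile

    px = speckle.pixels
    if not np.issubdtype(px.dtype, np.integer):
        px = px.astype(np.float32)
    meta: dict[str, Any] = {"plane_distance": speckle.plane_distance,
                            "pitch": speckle.pitch, "meta": speckle.meta}
    tifffile.imwrite(path, px, description=json.dumps(meta))


def load_speckle(path: str) -> SpeckleImage:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        px = tf.asarray()
        desc = json.loads(tf.pages[0].description)
    return SpeckleImage(px, desc["plane_distance"], desc["pitch"], desc.get("meta", {}))
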