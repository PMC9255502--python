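"""Synthetic measurement-side scenes with known ground truth.

Thin-element phantoms (resolution bar targets, programmable phase patches,
spherical phase-only beads) stand in for the physical targets used to
characterize a lensless phase endoscope.  Each phantom records the exact
generating parameters in ``ground_truth`` so it can be regenerated
bit-exactly and so downstream measurements (linewidth, bead fit) can be
checked against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .field_optics import ComplexField, OpticalConfig, angular_spectrum_propagate, grid_coords

__all__ = [
    "Phantom",
    "usaf_bars",
    "phase_patch",
    "bead_phantom",
    "two_line_phase_target",
    "compose_scene",
    "phantom_from_ground_truth",
]


@dataclass
class Phantom:
    """A thin transmission element at a stated distance from the facet.

    ``amplitude_mask`` in [0, 1] and ``phase_map`` in radians define the
    complex transmission ``t = A * exp(i*phi)``; ``pitch`` is the raster
    pitch in micrometres.  ``ground_truth`` holds the generating parameters
    (sufficient to regenerate the phantom bit-exactly).
    """

    amplitude_mask: np.ndarray
    phase_map: np.ndarray
    distance_from_facet: float  # mm
    pitch: float  # um
    ground_truth: dict = dataclass_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.amplitude_mask = np.asarray(self.amplitude_mask, dtype=float)
        self.phase_map = np.asarray(self.phase_map, dtype=float)
        if self.amplitude_mask.shape != self.phase_map.shape:
            raise ValueError("amplitude and phase rasters must share a shape")
        if np.any(self.amplitude_mask < 0) or np.any(self.amplitude_mask > 1):
            raise ValueError("amplitude mask must lie in [0, 1]")

    @property
    def transmission(self) -> np.ndarray:
        return self.amplitude_mask * np.exp(1j * self.phase_map)


def usaf_bars(linewidths: list[float], polarity: str = "negative",
              pitch: float = 1.0, canvas: int = 512, *,
              distance_from_facet: float = 0.0,
              center: tuple[float, float] = (0.0, 0.0),
              gap_factor: float = 2.0) -> Phantom:
    """Three-bar resolution-target groups, one group per linewidth.

    Bars are vertical (width along x, length 5x the width along y) with a
    one-linewidth gap between bars, stacked top to bottom with the stated
    ``center`` offset (um).  ``polarity='negative'`` makes the bars
    transparent (amplitude 1) on an opaque background, ``'positive'`` the
    inverse.  Ground truth records every group's bounding box and the pixel
    ROI of each group's central bar for linewidth verification.
    """
    if polarity not in ("negative", "positive"):
        raise ValueError("polarity must be 'negative' or 'positive'")
    for w in linewidths:
        if w < 2 * pitch:
            raise ValueError(f"linewidth {w} um is below 2 pixels at pitch {pitch}")
    bars = np.zeros((canvas, canvas), dtype=float)
    c = canvas // 2
    groups = []
    # vertical extent of each group is its bar length (5 w)
    heights = [5.0 * w for w in linewidths]
    gaps = [gap_factor * w for w in linewidths]
    total = sum(heights) + sum(gaps[:-1]) if linewidths else 0.0
    y_top = center[1] - total / 2.0
    for w, h in zip(linewidths, heights):
        w_px = int(round(w / pitch))
        h_px = int(round(h / pitch))
        i0 = int(round(y_top / pitch)) + c
        group_rois = []
        for b in range(3):
            x_off = center[0] + (b - 1) * 2.0 * w  # bar centres 2w apart
            j_c = int(round(x_off / pitch)) + c
            j0 = j_c - w_px // 2
            bars[max(i0, 0):max(i0 + h_px, 0), max(j0, 0):max(j0 + w_px, 0)] = 1.0
            group_rois.append([i0, i0 + h_px, j0, j0 + w_px])
        groups.append({"linewidth": w, "bar_px": w_px,
                       "rois": group_rois, "central_bar_roi": group_rois[1]})
        y_top += h + gap_factor * w
    if polarity == "negative":
        amp = bars
    else:
        amp = 1.0 - bars
    gt = {"kind": "usaf_bars", "linewidths": list(linewidths),
          "polarity": polarity, "pitch": pitch, "canvas": canvas,
          "distance_from_facet": distance_from_facet,
          "center": list(center), "gap_factor": gap_factor, "groups": groups}
    return Phantom(amp, np.zeros_like(amp), distance_from_facet, pitch, gt)


def phase_patch(shape: np.ndarray, phase_value: float, *,
                pitch: float = 1.0,
                distance_from_facet: float = 0.0) -> Phantom:
    """A programmable pure-phase target: ``phase_value`` inside a mask.

    Emulates an SLM-projected phase object with tunable phase value; the
    amplitude is 1 everywhere.
    """
    mask = np.asarray(shape, dtype=bool)
    if not np.any(mask):
        raise ValueError("phase patch mask is empty")
    if abs(phase_value) > 2 * np.pi:
        raise ValueError("|phase_value| must not exceed 2*pi")
    phase = np.where(mask, float(phase_value), 0.0)
    gt = {"kind": "phase_patch", "phase_value": float(phase_value),
          "pitch": pitch, "distance_from_facet": distance_from_facet,
          "mask": mask.copy()}
    return Phantom(np.ones(mask.shape), phase, distance_from_facet, pitch, gt)


def disc_mask(canvas: int, radius_um: float, pitch: float = 1.0,
              center: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Boolean disc of the given physical radius, centred on the grid centre."""
    x = grid_coords(canvas, pitch) - center[0]
    y = grid_coords(canvas, pitch) - center[1]
    return (x[np.newaxis, :] ** 2 + y[:, np.newaxis] ** 2) <= radius_um**2


def bead_phantom(diameter: float, n_bead: float, n_medium: float,
                 wavelength: float, pitch: float, *, canvas: int = 256,
                 distance_from_facet: float = 0.0,
                 center: tuple[float, float] = (0.0, 0.0)) -> Phantom:
    """Ideal homogeneous sphere as a pure-phase object (hydrogel bead).

    The phase follows the spherical chord: ``phi(rho) = (2*pi/lambda) *
    (n_bead - n_medium) * 2*sqrt((d/2)^2 - rho^2)`` inside the bead and 0
    outside; the amplitude is 1 (no absorption).
    """
    if not diameter > 0:
        raise ValueError("diameter must be positive")
    for n in (n_bead, n_medium):
        if not 1.2 <= n <= 1.8:
            raise ValueError("refractive indices must be physical (~1.3-1.6)")
    r = diameter / 2.0
    x = grid_coords(canvas, pitch) - center[0]
    y = grid_coords(canvas, pitch) - center[1]
    rho2 = x[np.newaxis, :] ** 2 + y[:, np.newaxis] ** 2
    chord = 2.0 * np.sqrt(np.clip(r**2 - rho2, 0.0, None))
    chord[rho2 > r**2] = 0.0
    phase = (2.0 * np.pi / wavelength) * (n_bead - n_medium) * chord
    gt = {"kind": "bead", "diameter": diameter, "n_bead": n_bead,
          "n_medium": n_medium, "wavelength": wavelength, "pitch": pitch,
          "canvas": canvas, "distance_from_facet": distance_from_facet,
          "center": list(center)}
    return Phantom(np.ones(phase.shape), phase, distance_from_facet, pitch, gt)


def two_line_phase_target(separation: float, phase_value: float, *,
                          line_width: float = 2.0, line_length: float = 30.0,
                          pitch: float = 1.0, canvas: int = 256,
                          distance_from_facet: float = 0.0) -> Phantom:
    """Two parallel phase lines at a centre-to-centre ``separation`` (um).

    Used by the resolution sweep: the smallest separation at which the
    reconstruction shows a dip between the lines defines the lateral
    resolution at that phase value.
    """
    if separation <= line_width:
        raise ValueError("separation must exceed the line width")
    x = grid_coords(canvas, pitch)
    y = grid_coords(canvas, pitch)
    mask = np.zeros((canvas, canvas), dtype=bool)
    inside_y = np.abs(y) <= line_length / 2.0
    for x0 in (-separation / 2.0, separation / 2.0):
        inside_x = np.abs(x - x0) <= line_width / 2.0
        mask |= inside_y[:, np.newaxis] & inside_x[np.newaxis, :]
    ph = phase_patch(mask, phase_value, pitch=pitch,
                     distance_from_facet=distance_from_facet)
    ph.ground_truth.update({"kind": "two_line", "separation": separation,
                            "line_width": line_width,
                            "line_length": line_length, "canvas": canvas})
    return ph


def phantom_from_ground_truth(gt: dict) -> Phantom:
    """Regenerate a phantom bit-exactly from its ground-truth record."""
    kind = gt["kind"]
    if kind == "usaf_bars":
        return usaf_bars(gt["linewidths"], gt["polarity"], gt["pitch"],
                         gt["canvas"],
                         distance_from_facet=gt["distance_from_facet"],
                         center=tuple(gt["center"]),
                         gap_factor=gt["gap_factor"])
    if kind == "phase_patch":
        return phase_patch(gt["mask"], gt["phase_value"], pitch=gt["pitch"],
                           distance_from_facet=gt["distance_from_facet"])
    if kind == "two_line":
        return two_line_phase_target(gt["separation"], gt["phase_value"],
                                     line_width=gt["line_width"],
                                     line_length=gt["line_length"],
                                     pitch=gt["pitch"], canvas=gt["canvas"],
                                     distance_from_facet=gt["distance_from_facet"])
    if kind == "bead":
        return bead_phantom(gt["diameter"], gt["n_bead"], gt["n_medium"],
                            gt["wavelength"], gt["pitch"], canvas=gt["canvas"],
                            distance_from_facet=gt["distance_from_facet"],
                            center=tuple(gt["center"]))
    raise ValueError(f"unknown phantom kind {kind!r}")


def _illumination_field(illumination: str, config: OpticalConfig,
                        plane_distance: float, grid_size: int,
                        source_distance: float) -> ComplexField:
    """Illumination at the plane ``plane_distance`` mm from the facet."""
    n = grid_size
    pitch = config.pitch
    lam = config.wavelength
    if illumination == "plane":
        return ComplexField(np.ones((n, n), dtype=complex), pitch, lam,
                            z_label=plane_distance)
    if illumination == "point":
        # diverging spherical wave from an on-axis source behind the plane
        z = (source_distance - plane_distance) * 1000.0  # um from source
        if z <= 0:
            raise ValueError("point source must lie behind the farthest layer")
        x = grid_coords(n, pitch)
        rho2 = x[np.newaxis, :] ** 2 + x[:, np.newaxis] ** 2
        path = np.sqrt(z**2 + rho2)
        vals = np.exp(2j * np.pi * path / lam) * (z / path)
        return ComplexField(vals, pitch, lam, z_label=plane_distance)
    raise ValueError("illumination must be 'plane' or 'point'")


def compose_scene(phantoms: list[Phantom], illumination: str,
                  config: OpticalConfig, *,
                  source_distance: float = 50.0) -> ComplexField:
    """Propagate the illumination through a stack of thin phantoms to the facet.

    Phantoms must be ordered by decreasing distance from the facet; the field
    is multiplied by each phantom's complex transmission and angular-spectrum
    propagated (periodic, unitary) between layers, ending at the measurement
    facet plane (z = 0).  ``source_distance`` (mm) locates the point source
    for ``illumination='point'``.
    """
    dists = [p.distance_from_facet for p in phantoms]
    if any(d2 >= d1 for d1, d2 in zip(dists, dists[1:])):
        raise ValueError("phantoms must be sorted by strictly decreasing "
                         "distance from the facet")
    n = config.grid_size
    start = dists[0] if phantoms else 0.0
    u = _illumination_field(illumination, config, start, n, source_distance)
    z = start
    for idx, p in enumerate(phantoms):
        if p.amplitude_mask.shape != (n, n):
            raise ValueError("phantom raster does not match the scene grid")
        if abs(p.pitch - config.pitch) > 1e-12:
            raise ValueError("phantom pitch does not match the scene grid")
        u = ComplexField(u.values * p.transmission, u.pitch, u.wavelength,
                         z_label=z)
        # next hop along the direction of travel: toward the facet (z = 0)
        z_next = dists[idx + 1] if idx + 1 < len(phantoms) else 0.0
        u = angular_spectrum_propagate(u, z - z_next, bandlimit=False)
        z = z_next
    u.z_label = 0.0
    return u
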