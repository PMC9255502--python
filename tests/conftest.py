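"""Shared fixtures: small-scale optical configs, bundles and pipeline runs.

The expensive end-to-end runs (reference retrieval + sample decoding) are
session-scoped and shared across test modules; they use reduced problem
sizes (256^2 grids, 61-core to ~1,100-core bundles) so the whole suite
stays fast while still exercising the full physics.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import mcfqpi as m
from mcfqpi import cli_app as ca


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def small_cfg() -> m.OpticalConfig:
    return m.OpticalConfig(grid_size=256, z2=1.6)


@pytest.fixture(scope="session")
def plane_wave(small_cfg) -> m.ComplexField:
    n = small_cfg.grid_size
    return m.ComplexField(np.ones((n, n), complex), small_cfg.pitch,
                          small_cfg.wavelength)


@pytest.fixture(scope="session")
def mcf61() -> m.MCFModel:
    """Tiny 61-core bundle (centre + four rings)."""
    return m.build_mcf(3.2, None, 61, 0.8, 0.05, seed=2)


@pytest.fixture(scope="session")
def ref61(small_cfg, plane_wave, mcf61) -> m.RetrievalResult:
    """Converged reference retrieval for the 61-core bundle, noiseless."""
    sp0 = m.simulate_speckle(plane_wave, mcf61, small_cfg.z0, small_cfg)
    sp1 = m.simulate_speckle(plane_wave, mcf61, small_cfg.z1, small_cfg)
    opts = m.IterationOptions(max_iter=400, tol=1e-12,
                              support_diameter=mcf61.bundle_diameter)
    return m.retrieve_reference(sp0, sp1, small_cfg, opts)


def _mini_config(**overrides) -> ca.ExperimentConfig:
    doc = {
        "optical": {"grid_size": 256, "z2": 1.6},
        "mcf": {"bundle_diameter": 120.0, "seed": 5},
        "retrieval": {"reference_max_iter": 500, "sample_max_iter": 200},
    }
    for key, val in overrides.items():
        doc.setdefault(key, {}).update(val) if isinstance(val, dict) else doc.update({key: val})
    return ca.validate_config(doc)


@pytest.fixture(scope="session")
def mini():
    """Noiseless end-to-end pipeline on a 120 um bundle (~1,100 cores).

    One shared reference retrieval plus three decoded scenes: a 0.8*pi phase
    disc at 1.6 mm, a negative three-bar amplitude target at 1.6 mm with
    bars long enough to stick out beyond the bundle footprint, and an empty
    scene.  Used by the retrieval round-trip, refocusing, autofocus and
    field-of-view tests.
    """
    cfg = _mini_config()
    mcf = ca.build_bundle(cfg)
    sim_empty = ca.simulate_experiment(cfg)
    ref = ca.calibrate_experiment(cfg, sim_empty["ref_z0"], sim_empty["ref_z1"], mcf)

    from mcfqpi.phantoms import disc_mask

    n = cfg.optical.grid_size
    disc = m.phase_patch(disc_mask(n, 20.0, cfg.optical.pitch), 0.8 * np.pi,
                         pitch=cfg.optical.pitch, distance_from_facet=1.6)
    bars = m.usaf_bars([11.0], "negative", cfg.optical.pitch, n,
                       distance_from_facet=1.6, center=(0.0, 0.0))
    # add a long transparent slit that sticks out beyond the 120 um bundle
    # footprint (for the field-of-view extension check)
    slit = np.zeros((n, n))
    slit[n // 2 - 85:n // 2 + 85, n // 2 + 25:n // 2 + 35] = 1.0
    amp = np.maximum(bars.amplitude_mask, slit)
    bars = m.Phantom(amp, np.zeros_like(amp), 1.6, cfg.optical.pitch,
                     bars.ground_truth)
    runs = {}
    for name, phantom in [("disc", disc), ("bars", bars)]:
        scene = m.compose_scene([phantom], "plane", cfg.optical)
        sp = m.simulate_speckle(scene, mcf, cfg.optical.z1, cfg.optical)
        runs[name] = {
            "phantom": phantom,
            "scene_field": scene,
            "reconstruction": ca.reconstruct_experiment(cfg, sp, ref, mcf),
        }
    runs["empty"] = {
        "phantom": None,
        "scene_field": sim_empty["scene_field"],
        "reconstruction": ca.reconstruct_experiment(cfg, sim_empty["sample_z1"],
                                                    ref, mcf),
    }
    runs["bars"]["slit_mask"] = slit > 0.5
    return {"cfg": cfg, "mcf": mcf, "reference": ref, "runs": runs}


@pytest.fixture(scope="session")
def noisy_patch():
    """Phase-disc pipeline with Poisson shot noise (1e4 photons/pixel)."""
    cfg = _mini_config(noise={"photons": 1.0e4, "bit_depth": 16, "seed": 3})
    from mcfqpi.phantoms import disc_mask

    n = cfg.optical.grid_size
    cfg.scene.phantoms = [{"kind": "phase_disc", "radius": 20.0,
                           "phase_value": float(0.8 * np.pi), "distance": 1.6}]
    mcf = ca.build_bundle(cfg)
    sim = ca.simulate_experiment(cfg)
    ref = ca.calibrate_experiment(cfg, sim["ref_z0"], sim["ref_z1"], mcf)
    rec = ca.reconstruct_experiment(cfg, sim["sample_z1"], ref, mcf)
    return {"cfg": cfg, "mcf": mcf, "reference": ref, "sim": sim,
            "reconstruction": rec}
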