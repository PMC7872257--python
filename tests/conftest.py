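"""Shared fixtures: small phantoms, geometries and one reusable recon run."""

from __future__ import annotations

import numpy as np
import pytest

import cbctraj as c
from cbctraj.cli import circular_angle_list, fit_detector


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_spec() -> c.PhantomSpec:
    """32³ phantom at 2 mm spacing (same 64 mm physical extent as default)."""
    return c.PhantomSpec(grid_size=(32, 32, 32), spacing_mm=2.0, voi_half_width_voxels=4)


@pytest.fixture(scope="session")
def small_phantom(small_spec) -> c.Volume:
    return c.make_phantom(small_spec)


@pytest.fixture(scope="session")
def small_geom() -> c.GeometryParams:
    return fit_detector(48, 64.0)


@pytest.fixture(scope="session")
def recon_run(small_geom):
    """Noiseless 60-view, 210° circular scan of a 32³ two-ellipsoid phantom,
    reconstructed with 5 ASD-POCS outer iterations (history + RMSE tracked)."""
    spec = c.PhantomSpec(
        grid_size=(32, 32, 32),
        spacing_mm=2.0,
        inserts=(c.Insert((0.0, 6.0, 2.0), 8.0, 1000.0, "insert"),),
        voi_half_width_voxels=4,
    )
    mu = c.hu_to_attenuation(c.make_phantom(spec))
    poses = [
        c.pose_from_angles(a, small_geom) for a in circular_angle_list(210.0, 60)
    ]
    stack = c.forward_project(mu, poses, small_geom)
    history: list[dict] = []
    rmses: list[float] = []
    gt = mu.voxels

    def track(_it: int, vol: c.Volume) -> None:
        rmses.append(float(np.sqrt(np.mean((vol.voxels - gt) ** 2))))

    recon = c.asd_pocs(
        stack, c.GridSpec.of(mu), small_geom, c.ReconParams(), history=history,
        callback=track,
    )
    return {
        "mu": mu,
        "stack": stack,
        "geom": small_geom,
        "recon": recon,
        "history": history,
        "rmses": rmses,
    }
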