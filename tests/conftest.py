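"""Shared miniature study configurations for fast tests.

The "mini" scan is a deliberately small acquisition (24 views, 64x64
detector, 32^3 reconstruction grid) with the same structure as the full
desk-scale fixtures; unit and property tests run on it in seconds.
"""

import numpy as np
import pytest

from mbscatter.config import (CorrectionConfig, DetectionConfig, GridSpec,
                              RunConfig, simulate_stage)
from mbscatter.evaluate import ROISpec
from mbscatter.recon import ReconParams
from mbscatter.simulate import (BlockerTrajectory, PhantomSpec, ScanGeometry,
                                ScatterSimParams, build_masks)


def make_mini_config(seed: int = 7, noise: bool = True,
                     spr: float = 1.0) -> RunConfig:
    geom = ScanGeometry.uniform(24, sad=1000.0, sdd=1500.0,
                                det_rows=64, det_cols=64, pixel_pitch=3.0)
    phantom = PhantomSpec()
    phantom.add("cylinder", (0, 0, 0), (50, 50, 100), 0.02)
    phantom.add("cylinder", (0, 0, 0), (15, 15, 100), 0.0)
    blocker = BlockerTrajectory(strip_width_det=24.0, strip_gap_det=24.0,
                                amplitude=48.0, period_views=12,
                                penumbra_margin=2)
    rois = [ROISpec("air", "cylinder", (0, 0, 0), radius=8, half_z=16),
            ROISpec("tissue", "cylinder", (30, 0, 0), radius=8, half_z=16)]
    return RunConfig(
        geometry=geom, phantom=phantom, blocker=blocker,
        scatter=ScatterSimParams(spr=spr, blur_sigma=40.0,
                                 apply_poisson=noise),
        detection=DetectionConfig(method="adaptive", n_adjacent=5),
        correction=CorrectionConfig(method="mvsc", n_adjacent=5,
                                    max_span_deg=90.0),
        recon=ReconParams(lam=0.5, n_iterations=10, tv_steps=5),
        grid=GridSpec(shape=(32, 32, 32), voxel_size_mm=4.0),
        sim_grid=GridSpec(shape=(64, 64, 56), voxel_size_mm=2.5),
        rois=rois, seed=seed, i0=1e5, name="mini")


@pytest.fixture(scope="session")
def mini_config_factory():
    return make_mini_config


@pytest.fixture(scope="session")
def mini_config():
    return make_mini_config()


@pytest.fixture(scope="session")
def mini_sim(mini_config):
    """Noisy mini acquisition with its truth masks."""
    stack = simulate_stage(mini_config)
    masks = build_masks(mini_config.blocker, mini_config.geometry)
    return mini_config, stack, masks


@pytest.fixture(scope="session")
def robustness_sim():
    """Wide low-contrast phantom scan (the edge-detection stress case)."""
    from mbscatter.config import make_fixture
    cfg = make_fixture("robustness", seed=1)
    stack = simulate_stage(cfg)
    masks = build_masks(cfg.blocker, cfg.geometry)
    return cfg, stack, masks


@pytest.fixture(scope="session")
def boundary_sim():
    """Short offset phantom whose shadow outruns the blocker board."""
    from mbscatter.config import make_fixture
    cfg = make_fixture("boundary", seed=1)
    stack = simulate_stage(cfg)
    masks = build_masks(cfg.blocker, cfg.geometry)
    return cfg, stack, masks


@pytest.fixture(scope="session")
def mini_sim_noisefree():
    """Noise-free mini acquisition (closure tests)."""
    cfg = make_mini_config(noise=False)
    stack = simulate_stage(cfg)
    masks = build_masks(cfg.blocker, cfg.geometry)
    return cfg, stack, masks
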