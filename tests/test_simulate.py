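"""Phantom rasterization, ray tracing, scatter model and acquisition."""

import numpy as np
import pytest

import mbscatter as mb
from mbscatter._ray import ray_hits
from mbscatter.simulate import _runs


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

class TestMakePhantom:
    def test_water_cylinder_inside_outside(self):
        spec = mb.PhantomSpec().add("cylinder", (0, 0, 0), (20, 20, 30), 0.02)
        vol = mb.make_phantom(spec, (32, 32, 32), 2.0)
        x, y, z = vol.voxel_centers()
        inside = (x**2 + y**2 <= 400) & (np.abs(z) <= 30)
        assert np.all(vol.values[inside] == 0.02)
        assert np.all(vol.values[~inside] == 0.0)

    def test_empty_spec_raises(self):
        with pytest.raises(ValueError, match="no primitives"):
            mb.make_phantom(mb.PhantomSpec(), (8, 8, 8), 1.0)

    def test_overwrite_rule_air_hole(self):
        # per-voxel membership oracle: later primitive wins
        spec = (mb.PhantomSpec()
                .add("cylinder", (0, 0, 0), (20, 20, 30), 0.02)
                .add("ellipsoid", (0, 0, 0), (6, 6, 6), 0.0))
        vol = mb.make_phantom(spec, (32, 32, 32), 2.0)
        x, y, z = vol.voxel_centers()
        hole = (x**2 + y**2 + z**2) / 36.0 <= 1.0
        water = (x**2 + y**2 <= 400) & (np.abs(z) <= 30) & ~hole
        assert np.all(vol.values[hole] == 0.0)
        assert np.all(vol.values[water] == 0.02)

    def test_bad_primitive_rejected(self):
        with pytest.raises(ValueError):
            mb.Primitive("cube", (0, 0, 0), (1, 1, 1), 0.1)
        with pytest.raises(ValueError):
            mb.Primitive("ellipsoid", (0, 0, 0), (1, -1, 1), 0.1)


# ---------------------------------------------------------------------------
# forward projection
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_geom():
    return mb.ScanGeometry.uniform(4, det_rows=32, det_cols=32,
                                   pixel_pitch=4.0)


class TestForwardProject:
    def test_zero_volume(self, small_geom):
        vol = mb.AttenuationVolume.zeros((16, 16, 16), 4.0)
        assert np.all(mb.forward_project(vol, small_geom, 0) == 0.0)

    def test_central_chord_through_cylinder(self):
        # central axial ray through a uniform cylinder: integral = 2 r mu
        spec = mb.PhantomSpec().add("cylinder", (0, 0, 0), (50, 50, 100),
                                    0.02)
        vol = mb.make_phantom(spec, (128, 128, 64), 1.0)
        geom = mb.ScanGeometry.uniform(1, det_rows=32, det_cols=32,
                                       pixel_pitch=1.0)
        p = mb.forward_project(vol, geom, 0)
        # pixels nearest the detector center
        assert p[15:17, 15:17] == pytest.approx(2.0, rel=1e-3)

    def test_magnification(self):
        # a 10 mm feature at the isocenter spans 15 mm on the detector
        # (sdd/sad = 1500/1000)
        spec = mb.PhantomSpec().add("cylinder", (0, 0, 0), (5, 5, 100), 0.05)
        vol = mb.make_phantom(spec, (80, 80, 40), 0.5)
        geom = mb.ScanGeometry.uniform(1, det_rows=8, det_cols=128,
                                       pixel_pitch=0.5)
        p = mb.forward_project(vol, geom, 0)
        width_mm = np.count_nonzero(p[4] > 0) * geom.pixel_pitch
        assert width_mm == pytest.approx(15.0, abs=2 * geom.pixel_pitch)

    def test_linearity(self, small_geom):
        rng = np.random.default_rng(3)
        v1 = mb.AttenuationVolume(rng.uniform(0, 0.05, (8, 8, 8)), 8.0,
                                  np.full(3, -32.0))
        v2 = mb.AttenuationVolume(rng.uniform(0, 0.05, (8, 8, 8)), 8.0,
                                  np.full(3, -32.0))
        combo = mb.AttenuationVolume(2.0 * v1.values + 3.0 * v2.values, 8.0,
                                     np.full(3, -32.0))
        p = mb.forward_project(combo, small_geom, 1)
        expected = (2.0 * mb.forward_project(v1, small_geom, 1)
                    + 3.0 * mb.forward_project(v2, small_geom, 1))
        np.testing.assert_allclose(p, expected, rtol=1e-12, atol=1e-12)

    def test_source_inside_volume_rejected(self):
        vol = mb.AttenuationVolume.zeros((16, 16, 16), 200.0)
        geom = mb.ScanGeometry.uniform(1, det_rows=8, det_cols=8,
                                       pixel_pitch=1.0)
        with pytest.raises(ValueError, match="inside the volume"):
            mb.forward_project(vol, geom, 0)


def _segment_walk_length(origin, vs, n, src, end, n_sub=200000):
    """Brute-force oracle: path length inside the grid bounding box."""
    ts = (np.arange(n_sub) + 0.5) / n_sub
    pts = src[None, :] + ts[:, None] * (end - src)[None, :]
    lo, hi = origin, origin + vs * np.asarray(n)
    inside = np.all((pts >= lo) & (pts < hi), axis=1)
    return inside.mean() * np.linalg.norm(end - src)


class TestRayTracer:
    def test_projector_exact_on_axis_aligned_box(self):
        # a uniform box rasterizes exactly, so the projector must agree
        # with the analytic slab-intersection integral for every ray
        mu = 0.03
        n, vs = 24, 4.0
        half = n * vs / 2
        vol = mb.AttenuationVolume(np.full((n, n, n), mu), vs,
                                   np.full(3, -half))
        geom = mb.ScanGeometry.uniform(3, det_rows=48, det_cols=48,
                                       pixel_pitch=4.0)
        for v in range(geom.n_views):
            src = geom.source_position(v)
            pix = geom.detector_pixel_positions(v)
            d = pix - src
            tmin = np.zeros(d.shape[:2])
            tmax = np.ones(d.shape[:2])
            for ax in range(3):
                with np.errstate(divide="ignore", invalid="ignore"):
                    t0 = (-half - src[ax]) / d[..., ax]
                    t1 = (half - src[ax]) / d[..., ax]
                lo, hi = np.minimum(t0, t1), np.maximum(t0, t1)
                par = np.abs(d[..., ax]) < 1e-12
                lo[par], hi[par] = -np.inf, np.inf
                tmin = np.maximum(tmin, lo)
                tmax = np.minimum(tmax, hi)
            seg = np.maximum(tmax - tmin, 0.0)
            expected = mu * seg * np.linalg.norm(d, axis=-1)
            p = mb.forward_project(vol, geom, v)
            np.testing.assert_allclose(p, expected, rtol=1e-9, atol=1e-9)

    def test_lengths_sum_to_box_path(self):
        # intersection lengths per ray sum to the in-box path length
        rng = np.random.default_rng(11)
        origin = np.array([-8.0, -8.0, -8.0])
        for _ in range(25):
            src = rng.uniform(-60, 60, 3)
            src[0] = 80.0  # keep the source outside the box
            end = rng.uniform(-12, 12, 3)
            end[0] = -80.0
            idx, lens = ray_hits(8, 8, 8, origin, 2.0, src, end)
            oracle = _segment_walk_length(origin, 2.0, (8, 8, 8), src, end)
            assert lens.sum() == pytest.approx(oracle, abs=0.02)
            assert np.all(lens > 0)
            assert len(np.unique(idx)) == len(idx)


# ---------------------------------------------------------------------------
# scatter model
# ---------------------------------------------------------------------------

class TestSimulateScatter:
    def test_zero_spr(self):
        primary = np.full((4, 16, 16), 5e4)
        params = mb.ScatterSimParams(spr=0.0)
        assert np.all(mb.simulate_scatter(primary, 1e5, params, 1.0) == 0)

    def test_negative_spr_rejected(self):
        with pytest.raises(ValueError):
            mb.ScatterSimParams(spr=-0.5)

    def test_uniform_deficit_exact_ratio(self):
        primary = np.full((2, 32, 32), 4e4)
        params = mb.ScatterSimParams(spr=1.5, blur_sigma=10.0)
        s = mb.simulate_scatter(primary, 1e5, params, 1.0)
        ratio = s.mean() / primary.mean()
        assert ratio == pytest.approx(1.5, rel=1e-9)
        assert np.ptp(s) < 1e-6 * s.mean()  # spatially uniform

    def test_step_edge_transition(self):
        # closed form: blurring a step gives an erf profile of width sigma
        from scipy.special import erf
        primary = np.full((64, 64), 1e5)
        primary[32:, :] = 2e4  # object shadow in lower half
        params = mb.ScatterSimParams(spr=1.0, blur_sigma=6.0)
        s = mb.simulate_scatter(primary, 1e5, params, pixel_pitch=1.0)
        prof = s[:, 32]
        assert np.all(np.diff(prof) >= -1e-9)  # monotone across the edge
        rows = np.arange(64)
        expected = 0.5 * (1 + erf((rows - 31.5) / (6.0 * np.sqrt(2))))
        expected = prof.min() + (prof.max() - prof.min()) * expected
        interior = slice(8, 56)  # away from filter boundary handling
        np.testing.assert_allclose(prof[interior], expected[interior],
                                   atol=0.02 * prof.max())


# ---------------------------------------------------------------------------
# blocker masks
# ---------------------------------------------------------------------------

class TestBuildMasks:
    def setup_method(self):
        self.geom = mb.ScanGeometry.uniform(8, det_rows=64, det_cols=16,
                                            pixel_pitch=2.0)

    def test_equal_width_gap_blocks_half(self):
        traj = mb.BlockerTrajectory(strip_width_det=16, strip_gap_det=16,
                                    amplitude=32, period_views=8)
        masks = mb.build_masks(traj, self.geom)
        frac = masks.blocked.mean(axis=(1, 2))
        quant = 1.0 / self.geom.det_rows  # one pixel-quantization band
        assert np.all(np.abs(frac - 0.5) <= quant + 1e-12)

    def test_offset_full_period_identity(self):
        base = mb.BlockerTrajectory(strip_width_det=16, strip_gap_det=16,
                                    offset_per_view=np.zeros(8),
                                    amplitude=32)
        shifted = mb.BlockerTrajectory(strip_width_det=16, strip_gap_det=16,
                                       offset_per_view=np.full(8, 32.0),
                                       amplitude=32)
        m0 = mb.build_masks(base, self.geom)
        m1 = mb.build_masks(shifted, self.geom)
        np.testing.assert_array_equal(m0.blocked, m1.blocked)

    def test_penumbra_erosion_vanishes_thin_band(self):
        # 4-pixel band eroded by 2 pixels per side vanishes
        traj = mb.BlockerTrajectory(strip_width_det=8, strip_gap_det=24,
                                    offset_per_view=np.zeros(8),
                                    amplitude=1, penumbra_margin=2)
        masks = mb.build_masks(traj, self.geom)
        assert masks.blocked.any()
        assert not masks.eroded.any()

    def test_complementarity_and_subset(self):
        traj = mb.BlockerTrajectory(strip_width_det=16, strip_gap_det=16,
                                    amplitude=32, period_views=8)
        masks = mb.build_masks(traj, self.geom)
        assert np.all(masks.blocked | masks.unblocked)
        assert not np.any(masks.eroded & ~masks.blocked)

    def test_period_must_fit_detector(self):
        traj = mb.BlockerTrajectory(strip_width_det=100, strip_gap_det=100)
        with pytest.raises(ValueError, match="period"):
            mb.build_masks(traj, self.geom)

    def test_triangular_offsets_bounded(self):
        traj = mb.BlockerTrajectory(amplitude=20.0, period_views=10)
        offs = traj.offsets(40)
        assert np.max(np.abs(offs)) <= 20.0 + 1e-12
        assert offs[0] == pytest.approx(0.0)


class TestAcquire:
    def test_blocked_pixels_receive_scatter_only(self, mini_sim_noisefree):
        cfg, stack, masks = mini_sim_noisefree
        gt = stack.ground_truth
        blocked = masks.blocked
        np.testing.assert_array_equal(stack.intensities[blocked],
                                      gt["scatter"][blocked])

    def test_unblocked_is_primary_plus_scatter(self, mini_sim_noisefree):
        cfg, stack, masks = mini_sim_noisefree
        gt = stack.ground_truth
        un = ~masks.blocked
        np.testing.assert_allclose(
            stack.intensities[un],
            gt["primary"][un] + gt["scatter"][un], rtol=1e-12)

    def test_vacuum_no_scatter_gives_i0(self):
        vol = mb.AttenuationVolume.zeros((16, 16, 16), 8.0)
        geom = mb.ScanGeometry.uniform(2, det_rows=32, det_cols=16,
                                       pixel_pitch=2.0)
        params = mb.ScatterSimParams(spr=0.0, apply_poisson=False)
        stack = mb.acquire(vol, geom, None, params, i0=1e5)
        np.testing.assert_allclose(stack.intensities, 1e5, rtol=1e-12)

    def test_same_seed_identical(self):
        spec = mb.PhantomSpec().add("cylinder", (0, 0, 0), (40, 40, 80),
                                    0.02)
        vol = mb.make_phantom(spec, (32, 32, 32), 4.0)
        geom = mb.ScanGeometry.uniform(3, det_rows=32, det_cols=32,
                                       pixel_pitch=3.0)
        traj = mb.BlockerTrajectory(strip_width_det=18, strip_gap_det=18,
                                    amplitude=36, period_views=3)
        params = mb.ScatterSimParams(spr=1.0, noise_seed=42)
        a = mb.acquire(vol, geom, traj, params)
        b = mb.acquire(vol, geom, traj, params)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_log_transform_recovers_line_integrals(self, mini_config_factory):
        # spr=0, noise off: -ln(I/i0) on unblocked pixels equals the
        # forward projection to machine precision
        from mbscatter.config import simulate_stage
        mini = mini_config_factory(noise=False, spr=0.0)
        stack = simulate_stage(mini)
        masks = mb.build_masks(mini.blocker, mini.geometry)
        li = stack.ground_truth["line_integrals"]
        un = ~masks.blocked
        p = -np.log(stack.intensities[un] / stack.i0)
        np.testing.assert_allclose(p, li[un], rtol=1e-10, atol=1e-12)


def test_strip_width_projection_roundtrip():
    w_det = mb.projected_strip_width(3.2, sdd=1500.0, source_blocker_mm=250.0)
    assert w_det == pytest.approx(19.2)
    assert mb.physical_strip_width(w_det, 1500.0, 250.0) == pytest.approx(3.2)
    with pytest.raises(ValueError):
        mb.projected_strip_width(3.2, 1500.0, 1600.0)


def test_runs_helper():
    assert _runs(np.array([0, 1, 1, 0, 1], bool)) == [(1, 3), (4, 5)]
    assert _runs(np.zeros(4, bool)) == []
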