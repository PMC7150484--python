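"""MACWE tracker: operator sets, evolution steps, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from hifutrack.metrics import dsc
from hifutrack.preprocess import Frame
from hifutrack.tracker import (
    ACWEParams,
    EmptyInitializationError,
    OperatorSet,
    RigidTransform2D,
    TrackerError,
    TrackingLostError,
    attachment_step,
    balloon_step,
    evolve_frame,
    evolve_iteration,
    init_from_preop,
    k3,
    k15,
    region_means,
    si_is_smooth,
)
from reference import (
    K3_SEGMENTS,
    brute_balloon,
    brute_is,
    brute_region_means,
    brute_si,
    segments_from_angles,
)

binary_16 = arrays(np.uint8, (16, 16), elements=st.integers(0, 1))


class TestOperatorSet:
    def test_k3_offsets_are_the_classic_3px_lines(self):
        offs = [set(map(tuple, o)) for o in k3().offsets()]
        assert [set(s) for s in K3_SEGMENTS] == offs

    def test_k15_default_is_single_horizontal_segment(self):
        (seg,) = k15().offsets()
        assert set(map(tuple, seg)) == {(0, d) for d in range(-7, 8)}

    def test_even_or_short_lengths_rejected(self):
        with pytest.raises(TrackerError):
            OperatorSet(((4, 0.0),))
        with pytest.raises(TrackerError):
            OperatorSet(((1, 0.0),))
        with pytest.raises(TrackerError):
            OperatorSet(())


class TestRegionMeans:
    def test_constant_image(self):
        img = Frame(np.full((5, 5), 0.7))
        u = np.zeros((5, 5), dtype=np.uint8)
        u[2, 2] = 1
        stats = region_means(img, u)
        assert stats.c1 == pytest.approx(0.7)
        assert stats.c2 == pytest.approx(0.7)

    def test_tiny_exhaustive_case(self):
        img = Frame(np.array([[1.0, 0.0], [0.0, 0.0]]))
        u = np.array([[1, 0], [0, 0]], dtype=np.uint8)
        stats = region_means(img, u)
        assert stats.c1 == pytest.approx(1.0)
        assert stats.c2 == pytest.approx(0.0)

    def test_matches_brute_force(self, rng):
        img = rng.random((8, 8))
        u = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        stats = region_means(Frame(img), u)
        c1, c2 = brute_region_means(img, u)
        assert stats.c1 == pytest.approx(c1)
        assert stats.c2 == pytest.approx(c2)

    def test_empty_region_flags_degenerate(self):
        img = Frame(np.random.default_rng(0).random((4, 4)))
        stats = region_means(img, np.zeros((4, 4), dtype=np.uint8))
        assert stats.degenerate
        assert np.isfinite(stats.c1)


class TestBalloonStep:
    def test_nu_zero_is_identity(self, rng):
        u = (rng.random((10, 10)) > 0.5).astype(np.uint8)
        assert np.array_equal(balloon_step(u, 0), u)

    def test_single_pixel_dilates_to_cross(self):
        u = np.zeros((5, 5), dtype=np.uint8)
        u[2, 2] = 1
        out = balloon_step(u, 1)
        assert out.sum() == 5
        assert out[2, 2] and out[1, 2] and out[3, 2] and out[2, 1] and out[2, 3]

    @pytest.mark.parametrize("nu", [-1, 1])
    def test_matches_brute_force_cross_extremum(self, rng, nu):
        u = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        assert np.array_equal(balloon_step(u, nu), brute_balloon(u, nu))


class TestAttachmentStep:
    def test_uniform_zero_mask_unchanged(self):
        img = Frame(np.random.default_rng(0).random((6, 6)))
        u = np.zeros((6, 6), dtype=np.uint8)
        stats = region_means(img, u)
        assert np.array_equal(attachment_step(u, img, ACWEParams(), stats), u)

    def test_boundary_pixels_join_nearer_region(self):
        # two-level 6x6 image, vertical contour strictly between the levels
        img = np.full((6, 6), 0.9)
        img[:, :3] = 0.1
        u = np.zeros((6, 6), dtype=np.uint8)
        u[:, :2] = 1  # contour one column short of the true edge
        stats = region_means(Frame(img), u)
        out = attachment_step(u, Frame(img), ACWEParams(), stats)
        # enumerate the sign test: column 2 (dark, nearer c1) flips to 1,
        # column 3 (bright, nearer c2) stays 0
        assert np.all(out[:, 2] == 1)
        assert np.all(out[:, 3] == 0)

    def test_exact_tie_leaves_pixel(self):
        img = np.full((4, 4), 0.5)
        u = np.zeros((4, 4), dtype=np.uint8)
        u[:2] = 1
        stats = region_means(Frame(img), u)  # c1 == c2 == 0.5 -> zero force
        assert np.array_equal(attachment_step(u, Frame(img), ACWEParams(), stats), u)


class TestSiIsSmooth:
    def test_all_ones_fixed_point(self):
        u = np.ones((10, 10), dtype=np.uint8)
        for mu in (1, 3):
            assert np.array_equal(si_is_smooth(u, k3(), mu), u)

    def test_mu_zero_identity(self, rng):
        u = (rng.random((12, 12)) > 0.5).astype(np.uint8)
        assert np.array_equal(si_is_smooth(u, k3(), 0), u)

    def test_matches_brute_force_k3(self, rng):
        for _ in range(10):
            u = (rng.random((16, 16)) > 0.5).astype(np.uint8)
            expected = brute_si(brute_is(u, K3_SEGMENTS), K3_SEGMENTS)
            assert np.array_equal(si_is_smooth(u, k3(), 1), expected)

    def test_matches_brute_force_k15_multi_orientation(self, rng):
        segs = segments_from_angles(15, (0.0, 45.0, 90.0, 135.0))
        ops = OperatorSet(tuple((15, a) for a in (0.0, 45.0, 90.0, 135.0)))
        u = (rng.random((24, 24)) > 0.5).astype(np.uint8)
        expected = brute_si(brute_is(u, segs), segs)
        assert np.array_equal(si_is_smooth(u, ops, 1), expected)

    def test_filament_removed_disk_kept(self, disk_mask):
        # 1-px-thick, 8-px-long filament attached to a disk larger than the
        # operator scale, transverse to the segment so its run length along
        # the segment stays below 15
        disk = disk_mask((70, 50), (25, 25), 16)
        u = disk.copy()
        u[42:50, 25] = 1
        out = si_is_smooth(u, k15(), 2)  # second repetition is the opening phase
        assert np.all(out[43:50, 25] == 0)
        assert dsc(out, disk) > 0.95

    @settings(max_examples=25, deadline=None)
    @given(u=binary_16, v=binary_16)
    def test_monotone(self, u, v):
        lo = np.minimum(u, v)
        hi = np.maximum(u, v)
        for opset in (k3(), k15()):
            assert np.all(si_is_smooth(lo, opset, 1) <= si_is_smooth(hi, opset, 1))

    @settings(max_examples=25, deadline=None)
    @given(u=binary_16)
    def test_si_is_duality(self, u):
        from hifutrack.tracker import _is, _si

        for opset in (k3(), k15()):
            offs = opset.offsets()
            assert np.array_equal(_si(1 - u, offs), 1 - _is(u, offs))

    def test_maps_binary_to_binary(self, rng):
        u = (rng.random((16, 16)) > 0.3).astype(np.uint8)
        out = si_is_smooth(u, k15(), 2)
        assert set(np.unique(out)) <= {0, 1}


class TestEvolveFrame:
    def test_noiseless_disk_converges(self, disk_mask):
        truth = disk_mask((128, 128), (64, 64), 30)
        img = np.where(truth, 0.2, 0.8)
        from scipy import ndimage

        init = ndimage.binary_erosion(truth, iterations=3).astype(np.uint8)
        u, _ = evolve_frame(init, Frame(img), ACWEParams(operator_set=k3(), iters_per_frame=20))
        assert dsc(u, truth) >= 0.98

    def test_exact_partition_is_near_fixed_point(self, disk_mask):
        truth = disk_mask((64, 64), (32, 32), 20)
        img = np.where(truth, 0.2, 0.8)
        u, _ = evolve_frame(truth, Frame(img), ACWEParams(operator_set=k3(), iters_per_frame=5))
        assert dsc(u, truth) >= 0.995

    def test_degenerate_embedding_raises_with_last_valid(self):
        img = Frame(np.full((32, 32), 0.9))
        u = np.zeros((32, 32), dtype=np.uint8)
        u[15:17, 15:17] = 1  # 2x2 island in a uniform image collapses
        params = ACWEParams(operator_set=k15(), nu=-1, iters_per_frame=50)
        with pytest.raises(TrackingLostError) as exc:
            evolve_frame(u, img, params)
        assert exc.value.last_valid.any()

    def test_empty_init_rejected(self):
        with pytest.raises(TrackerError):
            evolve_frame(np.zeros((8, 8)), Frame(np.zeros((8, 8))), ACWEParams())

    def test_matches_skimage_chan_vese_on_clean_shape(self, disk_mask):
        """Independent cross-check: on a noiseless two-level image both our
        tracker (K3, no balloon) and scikit-image's morphological Chan-Vese
        settle on the same region."""
        from skimage.segmentation import morphological_chan_vese

        truth = disk_mask((96, 96), (48, 48), 25)
        img = np.where(truth, 0.25, 0.75)
        init = disk_mask((96, 96), (44, 48), 25)
        ours, _ = evolve_frame(
            init, Frame(img), ACWEParams(operator_set=k3(), nu=0, iters_per_frame=40)
        )
        theirs = morphological_chan_vese(img, num_iter=40, init_level_set=init.astype(np.int8))
        assert dsc(ours, theirs) >= 0.98


class TestOverflowGuard:
    def test_inactive_when_contour_away_from_border(self, disk_mask):
        from hifutrack.tracker import overflow_guard

        u_prev = disk_mask((64, 64), (32, 32), 10)
        u_cand = disk_mask((64, 64), (32, 32), 12)
        img = Frame(np.where(u_prev, 0.1, 0.9))
        stats = region_means(img, u_prev)
        out, active = overflow_guard(u_cand, u_prev, img, stats, tau=0.0)
        assert not active
        assert np.array_equal(out, u_cand)

    def test_inactive_when_force_fraction_low(self, disk_mask):
        from hifutrack.tracker import overflow_guard

        u_prev = disk_mask((64, 64), (5, 32), 10)  # touches the top border
        u_cand = disk_mask((64, 64), (5, 32), 11)
        img = Frame(np.where(u_prev, 0.1, 0.9))
        stats = region_means(img, u_prev)  # contour forces balanced -> f ~ 0.5
        out, active = overflow_guard(u_cand, u_prev, img, stats, tau=0.99)
        assert not active
        assert np.array_equal(out, u_cand)

    def test_active_guard_blocks_growth(self, disk_mask):
        from hifutrack.tracker import overflow_guard

        u_prev = disk_mask((64, 64), (60, 32), 10)  # cut by bottom border
        u_cand = disk_mask((64, 64), (60, 32), 14)
        img = Frame(np.full((64, 64), 0.2))  # everything matches the inside
        stats = type(region_means(img, u_prev))(c1=0.2, c2=0.9)
        out, active = overflow_guard(u_cand, u_prev, img, stats, tau=0.5)
        assert active
        assert np.array_equal(out, u_cand & u_prev)


class TestInitFromPreop:
    def test_identity_transform_round_trips(self, disk_mask):
        m = disk_mask((64, 64), (30, 40), 9)
        out = init_from_preop(m, RigidTransform2D(), (64, 64))
        assert np.array_equal(out, m)

    def test_pure_translation_shifts_centroid(self, disk_mask):
        m = disk_mask((64, 64), (30, 30), 8)
        tr = RigidTransform2D(translation_mm=(5.0, 0.0))
        out = init_from_preop(m, tr, (64, 64), target_spacing_mm=1.0)
        r, c = np.nonzero(out)
        r0, c0 = np.nonzero(m)
        assert abs(r.mean() - r0.mean() - 5.0) <= 0.5
        assert abs(c.mean() - c0.mean()) <= 0.5

    def test_quarter_rotation_moves_centroid_analytically(self, disk_mask):
        m = disk_mask((65, 65), (20, 32), 6)  # off-centre blob
        tr = RigidTransform2D(rotation=np.pi / 2)
        out = init_from_preop(m, tr, (65, 65))
        r, c = np.nonzero(out)
        # centre (32,32); source centroid offset (-12, 0) rotates to (0, -12)
        assert abs(r.mean() - 32.0) <= 1.0
        assert abs(c.mean() - 20.0) <= 1.0

    def test_transform_off_grid_raises(self, disk_mask):
        m = disk_mask((64, 64), (32, 32), 5)
        tr = RigidTransform2D(translation_mm=(500.0, 0.0))
        with pytest.raises(EmptyInitializationError):
            init_from_preop(m, tr, (64, 64))
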