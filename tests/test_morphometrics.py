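"""Fiber morphometrics: mask generation, skeleton topology, pattern metrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from shgfiber import morphometrics as mm
from shgfiber import synthetic as syn

from conftest import isolated_scene_params, make_fiber_mask


class TestAverageFrames:
    def test_constant_frames(self):
        stack = syn.ChannelStack(
            np.full((20, 8, 8), 7, np.uint8), np.zeros((20, 8, 8), np.uint8), 0.09
        )
        assert np.all(mm.average_frames(stack).pixels == 7.0)

    def test_alternating_frames(self):
        frames = np.zeros((20, 4, 4), np.uint8)
        frames[1::2] = 255
        stack = syn.ChannelStack(frames, frames.copy(), 0.09)
        assert np.all(mm.average_frames(stack).pixels == 127.5)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(0)
        frames = rng.integers(0, 256, (7, 16, 16)).astype(np.uint8)
        stack = syn.ChannelStack(frames, frames.copy(), 0.09)
        avg = mm.average_frames(stack).pixels
        naive = np.zeros((16, 16))
        for f in frames:
            naive += f
        naive /= len(frames)
        np.testing.assert_allclose(avg, naive)

    def test_empty_stack_rejected(self):
        stack = syn.ChannelStack(
            np.zeros((0, 4, 4), np.uint8), np.zeros((0, 4, 4), np.uint8), 0.09
        )
        with pytest.raises(ValueError):
            mm.average_frames(stack)


class TestContrastSaturate:
    def test_minmax_stretch(self):
        img = mm.AveragedImage(np.linspace(10, 200, 64).reshape(8, 8))
        out = mm.contrast_saturate(img, 0.0).pixels
        assert out.min() == pytest.approx(0.0)
        assert out.max() == pytest.approx(255.0)

    def test_constant_unchanged(self):
        img = mm.AveragedImage(np.full((8, 8), 42.0))
        np.testing.assert_array_equal(mm.contrast_saturate(img, 0.3).pixels, 42.0)

    def test_clip_limits_match_quantiles(self):
        rng = np.random.default_rng(1)
        px = rng.uniform(0, 255, (64, 64))
        img = mm.AveragedImage(px)
        out = mm.contrast_saturate(img, 0.35).pixels
        lo, hi = np.sort(px.ravel())[
            [int(0.175 * px.size), int(0.825 * px.size)]
        ]
        # pixels at/below the lower quantile map to 0, at/above the upper to 255
        assert np.all(out[px <= lo - 1e-9] == 0.0)
        assert np.all(out[px >= hi + 1e-9] == 255.0)
        mid = (px > lo + 1) & (px < hi - 1)
        np.testing.assert_allclose(
            out[mid], (px[mid] - lo) / (hi - lo) * 255.0, atol=0.5
        )


class TestRidgeDetection:
    def test_blank_image_empty_mask(self):
        img = mm.AveragedImage(np.zeros((128, 128)))
        fm = mm.detect_ridges(img, mm.MaskParams())
        assert not fm.mask.any()
        assert not fm.skeleton.any()

    def test_single_fiber_topology(self, straight_fiber_image):
        sat = mm.contrast_saturate(straight_fiber_image, 0.0035)
        fm = mm.detect_ridges(sat, mm.MaskParams())
        from scipy import ndimage

        _, n = ndimage.label(fm.skeleton, structure=np.ones((3, 3)))
        assert n == 1
        assert mm.skeleton_topology(fm) == (2, 0)

    def test_skeleton_subset_of_mask(self, straight_fiber_image):
        sat = mm.contrast_saturate(straight_fiber_image, 0.0035)
        fm = mm.detect_ridges(sat, mm.MaskParams())
        assert np.all(fm.mask[fm.skeleton])

    def test_recovers_ground_truth_length(self, measured_isolated_scenes):
        for _params, truth, _img, record in measured_isolated_scenes:
            err = abs(record.total_length - truth.true_total_length)
            assert err <= 0.10 * truth.true_total_length


class TestSkeletonTopology:
    def test_straight_line(self):
        s = np.zeros((16, 16), bool)
        s[8, 2:14] = True
        assert mm.skeleton_topology(make_fiber_mask(s)) == (2, 0)

    def test_plus_sign(self):
        s = np.zeros((17, 17), bool)
        s[8, 2:15] = True
        s[2:15, 8] = True
        assert mm.skeleton_topology(make_fiber_mask(s)) == (4, 1)

    def test_matches_bruteforce_neighbor_enumeration(self):
        params = isolated_scene_params(5, n_fibers=6)
        fibers, _ = syn.sample_fiber_network(params)
        ff, _ = syn.rasterize_scene(fibers, params)
        img = mm.contrast_saturate(mm.AveragedImage(np.clip(ff, 0, 255)), 0.0035)
        fm = mm.detect_ridges(img, mm.MaskParams())
        skel = fm.skeleton
        # brute force: per-pixel neighbor count by explicit loops
        ep = 0
        junction = np.zeros(skel.shape, bool)
        H, W = skel.shape
        for r in range(H):
            for c in range(W):
                if not skel[r, c]:
                    continue
                n = 0
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if (dr or dc) and 0 <= r + dr < H and 0 <= c + dc < W:
                            n += skel[r + dr, c + dc]
                if n == 1:
                    ep += 1
                elif n >= 3:
                    junction[r, c] = True
        from scipy import ndimage

        _, nbp = ndimage.label(junction, structure=np.ones((3, 3)))
        assert mm.skeleton_topology(fm) == (ep, nbp)


class TestLengthAndArea:
    def test_horizontal_line_length(self):
        s = np.zeros((32, 128), bool)
        s[10, 5:106] = True
        assert mm.total_length(make_fiber_mask(s)) == pytest.approx(100.0)

    def test_diagonal_line_length(self):
        s = np.zeros((128, 128), bool)
        idx = np.arange(101)
        s[idx, idx] = True
        assert mm.total_length(make_fiber_mask(s)) == pytest.approx(100 * np.sqrt(2))

    def test_mask_area_trivials(self):
        assert mm.mask_area(make_fiber_mask(np.zeros((8, 8), bool))) == 0
        block = np.zeros((32, 32), bool)
        block[4:14, 6:16] = True
        assert mm.mask_area(make_fiber_mask(block)) == 100

    @given(arrays(bool, (24, 24), elements=st.booleans()))
    def test_mask_area_counting_oracle(self, mask):
        assert mm.mask_area(make_fiber_mask(mask)) == int(
            sum(bool(v) for v in mask.ravel())
        )


class TestLacunarity:
    def test_full_mask_is_one(self):
        assert mm.lacunarity(make_fiber_mask(np.ones((64, 64), bool))) == pytest.approx(1.0)

    def test_empty_mask_zero_by_convention(self):
        assert mm.lacunarity(make_fiber_mask(np.zeros((64, 64), bool))) == 0.0

    def test_checkerboard_exact(self):
        cb = (np.indices((8, 8)).sum(axis=0) % 2).astype(bool)
        assert mm.lacunarity(make_fiber_mask(cb), [1]) == pytest.approx(2.0)

    def test_matches_exhaustive_window_enumeration(self):
        rng = np.random.default_rng(2)
        mask = rng.uniform(size=(20, 20)) < 0.3
        r = 3
        masses = []
        for i in range(20 - r + 1):
            for j in range(20 - r + 1):
                masses.append(mask[i : i + r, j : j + r].sum())
        masses = np.asarray(masses, float)
        expected = np.mean(masses**2) / np.mean(masses) ** 2
        assert mm.lacunarity(make_fiber_mask(mask), [r]) == pytest.approx(expected)

    def test_oversized_box_rejected(self):
        with pytest.raises(ValueError):
            mm.lacunarity(make_fiber_mask(np.ones((8, 8), bool)), [16])

    def test_nonempty_mask_at_least_one(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            mask = rng.uniform(size=(40, 40)) < rng.uniform(0.05, 0.9)
            if mask.any():
                assert mm.lacunarity(make_fiber_mask(mask)) >= 1.0 - 1e-12


class TestFractalDimension:
    def test_filled_square(self):
        bcfd = mm.box_counting_fractal_dimension(make_fiber_mask(np.ones((512, 512), bool)))
        assert bcfd == pytest.approx(2.0, abs=0.05)

    def test_straight_line(self):
        s = np.zeros((512, 512), bool)
        s[256, :] = True
        assert mm.box_counting_fractal_dimension(make_fiber_mask(s)) == pytest.approx(1.0, abs=0.05)

    def test_sierpinski_triangle(self):
        i, j = np.meshgrid(np.arange(128), np.arange(128), indexing="ij")
        sier = (i & j) == 0  # depth-7 Sierpinski raster on a 2^7 grid
        bcfd = mm.box_counting_fractal_dimension(make_fiber_mask(sier))
        assert bcfd == pytest.approx(np.log(3) / np.log(2), abs=0.05)

    def test_empty_mask_flagged_missing(self):
        assert np.isnan(
            mm.box_counting_fractal_dimension(make_fiber_mask(np.zeros((64, 64), bool)))
        )


class TestCurvature:
    def test_straight_fiber_zero(self):
        s = np.zeros((256, 256), bool)
        s[100, 20:220] = True
        assert mm.curvature(make_fiber_mask(s), 40) == pytest.approx(0.0, abs=1e-9)

    def test_circular_arc_chord_angle(self):
        # R = 200 px, window 40 -> successive chords turn by ~(180/pi)(40/200)
        th = np.linspace(0, np.pi / 1.5, 4000)
        rr = np.round(256 + 200 * np.sin(th)).astype(int)
        cc = np.round(40 + 200 * (1 - np.cos(th))).astype(int)
        arc = np.zeros((512, 512), bool)
        arc[rr, cc] = True
        arc = mm.thin(arc)
        got = mm.curvature(make_fiber_mask(arc), 40)
        assert got == pytest.approx(np.rad2deg(40 / 200), abs=0.5)

    def test_matches_direct_path_recomputation(self):
        rng = np.random.default_rng(4)
        # random-walk digital path
        pts = [np.array([128.0, 20.0])]
        theta = 0.1
        for _ in range(250):
            theta += rng.normal(0, np.deg2rad(4))
            pts.append(pts[-1] + [np.sin(theta), np.cos(theta)])
        pix = np.unique(np.round(pts).astype(int), axis=0)
        skel = np.zeros((256, 300), bool)
        skel[pix[:, 0], pix[:, 1]] = True
        skel = mm.thin(skel)
        paths = mm.skeleton_paths(skel)
        window = 25.0
        # direct recomputation: same definition, written out longhand
        from scipy.ndimage import uniform_filter1d

        num = den = 0.0
        for p in paths:
            f = p.astype(float)
            plen = float(np.linalg.norm(np.diff(f, axis=0), axis=1).sum())
            if plen < 2 * window or len(f) < 3:
                continue
            if len(f) >= 5:
                f = uniform_filter1d(f, size=5, axis=0, mode="nearest")
            s = np.concatenate([[0], np.cumsum(np.linalg.norm(np.diff(f, axis=0), axis=1))])
            si = np.arange(0.0, s[-1] + 1e-9, window)
            xs, ys = np.interp(si, s, f[:, 1]), np.interp(si, s, f[:, 0])
            ang = np.arctan2(np.diff(ys), np.diff(xs))
            d = np.diff(ang)
            d = (d + np.pi) % (2 * np.pi) - np.pi
            num += np.mean(np.abs(np.rad2deg(d))) * plen
            den += plen
        expected = num / den
        assert mm.curvature(make_fiber_mask(skel, skel), window) == pytest.approx(expected)

    def test_window_below_one_rejected(self):
        with pytest.raises(ValueError):
            mm.curvature(make_fiber_mask(np.zeros((8, 8), bool)), 0.5)


class TestHdmAndAlignment:
    @pytest.mark.parametrize(
        "value,threshold,expected",
        [(255, 200, 1.0), (0, 200, 0.0)],
    )
    def test_hdm_constant(self, value, threshold, expected):
        img = mm.AveragedImage(np.full((16, 16), float(value)))
        assert mm.high_density_matrix(img, threshold) == expected

    def test_hdm_half(self):
        px = np.full((16, 16), 10.0)
        px[:8] = 210.0
        assert mm.high_density_matrix(mm.AveragedImage(px), 200) == 0.5

    def test_parallel_lines_coherent(self):
        px = np.zeros((256, 256))
        px[::16, :] = 255.0
        assert mm.alignment(mm.AveragedImage(px)) >= 0.95

    def test_isotropic_noise_incoherent(self):
        rng = np.random.default_rng(5)
        px = rng.uniform(0, 255, (512, 512))
        assert mm.alignment(mm.AveragedImage(px)) <= 0.1

    def test_orthogonal_families_cancel(self):
        px = np.zeros((256, 256))
        px[::16, :] = 255.0
        px[:, ::16] = 255.0
        img = mm.AveragedImage(px)
        got = mm.alignment(img)
        # eigen oracle: explicit decomposition of the summed structure tensor
        from skimage.feature import structure_tensor

        arr, arc, acc = structure_tensor(px, sigma=2.0, mode="nearest", order="rc")
        T = np.array([[arr.sum(), arc.sum()], [arc.sum(), acc.sum()]])
        l2, l1 = np.linalg.eigvalsh(T)
        expected = (l1 - l2) / (l1 + l2)
        assert got == pytest.approx(expected, abs=1e-9)
        assert got <= 0.05

    def test_gradient_free_image_zero(self):
        assert mm.alignment(mm.AveragedImage(np.full((32, 32), 9.0))) == 0.0


class TestDerivedMetrics:
    def test_hgu_cohort_magnitude(self):
        # printed cohort means: length 4724.3 px over 120.9 endpoints
        assert mm.hyphal_growth_unit(4724.3, 120.9) == pytest.approx(39.08, abs=0.01)

    def test_hgu_trivial_and_identity(self):
        assert mm.hyphal_growth_unit(100.0, 2) == 50.0
        assert np.isnan(mm.hyphal_growth_unit(100.0, 0))
        length, endpoints = 731.4, 17
        assert mm.hyphal_growth_unit(length, endpoints) * endpoints == pytest.approx(length)

    def test_avg_fiber_length_from_cohort_means(self):
        avg_len, _ = mm.derived_metrics(4724.3, 120.9, 9.2, 0.1, 45.96**2)
        assert avg_len == pytest.approx(4724.3 / 65.05, abs=1e-9)
        assert avg_len == pytest.approx(72.63, abs=0.01)

    def test_fiber_thickness_um_convention(self):
        # hdm 0.1, FOV 45.96^2 um^2, average length 73.8 px -> ~31.9 um
        px_um = 45.96 / 512
        length = 73.8 * (0.5 * (2.0 + 0.0))  # one fiber with 2 endpoints
        _, thick = mm.derived_metrics(length, 2.0, 0.0, 0.1, 45.96**2, px_um)
        assert thick == pytest.approx(31.9, abs=0.1)

    def test_px_units_mode(self):
        px_um = 45.96 / 512
        _, thick_px = mm.derived_metrics(100.0, 2.0, 0.0, 0.5, 45.96**2, px_um, um_units=False)
        # avg fiber length = 100 / (0.5 * 2) = 100 px; FOV = 512^2 px^2
        assert thick_px == pytest.approx(0.5 * 512**2 / 100.0)

    def test_zero_denominator_flagged(self):
        avg_len, thick = mm.derived_metrics(10.0, 0.0, 0.0, 0.1, 100.0)
        assert np.isnan(avg_len) and np.isnan(thick)

    def test_single_fiber_average_length(self):
        avg_len, _ = mm.derived_metrics(321.0, 2.0, 0.0, 0.1, 100.0)
        assert avg_len == pytest.approx(321.0)


class TestMeasureImage:
    def test_blank_image(self):
        rec = mm.measure_image(mm.AveragedImage(np.zeros((128, 128))))
        assert rec.area == 0
        assert rec.total_length == 0
        assert np.isnan(rec.hgu)
        assert np.isnan(rec.avg_fiber_length)

    def test_single_fiber_composition(self, straight_fiber_image):
        rec = mm.measure_image(straight_fiber_image)
        assert rec.endpoints == 2
        assert rec.branchpoints == 0
        assert rec.curvature == pytest.approx(0.0, abs=1.0)
        assert rec.alignment >= 0.95

    def test_deterministic(self, straight_fiber_image):
        r1 = mm.measure_image(straight_fiber_image)
        r2 = mm.measure_image(straight_fiber_image)
        assert r1.as_dict() == r2.as_dict()

    def test_identities_hold(self, measured_isolated_scenes):
        for _params, _truth, _img, rec in measured_isolated_scenes:
            assert rec.hgu * rec.endpoints == pytest.approx(rec.total_length)
            assert rec.avg_fiber_length * (rec.endpoints + rec.branchpoints) / 2 == pytest.approx(
                rec.total_length
            )
            assert 0.0 <= rec.bcfd <= 2.0
            assert rec.lacunarity >= 1.0
            assert 0.0 <= rec.alignment <= 1.0
            # sanity bound for constant-width rendered fibers (20% slack)
            assert rec.total_length <= 1.2 * (np.pi / 2) * rec.area / 15.0


def test_density_scaling_monotone_in_metrics():
    """More fibers: area and length up, lacunarity down (3 levels x 6 seeds)."""
    means = {"area": [], "total_length": [], "lacunarity": []}
    for n in (5, 15, 35):
        recs = []
        for seed in range(6):
            params = syn.SceneParams(
                seed=seed, image_shape=(192, 192), n_fibers=n, length_mean=60,
                length_sd=10, length_min=20, n_frames=2,
            )
            fibers, _ = syn.sample_fiber_network(params)
            ff, bf = syn.rasterize_scene(fibers, params)
            stack = syn.simulate_stack(ff, bf, params)
            recs.append(mm.measure_image(mm.average_frames(stack)))
        for k in means:
            means[k].append(np.mean([getattr(r, k) for r in recs]))
    assert means["area"][0] < means["area"][1] < means["area"][2]
    assert means["total_length"][0] < means["total_length"][1] < means["total_length"][2]
    assert means["lacunarity"][0] > means["lacunarity"][1] > means["lacunarity"][2]
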