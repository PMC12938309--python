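"""Image-pipeline tests: binarization, contour, skeleton, orientation,
resampling, and the full extraction round trip."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from skimage.draw import disk as draw_disk

import cturnkit as ck
from cturnkit.midline import (
    binarize,
    compute_threshold,
    extract_contour,
    orient_head_tail,
    resample_smooth,
    skeletonize_midline,
)
from cturnkit.synthetic import true_midline_world


def _two_level_frame(fg=40, bg=200, shape=(128, 128)):
    img = np.full(shape, bg, dtype=np.uint8)
    rr, cc = draw_disk((64, 64), 20)
    img[rr, cc] = fg
    return img


class TestBinarize:
    def test_mean_gap_threshold_midway(self):
        img = _two_level_frame()
        assert compute_threshold(img, "mean-gap") == pytest.approx(120.0, abs=1.0)
        mask = binarize(img, "mean-gap")
        assert mask.sum() == pytest.approx((img == 40).sum(), rel=0.01)

    def test_uniform_frame_raises(self):
        with pytest.raises(ValueError, match="no fish detected"):
            binarize(np.full((64, 64), 180, dtype=np.uint8))

    def test_noise_robust_area(self):
        img = _two_level_frame()
        rng = np.random.default_rng(3)
        noisy = np.clip(img.astype(float)
                        + rng.normal(0, 10, img.shape), 0, 255).astype(np.uint8)
        clean_area = binarize(img).sum()
        noisy_area = binarize(noisy).sum()
        assert abs(noisy_area / clean_area - 1) < 0.03


class TestContour:
    def test_disk_contour_length(self):
        img = _two_level_frame()
        mask = binarize(img)
        contour = extract_contour(mask)
        length = np.linalg.norm(
            np.diff(np.vstack([contour, contour[:1]]), axis=0), axis=1).sum()
        assert length == pytest.approx(2 * np.pi * 20, rel=0.02)

    def test_hole_filled_equals_hole_free(self):
        img = _two_level_frame()
        holey = img.copy()
        holey[64, 64] = 200  # 1-px hole, filled by binarize
        a = extract_contour(binarize(img))
        b = extract_contour(binarize(holey))
        assert np.array_equal(a, b)

    def test_multiple_components_rejected(self):
        mask = np.zeros((64, 64), bool)
        mask[10:20, 10:20] = True
        mask[40:50, 40:50] = True
        with pytest.raises(ValueError, match="component"):
            extract_contour(mask)


class TestSkeleton:
    def test_straight_rectangle_centerline(self):
        mask = np.zeros((64, 256), bool)
        mask[28:37, 20:236] = True  # 9 px tall, centered on row 32
        path = skeletonize_midline(mask)
        rms = np.sqrt(np.mean((path[:, 1] - 32.0) ** 2))
        assert rms < 1.0

    def test_c_shaped_arc_length(self, roundtrip):
        """Peak-bend synthetic frame: skeleton+tips arc length within 3% of
        the generating midline's."""
        rt = roundtrip("turn_mid")
        tpl = rt["template"]
        i = len(rt["midlines"]) // 3  # deep in the bend
        m = rt["midlines"][i]
        assert m.L_measured == pytest.approx(tpl.L, rel=0.03)

    def test_disk_is_degenerate(self):
        img = _two_level_frame()
        mask = binarize(img)
        with pytest.raises(ValueError, match="degenerate"):
            skeletonize_midline(mask)


class TestOrientation:
    def test_head_is_wide_end(self, straight_sequence):
        tpl, fld, pose, seq = straight_sequence
        mask = binarize(seq.frames[0])
        path = skeletonize_midline(mask)
        oriented, low = orient_head_tail(path, mask)
        true_mid = true_midline_world(fld, pose, tpl.L, 0)
        org = np.array(seq.meta["origin"])
        head_px = (true_mid[0] - org) / seq.scale * np.array([1, -1])
        d_head = np.linalg.norm(oriented[0] - head_px)
        d_tail = np.linalg.norm(oriented[-1] - head_px)
        assert d_head < d_tail

    def test_no_flips_across_sequence(self, roundtrip):
        rt = roundtrip("turn_large")
        heads = np.array([m.points[0] for m in rt["midlines"]])
        steps = np.linalg.norm(np.diff(heads, axis=0), axis=1)
        # a head/tail flip would jump by ~the body length
        assert steps.max() < 0.5 * rt["template"].L

    def test_symmetric_dumbbell_low_confidence(self):
        mask = np.zeros((64, 200), bool)
        mask[30:35, 20:180] = True
        rr, cc = draw_disk((32, 30), 14)
        mask[rr, cc] = True
        rr, cc = draw_disk((32, 170), 14)
        mask[rr, cc] = True
        path = skeletonize_midline(mask)
        _, low = orient_head_tail(path, mask)
        assert low


class TestResample:
    def test_straight_path_residual(self):
        path = np.column_stack([np.linspace(10, 200, 191),
                                np.full(191, 40.0)])
        m = resample_smooth(path, n_s=50, scale=0.01)
        # y-up cm frame: the line must stay at y = -0.40 within 0.1 px
        assert np.abs(m.points[:, 1] - (-0.40)).max() < 0.1 * 0.01

    def test_uniform_arc_spacing(self, roundtrip):
        rt = roundtrip("turn_mid")
        for m in rt["midlines"][::10]:
            seg = np.linalg.norm(np.diff(m.points, axis=0), axis=1)
            assert seg.std() / seg.mean() < 0.01

    def test_min_resolution_guard(self):
        path = np.column_stack([np.arange(100.0), np.full(100, 5.0)])
        with pytest.raises(ValueError, match="insufficient resolution"):
            resample_smooth(path, n_s=3, scale=0.01)


class TestFullRoundTrip:
    @pytest.mark.parametrize("name", ["turn_small", "turn_mid", "turn_large"])
    def test_hausdorff_and_length_stability(self, roundtrip, name):
        """Noiseless synthetic frames: midline within 1.5% of L of ground
        truth (Hausdorff), measured body length stable within 3%."""
        rt = roundtrip(name)
        tpl, fld, pose = rt["template"], rt["field"], rt["pose"]
        org = np.array(rt["seq"].meta["origin"])
        for i, m in enumerate(rt["midlines"]):
            truth = true_midline_world(fld, pose, tpl.L, i) - org
            d = max(cKDTree(truth).query(m.points)[0].max(),
                    cKDTree(m.points).query(truth)[0].max())
            assert d < 0.015 * tpl.L, f"frame {i}"
        L = np.array([m.L_measured for m in rt["midlines"]])
        assert L.max() / L.min() - 1 < 0.03

    def test_pipeline_deterministic(self):
        tpl = ck.maneuver_template("turn_small")
        _, _, seq = ck.synthesize_maneuver(tpl)
        a, _, _ = ck.extract_midlines(seq)
        b, _, _ = ck.extract_midlines(seq)
        for ma, mb in zip(a, b):
            assert np.array_equal(ma.points, mb.points)
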