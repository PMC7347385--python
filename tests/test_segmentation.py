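import numpy as np
import pytest

from stringpull.segmentation import (ColorModel, MASK_OBJECTS, convex_hull_mask,
                                     define_colors, load_archive, mask_grid,
                                     mask_knn, mask_mser, mask_range,
                                     merge_close_regions, pack_masks, regions,
                                     save_archive, unpack_masks,
                                     auto_zoom_window)
from stringpull.synthetic import _ellipse_mask
from stringpull.videoio import ZoomWindow


def flat_color_frame(colors, size=24):
    """Frame tiled with vertical bands of the given colors."""
    frame = np.zeros((size, size, 3))
    w = size // len(colors)
    for i, c in enumerate(colors):
        frame[:, i * w:(i + 1) * w] = c
    return frame


class TestDefineColors:
    def test_three_flat_colors_recovered(self):
        colors = [(0.9, 0.1, 0.1), (0.1, 0.9, 0.1), (0.1, 0.1, 0.9)]
        frame = flat_color_frame(colors)
        clusters = define_colors(frame, ZoomWindow(0, 0, 24, 24), k=3, seed=0)
        assert len(clusters) == 3
        for c in colors:
            nearest = min(np.linalg.norm(cl.centroid - np.array(c))
                          for cl in clusters)
            assert nearest <= 1 / 255

    def test_k_exceeds_distinct_colors(self):
        frame = flat_color_frame([(0.5, 0.5, 0.5)] * 3)
        with pytest.raises(ValueError):
            define_colors(frame, ZoomWindow(0, 0, 24, 24), k=3)

    def test_accepting_cluster_twice_no_duplicates(self):
        frame = flat_color_frame([(0.9, 0.1, 0.1), (0.1, 0.9, 0.1)])
        clusters = define_colors(frame, ZoomWindow(0, 0, 24, 24), k=2, seed=0)
        model = ColorModel(object="hands", k=2)
        model.add_cluster(clusters[0])
        n = model.n_colors
        model.add_cluster(clusters[0])
        assert model.n_colors == n


class TestMaskRange:
    def test_exact_color_included(self):
        c = (0.2, 0.4, 0.6)
        frame = flat_color_frame([c, (0.9, 0.9, 0.9)])
        m = mask_range(frame, ColorModel("hands", [c]))
        assert m[:, :5].all() and not m[:, -5:].any()

    def test_distance_two_excluded(self):
        base = np.array([100, 100, 100]) / 255
        off = np.array([102, 100, 100]) / 255      # 2.0 8-bit units away
        frame = flat_color_frame([base, off])
        m = mask_range(frame, ColorModel("fur", [base]), radius=1.5)
        assert m[:, :5].all() and not m[:, -5:].any()

    def test_radius_monotonicity(self):
        rng = np.random.default_rng(0)
        frame = rng.random((10, 10, 3))
        model = ColorModel("fur", rng.random((3, 3)))
        m_small = mask_range(frame, model, radius=1.5)
        m_big = mask_range(frame, model, radius=3.0)
        assert (m_big | m_small == m_big).all()

    def test_empty_model_errors(self):
        with pytest.raises(ValueError):
            mask_range(np.zeros((4, 4, 3)), ColorModel("fur", []))


class TestMaskKnn:
    def test_model_color_included_midpoint_to_nearer(self):
        mc = np.array([0.2, 0.2, 0.2])
        bc = np.array([0.8, 0.8, 0.8])
        near_model = mc + 0.1
        frame = flat_color_frame([mc, near_model, bc])
        m = mask_knn(frame, ColorModel("fur", [mc]),
                     ColorModel("background", [bc]))
        assert m[:, :7].all()        # exact + nearer pixels
        assert not m[:, -7:].any()

    def test_matches_bruteforce_on_toy_image(self):
        rng = np.random.default_rng(1)
        frame = rng.integers(0, 256, (8, 8, 3)).astype(float) / 255
        model = ColorModel("fur", rng.random((4, 3)))
        background = ColorModel("fur", rng.random((4, 3)))
        m = mask_knn(frame, model, background)
        for r in range(8):
            for c in range(8):
                p = frame[r, c] * 255
                dm = min(np.linalg.norm(p - mc * 255) for mc in model.colors)
                db = min(np.linalg.norm(p - bc * 255)
                         for bc in background.colors)
                assert m[r, c] == (dm < db)


class TestMaskGrid:
    def test_whole_frame_grid_equals_range(self):
        rng = np.random.default_rng(2)
        frame = rng.random((12, 12, 3))
        model = ColorModel("fur", rng.random((2, 3)))
        np.testing.assert_array_equal(
            mask_grid(frame, model, radius=40.0, grid_size=12, min_count=1),
            mask_range(frame, model, radius=40.0))

    def test_isolated_pixel_removed(self):
        c = (0.9, 0.2, 0.2)
        frame = np.full((16, 16, 3), 0.5)
        frame[3, 3] = c                       # lone match in its cell
        frame[10:12, 10:12] = c               # 4 matches in another cell
        m = mask_grid(frame, ColorModel("hands", [c]), grid_size=8, min_count=2)
        assert not m[3, 3]
        assert m[10:12, 10:12].all()

    def test_subset_of_range_mask(self):
        rng = np.random.default_rng(3)
        frame = rng.random((16, 16, 3))
        model = ColorModel("fur", rng.random((3, 3)))
        g = mask_grid(frame, model, radius=30.0, grid_size=4, min_count=3)
        r = mask_range(frame, model, radius=30.0)
        assert (r | g == r).all()


class TestMaskMser:
    def test_blob_core_detected(self):
        hand = (0.2, 0.3, 0.9)
        frame = np.full((48, 48, 3), 0.5)
        blob = _ellipse_mask(48, 48, 24, 24, 8, 6, 0)
        frame[blob] = hand
        m = mask_mser(frame, ColorModel("hands", [hand]))
        assert (m & blob).sum() >= 0.5 * blob.sum()

    def test_non_model_blob_excluded(self):
        frame = np.full((48, 48, 3), 0.5)
        blob = _ellipse_mask(48, 48, 24, 24, 8, 6, 0)
        frame[blob] = (0.9, 0.9, 0.1)
        with pytest.warns(UserWarning):
            m = mask_mser(frame, ColorModel("hands", [(0.2, 0.3, 0.9)]))
        assert not m.any()


class TestRegions:
    def test_two_disjoint_blobs(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:7, 2:7] = True
        mask[12:17, 12:17] = True
        regs = regions(mask)
        assert len(regs) == 2
        assert sorted(r.area for r in regs) == [25, 25]

    def test_moment_ellipse_recovers_rendered_ellipse(self):
        mask = _ellipse_mask(200, 200, 100, 100, 60, 20, 30.0)
        (reg,) = regions(mask)
        assert reg.major_len == pytest.approx(120, rel=0.02)
        assert reg.minor_len == pytest.approx(40, rel=0.02)
        assert reg.orientation == pytest.approx(30.0, abs=1.0)

    def test_area_threshold_drops_small_hand(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:10, 5:8] = True                # 15 px^2 = 15 mm^2 at 1 px/mm
        assert regions(mask, min_area_mm2=20, px_per_mm=1.0) == []
        assert len(regions(mask)) == 1

    def test_area_sum_equals_pixel_count(self):
        rng = np.random.default_rng(4)
        mask = rng.random((30, 30)) > 0.6
        regs = regions(mask)
        assert sum(r.area for r in regs) == int(mask.sum())

    def test_orientation_rotation_equivariance(self):
        mask = _ellipse_mask(120, 120, 60, 60, 40, 10, 20.0)
        (a,) = regions(mask)
        (b,) = regions(np.rot90(mask))
        diff = (a.orientation - b.orientation) % 180
        assert min(diff, 180 - diff) == pytest.approx(90.0, abs=1.0)


class TestMergeAndHull:
    def test_close_blobs_merge(self):
        mask = np.zeros((20, 40), dtype=bool)
        mask[8:12, 5:10] = True
        mask[8:12, 13:18] = True              # 3 px gap
        merged = merge_close_regions(regions(mask), distance_px=10)
        assert len(merged) == 1
        assert merged[0].area == 40

    def test_distant_blobs_unchanged(self):
        mask = np.zeros((20, 80), dtype=bool)
        mask[8:12, 0:5] = True
        mask[8:12, 55:60] = True
        assert len(merge_close_regions(regions(mask), distance_px=10)) == 2

    def test_merge_idempotent(self):
        rng = np.random.default_rng(5)
        mask = rng.random((25, 25)) > 0.8
        once = merge_close_regions(regions(mask), 5)
        twice = merge_close_regions(once, 5)
        assert sorted(r.area for r in once) == sorted(r.area for r in twice)

    def test_hull_joins_blobs_and_is_superset(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:5, 2:5] = True
        mask[15:18, 15:18] = True
        hull = convex_hull_mask(mask)
        assert (hull | mask == hull).all()
        assert len(regions(hull)) == 1

    def test_hull_of_convex_blob_unchanged(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        np.testing.assert_array_equal(convex_hull_mask(mask), mask)

    def test_hull_empty_mask_errors(self):
        with pytest.raises(ValueError):
            convex_hull_mask(np.zeros((5, 5), dtype=bool))


class TestAutoZoomWindow:
    def test_contains_all_body_pixels(self, small_session):
        stack = small_session["stack"]
        truth = small_session["truth"]
        window = auto_zoom_window(stack, small_session["models"]["fur"],
                                  margin_px=5)
        rs, cs = window.slices()
        for t in range(0, stack.n_frames, 10):
            fur = truth.part_mask("fur", t)
            outside = fur.copy()
            outside[rs, cs] = False
            assert not outside.any()

    def test_window_inside_frame(self, small_session):
        stack = small_session["stack"]
        window = auto_zoom_window(stack, small_session["models"]["fur"],
                                  margin_px=500)
        assert window.row0 == 0 and window.col0 == 0
        assert window.height <= stack.shape[0]
        assert window.width <= stack.shape[1]


class TestMaskArchive:
    def test_roundtrip_identity(self):
        rng = np.random.default_rng(6)
        masks = rng.random((5, 12, 14, 4)) > 0.5
        arch = pack_masks(masks)
        np.testing.assert_array_equal(unpack_masks(arch), masks)
        assert ((arch.planes >> 5) == 0).all()     # bits 5-7 unused

    def test_all_zero(self):
        arch = pack_masks(np.zeros((5, 4, 4, 2), dtype=bool))
        assert arch.planes.max() == 0

    def test_fur_is_bit_zero(self):
        masks = np.zeros((5, 2, 2, 1), dtype=bool)
        masks[0, 0, 0, 0] = True              # fur only
        arch = pack_masks(masks)
        assert arch.planes[0, 0, 0] == 1
        assert MASK_OBJECTS[0] == "fur"

    def test_too_many_masks(self):
        with pytest.raises(ValueError):
            pack_masks(np.zeros((9, 2, 2, 1), dtype=bool),
                       objects=tuple("abcdefghi"))

    def test_file_roundtrip(self, tmp_path):
        rng = np.random.default_rng(7)
        masks = rng.random((5, 6, 8, 3)) > 0.5
        arch = pack_masks(masks, epoch=(10, 12))
        save_archive(arch, tmp_path / "m.bin")
        back = load_archive(tmp_path / "m.bin")
        np.testing.assert_array_equal(back.planes, arch.planes)
        assert back.objects == arch.objects
        assert back.epoch == (10, 12)


def test_mask_methods_agree_on_separated_colors():
    """All three methods coincide when pixels are either exact model colors
    or far from them."""
    mc = np.array([0.2, 0.6, 0.3])
    bc = np.array([0.8, 0.1, 0.7])
    frame = flat_color_frame([mc, bc], size=12)
    model = ColorModel("fur", [mc])
    background = ColorModel("fur", [bc])
    m_range = mask_range(frame, model, radius=1.5)
    m_knn = mask_knn(frame, model, background)
    m_grid = mask_grid(frame, model, radius=1.5, grid_size=12, min_count=1)
    np.testing.assert_array_equal(m_range, m_knn)
    np.testing.assert_array_equal(m_range, m_grid)


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    @given(masks=arrays(bool, (3, 5, 7, 2)))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_pack_unpack_roundtrip_property(masks):
        arch = pack_masks(masks, objects=("a", "b", "c"))
        np.testing.assert_array_equal(unpack_masks(arch), masks)
        assert ((arch.planes >> 3) == 0).all()
except ImportError:  # pragma: no cover
    pass


def test_color_model_json_roundtrip(tmp_path):
    model = ColorModel("nose", [(0.9, 0.4, 0.5), (0.8, 0.3, 0.4)], k=7)
    model.save(tmp_path / "nose.json")
    back = ColorModel.load(tmp_path / "nose.json")
    assert back.object == "nose" and back.k == 7
    np.testing.assert_allclose(back.colors, model.colors)
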