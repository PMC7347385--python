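import numpy as np
import pandas as pd
import pytest

from conftest import color_models, make_small_spec, mask_provider
from stringpull.segmentation import pack_masks
from stringpull.synthetic import GroundTruth, _ellipse_mask, modeled_mouse
from stringpull.tracking import (BodyFit, apply_overrides, benchmark_accuracy,
                                 find_ears, find_nose, fit_body, head_box,
                                 run_tracking, step_hands, PoseTrack)


class TestFitBody:
    def test_vertical_ellipse_length_and_angle(self):
        mask = _ellipse_mask(600, 600, 300, 300, 200, 80, 90.0)
        fit = fit_body(mask, px_per_mm=10.0)
        assert fit.length_mm(10.0) == pytest.approx(40.0, rel=0.02)
        assert fit.orientation == pytest.approx(90.0, abs=1.0)

    def test_horizontal_ellipse_angle_zero(self):
        mask = _ellipse_mask(300, 600, 300, 150, 200, 80, 0.0)
        assert fit_body(mask).orientation == pytest.approx(0.0, abs=1.0)

    def test_string_split_rejoined_by_hull(self):
        mask = _ellipse_mask(600, 600, 300, 300, 200, 80, 90.0)
        split = mask.copy()
        split[298:301, :] = False             # 3 px horizontal string
        whole = fit_body(mask)
        rejoined = fit_body(split)
        assert rejoined.major_len == pytest.approx(whole.major_len, rel=0.02)

    def test_empty_mask_invalid(self):
        assert not fit_body(np.zeros((10, 10), dtype=bool)).valid


def body_at(cx=100.0, cy=120.0, major=120.0, minor=60.0, orient=90.0):
    return BodyFit(cx=cx, cy=cy, major_len=major, minor_len=minor,
                   orientation=orient)


def blob_mask(shape, centers, radius=4):
    mask = np.zeros(shape, dtype=bool)
    for (x, y) in centers:
        mask |= _ellipse_mask(shape[0], shape[1], x, y, radius, radius, 0)
    return mask


class TestFindEars:
    def test_side_rule_image_left_is_right_ear(self):
        body = body_at()
        mask = blob_mask((200, 200), [(70, 50), (130, 50)])
        ears = find_ears(mask, body)
        assert ears["ear_R"][0] < body.cx < ears["ear_L"][0]

    def test_blob_inside_body_ellipse_removed(self):
        body = body_at()
        mask = blob_mask((200, 200), [(100, 120)])   # at the body centroid
        ears = find_ears(mask, body)
        assert ears["ear_R"] is None and ears["ear_L"] is None

    def test_single_blob_assigned_to_nearest_previous(self):
        body = body_at()
        mask = blob_mask((200, 200), [(75, 50)])
        prev = {"ear_R": (70.0, 52.0), "ear_L": (130.0, 52.0)}
        ears = find_ears(mask, body, prev_ears=prev)
        assert ears["ear_R"] is not None and ears["ear_L"] is None

    def test_mirror_swaps_ear_labels(self):
        W = 200
        body = body_at()
        mask = blob_mask((200, W), [(70, 50), (130, 50)])
        ears = find_ears(mask, body)
        mirrored_body = body_at(cx=W - 1 - body.cx)
        ears_m = find_ears(mask[:, ::-1], mirrored_body)
        assert ears_m["ear_R"][0] == pytest.approx(W - 1 - ears["ear_L"][0], abs=0.5)
        assert ears_m["ear_L"][0] == pytest.approx(W - 1 - ears["ear_R"][0], abs=0.5)


class TestFindNose:
    def test_nearer_candidate_to_ellipse_top_wins(self):
        body = body_at(cx=100, cy=120, orient=90.0)   # top vertex (100, 60)
        near = (100, 55)
        far = (100, 0)
        mask = blob_mask((200, 200), [near, far], radius=3)
        nose = find_nose(mask, body)
        assert abs(nose[1] - 52) < 3                  # near blob's top

    def test_nose_point_is_topmost_of_circle(self):
        body = body_at()
        mask = blob_mask((200, 200), [(100, 50)], radius=5)
        nose = find_nose(mask, body)
        assert nose[0] == pytest.approx(100, abs=0.5)
        assert nose[1] == pytest.approx(45, abs=1.0)

    def test_empty_mask_invalid(self):
        assert find_nose(np.zeros((50, 50), dtype=bool), body_at()) is None


class TestStepHands:
    def test_merged_blob_split_left_right(self):
        # one elongated blob spanning both previous hands
        mask = np.zeros((60, 120), dtype=bool)
        mask[25:35, 20:100] = True
        prev_R, prev_L = (30.0, 30.0), (90.0, 30.0)
        out = step_hands(mask, prev_R, prev_L, px_per_mm=1.0)
        assert out["hand_R"].centroid[0] < out["hand_L"].centroid[0]
        assert out["hand_R"].area == out["hand_L"].area

    def test_two_region_assignment_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            centers = rng.uniform(15, 105, size=(2, 2))
            if np.linalg.norm(centers[0] - centers[1]) < 25:
                continue
            mask = blob_mask((120, 120), [tuple(c) for c in centers])
            prev_R = tuple(rng.uniform(10, 110, 2))
            prev_L = tuple(rng.uniform(10, 110, 2))
            out = step_hands(mask, prev_R, prev_L, px_per_mm=1.0)
            got = (out["hand_R"].centroid, out["hand_L"].centroid)

            def cost(pair):
                (r, l) = pair
                return (np.hypot(r[0] - prev_R[0], r[1] - prev_R[1])
                        + np.hypot(l[0] - prev_L[0], l[1] - prev_L[1]))

            cands = [(got[0], got[1]), (got[1], got[0])]
            assert cost(cands[0]) <= cost(cands[1]) + 1e-9

    def test_distractor_eliminated_by_shortlist(self):
        prev_R, prev_L = (30.0, 60.0), (90.0, 60.0)
        mask = blob_mask((120, 120), [(32, 62), (88, 58), (60, 10)])
        out = step_hands(mask, prev_R, prev_L, px_per_mm=1.0)
        for hand in ("hand_R", "hand_L"):
            assert out[hand].centroid[1] > 40     # distractor at y=10 dropped

    def test_small_regions_dropped(self):
        mask = blob_mask((120, 120), [(30, 60), (90, 60)], radius=2)
        # ~13 px^2 at 1 px/mm -> below the 20 mm^2 floor
        assert step_hands(mask, (30, 60), (90, 60), px_per_mm=1.0) is None


class TestHeadBox:
    def test_contains_parts_plus_margin(self):
        track = PoseTrack(n_frames=2)
        track.set_point("ear_R", 0, 40, 50)
        track.set_point("ear_L", 0, 80, 50)
        track.set_point("nose", 0, 60, 30)
        box = head_box(track, 0, None, (200, 200))
        assert box.row0 <= 30 - 15 and box.col0 <= 40 - 15
        assert box.row0 + box.height >= 50 + 15
        assert box.col0 + box.width >= 80 + 15

    def test_fallback_to_body_top(self):
        track = PoseTrack(n_frames=1)
        box = head_box(track, 0, body_at(), (200, 200))
        assert box.height >= 1 and box.width >= 1

    def test_clipped_to_frame(self):
        track = PoseTrack(n_frames=1)
        track.set_point("nose", 0, 2, 2)
        box = head_box(track, 0, None, (50, 50))
        assert box.row0 >= 0 and box.col0 >= 0
        assert box.row0 + box.height <= 50
        assert box.col0 + box.width <= 50


class TestOverrides:
    def test_override_replaces_and_flags(self):
        track = PoseTrack(n_frames=3)
        track.set_point("hand_L", 1, 10, 10)
        ov = pd.DataFrame([{"frame": 1, "part": "hand_L", "x": 99.0, "y": 88.0}])
        apply_overrides(track, ov)
        assert track.point("hand_L", 1) == (99.0, 88.0)
        assert track.override["hand_L"][1]

    def test_unknown_part_errors(self):
        track = PoseTrack(n_frames=1)
        ov = pd.DataFrame([{"frame": 0, "part": "tail", "x": 1, "y": 2}])
        with pytest.raises(ValueError):
            apply_overrides(track, ov)

    def test_empty_table_identity(self):
        track = PoseTrack(n_frames=2)
        track.set_point("nose", 0, 5, 5)
        apply_overrides(track, pd.DataFrame(columns=["frame", "part", "x", "y"]))
        assert track.point("nose", 0) == (5.0, 5.0)
        assert not track.override["nose"].any()

    def test_rerun_uses_corrected_state(self, small_session):
        """An override replaces the tracked point and seeds later frames."""
        stack = small_session["stack"]
        truth = small_session["truth"]
        init = {"hand_R": truth.part_xy("hand_R", 0),
                "hand_L": truth.part_xy("hand_L", 0)}
        # swap hands at frame 5 via overrides: later frames follow the swap
        rx, ry = truth.part_xy("hand_R", 5)
        lx, ly = truth.part_xy("hand_L", 5)
        ov = pd.DataFrame([
            {"frame": 5, "part": "hand_R", "x": lx, "y": ly},
            {"frame": 5, "part": "hand_L", "x": rx, "y": ry},
        ])
        track = run_tracking(small_session["provider"], 10, stack.px_per_mm,
                             init, overrides=ov)
        assert track.override["hand_R"][5]
        # frame 6 hand_R should now follow the (swapped) left-side truth
        tx, _ = truth.part_xy("hand_L", 6)
        assert track.point("hand_R", 6)[0] == pytest.approx(tx, abs=2.0)


class TestBenchmark:
    def test_all_correct_is_100(self, small_session):
        acc = benchmark_accuracy(small_session["track"],
                                 small_session["truth"])
        assert acc["body"] == 100.0
        assert acc["ears"] == 100.0
        assert acc["nose"] == 100.0
        assert acc["hands"] >= 99.0

    def test_six_of_477_gives_9874(self):
        """6 mislabeled hand frames out of 477 -> 98.74% correct."""
        N = 477
        masks = np.zeros((len(("fur", "ear_R", "ear_L", "nose", "hand_R",
                               "hand_L")), 8, 8, N), dtype=bool)
        masks[4, 1:3, 1:3, :] = True     # hand_R region
        masks[5, 5:7, 5:7, :] = True     # hand_L region
        truth = GroundTruth(
            masks=pack_masks(masks, objects=("fur", "ear_R", "ear_L", "nose",
                                             "hand_R", "hand_L")),
            table=pd.DataFrame())
        track = PoseTrack(n_frames=N)
        for t in range(N):
            if t < 6:                     # swapped = incorrect
                track.set_point("hand_R", t, 5.5, 5.5)
                track.set_point("hand_L", t, 1.5, 1.5)
            else:
                track.set_point("hand_R", t, 1.5, 1.5)
                track.set_point("hand_L", t, 5.5, 5.5)
        acc = benchmark_accuracy(track, truth)
        assert round(acc["hands"], 2) == 98.74

    def test_absent_part_excluded_from_denominator(self):
        N = 4
        objs = ("fur", "ear_R", "ear_L", "nose", "hand_R", "hand_L")
        masks = np.zeros((6, 8, 8, N), dtype=bool)
        masks[3, 2:4, 2:4, :2] = True     # nose present in 2 of 4 frames
        truth = GroundTruth(masks=pack_masks(masks, objects=objs),
                            table=pd.DataFrame())
        track = PoseTrack(n_frames=N)
        track.set_point("nose", 0, 2.5, 2.5)
        track.set_point("nose", 1, 2.5, 2.5)
        acc = benchmark_accuracy(track, truth)
        assert acc["nose"] == 100.0

    def test_frame_count_mismatch(self, small_session):
        track = PoseTrack(n_frames=3)
        with pytest.raises(ValueError):
            benchmark_accuracy(track, small_session["truth"])


class TestTrackingProperties:
    def test_hand_labels_never_swap(self, small_session):
        """Hands stay >= 30 px apart in the synthetic video, so labels must
        remain stable over the whole epoch."""
        track = small_session["track"]
        truth = small_session["truth"]
        for t in range(track.n_frames):
            pr = track.point("hand_R", t)
            tr = truth.part_xy("hand_R", t)
            assert np.hypot(pr[0] - tr[0], pr[1] - tr[1]) < 10

    def test_no_invalid_body_frames(self, small_session):
        assert small_session["track"].valid["body"].all()

    def test_track_csv_roundtrip(self, tmp_path, small_session):
        track = small_session["track"]
        track.save_csv(tmp_path / "t.csv", fps=60, px_per_mm=1.0)
        df = pd.read_csv(tmp_path / "t.csv", comment="#")
        back = PoseTrack.from_dataframe(df)
        for part in ("body", "nose", "hand_R"):
            np.testing.assert_allclose(back.xy[part], track.xy[part],
                                       equal_nan=True)
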