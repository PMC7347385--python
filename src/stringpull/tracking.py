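"""Heuristic per-frame identification of body, ears, nose and hands.

Each frame's part masks are reduced to a small set of labelled points using
rules that exploit the animal's geometry and the previous frame's state:

* **body** — convex hull of the fur mask, largest connected region, moment
  ellipse; body length = major axis, body tilt = orientation.
* **ears** — ear-colored regions *outside* the body ellipse; with two
  candidates the image-left one is the animal's RIGHT ear (the mouse faces
  the camera), otherwise the previous frame disambiguates.
* **nose** — candidate region closest to the top vertex of the body
  ellipse; the reported point is the topmost point of its moment ellipse.
* **hands** — initialised by the user in the first frame, then tracked by
  continuity: small regions (< 20 mm^2) are dropped, close regions merged;
  one surviving region is split into two equal halves across its major
  axis, two regions are assigned by the pairing minimising total distance
  to the previous hands, more than two are shortlisted by a
  distance-minus-overlap score and fed back recursively.

Manual corrections enter through an override table; accuracy against ground
truth is summarised per part as the percentage of frames correctly detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .segmentation import Region, convex_hull_mask, merge_close_regions, regions
from .videoio import ZoomWindow

__all__ = ["PoseTrack", "BodyFit", "TrackConfig", "PARTS",
           "fit_body", "find_ears", "find_nose", "step_hands", "head_box",
           "run_tracking", "apply_overrides", "benchmark_accuracy"]

PARTS = ("body", "ear_R", "ear_L", "nose", "hand_R", "hand_L")


@dataclass(frozen=True)
class TrackConfig:
    """Tunable thresholds of the heuristic tracker (one block, as in the
    original toolbox's region-selection knobs)."""

    min_hand_area_mm2: float = 20.0   # regions below this are not hands
    min_ear_area_px: int = 5
    min_nose_area_px: int = 5
    merge_distance_px: float = 10.0   # single-linkage merge radius
    overlap_lambda: float = 1.0       # px discount per overlap pixel in the
                                      # >2-candidate hand shortlist score
    head_margin_px: int = 20


@dataclass
class BodyFit:
    """Moment-ellipse fit of the body for one frame."""

    cx: float
    cy: float
    major_len: float
    minor_len: float
    orientation: float        # degrees from horizontal, y up
    valid: bool = True

    def length_mm(self, px_per_mm: float) -> float:
        return self.major_len / px_per_mm

    def contains(self, x: float, y: float) -> bool:
        th = np.radians(self.orientation)
        dx, dy = x - self.cx, -(y - self.cy)
        xr = dx * np.cos(th) + dy * np.sin(th)
        yr = -dx * np.sin(th) + dy * np.cos(th)
        return (xr / (self.major_len / 2)) ** 2 + (yr / (self.minor_len / 2)) ** 2 <= 1.0

    def top_vertex(self) -> tuple[float, float]:
        """End of the major axis nearer the top of the frame (smaller row)."""
        th = np.radians(self.orientation)
        dx = (self.major_len / 2) * np.cos(th)
        dy_up = (self.major_len / 2) * np.sin(th)
        p1 = (self.cx + dx, self.cy - dy_up)
        p2 = (self.cx - dx, self.cy + dy_up)
        return p1 if p1[1] <= p2[1] else p2


@dataclass
class PoseTrack:
    """Per-frame part positions with validity and override flags."""

    n_frames: int
    xy: dict = field(default_factory=dict)        # part -> (N, 2) float
    valid: dict = field(default_factory=dict)     # part -> (N,) bool
    override: dict = field(default_factory=dict)  # part -> (N,) bool
    body_major: np.ndarray | None = None
    body_minor: np.ndarray | None = None
    body_orientation: np.ndarray | None = None
    hand_area: dict = field(default_factory=dict)  # hand part -> (N,)

    def __post_init__(self) -> None:
        N = self.n_frames
        for part in PARTS:
            self.xy.setdefault(part, np.full((N, 2), np.nan))
            self.valid.setdefault(part, np.zeros(N, dtype=bool))
            self.override.setdefault(part, np.zeros(N, dtype=bool))
        if self.body_major is None:
            self.body_major = np.full(N, np.nan)
            self.body_minor = np.full(N, np.nan)
            self.body_orientation = np.full(N, np.nan)
        for h in ("hand_R", "hand_L"):
            self.hand_area.setdefault(h, np.full(N, np.nan))

    def set_point(self, part: str, t: int, x: float, y: float,
                  override: bool = False) -> None:
        self.xy[part][t] = (x, y)
        self.valid[part][t] = True
        if override:
            self.override[part][t] = True

    def point(self, part: str, t: int) -> tuple[float, float] | None:
        if not self.valid[part][t]:
            return None
        return tuple(self.xy[part][t])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for t in range(self.n_frames):
            for part in PARTS:
                x, y = self.xy[part][t]
                rows.append({"frame": t, "part": part, "x": x, "y": y,
                             "valid": bool(self.valid[part][t]),
                             "override": bool(self.override[part][t])})
        return pd.DataFrame(rows)

    def save_csv(self, path: str | Path, fps: float | None = None,
                 px_per_mm: float | None = None) -> None:
        import json

        path = Path(path)
        meta = {"n_frames": self.n_frames, "fps": fps, "px_per_mm": px_per_mm}
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(meta) + "\n")
            self.to_dataframe().to_csv(fh, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PoseTrack":
        track = cls(n_frames=int(df.frame.max()) + 1)
        for _, r in df.iterrows():
            if r.valid:
                track.set_point(r.part, int(r.frame), r.x, r.y,
                                override=bool(r.get("override", False)))
        return track


# ---------------------------------------------------------------------------
# Per-frame rules
# ---------------------------------------------------------------------------

def fit_body(fur_mask: np.ndarray, px_per_mm: float = 1.0) -> BodyFit:
    """Convex hull -> largest region -> moment ellipse."""
    fur_mask = np.asarray(fur_mask, dtype=bool)
    if not fur_mask.any():
        return BodyFit(np.nan, np.nan, np.nan, np.nan, np.nan, valid=False)
    hull = convex_hull_mask(fur_mask)
    regs = regions(hull)
    body = max(regs, key=lambda r: r.area)
    return BodyFit(cx=body.centroid[0], cy=body.centroid[1],
                   major_len=body.major_len, minor_len=body.minor_len,
                   orientation=body.orientation)


def _ellipse_complement(mask_shape: tuple[int, int], body: BodyFit) -> np.ndarray:
    H, W = mask_shape
    rr, cc = np.mgrid[0:H, 0:W]
    th = np.radians(body.orientation)
    dx = cc - body.cx
    dy = -(rr - body.cy)
    xr = dx * np.cos(th) + dy * np.sin(th)
    yr = -dx * np.sin(th) + dy * np.cos(th)
    inside = (xr / (body.major_len / 2)) ** 2 + (yr / (body.minor_len / 2)) ** 2 <= 1
    return ~inside


def find_ears(ear_mask: np.ndarray, body: BodyFit,
              prev_ears: dict | None = None,
              head_window: ZoomWindow | None = None,
              config: TrackConfig = TrackConfig()) -> dict:
    """Locate the two ears; returns {'ear_R': (x, y) | None, 'ear_L': ...}.

    Image-left of the body centroid is the animal's RIGHT ear.
    """
    if not body.valid:
        return {"ear_R": None, "ear_L": None}
    ear_mask = np.asarray(ear_mask, dtype=bool)
    if head_window is not None:
        boxed = np.zeros_like(ear_mask)
        rs, cs = head_window.slices()
        boxed[rs, cs] = ear_mask[rs, cs]
        ear_mask = boxed
    ear_mask = ear_mask & _ellipse_complement(ear_mask.shape, body)
    regs = merge_close_regions(regions(ear_mask), config.merge_distance_px)
    regs = [r for r in regs if r.area >= config.min_ear_area_px]
    if not regs:
        return {"ear_R": None, "ear_L": None}
    if len(regs) > 2:
        if prev_ears and any(prev_ears.get(k) for k in ("ear_R", "ear_L")):
            refs = [prev_ears[k] for k in ("ear_R", "ear_L") if prev_ears.get(k)]
            regs = sorted(regs, key=lambda r: min(
                np.hypot(r.centroid[0] - p[0], r.centroid[1] - p[1])
                for p in refs))[:2]
        else:
            regs = sorted(regs, key=lambda r: -r.area)[:2]
    if len(regs) == 2:
        regs = sorted(regs, key=lambda r: r.centroid[0])
        return {"ear_R": regs[0].centroid, "ear_L": regs[1].centroid}
    # single candidate: nearest previous ear wins; else side of body centroid
    c = regs[0].centroid
    if prev_ears and (prev_ears.get("ear_R") or prev_ears.get("ear_L")):
        dists = {}
        for k in ("ear_R", "ear_L"):
            p = prev_ears.get(k)
            if p is not None:
                dists[k] = np.hypot(c[0] - p[0], c[1] - p[1])
        side = min(dists, key=dists.get)
    else:
        side = "ear_R" if c[0] < body.cx else "ear_L"
    out = {"ear_R": None, "ear_L": None}
    out[side] = c
    return out


def _ellipse_top_point(region: Region) -> tuple[float, float]:
    """Topmost (smallest row) point of a region's moment ellipse."""
    th = np.radians(region.orientation)
    a = region.major_len / 2
    b = region.minor_len / 2
    t = np.arctan2(b * np.cos(th), a * np.sin(th))
    for tt in (t, t + np.pi):
        y_up = a * np.cos(tt) * np.sin(th) + b * np.sin(tt) * np.cos(th)
        if y_up >= 0:
            dx = a * np.cos(tt) * np.cos(th) - b * np.sin(tt) * np.sin(th)
            return (region.centroid[0] + dx, region.centroid[1] - y_up)
    return region.centroid  # pragma: no cover - defensive


def find_nose(nose_mask: np.ndarray, body: BodyFit,
              prev_nose: tuple[float, float] | None = None,
              config: TrackConfig = TrackConfig()) -> tuple[float, float] | None:
    """Nose point: topmost point of the candidate region nearest the body
    ellipse's top vertex; ``None`` when occluded (e.g. behind the string)."""
    if not body.valid:
        return None
    nose_mask = np.asarray(nose_mask, dtype=bool)
    regs = merge_close_regions(regions(nose_mask), config.merge_distance_px)
    regs = [r for r in regs if r.area >= config.min_nose_area_px]
    if not regs:
        return None
    top = body.top_vertex()
    best = min(regs, key=lambda r: np.hypot(r.centroid[0] - top[0],
                                            r.centroid[1] - top[1]))
    return _ellipse_top_point(best)


def _split_region(region: Region) -> tuple[Region, Region]:
    """Split a merged two-hand blob into equal halves across its major axis."""
    th = np.radians(region.orientation)
    d = np.array([np.cos(th), -np.sin(th)])      # major axis in (col, row)
    rel = region.pixels[:, ::-1].astype(np.float64)
    rel[:, 0] -= region.centroid[0]
    rel[:, 1] -= region.centroid[1]
    proj = rel @ d
    order = np.argsort(proj, kind="stable")
    half = len(order) // 2
    from .segmentation import _region_from_pixels

    a = _region_from_pixels(region.pixels[order[:half]])
    b = _region_from_pixels(region.pixels[order[half:]])
    return a, b


def _pair_assignment(regs: list[Region], prev_R, prev_L):
    """Assign two regions to R/L by the pairing minimising total distance."""
    c0, c1 = regs[0].centroid, regs[1].centroid

    def d(p, q):
        return np.hypot(p[0] - q[0], p[1] - q[1])

    if d(c0, prev_R) + d(c1, prev_L) <= d(c1, prev_R) + d(c0, prev_L):
        return regs[0], regs[1]
    return regs[1], regs[0]


def step_hands(hand_mask: np.ndarray, prev_R: tuple[float, float],
               prev_L: tuple[float, float], px_per_mm: float,
               config: TrackConfig = TrackConfig(),
               prev_pixels: dict | None = None,
               _regs: list[Region] | None = None) -> dict | None:
    """One frame of the hand heuristic; returns region assignments or None.

    ``prev_pixels`` optionally carries the previous hand regions' pixel
    coordinates for the overlap term of the >2-candidate shortlist.
    """
    if _regs is None:
        regs = regions(hand_mask, min_area_mm2=config.min_hand_area_mm2,
                       px_per_mm=px_per_mm)
        regs = merge_close_regions(regs, config.merge_distance_px)
    else:
        regs = _regs
    if not regs:
        return None
    if len(regs) == 1:
        a, b = _split_region(regs[0])
        r, l = _pair_assignment([a, b], prev_R, prev_L)
        return {"hand_R": r, "hand_L": l}
    if len(regs) == 2:
        r, l = _pair_assignment(regs, prev_R, prev_L)
        return {"hand_R": r, "hand_L": l}
    # more than two candidates: shortlist by distance minus overlap, recurse
    def score(region: Region) -> float:
        c = region.centroid
        dist = min(np.hypot(c[0] - prev_R[0], c[1] - prev_R[1]),
                   np.hypot(c[0] - prev_L[0], c[1] - prev_L[1]))
        overlap = 0
        if prev_pixels:
            keys = {tuple(p) for p in region.pixels}
            for px in prev_pixels.values():
                overlap = max(overlap, sum(tuple(p) in keys for p in px))
        return dist - config.overlap_lambda * overlap

    shortlist = sorted(regs, key=score)[:2]
    return step_hands(hand_mask, prev_R, prev_L, px_per_mm, config,
                      prev_pixels, _regs=shortlist)


def head_box(track: PoseTrack, t_prev: int, body: BodyFit | None,
             frame_shape: tuple[int, int],
             config: TrackConfig = TrackConfig()) -> ZoomWindow:
    """Search window around the head from the previous frame's ears/nose,
    falling back to the top 40% of the body ellipse bounding box."""
    H, W = frame_shape
    pts = [track.point(p, t_prev) for p in ("ear_R", "ear_L", "nose")]
    pts = [p for p in pts if p is not None]
    m = config.head_margin_px
    if pts:
        xs = [p[0] for p in pts]
        ys = [p[1] for p in pts]
        r0, r1 = min(ys) - m, max(ys) + m
        c0, c1 = min(xs) - m, max(xs) + m
    elif body is not None and body.valid:
        half = body.major_len / 2
        r0 = body.cy - half - m
        r1 = body.cy - half + 0.4 * body.major_len + m
        c0 = body.cx - body.minor_len / 2 - m
        c1 = body.cx + body.minor_len / 2 + m
    else:
        return ZoomWindow(0, 0, H, W)
    r0 = int(np.clip(np.floor(r0), 0, H - 1))
    c0 = int(np.clip(np.floor(c0), 0, W - 1))
    r1 = int(np.clip(np.ceil(r1), r0 + 1, H))
    c1 = int(np.clip(np.ceil(c1), c0 + 1, W))
    return ZoomWindow(row0=r0, col0=c0, height=r1 - r0, width=c1 - c0)


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def run_tracking(mask_provider, n_frames: int, px_per_mm: float,
                 init_hands: dict,
                 config: TrackConfig = TrackConfig(),
                 overrides: pd.DataFrame | None = None,
                 use_head_box: bool = False) -> PoseTrack:
    """Track all parts over an epoch.

    ``mask_provider(t)`` returns a dict with boolean masks for ``fur``,
    ``ears``, ``nose`` and ``hands`` for frame ``t``.  ``init_hands`` holds
    the user-marked first-frame hand centroids
    ``{"hand_R": (x, y), "hand_L": (x, y)}``.  Overrides (columns frame,
    part, x, y) replace automatic results *during* tracking, so corrected
    frames seed the subsequent frames' context.
    """
    track = PoseTrack(n_frames=n_frames)
    prev_R = tuple(init_hands["hand_R"])
    prev_L = tuple(init_hands["hand_L"])
    prev_pixels: dict = {}
    ov = {}
    if overrides is not None and len(overrides):
        for _, r in overrides.iterrows():
            ov.setdefault(int(r.frame), {})[r.part] = (float(r.x), float(r.y))
            if r.part not in PARTS:
                raise ValueError(f"unknown part in override table: {r.part!r}")

    for t in range(n_frames):
        masks = mask_provider(t)
        body = fit_body(masks["fur"], px_per_mm)
        if body.valid:
            track.set_point("body", t, body.cx, body.cy)
            track.body_major[t] = body.major_len
            track.body_minor[t] = body.minor_len
            track.body_orientation[t] = body.orientation

        prev_ears = None
        if t > 0:
            prev_ears = {p: track.point(p, t - 1) for p in ("ear_R", "ear_L")}
        hw = None
        if use_head_box and t > 0:
            hw = head_box(track, t - 1, body, masks["fur"].shape, config)
        ears = find_ears(masks["ears"], body, prev_ears, hw, config)
        for part in ("ear_R", "ear_L"):
            if ears[part] is not None:
                track.set_point(part, t, *ears[part])

        prev_nose = track.point("nose", t - 1) if t > 0 else None
        nose = find_nose(masks["nose"], body, prev_nose, config)
        if nose is not None:
            track.set_point("nose", t, *nose)

        hands = step_hands(masks["hands"], prev_R, prev_L, px_per_mm,
                           config, prev_pixels)
        if hands is not None:
            for part in ("hand_R", "hand_L"):
                reg = hands[part]
                track.set_point(part, t, *reg.centroid)
                track.hand_area[part][t] = reg.area

        # manual overrides replace the automatic result and seed context
        for part, (x, y) in ov.get(t, {}).items():
            track.set_point(part, t, x, y, override=True)

        for part in ("hand_R", "hand_L"):
            p = track.point(part, t)
            if p is not None:
                if part == "hand_R":
                    prev_R = p
                else:
                    prev_L = p
        if hands is not None:
            prev_pixels = {p: hands[p].pixels for p in ("hand_R", "hand_L")}
    return track


def apply_overrides(track: PoseTrack, overrides: pd.DataFrame) -> PoseTrack:
    """Replace listed part coordinates and set the override flag."""
    for _, r in overrides.iterrows():
        part = r.part
        if part not in PARTS:
            raise ValueError(f"unknown part name {part!r}")
        track.set_point(part, int(r.frame), float(r.x), float(r.y),
                        override=True)
    return track


# ---------------------------------------------------------------------------
# Benchmarking
# ---------------------------------------------------------------------------

def _point_in_mask(p: tuple[float, float], mask: np.ndarray) -> bool:
    c, r = int(round(p[0])), int(round(p[1]))
    H, W = mask.shape
    return 0 <= r < H and 0 <= c < W and bool(mask[r, c])


def benchmark_accuracy(track: PoseTrack, truth, nose_dilate_px: int = 2) -> dict:
    """Percentage of frames each part is correctly detected.

    A part is correct when its detected point lies inside the ground-truth
    region: the body centroid inside the true body ellipse; each ear inside
    its own ear (sides not swapped); the nose within the nose region dilated
    by ``nose_dilate_px``; both hands inside their own regions with correct
    labels.  Frames where a part is absent from the truth are excluded from
    that part's denominator.
    """
    from scipy.ndimage import binary_dilation

    N = track.n_frames
    if truth.masks.n_frames != N:
        raise ValueError("truth and track frame counts differ")
    correct = {k: 0 for k in ("body", "ears", "nose", "hands")}
    present = {k: 0 for k in ("body", "ears", "nose", "hands")}
    for t in range(N):
        fur = truth.part_mask("fur", t)
        if fur.any():
            present["body"] += 1
            p = track.point("body", t)
            if p is not None and _point_in_mask(p, fur):
                correct["body"] += 1
        er, el = truth.part_mask("ear_R", t), truth.part_mask("ear_L", t)
        if er.any() and el.any():
            present["ears"] += 1
            pr, pl = track.point("ear_R", t), track.point("ear_L", t)
            if (pr is not None and pl is not None
                    and _point_in_mask(pr, er) and _point_in_mask(pl, el)):
                correct["ears"] += 1
        nm = truth.part_mask("nose", t)
        if nm.any():
            present["nose"] += 1
            p = track.point("nose", t)
            if p is not None and _point_in_mask(
                    p, binary_dilation(nm, iterations=nose_dilate_px)):
                correct["nose"] += 1
        hr, hl = truth.part_mask("hand_R", t), truth.part_mask("hand_L", t)
        if hr.any() and hl.any():
            present["hands"] += 1
            pr, pl = track.point("hand_R", t), track.point("hand_L", t)
            if (pr is not None and pl is not None
                    and _point_in_mask(pr, hr) and _point_in_mask(pl, hl)):
                correct["hands"] += 1
    return {k: 100.0 * correct[k] / present[k] if present[k] else float("nan")
            for k in correct}
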