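"""Synthetic mouse videos with exact ground truth, plus analytic fixtures.

The *modeled* mouse renders flat-colored elliptical patches on a uniform
background: a dark body ellipse, two green ears at the top of the body, a
pink nose above them, and two blue hands whose x/y positions follow
sinusoidal oscillators sampled at ``360°/period`` steps — the two hands
180° out of phase with a 12-frame default period (one reach cycle at
60 fps), and the body tilt oscillating in phase with the reaching hand.
Part geometry is chosen so no part occludes another, hence rendered pixels
of each part exactly equal its ground-truth mask.

The *empirical* variant renders the same parts at geometry supplied per
frame (e.g. measured from real video), so a tracker can be validated
end-to-end on realistic trajectories.

:func:`fixtures` provides the small deterministic inputs used by the
optical-flow, fractal-dimension, ICA and kinematics test oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import MaskArchive, pack_masks, unpack_masks
from .videoio import FrameStack

__all__ = ["SyntheticSpec", "GroundTruth", "modeled_mouse", "empirical_mouse",
           "fixtures", "TRUTH_OBJECTS"]

#: Ground-truth mask order (animal's right = image left; mouse faces camera).
TRUTH_OBJECTS = ("fur", "ear_R", "ear_L", "nose", "hand_R", "hand_L")


@dataclass
class SyntheticSpec:
    """Geometry, colors and oscillator settings of the modeled mouse."""

    height: int = 480
    width: int = 480
    fps: float = 60.0
    n_frames: int = 300
    px_per_mm: float = 2.0   # 140 px body major axis ~= a 70 mm mouse
    seed: int = 0
    # flat part colors, RGB in [0,1]
    colors: dict = field(default_factory=lambda: {
        "background": (0.50, 0.50, 0.50),
        "fur": (0.15, 0.12, 0.10),       # dark fur
        "ears": (0.10, 0.70, 0.20),      # painted green
        "nose": (0.95, 0.45, 0.60),      # painted pink
        "hands": (0.20, 0.30, 0.90),     # painted blue
        "string": (0.90, 0.85, 0.20),
    })
    # body ellipse: centroid (x=col, y=row), semi-axes (major vertical)
    body_center: tuple[float, float] = (240.0, 280.0)
    body_axes: tuple[float, float] = (70.0, 40.0)   # (semi-major, semi-minor)
    tilt_amp_deg: float = 3.0
    # ears: horizontal offset from body centre, row, semi-axes
    ear_dx: float = 28.0
    ear_row: float = 195.0
    ear_axes: tuple[float, float] = (10.0, 8.0)     # (rx, ry)
    # nose
    nose_row: float = 170.0
    nose_axes: tuple[float, float] = (7.0, 6.0)
    # hand oscillators
    hand_dx: float = 75.0
    hand_row: float = 160.0
    hand_axes: tuple[float, float] = (11.0, 9.0)
    hand_amp_y: float = 60.0
    hand_amp_x: float = 15.0
    period: int = 12                                 # frames per reach cycle
    phase_offset_deg: float = 180.0
    draw_string: bool = False
    string_col: float = 240.0
    string_width: float = 2.0

    def __post_init__(self) -> None:
        if self.period < 4:
            raise ValueError("oscillator period must be >= 4 frames")
        radius = 1.5 / 255.0
        names = list(self.colors)
        cols = np.array([self.colors[n] for n in names])
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                d = np.linalg.norm(cols[i] - cols[j])
                if d <= 2 * radius:
                    raise ValueError(
                        f"colors {names[i]} and {names[j]} are not separable")


@dataclass
class GroundTruth:
    """Exact per-frame part masks and geometry of a synthetic video."""

    masks: MaskArchive                 # bit-packed, objects = TRUTH_OBJECTS
    table: pd.DataFrame                # frame, part, x, y, major, minor, orientation

    def part_mask(self, part: str, t: int) -> np.ndarray:
        b = self.masks.objects.index(part)
        return ((self.masks.planes[..., t] >> b) & 1).astype(bool)

    def part_xy(self, part: str, t: int) -> tuple[float, float]:
        row = self.table[(self.table.part == part) & (self.table.frame == t)]
        return float(row.x.iloc[0]), float(row.y.iloc[0])


def _ellipse_mask(H: int, W: int, cx: float, cy: float, rmaj: float,
                  rmin: float, theta_deg: float) -> np.ndarray:
    """Pixels inside the ellipse; theta measured from horizontal, y up.

    Evaluated only inside the ellipse's bounding box for speed.
    """
    r0 = max(0, int(np.floor(cy - rmaj)) - 1)
    r1 = min(H, int(np.ceil(cy + rmaj)) + 2)
    c0 = max(0, int(np.floor(cx - rmaj)) - 1)
    c1 = min(W, int(np.ceil(cx + rmaj)) + 2)
    out = np.zeros((H, W), dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return out
    rr, cc = np.mgrid[r0:r1, c0:c1]
    x = cc - cx
    y = -(rr - cy)                     # y up
    th = np.radians(theta_deg)
    xr = x * np.cos(th) + y * np.sin(th)
    yr = -x * np.sin(th) + y * np.cos(th)
    out[r0:r1, c0:c1] = (xr / rmaj) ** 2 + (yr / rmin) ** 2 <= 1.0
    return out


def _hand_positions(spec: SyntheticSpec, t: np.ndarray):
    """Oscillator positions of the right (image-left) and left hands."""
    cx, _ = spec.body_center
    phase = 2 * np.pi * t / spec.period
    off = np.radians(spec.phase_offset_deg)
    # right hand (image left) is the reference "reaching" oscillator
    xr = cx - spec.hand_dx + spec.hand_amp_x * np.cos(phase)
    yr = spec.hand_row - spec.hand_amp_y * np.sin(phase)
    xl = cx + spec.hand_dx + spec.hand_amp_x * np.cos(phase + off)
    yl = spec.hand_row - spec.hand_amp_y * np.sin(phase + off)
    return (xr, yr), (xl, yl)


def modeled_mouse(spec: SyntheticSpec | None = None) -> tuple[FrameStack, GroundTruth]:
    """Render the modeled synthetic mouse and its exact ground truth."""
    spec = spec or SyntheticSpec()
    H, W, N = spec.height, spec.width, spec.n_frames
    t = np.arange(N)
    phase = 2 * np.pi * t / spec.period
    tilt = spec.tilt_amp_deg * np.sin(phase)       # in phase with right hand
    (xr, yr), (xl, yl) = _hand_positions(spec, t)
    cx, cy = spec.body_center

    # frame-major layout during rendering (contiguous writes), moved to the
    # stack's HxWx3xN axis order as a view afterwards
    frames = np.empty((N, H, W, 3), dtype=np.float32)
    planes = np.zeros((N, H, W), dtype=np.uint8)
    rows = []
    bg = np.asarray(spec.colors["background"], dtype=np.float32)
    part_colors = {
        "fur": spec.colors["fur"], "ear_R": spec.colors["ears"],
        "ear_L": spec.colors["ears"], "nose": spec.colors["nose"],
        "hand_R": spec.colors["hands"], "hand_L": spec.colors["hands"],
    }
    for i in range(N):
        geom = {
            "fur": (cx, cy, spec.body_axes[0], spec.body_axes[1],
                    90.0 - tilt[i]),
            "ear_R": (cx - spec.ear_dx, spec.ear_row,
                      spec.ear_axes[0], spec.ear_axes[1], 0.0),
            "ear_L": (cx + spec.ear_dx, spec.ear_row,
                      spec.ear_axes[0], spec.ear_axes[1], 0.0),
            "nose": (cx, spec.nose_row, spec.nose_axes[0],
                     spec.nose_axes[1], 0.0),
            "hand_R": (xr[i], yr[i], spec.hand_axes[0], spec.hand_axes[1], 0.0),
            "hand_L": (xl[i], yl[i], spec.hand_axes[0], spec.hand_axes[1], 0.0),
        }
        img = np.broadcast_to(bg, (H, W, 3)).copy()
        if spec.draw_string:
            c0 = int(round(spec.string_col - spec.string_width / 2))
            c1 = int(round(spec.string_col + spec.string_width / 2))
            img[:, c0:c1 + 1] = spec.colors["string"]
        for b, part in enumerate(TRUTH_OBJECTS):
            gx, gy, rmaj, rmin, th = geom[part]
            m = _ellipse_mask(H, W, gx, gy, rmaj, rmin, th)
            planes[i][m] |= np.uint8(1 << b)
            img[m] = part_colors[part]
            rows.append({"frame": i, "part": part, "x": gx, "y": gy,
                         "major": 2 * rmaj, "minor": 2 * rmin,
                         "orientation": th})
        frames[i] = img

    stack = FrameStack(frames=np.moveaxis(frames, 0, -1), fps=spec.fps,
                       px_per_mm=spec.px_per_mm, epoch=(0, N - 1))
    archive = MaskArchive(planes=np.moveaxis(planes, 0, -1),
                          objects=TRUTH_OBJECTS, epoch=(0, N - 1))
    truth = GroundTruth(masks=archive, table=pd.DataFrame(rows))
    return stack, truth


def empirical_mouse(trajectories: pd.DataFrame,
                    spec: SyntheticSpec | None = None) -> tuple[FrameStack, GroundTruth]:
    """Render parts at externally supplied per-frame geometry.

    ``trajectories`` is long-format with columns
    ``frame, part, x, y, major, minor, orientation`` (axis lengths are full
    lengths, orientation in degrees from horizontal, y up); parts must be
    drawn from :data:`TRUTH_OBJECTS`.
    """
    spec = spec or SyntheticSpec()
    required = {"frame", "part", "x", "y", "major", "minor", "orientation"}
    missing = required - set(trajectories.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns: {sorted(missing)}")
    frames_idx = np.sort(trajectories.frame.unique())
    N = len(frames_idx)
    H, W = spec.height, spec.width
    frames = np.empty((H, W, 3, N), dtype=np.float32)
    masks = np.zeros((len(TRUTH_OBJECTS), H, W, N), dtype=bool)
    bg = np.asarray(spec.colors["background"], dtype=np.float32)
    part_colors = {
        "fur": spec.colors["fur"], "ear_R": spec.colors["ears"],
        "ear_L": spec.colors["ears"], "nose": spec.colors["nose"],
        "hand_R": spec.colors["hands"], "hand_L": spec.colors["hands"],
    }
    for i, f in enumerate(frames_idx):
        img = np.broadcast_to(bg, (H, W, 3)).copy()
        sub = trajectories[trajectories.frame == f]
        for b, part in enumerate(TRUTH_OBJECTS):
            row = sub[sub.part == part]
            if row.empty:
                continue
            r = row.iloc[0]
            m = _ellipse_mask(H, W, r.x, r.y, r.major / 2, r.minor / 2,
                              r.orientation)
            masks[b, ..., i] = m
            img[m] = part_colors[part]
        frames[..., i] = img
    stack = FrameStack(frames=frames, fps=spec.fps, px_per_mm=spec.px_per_mm,
                       epoch=(int(frames_idx[0]), int(frames_idx[-1])))
    truth = GroundTruth(masks=pack_masks(masks, objects=TRUTH_OBJECTS),
                        table=trajectories.copy())
    return stack, truth


# ---------------------------------------------------------------------------
# Analytic fixtures
# ---------------------------------------------------------------------------

def fixtures(kind: str, **params):
    """Deterministic analytic fixtures for the test oracles.

    Kinds: ``translating_square``, ``translating_texture``, ``sierpinski``,
    ``filled_square``, ``blinking_sources``, ``sine_trajectory``.
    """
    if kind == "translating_square":
        size = params.get("size", 64)
        square = params.get("square", 16)
        shift = params.get("shift", 2)
        n = params.get("n", 2)
        img = np.full((size, size), 0.1)
        r0 = (size - square) // 2
        img[r0:r0 + square, r0:r0 + square] = 0.9
        frames = np.stack([np.roll(img, i * shift, axis=1) for i in range(n)],
                          axis=-1)
        return frames
    if kind == "translating_texture":
        size = params.get("size", 64)
        shift = params.get("shift", 1.0)     # may be sub-pixel (x direction)
        n = params.get("n", 2)
        seed = params.get("seed", 0)
        from scipy.ndimage import fourier_shift, gaussian_filter

        rng = np.random.default_rng(seed)
        base = gaussian_filter(rng.random((size, size)), 2.0)
        base = (base - base.min()) / (base.max() - base.min())
        frames = []
        for i in range(n):
            f = np.fft.ifftn(fourier_shift(np.fft.fftn(base), (0, i * shift)))
            frames.append(np.real(f))
        return np.stack(frames, axis=-1)
    if kind == "sierpinski":
        depth = params.get("depth", 8)
        size = 2 ** depth
        x, y = np.meshgrid(np.arange(size), np.arange(size))
        return ((x & y) == 0).astype(np.float64)
    if kind == "filled_square":
        size = params.get("size", 256)
        return np.ones((size, size))
    if kind == "blinking_sources":
        n_frames = params.get("n_frames", 40)
        size = params.get("size", 32)
        seed = params.get("seed", 0)
        rng = np.random.default_rng(seed)
        m1 = np.zeros((size, size), dtype=bool)
        m2 = np.zeros((size, size), dtype=bool)
        q = size // 4
        m1[q:2 * q, q:2 * q] = True
        m2[2 * q:3 * q, 2 * q:3 * q] = True
        a1 = rng.integers(0, 2, n_frames).astype(np.float64)
        a2 = rng.integers(0, 2, n_frames).astype(np.float64)
        frames = (m1[..., None] * a1[None, None, :]
                  + m2[..., None] * a2[None, None, :])
        return frames, (m1, m2), (a1, a2)
    if kind == "sine_trajectory":
        n = params.get("n", 600)
        fps = params.get("fps", 60.0)
        freq = params.get("freq", 3.0)
        amp = params.get("amp", 1.0)
        t = np.arange(n) / fps
        return t, amp * np.sin(2 * np.pi * freq * t)
    raise ValueError(f"unknown fixture kind {kind!r}")
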