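"""Kinematic time series, reach-cycle analysis and group comparisons.

Positions from the tracker are calibrated to millimetres; hand positions
are reported relative to the *lower-left* corner of the frame (y increases
upward, as in the published kinematic panels).  Head pose combines the two
ears and the nose: yaw is the natural log of the ratio of nose-ear
distances (0 when the head faces the camera squarely), roll is the angle of
the inter-ear line from horizontal, and pitch is the signed perpendicular
distance of the nose from the ear line (positive above).

Reach cycles are segmented from a hand's vertical trajectory: troughs are
string releases, peaks are grasps; the rise (release to grasp) and fall
(grasp to release) times, amplitudes and the dominant frequency summarise
the rhythm.  Cycles are averaged after linear time-normalisation, and group
scalars are compared with a two-sample t-test and Cohen's d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.signal import find_peaks

from .tracking import PoseTrack

__all__ = ["KinematicSeries", "ReachCycle", "GroupComparison",
           "body_series", "head_pose", "head_pose_series",
           "nose_string_distance", "hand_series", "segment_reach_cycles",
           "dominant_frequency", "timewarp_average", "compare_groups",
           "series_to_csv"]


@dataclass
class KinematicSeries:
    """A named, calibrated time series with validity flags."""

    name: str
    t: np.ndarray          # seconds
    values: np.ndarray
    valid: np.ndarray | None = None
    units: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        if self.t.shape != self.values.shape:
            raise ValueError("t and values must have the same length")

    def summary(self) -> dict:
        v = self.values[self.valid]
        if v.size == 0:
            return {"max": np.nan, "min": np.nan, "range": np.nan, "mean": np.nan}
        return {"max": float(v.max()), "min": float(v.min()),
                "range": float(v.max() - v.min()), "mean": float(v.mean())}


@dataclass(frozen=True)
class ReachCycle:
    """One release -> grasp -> release hand cycle."""

    start: int
    peak: int
    end: int
    rise_time: float       # s, release -> grasp
    fall_time: float       # s, grasp -> release
    amplitude: float       # peak minus preceding trough, series units

    def __post_init__(self) -> None:
        if not self.start < self.peak < self.end:
            raise ValueError("cycle indices must satisfy start < peak < end")


@dataclass(frozen=True)
class GroupComparison:
    t_statistic: float
    p_value: float
    cohens_d: float
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float


def _times(n: int, fps: float) -> np.ndarray:
    return np.arange(n) / fps


def body_series(track: PoseTrack, fps: float, px_per_mm: float) -> dict:
    """Body length (mm), tilt angle (deg), linear speed (mm/s) and angular
    speed (deg/s) per frame."""
    N = track.n_frames
    valid = track.valid["body"]
    if valid.sum() < 2:
        raise ValueError("body valid in fewer than 2 frames")
    t = _times(N, fps)
    length = track.body_major / px_per_mm
    angle = track.body_orientation.copy()
    cx = track.xy["body"][:, 0]
    cy = track.xy["body"][:, 1]
    lin = np.full(N, np.nan)
    ang = np.full(N, np.nan)
    d = np.hypot(np.diff(cx), np.diff(cy)) * fps / px_per_mm
    da = np.abs(np.diff(angle)) * fps
    ok = valid[1:] & valid[:-1]
    lin[1:][ok] = d[ok]
    ang[1:][ok] = da[ok]
    return {
        "body_length": KinematicSeries("body_length", t, length, valid, "mm"),
        "body_angle": KinematicSeries("body_angle", t, angle, valid, "deg"),
        "body_linear_speed": KinematicSeries("body_linear_speed", t, lin,
                                             units="mm/s"),
        "body_angular_speed": KinematicSeries("body_angular_speed", t, ang,
                                              units="deg/s"),
    }


def head_pose(ear_R: tuple[float, float], ear_L: tuple[float, float],
              nose: tuple[float, float], px_per_mm: float) -> dict:
    """Yaw (log distance ratio), roll (deg) and pitch (mm) for one frame.

    Coordinates are image (x = col, y = row); pitch is positive when the
    nose lies above the ear-ear line (toward the frame top).
    """
    dR = np.hypot(nose[0] - ear_R[0], nose[1] - ear_R[1])
    dL = np.hypot(nose[0] - ear_L[0], nose[1] - ear_L[1])
    if dR == 0 or dL == 0:
        raise ValueError("nose coincides with an ear")
    yaw = float(np.log(dR / dL))
    ex = ear_L[0] - ear_R[0]
    ey_up = -(ear_L[1] - ear_R[1])
    if ex == 0 and ey_up == 0:
        raise ValueError("coincident ears: roll undefined")
    roll = float(np.degrees(np.arctan2(ey_up, ex)))
    # signed distance of the nose from the ear line, normal toward frame top
    nx = nose[0] - ear_R[0]
    ny_up = -(nose[1] - ear_R[1])
    ear_len = np.hypot(ex, ey_up)
    cross = ex * ny_up - ey_up * nx          # positive above the line
    pitch = float(cross / ear_len / px_per_mm)
    return {"yaw": yaw, "roll": roll, "pitch": pitch}


def head_pose_series(track: PoseTrack, fps: float, px_per_mm: float) -> dict:
    """Yaw/roll/pitch series; pitch degrades to the vertical nose-ear
    distance when only one ear is valid."""
    N = track.n_frames
    t = _times(N, fps)
    yaw = np.full(N, np.nan)
    roll = np.full(N, np.nan)
    pitch = np.full(N, np.nan)
    for i in range(N):
        nose = track.point("nose", i)
        if nose is None:
            continue
        er = track.point("ear_R", i)
        el = track.point("ear_L", i)
        if er is not None and el is not None:
            hp = head_pose(er, el, nose, px_per_mm)
            yaw[i], roll[i], pitch[i] = hp["yaw"], hp["roll"], hp["pitch"]
        elif er is not None or el is not None:
            ear = er if er is not None else el
            pitch[i] = (ear[1] - nose[1]) / px_per_mm  # vertical fallback
    return {
        "head_yaw": KinematicSeries("head_yaw", t, yaw, units="log-ratio"),
        "head_roll": KinematicSeries("head_roll", t, roll, units="deg"),
        "head_pitch": KinematicSeries("head_pitch", t, pitch, units="mm"),
    }


def nose_string_distance(nose: tuple[float, float], string_mask: np.ndarray,
                         px_per_mm: float) -> float:
    """Shortest distance (mm) from the nose point to any string pixel."""
    string_mask = np.asarray(string_mask, dtype=bool)
    if not string_mask.any():
        return float("nan")
    rr, cc = np.nonzero(string_mask)
    d = np.hypot(cc - nose[0], rr - nose[1]).min()
    return float(d / px_per_mm)


def _interp_gaps(values: np.ndarray, max_gap: int = 3) -> np.ndarray:
    """Linearly fill NaN runs of length <= max_gap between valid samples."""
    out = values.copy()
    isnan = ~np.isfinite(out)
    if not isnan.any():
        return out
    idx = np.arange(out.size)
    runs = []
    start = None
    for i, bad in enumerate(isnan):
        if bad and start is None:
            start = i
        elif not bad and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, out.size))
    for s, e in runs:
        if s == 0 or e == out.size or (e - s) > max_gap:
            continue
        out[s:e] = np.interp(idx[s:e], [s - 1, e], [out[s - 1], out[e]])
    return out


def hand_series(track: PoseTrack, fps: float, px_per_mm: float,
                frame_height: int) -> dict:
    """Hand positions (mm, lower-left origin) and speeds (mm/s).

    Image row ``r`` maps to ``y = (H - 1 - r) / px_per_mm`` so y increases
    upward; speeds are central finite differences of position times fps.
    Isolated invalid runs of up to 3 frames are linearly interpolated.
    """
    N = track.n_frames
    t = _times(N, fps)
    out = {}
    for part in ("hand_R", "hand_L"):
        x = track.xy[part][:, 0].copy()
        r = track.xy[part][:, 1].copy()
        bad = ~track.valid[part]
        x[bad] = np.nan
        r[bad] = np.nan
        x = _interp_gaps(x / px_per_mm)
        y = _interp_gaps((frame_height - 1 - r) / px_per_mm)
        vx = np.gradient(x, 1.0 / fps)
        vy = np.gradient(y, 1.0 / fps)
        out[f"{part}_x"] = KinematicSeries(f"{part}_x", t, x, units="mm")
        out[f"{part}_y"] = KinematicSeries(f"{part}_y", t, y, units="mm")
        out[f"{part}_vx"] = KinematicSeries(f"{part}_vx", t, vx, units="mm/s")
        out[f"{part}_vy"] = KinematicSeries(f"{part}_vy", t, vy, units="mm/s")
    return out


def segment_reach_cycles(vertical: np.ndarray | KinematicSeries, fps: float,
                         smooth_window: int = 3,
                         prominence_frac: float = 0.10) -> list[ReachCycle]:
    """Segment a hand's vertical trajectory into reach cycles.

    The series is smoothed with a centred moving average; troughs (releases)
    and peaks (grasps) are local extrema with prominence at least
    ``prominence_frac`` of the series range.  Each trough -> peak -> trough
    triple forms one cycle.
    """
    v = vertical.values if isinstance(vertical, KinematicSeries) else np.asarray(vertical, dtype=np.float64)
    n = v.size
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        v = np.convolve(np.pad(v, pad, mode="edge"), kernel, mode="valid")[:n]
    prom = prominence_frac * np.ptp(v)
    if prom == 0:
        return []
    peaks, _ = find_peaks(v, prominence=prom)
    troughs, _ = find_peaks(-v, prominence=prom)
    if peaks.size == 0 or troughs.size < 2:
        return []
    cycles = []
    for i in range(troughs.size - 1):
        s, e = troughs[i], troughs[i + 1]
        inner = peaks[(peaks > s) & (peaks < e)]
        if inner.size == 0:
            continue
        p = inner[np.argmax(v[inner])]
        cycles.append(ReachCycle(
            start=int(s), peak=int(p), end=int(e),
            rise_time=(p - s) / fps, fall_time=(e - p) / fps,
            amplitude=float(v[p] - v[s]),
        ))
    return cycles


def dominant_frequency(series: np.ndarray | KinematicSeries, fps: float) -> float:
    """Frequency (Hz) of the largest non-DC Fourier component; NaN for a
    constant series."""
    v = series.values if isinstance(series, KinematicSeries) else np.asarray(series, dtype=np.float64)
    if v.size < 32:
        raise ValueError("need at least 32 samples")
    v = v - v.mean()
    if np.ptp(v) == 0:
        return float("nan")
    spec = np.abs(np.fft.rfft(v))
    freqs = np.fft.rfftfreq(v.size, d=1.0 / fps)
    k = 1 + int(np.argmax(spec[1:]))
    return float(freqs[k])


def timewarp_average(cycles: list[np.ndarray], L: int = 100) -> np.ndarray:
    """Average cycles after linear time-normalisation to ``L`` points.

    Applying this twice — per-animal means first, then across animals —
    gives the two-level group-average cycle.
    """
    if not cycles:
        raise ValueError("no cycles to average")
    if L < 2:
        raise ValueError("L must be >= 2")
    grid = np.linspace(0.0, 1.0, L)
    resampled = []
    for c in cycles:
        c = np.asarray(c, dtype=np.float64)
        if c.size < 2:
            raise ValueError("cycles need at least 2 samples")
        resampled.append(np.interp(grid, np.linspace(0, 1, c.size), c))
    return np.mean(resampled, axis=0)


def compare_groups(values_a, values_b, equal_var: bool = True) -> GroupComparison:
    """Two-sample t-test (pooled variance by default) with Cohen's d.

    Cohen's d is the absolute standardised mean difference using the pooled
    sample standard deviation; infinite when the pooled variance is zero but
    the means differ.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    na, nb = a.size, b.size
    pooled_var = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                  / (na + nb - 2))
    diff = abs(a.mean() - b.mean())
    if pooled_var == 0:
        d = 0.0 if diff == 0 else float("inf")
    else:
        d = diff / np.sqrt(pooled_var)
    return GroupComparison(
        t_statistic=float(t), p_value=float(p), cohens_d=float(d),
        mean_a=float(a.mean()), sem_a=float(sps.sem(a)),
        mean_b=float(b.mean()), sem_b=float(sps.sem(b)),
    )


def series_to_csv(series: dict, path) -> None:
    """Export named series as tidy CSV (frame, time_s, name, value, valid)."""
    rows = []
    for name, s in series.items():
        for i in range(s.t.size):
            rows.append({"frame": i, "time_s": s.t[i], "name": name,
                         "value": s.values[i], "valid": bool(s.valid[i])})
    pd.DataFrame(rows).to_csv(path, index=False)
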