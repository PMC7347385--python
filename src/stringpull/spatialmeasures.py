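"""Scalar spatial measures of a single 2D frame.

Three measures summarise the spatial structure of a measurement frame (a
mean frame, a PC/IC score image, a speed frame, ...):

* **spatial entropy** — Shannon entropy (bits) of the 256-bin histogram of
  the min-max rescaled pixel values;
* **sharpness** — mean gradient magnitude, ``sum |grad I| / (H*W)``, with
  central differences (one-sided at the borders);
* **Hausdorff (box-counting) fractal dimension** — slope of
  ``log N(eps)`` vs ``log eps`` after binarising the frame at its mean,
  with dyadic box sizes anchored at the top-left corner.

These are the scalars compared between experimental groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["SpatialMeasures", "spatial_entropy", "sharpness", "hausdorff_fd",
           "box_counts", "measure_frame"]


@dataclass(frozen=True)
class SpatialMeasures:
    spatial_entropy: float  # bits
    sharpness: float        # intensity / px
    hfd: float              # dimensionless, ~[0, 2]


def spatial_entropy(frame: np.ndarray, n_bins: int = 256) -> float:
    """Entropy in bits of the rescaled intensity histogram of a frame."""
    frame = np.asarray(frame, dtype=np.float64)
    if not np.isfinite(frame).all():
        raise ValueError("frame must be finite")
    lo, hi = frame.min(), frame.max()
    z = np.zeros_like(frame) if hi == lo else (frame - lo) / (hi - lo)
    idx = np.minimum((z * n_bins).astype(np.int64), n_bins - 1)
    counts = np.bincount(idx.ravel(), minlength=n_bins).astype(np.float64)
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def sharpness(frame: np.ndarray) -> float:
    """Mean gradient magnitude of the frame (central differences)."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape[0] < 2 or frame.shape[1] < 2:
        raise ValueError("sharpness needs at least a 2x2 frame")
    gy, gx = np.gradient(frame)
    return float(np.hypot(gx, gy).sum() / frame.size)


def box_counts(binary: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Occupied-box counts N(eps) for dyadic box sizes eps = 1, 2, 4, ...

    Boxes are anchored at (0, 0); partial boxes at the right/bottom edges
    are included.  Returns (eps, counts).
    """
    binary = np.asarray(binary, dtype=bool)
    H, W = binary.shape
    max_exp = int(np.floor(np.log2(min(H, W))))
    eps = 2 ** np.arange(max_exp + 1)
    counts = np.empty(eps.size, dtype=np.int64)
    for i, e in enumerate(eps):
        Hp = -(-H // e) * e
        Wp = -(-W // e) * e
        padded = np.zeros((Hp, Wp), dtype=bool)
        padded[:H, :W] = binary
        blocks = padded.reshape(Hp // e, e, Wp // e, e).any(axis=(1, 3))
        counts[i] = int(blocks.sum())
    return eps, counts


def hausdorff_fd(frame: np.ndarray, complement_first: bool = False) -> float:
    """Box-counting fractal dimension of a frame binarised at its mean.

    ``complement_first`` inverts intensities before binarisation (used for
    dark-fur animals whose body is darker than the background).
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape[0] < 4 or frame.shape[1] < 4:
        raise ValueError("hausdorff_fd needs at least a 4x4 frame")
    if complement_first:
        frame = frame.max() + frame.min() - frame
    if frame.max() == frame.min():
        # constant frame: mean-thresholding degenerates; occupancy is simply
        # whether the constant level is above zero
        binary = frame > 0
    else:
        binary = frame > frame.mean()
    if not binary.any():
        warnings.warn("frame is empty after binarisation; HFD set to 0")
        return 0.0
    eps, counts = box_counts(binary)
    x = np.log(eps.astype(np.float64))
    y = np.log(counts.astype(np.float64))
    slope = np.polyfit(x, y, 1)[0]
    return float(-slope)


def measure_frame(frame: np.ndarray, complement_first: bool = False) -> SpatialMeasures:
    """All three spatial measures of a frame."""
    return SpatialMeasures(
        spatial_entropy=spatial_entropy(frame),
        sharpness=sharpness(frame),
        hfd=hausdorff_fd(frame, complement_first=complement_first),
    )
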