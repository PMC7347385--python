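"""Loading, calibration and basic geometry of video frame stacks.

A :class:`FrameStack` is the calibrated unit of analysis: a stack of frames
covering one string-pulling epoch, together with the acquisition rate (fps)
and the spatial calibration (pixels per millimetre).  Pixels are always held
as floats in ``[0, 1]``; 8-bit inputs are divided by 255 on load.

Frames are indexed 0-based internally; the CLI reports 1-based frame numbers
to match on-video frame counters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "FrameStack",
    "ZoomWindow",
    "load_frames",
    "to_gray",
    "complement",
    "crop",
    "calibrate_scale",
]

#: BT.601 luma weights used for RGB -> gray conversion.
GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp")


@dataclass
class FrameStack:
    """A calibrated stack of frames for one analysis epoch.

    Parameters
    ----------
    frames : ndarray
        ``H x W x N`` (gray) or ``H x W x 3 x N`` (color), values in [0, 1].
    fps : float
        Acquisition rate, frames per second.
    px_per_mm : float
        Spatial calibration, pixels per millimetre.
    epoch : tuple of int
        (start, end) inclusive frame indices within the source video.
    resize_factor : float
        Spatial resampling factor applied at load time, in (0, 1].
    """

    frames: np.ndarray
    fps: float = 60.0
    px_per_mm: float = 1.0
    epoch: tuple[int, int] | None = None
    resize_factor: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim not in (3, 4):
            raise ValueError("frames must be HxWxN (gray) or HxWx3xN (color)")
        if self.frames.ndim == 4 and self.frames.shape[2] != 3:
            raise ValueError("color stacks must have 3 channels on axis 2")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be positive")
        lo, hi = float(self.frames.min(initial=0)), float(self.frames.max(initial=0))
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise ValueError(f"pixel values must lie in [0,1]; got [{lo}, {hi}]")

    # -- basic geometry ---------------------------------------------------
    @property
    def is_color(self) -> bool:
        return self.frames.ndim == 4

    @property
    def n_frames(self) -> int:
        return self.frames.shape[-1]

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of a single frame."""
        return self.frames.shape[0], self.frames.shape[1]

    def frame(self, i: int) -> np.ndarray:
        """Return frame ``i`` as ``H x W`` or ``H x W x 3``."""
        return self.frames[..., i]

    def with_frames(self, frames: np.ndarray) -> "FrameStack":
        return replace(self, frames=frames)


@dataclass(frozen=True)
class ZoomWindow:
    """A sub-frame window: 0-based top-left origin, half-open extent."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("window must be at least 1x1")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("window origin must be non-negative")

    def validate(self, frame_shape: tuple[int, int]) -> None:
        H, W = frame_shape[:2]
        if self.row0 + self.height > H or self.col0 + self.width > W:
            raise ValueError(
                f"window {self} exceeds frame bounds {H}x{W}"
            )

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row0, self.row0 + self.height),
            slice(self.col0, self.col0 + self.width),
        )


def _resize_frame(img: np.ndarray, factor: float) -> np.ndarray:
    """Area-averaging downsample (anti-aliased); identity for factor 1."""
    if factor == 1.0:
        return img
    inv = 1.0 / factor
    if abs(inv - round(inv)) < 1e-9:
        # integer block mean: exact area averaging
        b = int(round(inv))
        H, W = img.shape[:2]
        Hc, Wc = (H // b) * b, (W // b) * b
        img = img[:Hc, :Wc]
        if img.ndim == 2:
            return img.reshape(Hc // b, b, Wc // b, b).mean(axis=(1, 3))
        return img.reshape(Hc // b, b, Wc // b, b, -1).mean(axis=(1, 3))
    from skimage.transform import resize as _sk_resize

    out_shape = (
        max(1, int(round(img.shape[0] * factor))),
        max(1, int(round(img.shape[1] * factor))),
    )
    return _sk_resize(img, out_shape, anti_aliasing=True, preserve_range=True)


def _read_image(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float32) / 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(np.float32) / 65535.0
    else:
        arr = arr.astype(np.float32)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return arr


def load_frames(
    source: str | Path,
    epoch: tuple[int, int] | None = None,
    resize_factor: float = 1.0,
    fps: float = 60.0,
    px_per_mm: float = 1.0,
) -> FrameStack:
    """Load the epoch's frames from a video file or an image directory.

    ``source`` may be a directory of PNG/TIFF frames (sorted
    lexicographically) or a video file readable by imageio.  ``epoch`` is an
    inclusive (start, end) 0-based frame range; ``None`` means all frames.
    The spatial calibration is rescaled by ``resize_factor`` so physical
    units stay correct after downsampling.
    """
    if not 0 < resize_factor <= 1:
        raise ValueError("resize_factor must be in (0, 1]")
    source = Path(source)
    if not source.exists():
        raise FileNotFoundError(str(source))

    if source.is_dir():
        paths = sorted(
            p for p in source.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not paths:
            raise FileNotFoundError(f"no image frames in {source}")
        n_total = len(paths)
        start, end = epoch if epoch is not None else (0, n_total - 1)
        if not (0 <= start <= end < n_total):
            raise ValueError(f"epoch {start}..{end} outside source of {n_total} frames")
        frames = []
        for i in range(start, end + 1):
            try:
                img = _read_image(paths[i])
            except Exception as exc:  # pragma: no cover - IO failure path
                raise IOError(f"unreadable frame {i} ({paths[i].name}): {exc}") from exc
            frames.append(_resize_frame(img, resize_factor))
    else:
        import imageio.v3 as iio

        try:
            raw = iio.imread(source, index=None)
        except Exception as exc:
            raise IOError(
                f"cannot read video {source}: {exc}. "
                "Install an ffmpeg-backed imageio plugin or supply a frame directory."
            ) from exc
        raw = np.asarray(raw)
        if raw.ndim == 3:  # single frame
            raw = raw[None]
        n_total = raw.shape[0]
        start, end = epoch if epoch is not None else (0, n_total - 1)
        if not (0 <= start <= end < n_total):
            raise ValueError(f"epoch {start}..{end} outside source of {n_total} frames")
        frames = []
        for i in range(start, end + 1):
            img = raw[i]
            if img.dtype == np.uint8:
                img = img.astype(np.float32) / 255.0
            frames.append(_resize_frame(img, resize_factor))

    arr = np.stack(frames, axis=-1).astype(np.float32)
    return FrameStack(
        frames=arr,
        fps=fps,
        px_per_mm=px_per_mm * resize_factor,
        epoch=(start, end),
        resize_factor=resize_factor,
    )


def to_gray(stack: FrameStack) -> FrameStack:
    """Convert a color stack to grayscale with BT.601 luma weights."""
    if not stack.is_color:
        warnings.warn("stack is already grayscale; returning as-is")
        return stack
    gray = np.tensordot(
        stack.frames.transpose(0, 1, 3, 2), GRAY_WEIGHTS, axes=([3], [0])
    )
    gray = np.clip(gray, 0.0, 1.0).astype(np.float32)
    return stack.with_frames(gray)


def complement(stack: FrameStack) -> FrameStack:
    """Photometric complement ``v -> 1 - v`` (used for dark-fur animals)."""
    if stack.is_color:
        raise ValueError("complement expects a grayscale stack")
    return stack.with_frames(1.0 - stack.frames)


def crop(stack: FrameStack, window: ZoomWindow) -> FrameStack:
    """Crop every frame to the given zoom window; calibration unchanged."""
    window.validate(stack.shape)
    rs, cs = window.slices()
    return stack.with_frames(stack.frames[rs, cs])


def calibrate_scale(
    p1: tuple[float, float], p2: tuple[float, float], known_mm: float
) -> float:
    """Pixels-per-mm from two clicked points a known distance apart."""
    if known_mm <= 0:
        raise ValueError("known_mm must be positive")
    d = float(np.hypot(p1[0] - p2[0], p1[1] - p2[1]))
    if d == 0:
        raise ValueError("calibration points coincide")
    return d / known_mm
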