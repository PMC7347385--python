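"""Per-pixel temporal statistics of image or speed stacks.

Each operation reduces a stack to a single measurement frame (a
:class:`StatFrame`): every pixel's intensity (or speed) time series is
summarised by one number — mean, dispersion, shape, Fano factor, temporal
entropy or Higuchi fractal dimension.  The mean frame additionally yields the
*mean-position mask* (pixels above the global mean), which localises the
animal's average position and is used to extract masked value distributions
for group comparisons.

Conventions (fixed so results are bit-stable): sample (N-1) variance wherever
a standard deviation appears; skewness and kurtosis as biased population
moment ratios, kurtosis non-excess (normal -> 3); mode computed on values
quantised to 8-bit levels with ties broken toward the smallest level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "StatFrame",
    "PositionMask",
    "DistributionSummary",
    "TEMPORAL_KINDS",
    "temporal_stat",
    "fano_frame",
    "entropy_frame",
    "hifd_frame",
    "higuchi_fd",
    "mean_position_mask",
    "masked_distribution",
]

TEMPORAL_KINDS = (
    "mean", "median", "mode", "std", "skewness", "kurtosis",
    "fano", "entropy", "hifd",
)


@dataclass
class StatFrame:
    """A single 2D measurement frame plus its provenance."""

    values: np.ndarray
    kind: str
    source: str = "image"
    n_undefined: int = 0  # pixels flagged NaN (e.g. zero-mean Fano pixels)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("StatFrame values must be 2D")


@dataclass
class PositionMask:
    """Binary H x W mask of the animal's average position."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class DistributionSummary:
    """Gaussian-KDE summary of masked measurement values."""

    sample_mean: float
    kde_grid: np.ndarray
    pdf: np.ndarray
    cdf: np.ndarray


def _series(stack) -> np.ndarray:
    """Stack -> (n_pixels, N) float64 time-series matrix plus shape."""
    frames = stack.frames if hasattr(stack, "frames") else np.asarray(stack)
    if frames.ndim != 3:
        raise ValueError("temporal statistics expect a grayscale HxWxN stack")
    H, W, N = frames.shape
    return frames.reshape(H * W, N).astype(np.float64), (H, W)


def temporal_stat(stack, kind: str) -> StatFrame:
    """Per-pixel temporal statistic of the given kind."""
    if kind == "fano":
        return fano_frame(stack)
    if kind == "entropy":
        return entropy_frame(stack)
    if kind == "hifd":
        return hifd_frame(stack)
    if kind not in TEMPORAL_KINDS:
        raise ValueError(f"unknown statistic kind {kind!r}")
    X, (H, W) = _series(stack)
    N = X.shape[1]
    if kind in ("std", "skewness", "kurtosis") and N < 2:
        raise ValueError(f"{kind} needs at least 2 frames")
    if kind == "mean":
        out = X.mean(axis=1)
    elif kind == "median":
        out = np.median(X, axis=1)
    elif kind == "mode":
        q = np.clip(np.round(X * 255), 0, 255).astype(np.int64)
        out = sps.mode(q, axis=1).mode.astype(np.float64) / 255.0
    elif kind == "std":
        out = X.std(axis=1, ddof=1)
    elif kind == "skewness":
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)  # constant pixels
            out = sps.skew(X, axis=1, bias=True)
        out = np.where(X.std(axis=1) == 0, 0.0, out)
    else:  # kurtosis
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            out = sps.kurtosis(X, axis=1, fisher=False, bias=True)
        out = np.where(X.std(axis=1) == 0, 0.0, out)
    return StatFrame(values=out.reshape(H, W), kind=kind)


def fano_frame(stack) -> StatFrame:
    """Per-pixel Fano factor: sample variance over mean of the time series.

    Zero-mean pixels have no defined Fano factor; they are set to NaN and
    counted in ``n_undefined``.
    """
    X, (H, W) = _series(stack)
    if X.shape[1] < 2:
        raise ValueError("Fano factor needs at least 2 frames")
    mu = X.mean(axis=1)
    var = X.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(mu != 0, var / mu, np.nan)
    return StatFrame(values=f.reshape(H, W), kind="fano",
                     n_undefined=int(np.sum(mu == 0)))


def entropy_frame(stack, n_bins: int = 256) -> StatFrame:
    """Per-pixel temporal entropy in bits.

    Each series is min-max rescaled to [0, 1] (constant series become all
    zeros), histogrammed into ``n_bins`` equal bins, and Shannon entropy
    ``-sum p log2 p`` is taken of the normalised counts.
    """
    X, (H, W) = _series(stack)
    n_px, N = X.shape
    lo = X.min(axis=1, keepdims=True)
    rng = X.max(axis=1, keepdims=True) - lo
    safe = np.where(rng == 0, 1.0, rng)
    Z = np.where(rng == 0, 0.0, (X - lo) / safe)
    idx = np.minimum((Z * n_bins).astype(np.int64), n_bins - 1)
    flat = np.arange(n_px)[:, None] * n_bins + idx
    counts = np.bincount(flat.ravel(), minlength=n_px * n_bins)
    counts = counts.reshape(n_px, n_bins).astype(np.float64)
    p = counts / N
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log2(p), 0.0)
    return StatFrame(values=terms.sum(axis=1).reshape(H, W), kind="entropy")


def higuchi_fd(X: np.ndarray, kmax: int = 10) -> np.ndarray:
    """Higuchi fractal dimension of each row of an (n_series, N) matrix.

    For lag k and offset m, the normalised curve length is

        L_m(k) = [ sum_i |x(m+ik) - x(m+(i-1)k)| ] * (N-1) / (floor((N-1-m)/k) * k) / k

    averaged over the k offsets; the dimension is the slope of
    log L(k) vs log(1/k) fitted by least squares over k = 1..kmax.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n_series, N = X.shape
    if N <= 2 * kmax:
        raise ValueError(f"series length {N} too short for kmax={kmax}")
    logL = np.empty((kmax, n_series))
    for k in range(1, kmax + 1):
        Lk = np.zeros(n_series)
        for m in range(k):
            n_steps = (N - 1 - m) // k
            seg = X[:, m: m + n_steps * k + 1: k]
            length = np.abs(np.diff(seg, axis=1)).sum(axis=1)
            Lk += length * (N - 1) / (n_steps * k) / k
        logL[k - 1] = np.log(np.maximum(Lk / k, 1e-300))
    logk = np.log(np.arange(1, kmax + 1))
    # least-squares slope of logL against log(1/k) == -log k
    xk = -logk
    xc = xk - xk.mean()
    slope = (xc[:, None] * (logL - logL.mean(axis=0))).sum(axis=0) / (xc ** 2).sum()
    constant = np.ptp(X, axis=1) == 0
    return np.where(constant, 0.0, slope)


def hifd_frame(stack, kmax: int = 10) -> StatFrame:
    """Per-pixel Higuchi fractal dimension frame (default kmax = 10)."""
    X, (H, W) = _series(stack)
    fd = higuchi_fd(X, kmax=kmax)
    return StatFrame(values=fd.reshape(H, W), kind="hifd")


def mean_position_mask(mean_frame: StatFrame) -> PositionMask:
    """Pixels strictly above the global mean of the temporal mean frame."""
    if mean_frame.kind != "mean":
        raise ValueError("mean_position_mask expects the temporal mean frame")
    v = mean_frame.values
    return PositionMask(mask=v > v.mean())


def masked_distribution(frame: StatFrame, mask: PositionMask,
                        n_grid: int = 512) -> DistributionSummary:
    """Gaussian-KDE PDF/CDF of a measurement frame inside the position mask.

    The sample mean of the masked values is the per-animal summary used for
    group comparisons.  The KDE uses Scott's-rule bandwidth on a grid
    spanning the data range extended by three bandwidths.
    """
    values = frame.values[mask.mask]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("mask selects no finite values")
    sample_mean = float(values.mean())
    if np.ptp(values) == 0:
        grid = np.array([values[0]])
        return DistributionSummary(sample_mean, grid, np.array([np.inf]),
                                   np.array([1.0]))
    kde = sps.gaussian_kde(values)  # Scott's rule by default
    bw = kde.factor * values.std(ddof=1)
    grid = np.linspace(values.min() - 3 * bw, values.max() + 3 * bw, n_grid)
    pdf = kde(grid)
    cdf = np.concatenate([[0.0], cumulative_trapezoid(pdf, grid)])
    cdf = np.minimum(cdf, 1.0)
    return DistributionSummary(sample_mean, grid, pdf, cdf)


def export_statframe(frame: StatFrame, tiff_path, csv_path=None,
                     mask: PositionMask | None = None) -> None:
    """Write a measurement frame as 32-bit float TIFF, optionally with a
    one-row CSV summary (kind, spatial measures, masked mean)."""
    import tifffile

    tifffile.imwrite(tiff_path, frame.values.astype(np.float32))
    if csv_path is not None:
        import pandas as pd

        from .spatialmeasures import measure_frame

        finite = np.nan_to_num(frame.values, nan=0.0)
        m = measure_frame(finite)
        row = {"kind": frame.kind, "source": frame.source,
               "spatial_entropy": m.spatial_entropy, "sharpness": m.sharpness,
               "hfd": m.hfd, "n_undefined": frame.n_undefined}
        if mask is not None and mask.n_pixels:
            row["masked_mean"] = masked_distribution(frame, mask).sample_mean
        pd.DataFrame([row]).to_csv(csv_path, index=False)
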