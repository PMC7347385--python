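"""Color-model based segmentation, region extraction and the mask store.

Body parts (fur, ears, nose, hands, string) are segmented by color: the
user accumulates representative RGB triplets for each part over a handful of
frames (k-means proposes clusters inside a zoom window; accepted clusters
are unioned into a :class:`ColorModel`).  Three mask generators are
provided —

* :func:`mask_range`  — range search: a pixel matches if its Euclidean RGB
  distance (on the 0-255 scale) to any model color is at most ``radius``
  (default 1.5);
* :func:`mask_knn`    — nearest neighbour against model vs background colors;
* :func:`mask_grid`   — range search per grid cell with a minimum-count
  threshold that suppresses spurious isolated matches;

plus an optional MSER-style detector for the fast-moving hands.  Masks feed
region extraction (8-connected components with the moment-ellipse fit used
throughout the tracker) and are archived bit-packed, one byte plane per
frame holding up to eight object masks.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .videoio import FrameStack, ZoomWindow, to_gray

__all__ = [
    "MASK_OBJECTS", "ColorModel", "ColorCluster", "Region", "MaskArchive",
    "define_colors", "mask_range", "mask_knn", "mask_grid", "mask_mser",
    "regions", "merge_close_regions", "convex_hull_mask", "auto_zoom_window",
    "pack_masks", "unpack_masks", "save_archive", "load_archive",
]

#: Fixed bit order of the packed mask planes: fur = bit 0 ... string = bit 4.
MASK_OBJECTS = ("fur", "ears", "nose", "hands", "string")

#: Default k-means cluster counts per object kind.
DEFAULT_K = {"fur": 3, "ears": 3, "hands": 3, "nose": 7, "string": 7}


@dataclass
class ColorCluster:
    """One k-means color cluster proposed to the user."""

    centroid: np.ndarray          # RGB in [0,1]
    colors: np.ndarray            # member RGB triplets, (n, 3) in [0,1]

    @property
    def n_colors(self) -> int:
        return self.colors.shape[0]


@dataclass
class ColorModel:
    """Accumulated RGB triplets describing one object's colors."""

    object: str
    colors: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    k: int = 3

    def __post_init__(self) -> None:
        self.colors = np.asarray(self.colors, dtype=np.float64).reshape(-1, 3)

    @property
    def n_colors(self) -> int:
        return self.colors.shape[0]

    def add_cluster(self, cluster: ColorCluster) -> "ColorModel":
        """Union the cluster's colors into the model (deduplicated)."""
        merged = np.vstack([self.colors, cluster.colors])
        # dedupe on the 8-bit grid: identical displayed colors collapse
        key = np.round(merged * 255).astype(np.int64)
        _, idx = np.unique(key, axis=0, return_index=True)
        self.colors = merged[np.sort(idx)]
        return self

    def to_json(self) -> str:
        return json.dumps({
            "object": self.object, "k": self.k,
            "colors": self.colors.tolist(),
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ColorModel":
        d = json.loads(text)
        return cls(object=d["object"], colors=np.asarray(d["colors"]), k=d["k"])

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "ColorModel":
        return cls.from_json(Path(path).read_text())


def define_colors(frame: np.ndarray, rect: ZoomWindow, k: int = 3,
                  seed: int = 0) -> list[ColorCluster]:
    """Propose ``k`` color clusters from the pixels inside ``rect``.

    The clusters are returned for the user (or CLI) to accept into a
    :class:`ColorModel`; repeated accepts over several frames union colors.
    """
    from sklearn.cluster import KMeans

    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError("define_colors expects a color frame")
    rect.validate(frame.shape[:2])
    if k < 2:
        raise ValueError("k must be >= 2")
    rs, cs = rect.slices()
    pix = frame[rs, cs].reshape(-1, 3)
    uniq = np.unique(np.round(pix * 255).astype(np.int64), axis=0)
    if k > uniq.shape[0]:
        raise ValueError(f"k={k} exceeds the {uniq.shape[0]} distinct colors in rect")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(pix)
    clusters = []
    for j in range(k):
        members = pix[km.labels_ == j]
        key = np.round(members * 255).astype(np.int64)
        _, idx = np.unique(key, axis=0, return_index=True)
        clusters.append(ColorCluster(centroid=km.cluster_centers_[j],
                                     colors=members[np.sort(idx)]))
    return clusters


# ---------------------------------------------------------------------------
# Mask generation
# ---------------------------------------------------------------------------

def _color_pixels(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError("expected a color frame (HxWx3)")
    return frame


def mask_range(frame: np.ndarray, model: ColorModel,
               radius: float = 1.5) -> np.ndarray:
    """Range-search mask: pixel in iff within ``radius`` (8-bit RGB units)
    of any model color."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if model.n_colors == 0:
        raise ValueError("empty color model")
    frame = _color_pixels(frame)
    H, W, _ = frame.shape
    pix = frame.reshape(-1, 3) * 255.0
    if model.n_colors <= 16:
        # direct distance test beats a KD-tree for small color sets
        r2 = radius * radius
        hit = np.zeros(pix.shape[0], dtype=bool)
        for c in model.colors * 255.0:
            diff = pix - c
            hit |= np.einsum("ij,ij->i", diff, diff) <= r2
        return hit.reshape(H, W)
    d, _ = cKDTree(model.colors * 255.0).query(pix, k=1)
    return (d <= radius).reshape(H, W)


def mask_knn(frame: np.ndarray, model: ColorModel,
             background: ColorModel) -> np.ndarray:
    """Nearest-neighbour mask: pixel in iff its nearest color among
    model + background colors belongs to the model (ties go to background)."""
    if model.n_colors == 0 or background.n_colors == 0:
        raise ValueError("both color models must be nonempty")
    frame = _color_pixels(frame)
    H, W, _ = frame.shape
    pix = frame.reshape(-1, 3) * 255.0
    dm, _ = cKDTree(model.colors * 255.0).query(pix, k=1)
    db, _ = cKDTree(background.colors * 255.0).query(pix, k=1)
    return (dm < db).reshape(H, W)


def mask_grid(frame: np.ndarray, model: ColorModel, radius: float = 1.5,
              grid_size: int = 8, min_count: int = 2) -> np.ndarray:
    """Range mask per grid cell; cells with fewer than ``min_count`` matched
    pixels are zeroed, eliminating spurious isolated matches."""
    if grid_size < 1 or min_count < 1:
        raise ValueError("grid_size and min_count must be >= 1")
    m = mask_range(frame, model, radius)
    H, W = m.shape
    out = m.copy()
    for r0 in range(0, H, grid_size):
        for c0 in range(0, W, grid_size):
            cell = m[r0:r0 + grid_size, c0:c0 + grid_size]
            if cell.sum() < min_count:
                out[r0:r0 + grid_size, c0:c0 + grid_size] = False
    return out


def mask_mser(frame: np.ndarray, model: ColorModel, radius: float = 1.5,
              delta: int = 2, max_variation: float = 0.25,
              min_area: int = 10, n_levels: int = 32) -> np.ndarray:
    """Stable-extremal-region mask for the hands.

    A threshold-sweep detector: the grayscale frame is thresholded at
    ``n_levels`` levels (both polarities); connected components whose area
    is stable across ``delta`` neighbouring levels (relative change below
    ``max_variation``) are kept as candidate regions.  Candidates retaining
    at least one pixel within ``radius`` of a model color form the mask.
    """
    from skimage.measure import label

    frame = _color_pixels(frame)
    color_hits = mask_range(frame, model, radius)
    if not color_hits.any():
        import warnings

        warnings.warn("no model-colored pixels; MSER mask is empty")
        return np.zeros(frame.shape[:2], dtype=bool)
    gray = frame @ np.array([0.299, 0.587, 0.114])
    levels = np.linspace(gray.min(), gray.max(), n_levels + 2)[1:-1]
    out = np.zeros(frame.shape[:2], dtype=bool)
    for polarity in (1, -1):
        g = gray if polarity == 1 else -gray
        ts = levels if polarity == 1 else -levels[::-1]
        labelled = [label(g >= t, connectivity=2) for t in ts]
        for i in range(delta, len(ts) - delta):
            lab = labelled[i]
            for rid in range(1, lab.max() + 1):
                comp = lab == rid
                a = comp.sum()
                if a < min_area:
                    continue
                # area of the enclosing component delta levels below and the
                # surviving part delta levels above
                rr, cc = np.nonzero(comp)
                seed = (rr[0], cc[0])
                lo = labelled[i - delta]
                a_lo = np.sum(lo == lo[seed]) if lo[seed] else a
                hi = labelled[i + delta]
                a_hi = np.sum(comp & (hi > 0))
                if (a_lo - a_hi) / a <= max_variation and (comp & color_hits).any():
                    out |= comp
    return out


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

@dataclass
class Region:
    """A connected component with its moment-ellipse fit.

    ``centroid`` is (x, y) in image coordinates (x = column, y = row).
    ``orientation`` is the major-axis angle in degrees from horizontal with
    the y axis pointing up, in (-90, 90].  Axis lengths follow the
    equal-second-moments ellipse convention (a single pixel has major axis
    about 1.15 px from the 1/12 pixel-extent term).
    """

    pixels: np.ndarray            # (n, 2) array of (row, col)
    area: int
    centroid: tuple[float, float]
    orientation: float
    major_len: float
    minor_len: float

    def area_mm2(self, px_per_mm: float) -> float:
        return self.area / px_per_mm ** 2

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


def _region_from_pixels(pixels: np.ndarray) -> Region:
    rows = pixels[:, 0].astype(np.float64)
    cols = pixels[:, 1].astype(np.float64)
    x = cols
    y = -rows                      # y up for the orientation convention
    mx, my = x.mean(), y.mean()
    uxx = ((x - mx) ** 2).mean() + 1.0 / 12.0
    uyy = ((y - my) ** 2).mean() + 1.0 / 12.0
    uxy = ((x - mx) * (y - my)).mean()
    common = np.sqrt((uxx - uyy) ** 2 + 4 * uxy ** 2)
    major = 2.0 * np.sqrt(2.0) * np.sqrt(uxx + uyy + common)
    minor = 2.0 * np.sqrt(2.0) * np.sqrt(max(uxx + uyy - common, 0.0))
    theta = np.degrees(0.5 * np.arctan2(2 * uxy, uxx - uyy))
    if theta <= -90.0:
        theta += 180.0
    return Region(
        pixels=pixels,
        area=int(pixels.shape[0]),
        centroid=(float(mx), float(rows.mean())),
        orientation=float(theta),
        major_len=float(major),
        minor_len=float(minor),
    )


def regions(mask: np.ndarray, min_area_mm2: float = 0.0,
            px_per_mm: float | None = None) -> list[Region]:
    """8-connected components of a binary mask with moment-ellipse fits.

    Regions smaller than ``min_area_mm2`` (converted with ``px_per_mm``)
    are dropped — the hand tracker uses a 20 mm^2 floor.
    """
    from skimage.measure import label

    mask = np.asarray(mask, dtype=bool)
    if min_area_mm2 > 0 and px_per_mm is None:
        raise ValueError("px_per_mm required for an area threshold in mm^2")
    min_px = min_area_mm2 * px_per_mm ** 2 if min_area_mm2 > 0 else 0.0
    lab = label(mask, connectivity=2)
    out = []
    for rid in range(1, lab.max() + 1):
        pixels = np.argwhere(lab == rid)
        if pixels.shape[0] < min_px:
            continue
        out.append(_region_from_pixels(pixels))
    return out


def merge_close_regions(region_list: list[Region],
                        distance_px: float = 10.0) -> list[Region]:
    """Single-linkage merge of regions whose minimum pixel-to-pixel distance
    is at most ``distance_px``; ellipse properties are recomputed on unions."""
    if distance_px < 0:
        raise ValueError("distance_px must be non-negative")
    n = len(region_list)
    if n <= 1:
        return list(region_list)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    trees = [cKDTree(r.pixels) for r in region_list]
    for i in range(n):
        for j in range(i + 1, n):
            d = trees[i].query(region_list[j].pixels, k=1)[0].min()
            if d <= distance_px:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    merged = []
    for members in groups.values():
        if len(members) == 1:
            merged.append(region_list[members[0]])
        else:
            pixels = np.vstack([region_list[i].pixels for i in members])
            merged.append(_region_from_pixels(pixels))
    return merged


def convex_hull_mask(mask: np.ndarray) -> np.ndarray:
    """Filled convex hull of all set pixels (rejoins a string-split body)."""
    from skimage.morphology import convex_hull_image

    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("convex hull of an empty mask")
    return convex_hull_image(mask)


def auto_zoom_window(stack: FrameStack, fur_model: ColorModel,
                     margin_px: int = 10, radius: float = 1.5) -> ZoomWindow:
    """Bounding window of the body over the whole epoch, plus a margin."""
    H, W = stack.shape
    union = np.zeros((H, W), dtype=bool)
    for i in range(stack.n_frames):
        union |= mask_range(stack.frame(i), fur_model, radius)
    if not union.any():
        raise ValueError("no body pixels found in any frame")
    rr, cc = np.nonzero(union)
    r0 = max(0, rr.min() - margin_px)
    c0 = max(0, cc.min() - margin_px)
    r1 = min(H, rr.max() + 1 + margin_px)
    c1 = min(W, cc.max() + 1 + margin_px)
    return ZoomWindow(row0=int(r0), col0=int(c0),
                      height=int(r1 - r0), width=int(c1 - c0))


# ---------------------------------------------------------------------------
# Bit-packed mask archive
# ---------------------------------------------------------------------------

@dataclass
class MaskArchive:
    """Up to eight object masks bit-packed into one byte plane per frame."""

    planes: np.ndarray            # uint8, H x W x N
    objects: tuple[str, ...] = MASK_OBJECTS
    epoch: tuple[int, int] | None = None

    @property
    def n_frames(self) -> int:
        return self.planes.shape[-1]


def pack_masks(masks: np.ndarray, objects: tuple[str, ...] = MASK_OBJECTS,
               epoch: tuple[int, int] | None = None) -> MaskArchive:
    """Pack a boolean ``(n_objects, H, W, N)`` mask array into byte planes.

    Bit ``b`` of a byte corresponds to object ``objects[b]`` (fur = bit 0).
    """
    masks = np.asarray(masks, dtype=bool)
    if masks.ndim != 4:
        raise ValueError("expected masks of shape (n_objects, H, W, N)")
    n_obj = masks.shape[0]
    if n_obj > 8:
        raise ValueError("at most 8 masks fit in a byte plane")
    if len(objects) != n_obj:
        raise ValueError("objects tuple must match the number of masks")
    planes = np.zeros(masks.shape[1:], dtype=np.uint8)
    for b in range(n_obj):
        planes |= (masks[b].astype(np.uint8) << b)
    return MaskArchive(planes=planes, objects=tuple(objects), epoch=epoch)


def unpack_masks(archive: MaskArchive) -> np.ndarray:
    """Inverse of :func:`pack_masks`; lossless."""
    n_obj = len(archive.objects)
    out = np.empty((n_obj,) + archive.planes.shape, dtype=bool)
    for b in range(n_obj):
        out[b] = (archive.planes >> b) & 1
    return out


def save_archive(archive: MaskArchive, path: str | Path) -> None:
    """Write the archive as zlib-compressed planes with a JSON header."""
    path = Path(path)
    header = json.dumps({
        "H": archive.planes.shape[0], "W": archive.planes.shape[1],
        "N": archive.planes.shape[2], "objects": list(archive.objects),
        "epoch": archive.epoch,
    }).encode()
    payload = zlib.compress(archive.planes.tobytes())
    with open(path, "wb") as fh:
        fh.write(len(header).to_bytes(4, "little"))
        fh.write(header)
        fh.write(payload)


def load_archive(path: str | Path) -> MaskArchive:
    with open(path, "rb") as fh:
        n = int.from_bytes(fh.read(4), "little")
        header = json.loads(fh.read(n).decode())
        planes = np.frombuffer(zlib.decompress(fh.read()), dtype=np.uint8)
    planes = planes.reshape(header["H"], header["W"], header["N"])
    epoch = tuple(header["epoch"]) if header["epoch"] else None
    return MaskArchive(planes=planes.copy(), objects=tuple(header["objects"]),
                       epoch=epoch)
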