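"""Weed segmentation: excess-green index -> Otsu -> morphology -> component filter.

Crops are detected upstream (bounding boxes are an input); everything green
that is left after masking the crop boxes out of the image is treated as
weed foliage.  The excess-green index ExG = 2G - R - B separates green
vegetation from soil, Otsu's threshold binarises the normalised index map,
a morphological opening removes specks, and connected components smaller
than the minimum connected domain size (MCDS) are discarded.  Each
surviving component yields a morphological centre (pixel-mean centroid) and
a minimum outer rectangle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .geometry import WorldPoint

__all__ = [
    "SegConfig",
    "Component",
    "ComponentSet",
    "Weed",
    "CalibratedCamera",
    "exg_map",
    "normalize_exg",
    "otsu_binarize",
    "morph_refine",
    "filter_components",
    "extract_weeds",
    "mask_crops",
    "pixel_to_robot",
    "segment_weeds",
]


@dataclass(frozen=True)
class SegConfig:
    """Segmentation knobs; defaults follow the field-tested settings."""

    mcds: int = 50  # minimum connected domain size (px)
    kernel_size: int = 3
    erode_iterations: int = 1
    dilate_iterations: int = 1
    rect_mode: str = "axis"  # "axis" or "rotated"
    clip_negative_exg: bool = False
    # vegetation by definition has 2G > R + B; requiring raw ExG above this
    # floor stops Otsu from hallucinating a foreground class out of soil
    # noise on images that contain no green matter at all
    greenness_floor: int = 0

    def __post_init__(self) -> None:
        if self.mcds < 1:
            raise ValueError("mcds must be >= 1")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel size must be odd")
        if self.rect_mode not in ("axis", "rotated"):
            raise ValueError("rect_mode must be 'axis' or 'rotated'")


def _as_rgb(img: np.ndarray) -> np.ndarray:
    a = np.asarray(img)
    if a.ndim != 3 or a.shape[2] < 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    return a[..., :3]


def exg_map(img: np.ndarray) -> np.ndarray:
    """Per-pixel excess-green index 2G - R - B, signed, range [-510, 510]."""
    rgb = _as_rgb(img).astype(np.int16)
    return (2 * rgb[..., 1] - rgb[..., 0] - rgb[..., 2]).astype(np.int16)


def normalize_exg(exg: np.ndarray, clip_negative: bool = False) -> np.ndarray:
    """Min-max rescale the signed index to the 8-bit range [0, 255]."""
    x = exg.astype(np.float64)
    if clip_negative:
        x = np.clip(x, 0, None)
    lo, hi = float(x.min()), float(x.max())
    if hi - lo < 1e-12:
        return np.zeros_like(x, dtype=np.uint8)
    return np.round((x - lo) / (hi - lo) * 255.0).astype(np.uint8)


def otsu_binarize(gray: np.ndarray) -> np.ndarray:
    """Binarise with the threshold maximising between-class variance.

    Foreground is strictly above the threshold.  A constant image has no
    two classes to separate; it yields an empty foreground with a warning.
    """
    g = np.asarray(gray)
    if g.min() == g.max():
        warnings.warn("constant image: Otsu threshold undefined, empty foreground")
        return np.zeros(g.shape, dtype=bool)
    thr = threshold_otsu(g.astype(np.uint8) if g.dtype != np.uint8 else g)
    return g > thr


def _cross_kernel(size: int) -> np.ndarray:
    k = np.zeros((size, size), dtype=bool)
    mid = size // 2
    k[mid, :] = True
    k[:, mid] = True
    return k


def morph_refine(mask: np.ndarray, cfg: SegConfig = SegConfig()) -> np.ndarray:
    """Opening (erode then dilate) to drop sub-kernel specks."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return m
    k = _cross_kernel(cfg.kernel_size)
    out = m
    for _ in range(cfg.erode_iterations):
        out = ndimage.binary_erosion(out, structure=k)
    for _ in range(cfg.dilate_iterations):
        out = ndimage.binary_dilation(out, structure=k)
    return out


@dataclass(frozen=True)
class Component:
    area: int
    centroid: tuple[float, float]  # (row, col), sub-pixel
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col) half-open
    coords: np.ndarray = field(repr=False)  # (n, 2) member pixel (row, col)


@dataclass(frozen=True)
class ComponentSet:
    components: tuple[Component, ...]
    mcds: int

    def __len__(self) -> int:
        return len(self.components)


def filter_components(mask: np.ndarray, mcds: int = 50) -> ComponentSet:
    """Label 8-connected components and keep those with area >= mcds."""
    lab = label(np.asarray(mask, dtype=bool), connectivity=2)
    kept = []
    for rp in regionprops(lab):
        if rp.area >= mcds:
            kept.append(
                Component(
                    area=int(rp.area),
                    centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                    bbox=tuple(int(v) for v in rp.bbox),
                    coords=rp.coords.copy(),
                )
            )
    # stable ordering by top-left member pixel
    kept.sort(key=lambda c: (c.bbox[0], c.bbox[1]))
    return ComponentSet(components=tuple(kept), mcds=mcds)


def _rotated_rect(coords: np.ndarray) -> np.ndarray:
    """Minimum-area rotated rectangle corners, (4, 2) in (row, col)."""
    from shapely import MultiPoint

    # treat each pixel as a unit square so single-row blobs stay 2-D
    pts = MultiPoint([(c, r) for r, c in coords])
    rect = pts.buffer(0.5, cap_style="square").minimum_rotated_rectangle
    xy = np.asarray(rect.exterior.coords)[:4]
    return xy[:, ::-1]  # back to (row, col)


@dataclass(frozen=True)
class Weed:
    centroid: tuple[float, float]  # (row, col) px
    area: int
    bbox: tuple[int, int, int, int]
    rect: np.ndarray = field(repr=False)  # (4, 2) rectangle corners (row, col)


def extract_weeds(components: ComponentSet, rect_mode: str = "axis") -> list[Weed]:
    """Morphological centre + minimum outer rectangle per component."""
    weeds = []
    for c in components.components:
        if rect_mode == "rotated":
            rect = _rotated_rect(c.coords)
        else:
            r0, c0, r1, c1 = c.bbox
            rect = np.array([[r0, c0], [r0, c1], [r1, c1], [r1, c0]], dtype=float)
        weeds.append(Weed(centroid=c.centroid, area=c.area, bbox=c.bbox, rect=rect))
    return weeds


def mask_crops(img: np.ndarray, boxes) -> np.ndarray:
    """Black out crop bounding boxes so crop foliage never enters the weed mask.

    ``boxes`` is an iterable of (xmin, ymin, xmax, ymax) pixel boxes
    (half-open); boxes are clipped to the image bounds.  Filling with black
    preserves global pixel coordinates for the weed positions.
    """
    out = _as_rgb(img).copy()
    h, w = out.shape[:2]
    for box in boxes:
        xmin, ymin, xmax, ymax = (int(round(v)) for v in _box_tuple(box))
        xmin, xmax = max(0, xmin), min(w, xmax)
        ymin, ymax = max(0, ymin), min(h, ymax)
        if xmin < xmax and ymin < ymax:
            out[ymin:ymax, xmin:xmax] = 0
    return out


def _box_tuple(box):
    if hasattr(box, "xmin"):
        return (box.xmin, box.ymin, box.xmax, box.ymax)
    return tuple(box)


@dataclass(frozen=True)
class CalibratedCamera:
    """Pixel -> robot-frame map: uniform scale plus a fixed translation.

    The camera looks straight down; the robot advances a fixed horizontal
    distance between imaging and weeding, which is folded into the offset.
    """

    mm_per_px: float
    camera_origin_world: tuple[float, float] = (0.0, 0.0)
    advance_offset_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")


def pixel_to_robot(pt_px: tuple[float, float], calib: CalibratedCamera) -> WorldPoint:
    """Map an image pixel (x, y) = (col, row) to ground-plane world mm."""
    x_px, y_px = pt_px
    x = x_px * calib.mm_per_px + calib.camera_origin_world[0] + calib.advance_offset_mm[0]
    y = y_px * calib.mm_per_px + calib.camera_origin_world[1] + calib.advance_offset_mm[1]
    return WorldPoint(x, y, 0.0)


def robot_to_pixel(p: WorldPoint, calib: CalibratedCamera) -> tuple[float, float]:
    x = (p.x - calib.camera_origin_world[0] - calib.advance_offset_mm[0]) / calib.mm_per_px
    y = (p.y - calib.camera_origin_world[1] - calib.advance_offset_mm[1]) / calib.mm_per_px
    return (x, y)


def segment_weeds(img: np.ndarray, crop_boxes=(), cfg: SegConfig = SegConfig()) -> list[Weed]:
    """Full chain: mask crops -> ExG -> Otsu + greenness floor -> opening ->
    MCDS filter."""
    masked = mask_crops(img, crop_boxes)
    exg = exg_map(masked)
    gray = normalize_exg(exg, clip_negative=cfg.clip_negative_exg)
    mask = otsu_binarize(gray) & (exg > cfg.greenness_floor)
    mask = morph_refine(mask, cfg)
    comps = filter_components(mask, cfg.mcds)
    return extract_weeds(comps, cfg.rect_mode)
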