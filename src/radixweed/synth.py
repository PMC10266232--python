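"""Ground-truthed synthetic fixtures: field images and 3-D spray scenes.

``gen_field_image`` renders a soil-coloured background with green weed
blobs of controlled pixel area and larger "crop" plants whose bounding
boxes are recorded, emulating a nadir view of a ridge planted with an
erect-growing crop.  The drawn masks are the ground truth — centroids and
areas are taken from the rasterised blob, never re-measured from the
rendered image.  ``gen_spray_scene`` draws feasible planning scenes (two
weed points with one crop cylinder between them), and
``gen_detection_tables`` builds box sets that reproduce requested TP/FP/FN
counts exactly under greedy IoU-0.5 matching.

What the images do NOT emulate: sunlight and overexposure, cast shadows,
leaf texture, terrain tilt, and adhering weed clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import CropObstacle, TrajectoryParams, WorldPoint

__all__ = [
    "ImageSceneConfig",
    "SpraySceneConfig",
    "FieldTruth",
    "PlacementError",
    "gen_field_image",
    "gen_spray_scene",
    "gen_detection_tables",
    "reference_scene",
]


class PlacementError(RuntimeError):
    """Raised when blobs cannot be placed without overlap."""


@dataclass(frozen=True)
class ImageSceneConfig:
    """Field-image generator knobs.

    Defaults emulate the acquisition regime of the segmentation study:
    1200x1200 nadir frames, a few tens of weeds of 100-900 px, a handful of
    larger crop plants, and a green/soil excess-green contrast of at least
    60 index units.
    """

    height: int = 1200
    width: int = 1200
    n_weeds: int = 30
    weed_area_min: int = 100
    weed_area_max: int = 900
    n_crops: int = 4
    crop_area_min: int = 1500
    crop_area_max: int = 4000
    soil_color: tuple[int, int, int] = (130, 85, 60)  # dry brown loam, ExG -20
    soil_noise: int = 12
    min_exg_contrast: int = 60
    blob_noise: int = 8
    min_gap_px: int = 6
    seed: int = 0
    max_retries: int = 200


@dataclass(frozen=True)
class FieldTruth:
    """Exact as-drawn ground truth for one generated field image."""

    weed_centroids: np.ndarray  # (n, 2) (row, col)
    weed_areas: np.ndarray  # (n,)
    weed_boxes: np.ndarray  # (n, 4) (xmin, ymin, xmax, ymax), half-open
    crop_boxes: np.ndarray  # (m, 4)


def _blob_mask(rng: np.random.Generator, area_lo: int, area_hi: int, retries: int = 60):
    """Rasterise an irregular ellipse-ish blob with area in [lo, hi].

    Returns (mask, rows, cols) with the mask tightly cropped.
    """
    for _ in range(retries):
        target = rng.uniform(area_lo, area_hi)
        aspect = rng.uniform(0.6, 1.6)
        a = np.sqrt(target / np.pi * aspect)
        b = np.sqrt(target / np.pi / aspect)
        rot = rng.uniform(0, np.pi)
        # boundary wobble: two low-order harmonics
        amp1, amp2 = rng.uniform(0.0, 0.12, size=2)
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        rmax = max(a, b) * 1.3 + 2
        n = int(np.ceil(2 * rmax)) + 1
        yy, xx = np.mgrid[0:n, 0:n]
        cy = cx = (n - 1) / 2.0
        dy, dx = yy - cy, xx - cx
        xr = dx * np.cos(rot) + dy * np.sin(rot)
        yr = -dx * np.sin(rot) + dy * np.cos(rot)
        phi = np.arctan2(yr, xr)
        wob = 1.0 + amp1 * np.cos(2 * phi + ph1) + amp2 * np.cos(3 * phi + ph2)
        mask = (xr / a) ** 2 + (yr / b) ** 2 <= wob**2
        area = int(mask.sum())
        if area_lo <= area <= area_hi:
            rs, cs = np.nonzero(mask)
            r0, r1 = rs.min(), rs.max() + 1
            c0, c1 = cs.min(), cs.max() + 1
            return mask[r0:r1, c0:c1]
    raise PlacementError("could not rasterise a blob within the area bounds")


def _place(
    rng: np.random.Generator,
    occupied: np.ndarray,
    blob: np.ndarray,
    gap: int,
    retries: int,
) -> tuple[int, int]:
    """Find a top-left anchor where blob (padded by gap) is free; mark it."""
    H, W = occupied.shape
    h, w = blob.shape
    if h + 2 * gap >= H or w + 2 * gap >= W:
        raise PlacementError("blob larger than image")
    for _ in range(retries):
        r = rng.integers(gap, H - h - gap)
        c = rng.integers(gap, W - w - gap)
        window = occupied[r - gap : r + h + gap, c - gap : c + w + gap]
        if not window.any():
            occupied[r : r + h, c : c + w] |= blob
            return int(r), int(c)
    raise PlacementError("no free placement found after bounded retries")


def _green_color(rng: np.random.Generator, soil_exg: float, contrast: int, noise: int):
    """Sample a green-dominant RGB whose ExG clears soil by >= contrast."""
    for _ in range(200):
        g = int(rng.integers(130, 210))
        r = int(rng.integers(40, 100))
        b = int(rng.integers(30, 90))
        # reserve headroom for per-pixel noise on both soil and blob
        if 2 * g - r - b >= soil_exg + contrast + 3 * noise:
            return (r, g, b)
    raise PlacementError("could not sample a green colour with enough contrast")


def gen_field_image(cfg: ImageSceneConfig = ImageSceneConfig()):
    """Render one field image; returns (image uint8 HxWx3, FieldTruth)."""
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.height, cfg.width
    soil = np.array(cfg.soil_color, dtype=np.int16)
    img = soil[None, None, :] + rng.integers(
        -cfg.soil_noise, cfg.soil_noise + 1, size=(H, W, 3), dtype=np.int16
    )
    soil_exg = float(2 * soil[1] - soil[0] - soil[2])
    occupied = np.zeros((H, W), dtype=bool)

    def paint(blob: np.ndarray, r: int, c: int, color) -> None:
        h, w = blob.shape
        patch = img[r : r + h, c : c + w]
        noise = rng.integers(-cfg.blob_noise, cfg.blob_noise + 1, size=(h, w, 3))
        patch[blob] = (np.array(color)[None, :] + noise[blob]).astype(np.int16)

    crop_boxes = []
    for _ in range(cfg.n_crops):
        blob = _blob_mask(rng, cfg.crop_area_min, cfg.crop_area_max)
        r, c = _place(rng, occupied, blob, cfg.min_gap_px, cfg.max_retries)
        color = _green_color(rng, soil_exg, cfg.min_exg_contrast, cfg.blob_noise)
        paint(blob, r, c, color)
        h, w = blob.shape
        crop_boxes.append((c, r, c + w, r + h))

    cents, areas, wboxes = [], [], []
    for _ in range(cfg.n_weeds):
        blob = _blob_mask(rng, cfg.weed_area_min, cfg.weed_area_max)
        r, c = _place(rng, occupied, blob, cfg.min_gap_px, cfg.max_retries)
        color = _green_color(rng, soil_exg, cfg.min_exg_contrast, cfg.blob_noise)
        paint(blob, r, c, color)
        rs, cs = np.nonzero(blob)
        cents.append((r + rs.mean(), c + cs.mean()))
        areas.append(int(blob.sum()))
        h, w = blob.shape
        wboxes.append((c, r, c + w, r + h))

    truth = FieldTruth(
        weed_centroids=np.array(cents, dtype=float).reshape(-1, 2),
        weed_areas=np.array(areas, dtype=int),
        weed_boxes=np.array(wboxes, dtype=int).reshape(-1, 4),
        crop_boxes=np.array(crop_boxes, dtype=int).reshape(-1, 4),
    )
    return np.clip(img, 0, 255).astype(np.uint8), truth


@dataclass(frozen=True)
class SpraySceneConfig:
    """Planning-scene generator: ranges in mm; scenes feasible by construction."""

    pair_distance: tuple[float, float] = (200.0, 400.0)
    w1_range: tuple[float, float] = (30.0, 80.0)
    w2_range: tuple[float, float] = (20.0, 60.0)
    h3_range: tuple[float, float] = (100.0, 160.0)
    ascent_h1: float = 20.0
    transition_h2: float = 150.0
    clearance_margin: float = 0.0
    seed: int = 0
    max_retries: int = 100


def gen_spray_scene(cfg: SpraySceneConfig = SpraySceneConfig()):
    """Draw (S, E, CropObstacle, TrajectoryParams), feasible by construction."""
    rng = np.random.default_rng(cfg.seed)
    params = TrajectoryParams(
        ascent_h1=cfg.ascent_h1,
        transition_h2=cfg.transition_h2,
        clearance_margin=cfg.clearance_margin,
    )
    for _ in range(cfg.max_retries):
        L = rng.uniform(*cfg.pair_distance)
        w1 = rng.uniform(*cfg.w1_range)
        w2 = rng.uniform(*cfg.w2_range)
        h3 = rng.uniform(*cfg.h3_range)
        if params.apex <= h3 + cfg.clearance_margin:
            continue
        if w1 + 2 * w2 >= L - 1.0:  # obstacle must fit between the weeds
            continue
        theta = rng.uniform(0, 2 * np.pi)
        s = WorldPoint(rng.uniform(-100, 100), rng.uniform(-100, 100), 0.0)
        e = WorldPoint(s.x + L * np.cos(theta), s.y + L * np.sin(theta), 0.0)
        return s, e, CropObstacle(w1, w2, h3), params
    raise PlacementError("no feasible spray scene drawn within bounded retries")


def reference_scene():
    """The benchmark simulation scene: plant height 150 mm, planning height
    170 mm, cylinder axis 100 mm from S (w1 = 60, hence w2 = 40), symmetric
    weed pair 200 mm apart."""
    s = WorldPoint(0.0, 0.0, 0.0)
    e = WorldPoint(200.0, 0.0, 0.0)
    obstacle = CropObstacle(standoff_w1=60.0, radius_w2=40.0, height_h3=150.0)
    params = TrajectoryParams(ascent_h1=20.0, transition_h2=150.0)
    return s, e, obstacle, params


def gen_detection_tables(tp: int, fp: int, fn: int, seed: int = 0):
    """Box sets whose greedy matching at IoU 0.5 yields exactly (tp, fp, fn).

    True positives are predictions coincident with their ground-truth box;
    false positives sit on a disjoint grid.  Returns (preds, gts) with preds
    as (box, confidence) pairs.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    size, pitch = 20, 40

    def grid_box(i: int, row_offset: int) -> tuple[float, float, float, float]:
        per_row = 1000
        r, c = divmod(i, per_row)
        x = c * pitch
        y = (2 * r + row_offset) * pitch
        return (float(x), float(y), float(x + size), float(y + size))

    gts = [grid_box(i, 0) for i in range(tp + fn)]
    preds = [(gts[i], float(rng.uniform(0.6, 1.0))) for i in range(tp)]
    preds += [
        (grid_box(i, 1), float(rng.uniform(0.1, 0.5))) for i in range(fp)
    ]
    return preds, gts
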