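"""Embryo localization and ER/RR/TE region construction.

The embryo is found on a binarized gradient image with a two-stage circular
Hough transform (CHT): radii 100-150 px first, then 150-250 px, the two
candidate circles compared by accumulator metric with ties broken toward the
larger radius.  From the winning circle three regions are derived:

* ER — disc of radius r + 5 px (embryo including the zona pellucida),
* RR — disc of radius r - 40 px (ICM + blastocoel, trophectoderm removed),
* TE — the annulus ER \\ RR (essentially the trophectoderm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import hough_circle

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import DegenerateRegionError, DetectionError, InputError

log = logging.getLogger("blastoquant")


@dataclass(frozen=True)
class EmbryoCircle:
    """Detected embryo circumference (0-based pixel coordinates, x = column)."""

    center_x: float
    center_y: float
    radius: float
    metric: float  # normalized accumulator peak, ~fraction of supported perimeter
    stage: int     # 1: radii 100-150, 2: radii 150-250
    diagnostics: tuple = field(default=(), compare=False)


@dataclass
class RegionMasks:
    """ER/RR/TE masks plus the ER-bounding-square crop of the image.

    Full-frame boolean masks live in ``er_mask``/``rr_mask``/``te_mask``;
    ``crop`` is the greyscale sub-image over the ER bounding square (side
    2*round(r+5)), with companion cropped masks flagging which crop pixels
    belong to each region (everything else is background, including any part
    of the square clipped at the image border).
    """

    circle: EmbryoCircle
    er_mask: np.ndarray
    rr_mask: np.ndarray
    te_mask: np.ndarray
    crop: np.ndarray
    crop_er_mask: np.ndarray
    crop_rr_mask: np.ndarray
    crop_te_mask: np.ndarray
    crop_origin: tuple[int, int]  # (row, col) of crop[0,0] in the full frame
    total_area: int               # true pixels in er_mask
    radius_er: float              # r + 5 by definition, even when clipped


def gradient_magnitude(img: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude, linearly rescaled to [0, 255] uint8."""
    f = np.asarray(img, dtype=np.float64)
    gx = ndimage.sobel(f, axis=1)
    gy = ndimage.sobel(f, axis=0)
    mag = np.hypot(gx, gy)
    peak = mag.max()
    if peak > 0:
        mag *= 255.0 / peak
    return np.floor(mag + 0.5).clip(0, 255).astype(np.uint8)


def binarize(grad: np.ndarray, threshold: int = 128) -> np.ndarray:
    """Binary edge image: true where intensity >= threshold."""
    return np.asarray(grad) >= threshold


def _stage_peak(binary: np.ndarray, radii: np.ndarray) -> dict:
    acc = hough_circle(binary, radii)  # (n_radii, H, W), normalized per radius
    idx = np.unravel_index(int(np.argmax(acc)), acc.shape)
    return {
        "radius": float(radii[idx[0]]),
        "center_y": float(idx[1]),
        "center_x": float(idx[2]),
        "metric": float(acc[idx]),
    }


def detect_embryo_circle(
    binary: np.ndarray, config: PipelineConfig | None = None
) -> EmbryoCircle:
    """Two-stage CHT embryo detection on a binary edge image.

    Each stage keeps its best-scoring circle; the stage with the higher
    accumulator metric wins, ties going to the larger radius.  Raises
    :class:`DetectionError` (with both stage diagnostics) when no circle
    reaches the minimum metric.
    """
    cfg = config or DEFAULT_CONFIG
    binary = np.asarray(binary, dtype=bool)
    if binary.ndim != 2:
        raise InputError("detect_embryo_circle expects a 2-D binary image")

    stages = []
    if binary.any():
        for lo, hi in (cfg.stage1_radii, cfg.stage2_radii):
            radii = np.arange(lo, hi + 1, cfg.radius_step)
            stages.append(_stage_peak(binary, radii))
    else:
        stages = [
            {"radius": np.nan, "center_y": np.nan, "center_x": np.nan, "metric": 0.0},
            {"radius": np.nan, "center_y": np.nan, "center_x": np.nan, "metric": 0.0},
        ]

    metrics = [s["metric"] for s in stages]
    if max(metrics) < cfg.embryo_min_metric:
        raise DetectionError(
            f"no embryo circle found (best metric {max(metrics):.3f} "
            f"< {cfg.embryo_min_metric})",
            stage_diagnostics=stages,
        )
    # best metric wins; near-ties go to the larger radius
    if abs(metrics[0] - metrics[1]) <= 1e-9:
        winner = max(range(2), key=lambda i: stages[i]["radius"])
    else:
        winner = int(np.argmax(metrics))
    s = stages[winner]
    lo_all = cfg.stage1_radii[0]
    hi_all = cfg.stage2_radii[1]
    radius = float(np.clip(s["radius"], lo_all, hi_all))
    log.debug("embryo circle: stage %d, r=%.1f, metric=%.3f", winner + 1, radius, s["metric"])
    return EmbryoCircle(
        center_x=s["center_x"],
        center_y=s["center_y"],
        radius=radius,
        metric=s["metric"],
        stage=winner + 1,
        diagnostics=tuple(stages),
    )


def _disc_mask(shape: tuple[int, int], cx: float, cy: float, radius: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2


def make_masks(
    circle: EmbryoCircle, img: np.ndarray, config: PipelineConfig | None = None
) -> RegionMasks:
    """Build ER (r+5), RR (r-40) and TE = ER \\ RR masks and the ER crop."""
    cfg = config or DEFAULT_CONFIG
    img = np.asarray(img)
    if img.ndim != 2:
        raise InputError("make_masks expects a 2-D greyscale image")
    r_er = circle.radius + cfg.er_delta
    r_rr = circle.radius + cfg.rr_delta
    if r_rr < 1:
        raise DegenerateRegionError(
            f"reduced radius {r_rr:.1f} < 1 px (embryo radius {circle.radius:.1f})"
        )
    er_mask = _disc_mask(img.shape, circle.center_x, circle.center_y, r_er)
    rr_mask = _disc_mask(img.shape, circle.center_x, circle.center_y, r_rr)
    te_mask = er_mask & ~rr_mask

    side = 2 * int(round(r_er))
    cy = int(round(circle.center_y))
    cx = int(round(circle.center_x))
    y0, x0 = cy - side // 2, cx - side // 2

    crop = np.zeros((side, side), dtype=img.dtype)
    crop_er = np.zeros((side, side), dtype=bool)
    crop_rr = np.zeros((side, side), dtype=bool)
    crop_te = np.zeros((side, side), dtype=bool)
    ys = slice(max(y0, 0), min(y0 + side, img.shape[0]))
    xs = slice(max(x0, 0), min(x0 + side, img.shape[1]))
    dys = slice(ys.start - y0, ys.stop - y0)
    dxs = slice(xs.start - x0, xs.stop - x0)
    crop[dys, dxs] = img[ys, xs]
    crop_er[dys, dxs] = er_mask[ys, xs]
    crop_rr[dys, dxs] = rr_mask[ys, xs]
    crop_te[dys, dxs] = te_mask[ys, xs]

    return RegionMasks(
        circle=circle,
        er_mask=er_mask,
        rr_mask=rr_mask,
        te_mask=te_mask,
        crop=crop,
        crop_er_mask=crop_er,
        crop_rr_mask=crop_rr,
        crop_te_mask=crop_te,
        crop_origin=(y0, x0),
        total_area=int(er_mask.sum()),
        radius_er=float(r_er),
    )


def segment_image(img: np.ndarray, config: PipelineConfig | None = None) -> RegionMasks:
    """Convenience wrapper: gradient -> binarize -> CHT -> masks."""
    cfg = config or DEFAULT_CONFIG
    grad = gradient_magnitude(img)
    binary = binarize(grad, cfg.binary_threshold)
    circle = detect_embryo_circle(binary, cfg)
    return make_masks(circle, img, cfg)
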