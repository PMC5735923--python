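"""Small dark/light circle detection inside the isolated embryo.

Rounded sub-structures (e.g. extruded blastomeres, lipid droplets, vesicles)
appear as small dark or light circles.  They are counted in two size classes
— radius 4-8 px (sensitivity 0.935) and radius 9-15 px (sensitivity 0.94) —
separately for dark and light polarity, giving variables DC1/LC1/DC2/LC2
plus the mean intensity over the detected circles (Mean DC1, ...).

The detector is an orientation-coded circular Hough transform: every Canny
edge pixel casts a single vote at the point one radius away along its
gradient direction, the sign of the step selecting the polarity (a dark
disc's gradient points outward, so its centre lies against the gradient;
a light disc's lies along it).  Coherent votes from a true circle pile up
at its centre while noise and texture edges scatter, which is what gives
the detector its specificity at radii this small.  The "sensitivity" s of
the reference circle finder maps to the normalized accumulator acceptance
threshold tau = clip(5*(1-s), 0.05, 0.95), so higher sensitivity admits
weaker circles.  Accepted peaks must further lie inside the region mask,
show the requested disc/surround intensity contrast, and have a refined
radius (median distance of their supporting edge pixels) inside the class
radius range — the last check keeps a circle from being counted in both
size classes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import canny

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import InputError
from .segment import RegionMasks

log = logging.getLogger("blastoquant")


@dataclass(frozen=True)
class CircleSet:
    """Detected circles of one polarity / radius class."""

    circles: tuple[tuple[float, float, float], ...]  # (center_x, center_y, radius)
    polarity: str                                    # "dark" | "light"
    radius_range: tuple[int, int]
    sensitivity: float

    @property
    def count(self) -> int:
        return len(self.circles)

    def mean_radius(self) -> float:
        if not self.circles:
            return 0.0
        return float(np.mean([c[2] for c in self.circles]))


def _disc(shape, cx, cy, radius):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2


def _fit_circle(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kasa) least-squares circle fit through edge points."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    a = np.column_stack([2.0 * x, 2.0 * y, np.ones(x.size)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    xc, yc = float(sol[0]), float(sol[1])
    rc = math.sqrt(max(float(sol[2]) + xc**2 + yc**2, 0.0))
    return xc, yc, rc


def sensitivity_to_threshold(sensitivity: float, scale: float = 5.0) -> float:
    """Map a sensitivity index in (0,1) to an accumulator threshold."""
    if not 0.0 < sensitivity < 1.0:
        raise InputError(f"sensitivity must be in (0,1), got {sensitivity}")
    return float(np.clip(scale * (1.0 - sensitivity), 0.05, 0.95))


def detect_inner_circles(
    image: np.ndarray,
    mask: np.ndarray,
    polarity: str,
    radius_range: tuple[int, int],
    sensitivity: float,
    config: PipelineConfig | None = None,
) -> CircleSet:
    """Orientation-coded CHT detection of small circles inside ``mask``.

    Returns every accepted circle as (center_x, center_y, radius); an empty
    result is valid.  See the module docstring for the acceptance rules.
    """
    cfg = config or DEFAULT_CONFIG
    if polarity not in ("dark", "light"):
        raise InputError(f"polarity must be 'dark' or 'light', got {polarity!r}")
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise InputError("image and mask shapes differ")
    if not mask.any():
        return CircleSet((), polarity, tuple(radius_range), sensitivity)

    # flatten the background to the masked mean so the mask border adds no edges
    work = image.copy()
    work[~mask] = image[mask].mean()
    smooth = ndimage.gaussian_filter(work, cfg.inner_canny_sigma)
    thr = cfg.inner_min_gradient / 255.0
    edges = canny(work / 255.0, sigma=cfg.inner_canny_sigma,
                  low_threshold=0.5 * thr, high_threshold=thr)
    ys, xs = np.nonzero(edges)
    if ys.size == 0:
        return CircleSet((), polarity, tuple(radius_range), sensitivity)
    gx = ndimage.sobel(smooth, axis=1) / 8.0
    gy = ndimage.sobel(smooth, axis=0) / 8.0
    mag = np.hypot(gx[ys, xs], gy[ys, xs])
    ok = mag >= cfg.inner_min_gradient
    ys, xs, mag = ys[ok], xs[ok], mag[ok]
    if ys.size == 0:
        return CircleSet((), polarity, tuple(radius_range), sensitivity)
    ux = gx[ys, xs] / mag
    uy = gy[ys, xs] / mag
    sign = -1.0 if polarity == "dark" else 1.0  # centre lies against/along the gradient

    rmin, rmax = radius_range
    radii = np.arange(rmin, rmax + 1)
    h, w = image.shape
    acc = np.zeros((radii.size, h, w))
    for ri, r in enumerate(radii):
        cxs = np.rint(xs + sign * r * ux).astype(int)
        cys = np.rint(ys + sign * r * uy).astype(int)
        inb = (cxs >= 0) & (cxs < w) & (cys >= 0) & (cys < h)
        np.add.at(acc[ri], (cys[inb], cxs[inb]), 1.0)
    # pool votes within +-1 px and normalize by the perimeter length
    acc = ndimage.uniform_filter(acc, size=(1, 3, 3)) * 9.0
    acc /= (2.0 * np.pi * radii)[:, None, None]

    tau = sensitivity_to_threshold(sensitivity, cfg.inner_sensitivity_scale)
    cand = np.argwhere(acc >= tau)
    if cand.size == 0:
        return CircleSet((), polarity, tuple(radius_range), sensitivity)
    scores = acc[cand[:, 0], cand[:, 1], cand[:, 2]]
    order = np.argsort(scores, kind="stable")[::-1]

    kept: list[tuple[float, float, float]] = []
    min_sep = float(rmin)
    for k in order:
        ri, cy, cx = (int(v) for v in cand[k])
        if not mask[cy, cx]:
            continue
        if any(
            (cx - kx) ** 2 + (cy - ky) ** 2 < max(min_sep, kr + 1.0) ** 2
            for kx, ky, kr in kept
        ):
            continue
        # a dark circle's gradient points outward from the centre, a light
        # one's inward: gather orientation-coherent edge pixels near the
        # candidate and refit a circle through them.  An alias response (a
        # peak raised by the contour of a larger circle or an elliptical
        # boundary) refits to that structure and fails the checks below.
        dx, dy = xs - cx, ys - cy
        dist = np.hypot(dx, dy)
        near = (dist >= 1.5) & (dist <= rmax + 4.0)
        radial_dot = np.zeros_like(dist)
        nz = dist > 0
        radial_dot[nz] = (dx[nz] * ux[nz] + dy[nz] * uy[nz]) / dist[nz]
        coherent = radial_dot > 0.8 if polarity == "dark" else radial_dot < -0.8
        pts = near & coherent
        if pts.sum() < 6:
            continue
        fx, fy, fr = _fit_circle(xs[pts], ys[pts])
        # inliers of the fitted circle, then one refit pass
        d_fit = np.hypot(xs - fx, ys - fy)
        inl = pts & (np.abs(d_fit - fr) <= 1.5)
        if inl.sum() < 6:
            continue
        fx, fy, fr = _fit_circle(xs[inl], ys[inl])
        d_fit = np.hypot(xs - fx, ys - fy)
        inl = pts & (np.abs(d_fit - fr) <= 1.5)
        if not (rmin - 0.5 <= fr <= rmax + 0.5):
            continue
        iy, ix = int(round(fy)), int(round(fx))
        if not (0 <= iy < h and 0 <= ix < w) or not mask[iy, ix]:
            continue
        if inl.sum() < tau * 2.0 * np.pi * fr:
            continue
        # a genuine circle is supported around most of its perimeter; arcs
        # of larger structures subtend well under half a turn
        angles = np.arctan2(ys[inl] - fy, xs[inl] - fx)
        bins = np.unique(((angles + np.pi) * (24 / (2.0 * np.pi))).astype(int) % 24)
        if bins.size < 0.6 * 24:
            continue
        if any(
            (fx - kx) ** 2 + (fy - ky) ** 2 < max(min_sep, kr + 1.0) ** 2
            for kx, ky, kr in kept
        ):
            continue
        fr_c = float(np.clip(fr, rmin, rmax))
        inner = _disc(image.shape, fx, fy, fr_c) & mask
        ring = (
            _disc(image.shape, fx, fy, fr_c + 5) & ~_disc(image.shape, fx, fy, fr_c + 2)
        ) & mask
        if not inner.any() or not ring.any():
            continue
        diff = image[inner].mean() - image[ring].mean()
        if polarity == "dark" and diff > -cfg.polarity_margin:
            continue
        if polarity == "light" and diff < cfg.polarity_margin:
            continue
        kept.append((float(fx), float(fy), fr_c))
    log.debug(
        "%s circles r=%s s=%.3f (tau=%.3f): %d kept of %d candidates",
        polarity, radius_range, sensitivity, tau, len(kept), len(order),
    )
    return CircleSet(tuple(kept), polarity, tuple(radius_range), sensitivity)


def circle_mean_intensity(
    cs: CircleSet, image: np.ndarray, mask: np.ndarray
) -> float:
    """Mean grey intensity over the union of detected circles.

    A binary mask is built by stamping a disc of the MEAN detected radius at
    every detected centre (restricted to the region mask); the mean intensity
    over that union is returned.  An empty circle set yields 0 by convention
    (flagged upstream).
    """
    if cs.count == 0:
        return 0.0
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    r_mean = cs.mean_radius()
    union = np.zeros(image.shape, dtype=bool)
    for cx, cy, _ in cs.circles:
        union |= _disc(image.shape, cx, cy, r_mean)
    union &= mask
    if not union.any():
        return 0.0
    return float(image[union].mean())


def circle_features(
    masks: RegionMasks, config: PipelineConfig | None = None
) -> tuple[dict[str, float], set[str]]:
    """Variables 9-16: counts and mean intensities for the four classes."""
    cfg = config or DEFAULT_CONFIG
    image, mask = masks.crop, masks.crop_er_mask
    combos = [
        ("DC1", "dark", cfg.inner_range_1, cfg.inner_sensitivity_1),
        ("LC1", "light", cfg.inner_range_1, cfg.inner_sensitivity_1),
        ("DC2", "dark", cfg.inner_range_2, cfg.inner_sensitivity_2),
        ("LC2", "light", cfg.inner_range_2, cfg.inner_sensitivity_2),
    ]
    out: dict[str, float] = {}
    flags: set[str] = set()
    for name, polarity, rng, sens in combos:
        cs = detect_inner_circles(image, mask, polarity, rng, sens, cfg)
        out[name] = float(cs.count)
        out[f"Mean {name}"] = circle_mean_intensity(cs, image, mask)
        if cs.count == 0:
            flags.add(f"no_circles_{name.lower()}")
    ordered = ["DC1", "Mean DC1", "LC1", "Mean LC1", "DC2", "Mean DC2", "LC2", "Mean LC2"]
    return {k: out[k] for k in ordered}, flags
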