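"""First-order intensity statistics and the Otsu edge-fraction (variables 17-31).

All fractions are normalized by the *total embryo area* — the pixel count of
the ER mask — not by the area of the region the pixels come from; this keeps
the RR and TE variants on a common scale.

Conventions (documented, not in the source protocol):
* Otsu foreground is strictly above the threshold; a constant region has no
  Otsu split and yields Sum ER = 0 with a quality flag.
* the intensity mode breaks ties toward the smallest intensity;
* the standard deviation uses the n-1 denominator and needs n >= 2 (NaN
  otherwise).
"""

from __future__ import annotations

import numpy as np
from skimage.filters import threshold_otsu

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import EmptyRegionError, InputError
from .segment import RegionMasks


def region_pixels(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """1-D vector of masked pixel intensities."""
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise InputError("image and mask shapes differ")
    x = image[mask]
    if x.size == 0:
        raise EmptyRegionError("region has no masked pixels")
    return x


def sum_er(x: np.ndarray, total_area: int) -> tuple[float, bool]:
    """Otsu-binarized foreground fraction of the embryo.

    Returns (fraction, degenerate_flag): the count of masked pixels strictly
    above the Otsu threshold divided by ``total_area``; a constant region
    has no threshold and returns (0.0, True).
    """
    x = np.asarray(x)
    if x.size == 0:
        raise EmptyRegionError("sum_er: empty region")
    if total_area < 1:
        raise InputError("total_area must be >= 1")
    if x.min() == x.max():
        return 0.0, True
    t = threshold_otsu(x)
    return float((x > t).sum() / total_area), False


def mean_grey(x: np.ndarray) -> float:
    x = np.asarray(x)
    if x.size == 0:
        raise EmptyRegionError("mean_grey: empty region")
    return float(x.mean())


def std_dev(x: np.ndarray) -> float:
    """Sample standard deviation (n-1 denominator); NaN for n < 2."""
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise EmptyRegionError("std_dev: empty region")
    if x.size < 2:
        return float("nan")
    return float(x.std(ddof=1))


def mode_value(x: np.ndarray) -> float:
    """Most frequent intensity; ties resolve to the smallest intensity."""
    x = np.asarray(x)
    if x.size == 0:
        raise EmptyRegionError("mode_value: empty region")
    counts = np.bincount(x.astype(np.int64), minlength=256)
    return float(np.argmax(counts))  # argmax returns the first (= smallest) maximum


def fraction_dark(x: np.ndarray, total_area: int, dark_max: int = 25) -> float:
    """count(x <= dark_max) / total_area (boundary inclusive)."""
    return float((np.asarray(x) <= dark_max).sum() / total_area)


def fraction_bright(x: np.ndarray, total_area: int, bright_min: int = 230) -> float:
    """count(x >= bright_min) / total_area (boundary inclusive)."""
    return float((np.asarray(x) >= bright_min).sum() / total_area)


def fraction_near_mean(x: np.ndarray, total_area: int, delta: float = 10.0) -> float:
    """count(mean - delta <= x <= mean + delta) / total_area, bounds inclusive."""
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise EmptyRegionError("fraction_near_mean: empty region")
    m = x.mean()
    return float(((x >= m - delta) & (x <= m + delta)).sum() / total_area)


def intensity_features(
    masks: RegionMasks, config: PipelineConfig | None = None
) -> tuple[dict[str, float], set[str]]:
    """Variables 17-31 in canonical order."""
    cfg = config or DEFAULT_CONFIG
    flags: set[str] = set()
    area = masks.total_area
    er = region_pixels(masks.crop, masks.crop_er_mask)

    s, degenerate = sum_er(er, area)
    if degenerate:
        flags.add("otsu_degenerate_er")
    out: dict[str, float] = {
        "Radius ER": masks.radius_er,
        "Sum ER": s,
        "Mean grey ER": mean_grey(er),
    }
    for suffix, m in (("RR", masks.crop_rr_mask), ("TE", masks.crop_te_mask)):
        x = region_pixels(masks.crop, m)
        sd = std_dev(x)
        if np.isnan(sd):
            flags.add(f"deviation_undefined_{suffix.lower()}")
        out[f"Deviation {suffix}"] = sd
        out[f"Mean grey {suffix}"] = mean_grey(x)
        out[f"Mode value {suffix}"] = mode_value(x)
        out[f"Dark {suffix}"] = fraction_dark(x, area, cfg.dark_max)
        out[f"Mean Count {suffix}"] = fraction_near_mean(x, area, cfg.near_mean_delta)
        out[f"Bright {suffix}"] = fraction_bright(x, area, cfg.bright_min)
    ordered = [
        "Radius ER", "Sum ER", "Mean grey ER",
        "Deviation RR", "Mean grey RR", "Mode value RR",
        "Dark RR", "Mean Count RR", "Bright RR",
        "Deviation TE", "Mean grey TE", "Mode value TE",
        "Dark TE", "Mean Count TE", "Bright TE",
    ]
    return {k: out[k] for k in ordered}, flags
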