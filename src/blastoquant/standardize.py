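"""Image standardization.

Every micrograph entering the pipeline is reduced to a canonical form: an
8-bit greyscale image of exactly 640x480 px (aspect ratio 0.75) whose
histogram has been linearly stretched so that roughly 1% of pixels saturate
at each end of the intensity range.  The four steps run in order:

1. load (BMP/JPG/PNG, 8-bit grey or RGB),
2. greyscale conversion (BT.601 luma weights),
3. geometry adjustment (crop to aspect 0.75, then resize to 640x480),
4. linear contrast stretch with percentile saturation.

A 1,280x1,024 capture (aspect 0.8) is first cropped by 64 rows from the top
(1,280x960, aspect 0.75) and then downscaled to 640x480; images that are too
wide instead lose columns symmetrically so the centred embryo stays centred.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import PIL.Image
from skimage.transform import resize

from .errors import FormatError, InputError

log = logging.getLogger("blastoquant")

#: ITU-R BT.601 luma weights for R, G, B.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

_SUPPORTED_MODES = {"L", "RGB", "RGBA", "LA", "P", "1"}


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def load_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit BMP/JPG (or PNG) image as a uint8 array.

    Returns a (H, W) array for greyscale input or (H, W, 3) for RGB.
    16-bit and floating-point images are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"image file not found: {path}")
    try:
        with PIL.Image.open(path) as im:
            mode = im.mode
            if mode not in _SUPPORTED_MODES:
                raise FormatError(
                    f"unsupported pixel format {mode!r} in {path.name}; "
                    "only 8-bit greyscale or RGB images are accepted"
                )
            if mode == "1":
                im = im.convert("L")
            elif mode == "LA":
                im = im.convert("L")
            elif mode in ("RGBA", "P"):
                im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.uint8)
    except FormatError:
        raise
    except PIL.UnidentifiedImageError as exc:
        raise FormatError(f"cannot decode {path.name}: not a supported image") from exc
    except OSError as exc:
        raise FormatError(f"cannot decode {path.name}: {exc}") from exc
    if arr.ndim not in (2, 3):
        raise FormatError(f"unexpected array shape {arr.shape} from {path.name}")
    return arr


def to_greyscale(img: np.ndarray) -> np.ndarray:
    """Convert an RGB image to 8-bit greyscale with BT.601 weights.

    Single-channel input passes through unchanged.  Rounding is half-up, so
    pure red (255, 0, 0) maps to round(0.299 * 255) = 76.
    """
    img = np.asarray(img)
    if img.ndim == 2:
        return img.astype(np.uint8, copy=False)
    if img.ndim == 3 and img.shape[2] == 3:
        w = np.asarray(LUMA_WEIGHTS)
        grey = img.astype(np.float64) @ w
        return _round_half_up(grey).clip(0, 255).astype(np.uint8)
    raise InputError(f"expected 1- or 3-channel image, got shape {img.shape}")


def adjust_geometry(
    img: np.ndarray, target_width: int = 640, target_height: int = 480
) -> np.ndarray:
    """Crop to the target aspect ratio, then resize to the target resolution.

    Too-tall images (height/width > ratio) lose rows from the top; too-wide
    images lose columns symmetrically.  Resizing is bicubic with
    anti-aliasing on downscale.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise InputError("adjust_geometry expects a single-channel image")
    h, w = img.shape
    if h < 8 or w < 8:
        raise InputError(f"degenerate image {w}x{h}: need at least 8x8 px")
    ratio = target_height / target_width
    if (h, w) == (target_height, target_width):
        return img.astype(np.uint8, copy=False)

    if h / w > ratio:
        new_h = int(round(ratio * w))
        img = img[h - new_h :, :]  # cut the excess from the TOP
    elif h / w < ratio:
        new_w = int(round(h / ratio))
        cut = w - new_w
        left = cut // 2
        img = img[:, left : left + new_w]

    if img.shape[1] < target_width:
        log.warning(
            "upscaling %dx%d to %dx%d", img.shape[1], img.shape[0], target_width, target_height
        )
    out = resize(
        img.astype(np.float64),
        (target_height, target_width),
        order=3,
        anti_aliasing=img.shape[0] > target_height,
        preserve_range=True,
    )
    return _round_half_up(out).clip(0, 255).astype(np.uint8)


def stretch_intensity(
    img: np.ndarray, lower_pct: float = 1.0, upper_pct: float = 1.0
) -> np.ndarray:
    """Linear contrast stretch saturating ``lower_pct`` % of pixels to 0 and
    ``upper_pct`` % to 255.

    The empirical ``lower_pct`` and ``100 - upper_pct`` percentiles map to 0
    and 255; values outside are clipped.  A constant image is returned
    unchanged (with a warning) since no stretch is defined.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise InputError("stretch_intensity expects a single-channel image")
    lo = float(np.percentile(img, lower_pct))
    hi = float(np.percentile(img, 100.0 - upper_pct))
    if hi <= lo:
        log.warning("constant (or near-constant) image: intensity stretch skipped")
        return img.astype(np.uint8, copy=False)
    out = (img.astype(np.float64) - lo) * 255.0 / (hi - lo)
    return _round_half_up(out).clip(0, 255).astype(np.uint8)


def standardize_image(source, config=None) -> np.ndarray:
    """Full standardization: load -> greyscale -> geometry -> stretch.

    ``source`` may be a file path or an in-memory uint8 array.
    """
    from .config import DEFAULT_CONFIG

    cfg = config or DEFAULT_CONFIG
    img = load_image(source) if isinstance(source, (str, Path)) else np.asarray(source)
    img = to_greyscale(img)
    img = adjust_geometry(img, cfg.target_width, cfg.target_height)
    return stretch_intensity(img, cfg.stretch_lower_pct, cfg.stretch_upper_pct)
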