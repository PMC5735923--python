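"""Grey-level co-occurrence texture statistics for the RR and TE regions.

The region is first quantized to 8 grey levels (equal-width bins between the
masked minimum and maximum), then the co-occurrence matrix P(i, j) counts
ordered pixel pairs (p, p + offset) with BOTH pixels inside the mask, at
offset distance d and angle theta (default: one pixel to the right).  The
matrix is normalized to probabilities but not symmetrized.  Four statistics
are derived:

* contrast     = sum |i-j|^2 p(i,j)                    (0 for a constant region)
* correlation  = sum (i-mu_i)(j-mu_j) p(i,j) / (sigma_i sigma_j)
                 (+-1 for perfectly linearly related neighbours; undefined —
                 NaN — when either marginal variance is zero)
* energy       = sum p(i,j)^2                          (1 for a constant region)
* homogeneity  = sum p(i,j) / (1 + |i-j|)              (1 for a diagonal GLCM)

Note on homogeneity: the denominator uses |i - j|, the distance from the
diagonal; see docs/methods.md for why the alternative |i + j| form is
rejected (it contradicts the diagonal-GLCM property above).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import EmptyRegionError, InputError
from .segment import RegionMasks

#: angle (degrees) -> (row, col) unit offset; image rows grow downward.
_ANGLE_OFFSETS = {0.0: (0, 1), 45.0: (-1, 1), 90.0: (-1, 0), 135.0: (-1, -1)}


@dataclass(frozen=True)
class GLCMatrix:
    """Normalized 8x8 co-occurrence matrix with its offset parameters."""

    p: np.ndarray      # (levels, levels) probabilities; zeros when degenerate
    d: int
    theta: float
    n_pairs: int

    @property
    def degenerate(self) -> bool:
        return self.n_pairs == 0

    @property
    def levels(self) -> int:
        return self.p.shape[0]

    def marginals(self) -> tuple[float, float, float, float]:
        """(mu_i, mu_j, sigma_i, sigma_j) of the row/column marginals."""
        idx = np.arange(self.levels, dtype=np.float64)
        pi = self.p.sum(axis=1)
        pj = self.p.sum(axis=0)
        mu_i = float(idx @ pi)
        mu_j = float(idx @ pj)
        sigma_i = math.sqrt(max(float(((idx - mu_i) ** 2) @ pi), 0.0))
        sigma_j = math.sqrt(max(float(((idx - mu_j) ** 2) @ pj), 0.0))
        return mu_i, mu_j, sigma_i, sigma_j


def quantize8(
    region_image: np.ndarray,
    mask: np.ndarray,
    levels: int = 8,
    fixed_range: bool = False,
) -> np.ndarray:
    """Quantize masked pixels into ``levels`` equal-width bins.

    By default the bins span the masked min..max (a constant region maps to
    level 0); with ``fixed_range`` they span 0..255.  Background pixels get
    level -1 and never contribute downstream.
    """
    img = np.asarray(region_image, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if img.shape != mask.shape:
        raise InputError("image and mask shapes differ")
    if not mask.any():
        raise EmptyRegionError("quantize8: empty mask")
    if fixed_range:
        lo, hi = 0.0, 255.0
    else:
        vals = img[mask]
        lo, hi = float(vals.min()), float(vals.max())
    q = np.full(img.shape, -1, dtype=np.int16)
    if hi <= lo:
        q[mask] = 0
        return q
    scaled = (img[mask] - lo) / (hi - lo)  # in [0, 1]
    q[mask] = np.minimum((scaled * levels).astype(np.int16), levels - 1)
    return q


def compute_glcm(
    q: np.ndarray,
    mask: np.ndarray,
    d: int = 1,
    theta: float = 0.0,
    levels: int = 8,
) -> GLCMatrix:
    """Co-occurrence matrix of a quantized grid over pairs inside the mask."""
    q = np.asarray(q)
    mask = np.asarray(mask, dtype=bool)
    if theta not in _ANGLE_OFFSETS:
        raise InputError(f"theta must be one of {sorted(_ANGLE_OFFSETS)}, got {theta}")
    dr, dc = (d * o for o in _ANGLE_OFFSETS[theta])
    h, w = q.shape

    # window of valid "first pixel" positions such that pixel+offset is in bounds
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    counts = np.zeros((levels, levels), dtype=np.int64)
    if r0 < r1 and c0 < c1:
        a = q[r0:r1, c0:c1]
        b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        if valid.any():
            np.add.at(counts, (a[valid], b[valid]), 1)
    n_pairs = int(counts.sum())
    p = counts / n_pairs if n_pairs else counts.astype(np.float64)
    return GLCMatrix(p=p, d=d, theta=theta, n_pairs=n_pairs)


def glcm_contrast(g: GLCMatrix) -> float:
    """sum |i-j|^2 p(i,j); 0 (flag upstream) for a degenerate GLCM."""
    i, j = np.indices(g.p.shape)
    return float(((i - j) ** 2 * g.p).sum())


def glcm_correlation(g: GLCMatrix) -> float:
    """Linear correlation of co-occurring levels; NaN when variance is zero."""
    if g.degenerate:
        return float("nan")
    mu_i, mu_j, sigma_i, sigma_j = g.marginals()
    denom = sigma_i * sigma_j
    if denom == 0.0:
        return float("nan")
    i, j = np.indices(g.p.shape)
    cov = float(((i - mu_i) * (j - mu_j) * g.p).sum())
    return cov / denom


def glcm_energy(g: GLCMatrix) -> float:
    """sum p(i,j)^2; 1 for a constant region (all mass in one cell)."""
    if g.degenerate:
        return 1.0
    return float((g.p**2).sum())


def glcm_homogeneity(g: GLCMatrix) -> float:
    """sum p(i,j) / (1 + |i-j|); 1 when all mass sits on the diagonal."""
    if g.degenerate:
        return 1.0
    i, j = np.indices(g.p.shape)
    return float((g.p / (1.0 + np.abs(i - j))).sum())


def region_texture(
    image: np.ndarray, mask: np.ndarray, config: PipelineConfig | None = None
) -> tuple[dict[str, float], GLCMatrix]:
    """(contrast, correlation, energy, homogeneity) of one masked region."""
    cfg = config or DEFAULT_CONFIG
    q = quantize8(image, mask, levels=cfg.glcm_levels, fixed_range=cfg.glcm_fixed_range)
    g = compute_glcm(q, mask, d=cfg.glcm_distance, theta=cfg.glcm_angle, levels=cfg.glcm_levels)
    stats = {
        "Contrast": glcm_contrast(g),
        "Correlation": glcm_correlation(g),
        "Energy": glcm_energy(g),
        "Homogeneity": glcm_homogeneity(g),
    }
    return stats, g


def texture_features(
    masks: RegionMasks, config: PipelineConfig | None = None
) -> tuple[dict[str, float], set[str]]:
    """Variables 1-8: the four GLCM statistics on RR, then on TE."""
    out: dict[str, float] = {}
    flags: set[str] = set()
    for suffix, region_mask in (("RR", masks.crop_rr_mask), ("TE", masks.crop_te_mask)):
        stats, g = region_texture(masks.crop, region_mask, config)
        for name, value in stats.items():
            out[f"{name} {suffix}"] = value
        if g.degenerate:
            flags.add(f"glcm_degenerate_{suffix.lower()}")
        if math.isnan(stats["Correlation"]):
            flags.add(f"correlation_undefined_{suffix.lower()}")
    ordered = [
        "Contrast RR", "Correlation RR", "Energy RR", "Homogeneity RR",
        "Contrast TE", "Correlation TE", "Energy TE", "Homogeneity TE",
    ]
    return {k: out[k] for k in ordered}, flags
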