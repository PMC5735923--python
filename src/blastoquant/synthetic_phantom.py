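"""Seeded synthetic blastocyst phantoms with exact ground truth.

A phantom emulates the geometry and photometry of a brightfield blastocyst
micrograph: a bright field, a roughly circular embryo bounded by a dark zona
pellucida ring, a textured trophectoderm annulus just inside the zona, a
darker blastocoel interior with faint large-scale granularity, a dark
elliptical inner cell mass, and optional small dark/light circular
inclusions — finished with an optics blur and additive Gaussian camera
noise.  All coordinates and sizes in :class:`PhantomSpec` are expressed in
the standardized 640x480 frame; rendering at 1,280x1,024 (the default)
scales everything by 2 and adds the 64 extra top rows that the
standardization step is expected to crop away, so the full pipeline path is
exercised.

Every random element is driven by ``spec.seed``; a given spec renders to a
byte-identical image on every call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import PIL.Image
from scipy import ndimage

from .errors import InputError, PhantomSpecError

STD_W, STD_H = 640, 480
RAW_W, RAW_H = 1280, 1024
_CROP_ROWS = 64  # top rows removed when standardizing a 1280x1024 capture


@dataclass(frozen=True)
class Inclusion:
    """One small circular inclusion (standardized-frame coordinates)."""

    x: float
    y: float
    radius: float          # 4..15 px
    polarity: str          # "dark" | "light"
    intensity: float

    @property
    def size_class(self) -> int:
        return 1 if self.radius <= 8 else 2


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic blastocyst image.

    Defaults describe a typical mid-expansion blastocyst: embryo radius
    150 px against a bright (220) field, a 4 px zona ring, a 35 px textured
    trophectoderm annulus, and a dark elliptical ICM.
    """

    width: int = RAW_W
    height: int = RAW_H
    embryo_center: tuple[float, float] = (320.0, 240.0)  # (x, y), standardized frame
    embryo_radius: float = 150.0
    background_intensity: float = 220.0
    interior_intensity: float = 170.0
    interior_texture: tuple[float, float] = (3.0, 5.0)   # (noise sd, blob scale px)
    zona_ring_width: float = 4.0
    zona_intensity: float = 110.0
    te_width: float = 35.0
    # TE granularity is kept finer-scale (1.2 px blobs) than the 4-15 px
    # circle-detector band so inclusion counts have unambiguous ground truth
    te_texture: tuple[float, float, float] = (150.0, 8.0, 1.2)  # (mean, sd, blob scale)
    icm_present: bool = True
    icm_offset: tuple[float, float] = (15.0, 5.0)        # from embryo centre
    icm_axes: tuple[float, float] = (50.0, 35.0)         # semi-axes a >= b
    icm_intensity: float = 90.0
    inclusions: tuple[Inclusion, ...] = ()
    blur_sigma: float = 1.2                              # optics blur, standardized px
    noise_sd: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if (self.width, self.height) not in ((STD_W, STD_H), (RAW_W, RAW_H)):
            raise PhantomSpecError("phantom size must be 640x480 or 1280x1024")
        cx, cy = self.embryo_center
        r = self.embryo_radius
        if not 100.0 <= r <= 245.0:
            raise PhantomSpecError(f"embryo radius {r} outside [100, 245]")
        # horizontal fit is mandatory; the tallest embryos may clip a few rows
        if cx - r < 0 or cx + r > STD_W:
            raise PhantomSpecError("embryo disc exceeds image width")
        if cy - r < -12 or cy + r > STD_H + 12:
            raise PhantomSpecError("embryo disc clips more than 12 rows vertically")
        a, b = self.icm_axes
        if not a >= b > 0:
            raise PhantomSpecError("icm semi-axes must satisfy a >= b > 0")
        ox, oy = self.icm_offset
        if self.icm_present and math.hypot(ox, oy) + a > r - self.zona_ring_width - self.te_width:
            raise PhantomSpecError("ICM must lie inside the blastocoel")
        interior = r - self.zona_ring_width - 2.0
        for inc in self.inclusions:
            if not 4.0 <= inc.radius <= 15.0:
                raise PhantomSpecError(f"inclusion radius {inc.radius} outside [4, 15]")
            if inc.polarity not in ("dark", "light"):
                raise PhantomSpecError(f"bad inclusion polarity {inc.polarity!r}")
            if math.hypot(inc.x - cx, inc.y - cy) + inc.radius > interior:
                raise PhantomSpecError("inclusion must lie inside the embryo")


@dataclass(frozen=True)
class GroundTruth:
    """What the pipeline should recover from a phantom (standardized frame)."""

    center_x: float
    center_y: float
    radius: float
    icm_present: bool
    icm_center: tuple[float, float]
    icm_axes: tuple[float, float]
    icm_area: float            # analytic pi*a*b
    icm_eccentricity: float    # sqrt(1 - (b/a)^2)
    inclusions: tuple[Inclusion, ...]

    def count(self, polarity: str, size_class: int) -> int:
        return sum(
            1 for inc in self.inclusions
            if inc.polarity == polarity and inc.size_class == size_class
        )


def _blob_field(rng: np.random.Generator, shape, sd: float, scale: float) -> np.ndarray:
    """Smooth zero-mean random field with pointwise standard deviation ``sd``."""
    if sd <= 0:
        return np.zeros(shape)
    g = ndimage.gaussian_filter(rng.standard_normal(shape), scale)
    s = g.std()
    return g * (sd / s) if s > 0 else g


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one phantom; returns (uint8 image, ground truth)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    scale = spec.width // STD_W
    crop = _CROP_ROWS if spec.height == RAW_H else 0

    def raw_xy(x: float, y: float) -> tuple[float, float]:
        return x * scale, y * scale + crop

    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cx, cy = raw_xy(*spec.embryo_center)
    r = spec.embryo_radius * scale
    dist = np.hypot(xx - cx, yy - cy)

    canvas = np.full((h, w), spec.background_intensity)
    embryo = dist <= r
    canvas[embryo] = spec.interior_intensity
    amp, blob = spec.interior_texture
    canvas[embryo] += _blob_field(rng, (h, w), amp, blob * scale)[embryo]

    te_mean, te_sd, te_blob = spec.te_texture
    zw = spec.zona_ring_width * scale
    tw = spec.te_width * scale
    te_band = (dist <= r - zw) & (dist > r - zw - tw)
    canvas[te_band] = te_mean + _blob_field(rng, (h, w), te_sd, te_blob * scale)[te_band]
    zona = (dist <= r) & (dist > r - zw)
    canvas[zona] = spec.zona_intensity

    if spec.icm_present:
        icx, icy = raw_xy(
            spec.embryo_center[0] + spec.icm_offset[0],
            spec.embryo_center[1] + spec.icm_offset[1],
        )
        a, b = (v * scale for v in spec.icm_axes)
        ellipse = ((xx - icx) / a) ** 2 + ((yy - icy) / b) ** 2 <= 1.0
        canvas[ellipse] = spec.icm_intensity

    for inc in spec.inclusions:
        ix, iy = raw_xy(inc.x, inc.y)
        disc = np.hypot(xx - ix, yy - iy) <= inc.radius * scale
        canvas[disc] = inc.intensity

    canvas = ndimage.gaussian_filter(canvas, spec.blur_sigma * scale)
    if spec.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sd, canvas.shape)
    image = np.floor(canvas + 0.5).clip(0, 255).astype(np.uint8)

    a, b = spec.icm_axes
    truth = GroundTruth(
        center_x=spec.embryo_center[0],
        center_y=spec.embryo_center[1],
        radius=spec.embryo_radius,
        icm_present=spec.icm_present,
        icm_center=(
            spec.embryo_center[0] + spec.icm_offset[0],
            spec.embryo_center[1] + spec.icm_offset[1],
        ),
        icm_axes=spec.icm_axes,
        icm_area=math.pi * a * b,
        icm_eccentricity=math.sqrt(max(0.0, 1.0 - (b / a) ** 2)),
        inclusions=spec.inclusions,
    )
    return image, truth


def _place_inclusions(
    rng: np.random.Generator,
    spec: PhantomSpec,
    n_per_class: dict[tuple[str, int], int],
    dark_intensity: float = 100.0,
    light_intensity: float = 240.0,
    min_gap: float = 6.0,
) -> tuple[Inclusion, ...]:
    """Sample non-overlapping inclusions inside the blastocoel."""
    cx, cy = spec.embryo_center
    placed: list[Inclusion] = []
    for (polarity, size_class), n in n_per_class.items():
        # truth radii keep a guard band around the 8|9 class boundary so the
        # size class of every inclusion is unambiguous at the detector's
        # radius resolution; light discs saturate in the contrast stretch and
        # bloom ~1 px outward, so their band is wider
        if polarity == "dark":
            lo, hi = (4.0, 7.5) if size_class == 1 else (9.5, 15.0)
        else:
            lo, hi = (4.0, 6.5) if size_class == 1 else (9.5, 13.5)
        intensity = dark_intensity if polarity == "dark" else light_intensity
        for _ in range(n):
            radius = float(rng.uniform(lo, hi))
            limit = spec.embryo_radius - spec.zona_ring_width - radius - 4.0
            for _attempt in range(200):
                rho = limit * math.sqrt(rng.uniform())
                phi = rng.uniform(0.0, 2.0 * math.pi)
                x, y = cx + rho * math.cos(phi), cy + rho * math.sin(phi)
                clear = all(
                    math.hypot(x - p.x, y - p.y) >= radius + p.radius + min_gap
                    for p in placed
                )
                if clear and spec.icm_present:
                    ox, oy = spec.icm_offset
                    a, b = spec.icm_axes
                    icx, icy = cx + ox, cy + oy
                    # keep inclusions off the ICM so their contrast is to the blastocoel
                    clear = ((x - icx) / (a + radius)) ** 2 + (
                        (y - icy) / (b + radius)
                    ) ** 2 > 1.0
                if clear:
                    placed.append(Inclusion(x, y, radius, polarity, intensity))
                    break
            else:
                raise PhantomSpecError("could not place inclusions without overlap")
    return tuple(placed)


def random_spec(
    seed: int,
    radius_range: tuple[float, float] = (110.0, 235.0),
    size: tuple[int, int] = (RAW_W, RAW_H),
    max_inclusions_per_class: int = 2,
) -> PhantomSpec:
    """Draw a random but valid phantom spec under one seed."""
    rng = np.random.default_rng(seed)
    radius = float(rng.uniform(*radius_range))
    cx = 320.0 + float(rng.uniform(-15, 15))
    cy = 240.0 + float(rng.uniform(-10, 10))
    # keep the disc inside the standardized frame (up to the tolerated clip)
    cx = float(np.clip(cx, radius, STD_W - radius))
    cy = float(np.clip(cy, radius - 10.0, STD_H - radius + 10.0))
    a = float(rng.uniform(0.25, 0.38)) * radius
    b = a * float(rng.uniform(0.55, 0.95))
    theta = rng.uniform(0.0, 2.0 * math.pi)
    max_off = max(0.0, radius - 4.0 - 35.0 - a - 2.0)
    off = min(float(rng.uniform(0.0, 0.35)) * radius, max_off)
    base = PhantomSpec(
        width=size[0],
        height=size[1],
        embryo_center=(cx, cy),
        embryo_radius=radius,
        icm_offset=(off * math.cos(theta), off * math.sin(theta)),
        icm_axes=(a, b),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    counts = {
        (pol, cls): int(rng.integers(0, max_inclusions_per_class + 1))
        for pol in ("dark", "light")
        for cls in (1, 2)
    }
    inclusions = _place_inclusions(rng, base, counts)
    return replace(base, inclusions=inclusions)


def generate_dataset(
    n: int,
    seed: int,
    out_dir: str | Path,
    radius_range: tuple[float, float] = (110.0, 235.0),
    size: tuple[int, int] = (RAW_W, RAW_H),
    image_format: str = "jpg",
) -> pd.DataFrame:
    """Write ``n`` seeded phantom images plus a ground-truth CSV.

    JPEG output uses quality 95 to bound compression artefacts; PNG is
    available for lossless tests.  Returns the truth table.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    if image_format not in ("jpg", "png"):
        raise InputError("image_format must be 'jpg' or 'png'")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    records = []
    for i in range(n):
        spec = random_spec(int(master.integers(0, 2**31 - 1)), radius_range, size)
        image, truth = generate_phantom(spec)
        name = f"phantom_{i + 1:03d}.{image_format}"
        pil = PIL.Image.fromarray(image)
        if image_format == "jpg":
            pil.save(out_dir / name, quality=95)
        else:
            pil.save(out_dir / name)
        records.append(
            {
                "image_id": Path(name).stem,
                "file": name,
                "center_x": truth.center_x,
                "center_y": truth.center_y,
                "radius": truth.radius,
                "icm_eccentricity": truth.icm_eccentricity,
                "icm_area": truth.icm_area,
                "n_dark_1": truth.count("dark", 1),
                "n_light_1": truth.count("light", 1),
                "n_dark_2": truth.count("dark", 2),
                "n_light_2": truth.count("light", 2),
                "seed": spec.seed,
            }
        )
    table = pd.DataFrame.from_records(records)
    table.to_csv(out_dir / "truth.csv", index=False)
    return table
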