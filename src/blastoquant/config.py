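"""Pipeline configuration.

Every tunable of the extraction pipeline lives here with its published
default, so a bare ``PipelineConfig()`` reproduces the reference protocol:
binary threshold 128 on the rescaled gradient, two-stage circular Hough
search over radii 100-150 then 150-250 px, region deltas +5 px (ER) and
-40 px (RR), inner-circle radius ranges (4,8)/(9,15) with sensitivities
0.935/0.94, an 8-level GLCM at offset d=1, theta=0, intensity cut-offs
25 (dark) / 230 (bright) / mean+-10, and 1% histogram saturation per tail.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .errors import InputError

log = logging.getLogger("blastoquant")


@dataclass(frozen=True)
class PipelineConfig:
    # --- standardization ---
    target_width: int = 640
    target_height: int = 480
    stretch_lower_pct: float = 1.0   # % of pixels saturated to 0
    stretch_upper_pct: float = 1.0   # % of pixels saturated to 255

    # --- embryo segmentation ---
    binary_threshold: int = 128
    stage1_radii: tuple[int, int] = (100, 150)
    stage2_radii: tuple[int, int] = (150, 250)
    radius_step: int = 2             # accumulator radius sampling (px)
    embryo_min_metric: float = 0.05  # min fraction of perimeter supported by edges
    er_delta: float = 5.0
    rr_delta: float = -40.0

    # --- inner dark/light circles ---
    inner_range_1: tuple[int, int] = (4, 8)
    inner_range_2: tuple[int, int] = (9, 15)
    inner_sensitivity_1: float = 0.935
    inner_sensitivity_2: float = 0.94
    inner_sensitivity_scale: float = 5.0  # tau = clip(scale*(1-s), 0.05, 0.95)
    inner_canny_sigma: float = 1.0
    # only edges at least this steep (grey levels / px) may vote: ~the Sobel
    # response of a minimally-detectable (30 grey level) blurred step edge
    inner_min_gradient: float = 12.0
    polarity_margin: float = 15.0    # min |disc mean - surround mean| (grey levels)

    # --- GLCM texture ---
    glcm_levels: int = 8
    glcm_distance: int = 1
    glcm_angle: float = 0.0          # degrees; 0 = one pixel to the right
    glcm_fixed_range: bool = False   # False: bin between masked min/max

    # --- first-order intensity ---
    dark_max: int = 25
    bright_min: int = 230
    near_mean_delta: float = 10.0

    # --- watershed / ICM ---
    watershed_smooth_sigma: float = 0.0  # Gaussian pre-smoothing, px (0 = raw surface)
    watershed_on_gradient: bool = False
    watershed_region: str = "ER"         # "ER" or "RR"

    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (0 <= self.binary_threshold <= 255, "binary_threshold must be in [0,255]"),
            (self.stage1_radii[0] < self.stage1_radii[1], "stage1_radii must increase"),
            (self.stage2_radii[0] < self.stage2_radii[1], "stage2_radii must increase"),
            (self.radius_step >= 1, "radius_step must be >= 1"),
            (0 < self.inner_sensitivity_1 < 1, "sensitivity must be in (0,1)"),
            (0 < self.inner_sensitivity_2 < 1, "sensitivity must be in (0,1)"),
            (self.glcm_levels >= 2, "glcm_levels must be >= 2"),
            (self.glcm_distance >= 1, "glcm_distance must be >= 1"),
            (self.glcm_angle in (0.0, 45.0, 90.0, 135.0), "glcm_angle must be one of 0/45/90/135"),
            (self.watershed_region in ("ER", "RR"), "watershed_region must be ER or RR"),
            (0.0 <= self.stretch_lower_pct < 50.0, "stretch_lower_pct must be in [0,50)"),
            (0.0 <= self.stretch_upper_pct < 50.0, "stretch_upper_pct must be in [0,50)"),
        ]
        for ok, msg in checks:
            if not ok:
                raise InputError(msg)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stage1_radii"] = list(d["stage1_radii"])
        d["stage2_radii"] = list(d["stage2_radii"])
        d["inner_range_1"] = list(d["inner_range_1"])
        d["inner_range_2"] = list(d["inner_range_2"])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a flat TOML key = value file; unknown keys are rejected."""
        path = Path(path)
        if not path.exists():
            raise InputError(f"config file not found: {path}")
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stage1_radii", "stage2_radii", "inner_range_1", "inner_range_2"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        lines = []
        for key, val in self.to_dict().items():
            if isinstance(val, str):
                lines.append(f'{key} = "{val}"')
            elif isinstance(val, bool):
                lines.append(f"{key} = {str(val).lower()}")
            elif isinstance(val, list):
                lines.append(f"{key} = [{', '.join(str(v) for v in val)}]")
            else:
                lines.append(f"{key} = {val}")
        Path(path).write_text("\n".join(lines) + "\n")


DEFAULT_CONFIG = PipelineConfig()
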