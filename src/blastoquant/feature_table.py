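"""Full-pipeline orchestration, the 36-variable table, and grading utilities.

``extract_all`` chains standardization, embryo segmentation and all four
feature groups into one 36-variable row per image.  The table layout mirrors
the deposited spreadsheet: identifier column(s), the 36 variables, the three
embryologists' IETS grades and their mode.  Inter-rater agreement is
summarized by Fleiss' kappa (and Light's kappa — the mean pairwise Cohen
kappa — as an alternative, since the named variant of the published index is
ambiguous).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats import inter_rater

from . import glcm_texture, hough_circles, intensity_stats, watershed_icm
from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import (
    BlastoquantError,
    ExtractionError,
    InputError,
    TableError,
)
from .segment import segment_image
from .standardize import standardize_image

log = logging.getLogger("blastoquant")

#: Canonical names of the 36 variables, in deposited column order (D..AM).
FEATURE_NAMES: tuple[str, ...] = (
    "Contrast RR", "Correlation RR", "Energy RR", "Homogeneity RR",
    "Contrast TE", "Correlation TE", "Energy TE", "Homogeneity TE",
    "DC1", "Mean DC1", "LC1", "Mean LC1", "DC2", "Mean DC2", "LC2", "Mean LC2",
    "Radius ER", "Sum ER", "Mean grey ER",
    "Deviation RR", "Mean grey RR", "Mode value RR",
    "Dark RR", "Mean Count RR", "Bright RR",
    "Deviation TE", "Mean grey TE", "Mode value TE",
    "Dark TE", "Mean Count TE", "Bright TE",
    "WSN", "Area ICM", "Convex ICM", "Eccen ICM", "Mean ICM",
)

GRADE_COLUMNS = ("Grade 1", "Grade 2", "Grade 3")
MODE_COLUMN = "Mode"


@dataclass
class FeatureVector36:
    """One image's 36 named variables plus quality flags."""

    image_id: str
    values: dict[str, float]
    quality_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if tuple(self.values.keys()) != FEATURE_NAMES:
            raise InputError("FeatureVector36 requires the 36 canonical variables in order")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in FEATURE_NAMES], dtype=np.float64)


@dataclass(frozen=True)
class GradeRecord:
    """Three embryologists' IETS grades for one image, plus their mode."""

    image_id: str
    g1: int
    g2: int
    g3: int

    def __post_init__(self) -> None:
        for g in (self.g1, self.g2, self.g3):
            if g not in (1, 2, 3):
                raise InputError(f"IETS grade must be 1, 2 or 3, got {g}")

    @property
    def mode(self) -> int:
        return modal_grade(self.g1, self.g2, self.g3)


def extract_all(source, config: PipelineConfig | None = None, image_id: str | None = None) -> FeatureVector36:
    """Run the whole pipeline on one image and return its 36 variables.

    ``source`` is a file path or an in-memory image array.  Deterministic
    for a fixed (input, config).  Any stage failure raises
    :class:`ExtractionError` carrying the stage name — never a partial row.
    """
    cfg = config or DEFAULT_CONFIG
    if image_id is None:
        image_id = Path(source).stem if isinstance(source, (str, Path)) else "<array>"

    stage = "standardize"
    try:
        std = standardize_image(source, cfg)
        stage = "segment"
        masks = segment_image(std, cfg)
        stage = "texture"
        values: dict[str, float] = {}
        flags: set[str] = set()
        for stage, fn in (
            ("texture", glcm_texture.texture_features),
            ("circles", hough_circles.circle_features),
            ("intensity", intensity_stats.intensity_features),
            ("watershed", watershed_icm.watershed_features),
        ):
            part, part_flags = fn(masks, cfg)
            values.update(part)
            flags |= part_flags
    except BlastoquantError as exc:
        raise ExtractionError(image_id, stage, exc) from exc
    ordered = {k: values[k] for k in FEATURE_NAMES}
    return FeatureVector36(image_id=image_id, values=ordered, quality_flags=flags)


# -- table I/O --------------------------------------------------------------


def rows_to_frame(
    rows: list[FeatureVector36], grades: dict[str, GradeRecord] | None = None
) -> pd.DataFrame:
    """Assemble feature rows (and optional grades) into the canonical layout."""
    if not rows:
        raise InputError("need at least one feature row")
    records = []
    for row in rows:
        rec: dict[str, object] = {"image_id": row.image_id}
        rec.update(row.values)
        gr = (grades or {}).get(row.image_id)
        if gr is not None:
            rec[GRADE_COLUMNS[0]] = gr.g1
            rec[GRADE_COLUMNS[1]] = gr.g2
            rec[GRADE_COLUMNS[2]] = gr.g3
            rec[MODE_COLUMN] = gr.mode
        else:
            for col in (*GRADE_COLUMNS, MODE_COLUMN):
                rec[col] = np.nan
        rec["quality_flags"] = ";".join(sorted(row.quality_flags))
        records.append(rec)
    cols = ["image_id", *FEATURE_NAMES, *GRADE_COLUMNS, MODE_COLUMN, "quality_flags"]
    return pd.DataFrame.from_records(records, columns=cols)


def write_table(
    rows: list[FeatureVector36],
    path: str | Path,
    grades: dict[str, GradeRecord] | None = None,
) -> pd.DataFrame:
    """Write the feature table as CSV (or XLSX when the suffix is .xlsx).

    Undefined statistics (NaN) become empty cells; the ``quality_flags``
    column records which values were degenerate.
    """
    frame = rows_to_frame(rows, grades)
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        frame.to_excel(path, index=False)
    else:
        frame.to_csv(path, index=False)
    return frame


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_table`."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"table not found: {path}")
    if path.suffix.lower() in (".xlsx", ".xls"):
        frame = pd.read_excel(path)
    else:
        frame = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in frame.columns]
    if missing:
        raise TableError(f"table lacks variable columns: {missing[:3]}...")
    return frame


def read_deposited_table(path: str | Path) -> pd.DataFrame:
    """Read the deposited spreadsheet layout by column position.

    Columns D..AM (0-based 3..38) are the 36 variables, AN..AP (39..41) the
    three grades, AQ (42) their mode.  Returns a frame with canonical names.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"deposited table not found: {path}")
    raw = pd.read_excel(path)
    if raw.shape[1] < 43:
        raise TableError(f"expected >= 43 columns (A..AQ), found {raw.shape[1]}")
    frame = pd.DataFrame({"image_id": raw.iloc[:, 0].astype(str)})
    for k, name in enumerate(FEATURE_NAMES):
        frame[name] = pd.to_numeric(raw.iloc[:, 3 + k], errors="coerce")
    for k, name in enumerate(GRADE_COLUMNS):
        frame[name] = pd.to_numeric(raw.iloc[:, 39 + k], errors="coerce")
    frame[MODE_COLUMN] = pd.to_numeric(raw.iloc[:, 42], errors="coerce")
    return frame


# -- grading ----------------------------------------------------------------


def modal_grade(g1: int, g2: int, g3: int) -> int:
    """Mode of three IETS grades; a 3-way disagreement resolves to the median.

    For three raters on grades {1,2,3} the majority grade, when one exists,
    equals the median of the sorted triple, and the (1,2,3) tie resolves to
    2 — so the median implements both rules.
    """
    grades = (g1, g2, g3)
    for g in grades:
        if g not in (1, 2, 3):
            raise InputError(f"IETS grade must be 1, 2 or 3, got {g}")
    counts = Counter(grades)
    top, n = counts.most_common(1)[0]
    if n >= 2:
        return int(top)
    return int(sorted(grades)[1])


def _grade_matrix(grades) -> np.ndarray:
    arr = np.asarray(grades)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise InputError("grades must be an (n_items, 3 raters) array")
    if arr.shape[0] < 2:
        raise InputError("need at least 2 items")
    if not np.isin(arr, (1, 2, 3)).all():
        raise InputError("grades must all be 1, 2 or 3")
    return arr.astype(int)


def fleiss_kappa(grades) -> float:
    """Fleiss' kappa for n items x 3 raters on categories {1, 2, 3}.

    Returns NaN when expected agreement is 1 (all items unanimous in a
    single category), where kappa is undefined.
    """
    arr = _grade_matrix(grades)
    table, _ = inter_rater.aggregate_raters(arr - 1, n_cat=3)
    marg = table.sum(axis=0) / table.sum()
    if np.max(marg) >= 1.0:
        return float("nan")
    return float(inter_rater.fleiss_kappa(table, method="fleiss"))


def light_kappa(grades) -> float:
    """Light's kappa: mean pairwise Cohen's kappa over the three rater pairs."""
    arr = _grade_matrix(grades)
    kappas = []
    for a, b in ((0, 1), (0, 2), (1, 2)):
        table = np.zeros((3, 3))
        for i, j in zip(arr[:, a], arr[:, b]):
            table[i - 1, j - 1] += 1
        res = inter_rater.cohens_kappa(table, return_results=False)
        kappas.append(float(res))
    return float(np.mean(kappas))


def grade_report(frame: pd.DataFrame) -> dict:
    """Modal-grade counts and both kappa variants from a table with grades."""
    for col in GRADE_COLUMNS:
        if col not in frame.columns:
            raise TableError(f"missing grade column {col!r}")
    g = frame.loc[:, list(GRADE_COLUMNS)].dropna()
    if len(g) < 2:
        raise TableError("need at least 2 graded rows")
    arr = g.to_numpy()
    if not np.isin(arr, (1, 2, 3)).all():
        bad = sorted(set(arr.ravel()) - {1, 2, 3})
        raise TableError(f"invalid grade value(s): {bad}")
    arr = arr.astype(int)
    if MODE_COLUMN in frame.columns and frame[MODE_COLUMN].notna().all():
        modes = frame.loc[g.index, MODE_COLUMN].astype(int).to_numpy()
    else:
        modes = np.array([modal_grade(*row) for row in arr])
    counts = {grade: int((modes == grade).sum()) for grade in (1, 2, 3)}
    fk = fleiss_kappa(arr)
    lk = light_kappa(arr)
    return {
        "n": int(len(arr)),
        "modal_counts": counts,
        "fleiss_kappa": fk if not math.isnan(fk) else None,
        "light_kappa": lk,
    }
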