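"""Landmark and feature table I/O.

Defines the 15-landmark schema for the C2–C4 cervical vertebrae and the
coordinate conventions everything downstream relies on.

Internal convention: coordinates in millimetres, y increasing upward
(anatomically superior).  Digitization software that exports image
coordinates (y increasing downward) is handled by the ``convention="image"``
flag on the readers, which negates y on input.

Canonical on-disk form is a long CSV with columns
``subject_id,age,point_label,x_mm,y_mm`` (optionally ``true_stage``); a wide
form with one row per subject and ``<label>_x``/``<label>_y`` columns is
accepted for convenience.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: The 15 recognized landmark labels.  C2 contributes only its lower border
#: (a, p, d); C3 and C4 contribute the full body quadrilateral (la, lp, ua,
#: up), the upper-border midpoint (um) and the lower-border apex (d).
LANDMARK_LABELS: tuple[str, ...] = (
    "C2a", "C2p", "C2d",
    "C3la", "C3lp", "C3ua", "C3up", "C3um", "C3d",
    "C4la", "C4lp", "C4ua", "C4up", "C4um", "C4d",
)

#: Feature-table columns, in canonical order (see morphometry.FEATURE_NAMES).
FEATURE_COLUMNS: tuple[str, ...] = (
    "D2", "D3", "D4", "AH3", "AH4", "PH3", "PH4", "UW3", "UW4", "LW3", "LW4",
    "D3_AH3", "D4_AH4", "PH3_UW3", "PH4_UW4", "PH3_LW3", "PH4_LW4",
    "ang2", "ang3", "ang4",
    "C2a_C3ua", "C2p_C3up", "C3la_C4ua", "C3lp_C4up",
)

DEFAULT_AGE_RANGE: tuple[float, float] = (4.0, 25.0)

VALID_STAGES = (1, 2, 3, 4)


@dataclass(frozen=True)
class LandmarkPoint:
    """A labeled 2-D landmark in millimetres (internal y-up convention)."""

    label: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.label not in LANDMARK_LABELS:
            raise ValidationError(f"unknown landmark label {self.label!r}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(
                f"non-finite coordinates for landmark {self.label!r}: "
                f"({self.x}, {self.y})"
            )


@dataclass
class SubjectRecord:
    """One subject: id, chronological age (years), optional expert stage,
    and the 15 landmarks keyed by label."""

    subject_id: str
    age: float
    points: dict[str, LandmarkPoint]
    true_stage: int | None = None

    def point(self, label: str) -> LandmarkPoint:
        try:
            return self.points[label]
        except KeyError:
            raise ValidationError(
                f"subject {self.subject_id!r}: missing landmark {label!r}"
            ) from None

    def validate(self, age_range: tuple[float, float] = DEFAULT_AGE_RANGE) -> None:
        """Check the 15-point schema, age plausibility and superior/inferior
        ordering of the C3/C4 borders (y-up convention)."""
        missing = [lbl for lbl in LANDMARK_LABELS if lbl not in self.points]
        if missing:
            raise ValidationError(
                f"subject {self.subject_id!r}: missing landmark(s) "
                + ", ".join(missing)
            )
        extra = [lbl for lbl in self.points if lbl not in LANDMARK_LABELS]
        if extra:
            raise ValidationError(
                f"subject {self.subject_id!r}: unknown landmark(s) "
                + ", ".join(extra)
            )
        lo, hi = age_range
        if not (lo <= self.age <= hi):
            raise ValidationError(
                f"subject {self.subject_id!r}: age {self.age} outside the "
                f"plausibility window [{lo}, {hi}] years"
            )
        if self.true_stage is not None and self.true_stage not in VALID_STAGES:
            raise ValidationError(
                f"subject {self.subject_id!r}: true_stage {self.true_stage!r} "
                f"not in {VALID_STAGES}"
            )
        for vert in ("C3", "C4"):
            for upper, lower in ((f"{vert}ua", f"{vert}la"), (f"{vert}up", f"{vert}lp")):
                if self.points[upper].y <= self.points[lower].y:
                    raise ValidationError(
                        f"subject {self.subject_id!r}: {upper} must be superior "
                        f"to {lower} (y_{upper}={self.points[upper].y:.3f} <= "
                        f"y_{lower}={self.points[lower].y:.3f})"
                    )


@dataclass
class Cohort:
    """Ordered collection of subjects with free-text provenance."""

    subjects: list[SubjectRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        seen: set[str] = set()
        for sid in ids:
            if sid in seen:
                raise ValidationError(f"duplicate subject_id {sid!r} in cohort")
            seen.add(sid)

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.subjects)

    def validate(self, age_range: tuple[float, float] = DEFAULT_AGE_RANGE) -> None:
        for s in self.subjects:
            s.validate(age_range)

    @property
    def true_stages(self) -> list[int | None]:
        return [s.true_stage for s in self.subjects]


def _to_internal_y(y: float, convention: str) -> float:
    if convention == "math":
        return y
    if convention == "image":
        return -y
    raise ValidationError(f"unknown axis convention {convention!r} (use 'math' or 'image')")


def _numeric(series: pd.Series, colname: str) -> pd.Series:
    converted = pd.to_numeric(series, errors="coerce")
    bad = converted.isna() & series.notna()
    if bad.any():
        row = int(bad.idxmax())
        raise ParseError(
            f"non-numeric value {series[row]!r} in column {colname!r} "
            f"(data row {row + 1})"
        )
    return converted


def read_landmark_table(
    path: str | Path,
    convention: str = "math",
    age_range: tuple[float, float] = DEFAULT_AGE_RANGE,
) -> Cohort:
    """Read a landmark CSV (long or wide) into a validated :class:`Cohort`.

    ``convention="image"`` declares y increasing downward (the usual
    digitizer export); those y values are negated on input so that all
    in-memory coordinates follow the y-up convention.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    if "point_label" in df.columns:
        cohort = _read_long(df, convention)
    else:
        cohort = _read_wide(df, convention)
    cohort.provenance = f"read from {path.name} (convention={convention})"
    cohort.validate(age_range)
    return cohort


def _read_long(df: pd.DataFrame, convention: str) -> Cohort:
    required = {"subject_id", "age", "point_label", "x_mm", "y_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError("landmark CSV missing column(s): " + ", ".join(sorted(missing)))
    df = df.copy()
    df["age"] = _numeric(df["age"], "age")
    df["x_mm"] = _numeric(df["x_mm"], "x_mm")
    df["y_mm"] = _numeric(df["y_mm"], "y_mm")
    has_stage = "true_stage" in df.columns
    subjects: list[SubjectRecord] = []
    for sid, grp in df.groupby("subject_id", sort=False):
        points: dict[str, LandmarkPoint] = {}
        for _, row in grp.iterrows():
            lbl = str(row["point_label"])
            if lbl in points:
                raise ValidationError(f"subject {sid!r}: duplicate landmark {lbl!r}")
            points[lbl] = LandmarkPoint(lbl, float(row["x_mm"]),
                                        _to_internal_y(float(row["y_mm"]), convention))
        stage = None
        if has_stage:
            vals = grp["true_stage"].dropna().unique()
            if len(vals) > 1:
                raise ValidationError(f"subject {sid!r}: inconsistent true_stage values")
            if len(vals) == 1:
                stage = int(vals[0])
        subjects.append(SubjectRecord(str(sid), float(grp["age"].iloc[0]), points, stage))
    return Cohort(subjects)


def _read_wide(df: pd.DataFrame, convention: str) -> Cohort:
    coord_cols = [f"{lbl}_{ax}" for lbl in LANDMARK_LABELS for ax in ("x", "y")]
    missing = [c for c in ["subject_id", "age", *coord_cols] if c not in df.columns]
    if missing:
        raise ParseError("landmark CSV missing column(s): " + ", ".join(missing))
    subjects: list[SubjectRecord] = []
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        points = {
            lbl: LandmarkPoint(
                lbl,
                float(_numeric(pd.Series([row[f"{lbl}_x"]]), f"{lbl}_x").iloc[0]),
                _to_internal_y(
                    float(_numeric(pd.Series([row[f"{lbl}_y"]]), f"{lbl}_y").iloc[0]),
                    convention,
                ),
            )
            for lbl in LANDMARK_LABELS
        }
        stage = None
        if "true_stage" in df.columns and pd.notna(row["true_stage"]):
            stage = int(row["true_stage"])
        subjects.append(SubjectRecord(sid, float(row["age"]), points, stage))
    return Cohort(subjects)


def write_landmark_table(cohort: Cohort, path: str | Path) -> None:
    """Write the canonical long-format CSV (y-up convention, 6 decimals)."""
    rows = []
    any_stage = any(s.true_stage is not None for s in cohort)
    for s in cohort:
        for lbl in LANDMARK_LABELS:
            if lbl not in s.points:
                raise ValidationError(f"subject {s.subject_id!r}: missing landmark {lbl!r}")
            p = s.points[lbl]
            row = {
                "subject_id": s.subject_id,
                "age": s.age,
                "point_label": lbl,
                "x_mm": p.x,
                "y_mm": p.y,
            }
            if any_stage:
                row["true_stage"] = s.true_stage
            rows.append(row)
    cols = ["subject_id", "age", "point_label", "x_mm", "y_mm"]
    if any_stage:
        cols.append("true_stage")
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.6f")


def read_feature_table(
    path: str | Path,
    required_features: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Read a feature CSV into a DataFrame.

    Mandatory columns are ``subject_id`` and ``age``; ``true_stage`` is kept
    when present.  ``required_features`` (default: none beyond age) lets a
    caller insist on specific measurement columns — prediction with the
    packaged primary model, e.g., needs only its four terms.  Unknown columns
    are ignored with a logged warning.
    """
    df = pd.read_csv(Path(path), dtype={"subject_id": str})
    for col in ("subject_id", "age"):
        if col not in df.columns:
            raise ParseError(f"feature CSV missing mandatory column {col!r}")
    known = {"subject_id", "age", "true_stage", *FEATURE_COLUMNS}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        logger.warning("ignoring unknown feature column(s): %s", ", ".join(unknown))
        df = df.drop(columns=unknown)
    if required_features:
        missing = [c for c in required_features if c not in df.columns]
        if missing:
            raise ParseError("feature CSV missing column(s): " + ", ".join(missing))
    df["age"] = _numeric(df["age"], "age")
    for col in df.columns:
        if col in FEATURE_COLUMNS:
            df[col] = _numeric(df[col], col)
    return df


def write_feature_table(features: pd.DataFrame, path: str | Path) -> None:
    """Write a feature DataFrame to CSV with 6-decimal coordinates."""
    features.to_csv(path, index=False, float_format="%.6f")
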