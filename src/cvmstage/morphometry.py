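"""Morphometric parameters of the C2–C4 vertebral bodies.

From the 15 landmarks of a subject, 24 quantities are computed:

* concavity depths D2, D3, D4 — perpendicular distance of the lower-border
  apex (d) to the line through the lower-border endpoints; ≈ 0 for the flat
  borders of immature vertebrae;
* body heights AH3/4 (anterior) and PH3/4 (posterior) — distances of ua/up
  to the lower-border line;
* body widths UW3/4 (upper) and LW3/4 (lower) — distances of ua/la to the
  posterior-border line (up–lp);
* six dimensionless ratios D:AH, PH:UW, PH:LW per vertebra;
* antero-superior angles @2, @3, @4 at the posterior-inferior landmark,
  between the rays to d and to the anterior-inferior landmark;
* four inter-vertebral Euclidean distances (C2a–C3ua, C2p–C3up, C3la–C4ua,
  C3lp–C4up), which shrink as the inter-body spaces close with maturation.

All quantities are built from unsigned point-to-line distances, vertex
angles and point distances, so they are invariant under rigid motion and
reflection (in particular the image-vs-math y-axis convention) and scale
linearly (distances) or not at all (ratios, angles) with uniform scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import GeometryError, ValidationError
from .landmarks import Cohort, SubjectRecord

#: Canonical feature order (matches the feature-CSV column order).
FEATURE_NAMES: tuple[str, ...] = (
    "D2", "D3", "D4", "AH3", "AH4", "PH3", "PH4", "UW3", "UW4", "LW3", "LW4",
    "D3_AH3", "D4_AH4", "PH3_UW3", "PH4_UW4", "PH3_LW3", "PH4_LW4",
    "ang2", "ang3", "ang4",
    "C2a_C3ua", "C2p_C3up", "C3la_C4ua", "C3lp_C4up",
)

#: Names a staging or correction model may reference.
MODEL_FEATURE_NAMES: tuple[str, ...] = ("age", *FEATURE_NAMES)


def point_line_distance(p, a, b) -> float:
    """Unsigned perpendicular distance (mm) from ``p`` to the infinite line
    through ``a`` and ``b``: |cross(b−a, p−a)| / |b−a|.

    Raises :class:`GeometryError` if ``a`` and ``b`` coincide.
    """
    p = np.asarray(p, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    norm = float(np.hypot(*ab))
    if norm == 0.0:
        raise GeometryError(f"degenerate line: points {a.tolist()} and {b.tolist()} coincide")
    ap = p - a
    return abs(float(ab[0] * ap[1] - ab[1] * ap[0])) / norm


def vertex_angle(vertex, q1, q2) -> float:
    """Unsigned angle in degrees, in [0, 180], between the rays
    vertex→q1 and vertex→q2.

    Computed as atan2(|u×v|, u·v) rather than arccos of the normalized dot
    product: the two are mathematically identical, but atan2 stays
    well-conditioned for the near-collinear rays that flat vertebral
    borders produce (arccos loses ~8 digits there).
    """
    vertex = np.asarray(vertex, dtype=float)
    u = np.asarray(q1, dtype=float) - vertex
    v = np.asarray(q2, dtype=float) - vertex
    if np.hypot(*u) == 0.0 or np.hypot(*v) == 0.0:
        raise GeometryError("zero-length ray: a ray endpoint coincides with the vertex")
    cross = u[0] * v[1] - u[1] * v[0]
    return float(np.degrees(np.arctan2(abs(cross), float(np.dot(u, v)))))


@dataclass(frozen=True)
class FeatureVector:
    """Age plus the 24 morphometric parameters of one subject."""

    age: float
    D2: float
    D3: float
    D4: float
    AH3: float
    AH4: float
    PH3: float
    PH4: float
    UW3: float
    UW4: float
    LW3: float
    LW4: float
    D3_AH3: float
    D4_AH4: float
    PH3_UW3: float
    PH4_UW4: float
    PH3_LW3: float
    PH4_LW4: float
    ang2: float
    ang3: float
    ang4: float
    C2a_C3ua: float
    C2p_C3up: float
    C3la_C4ua: float
    C3lp_C4up: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def validate(self) -> None:
        d = self.as_dict()
        for name, value in d.items():
            if not np.isfinite(value):
                raise ValidationError(f"feature {name!r} is not finite: {value!r}")
        for name in ("D2", "D3", "D4", "AH3", "AH4", "PH3", "PH4",
                     "UW3", "UW4", "LW3", "LW4",
                     "C2a_C3ua", "C2p_C3up", "C3la_C4ua", "C3lp_C4up"):
            if d[name] < 0:
                raise ValidationError(f"distance feature {name!r} is negative: {d[name]!r}")
        for name in ("ang2", "ang3", "ang4"):
            if not (0.0 <= d[name] <= 180.0):
                raise ValidationError(f"angle {name!r} outside [0, 180]: {d[name]!r}")
        for ratio, num, den in (
            ("D3_AH3", "D3", "AH3"), ("D4_AH4", "D4", "AH4"),
            ("PH3_UW3", "PH3", "UW3"), ("PH4_UW4", "PH4", "UW4"),
            ("PH3_LW3", "PH3", "LW3"), ("PH4_LW4", "PH4", "LW4"),
        ):
            expected = d[num] / d[den]
            if not np.isclose(d[ratio], expected, rtol=1e-9, atol=0.0):
                raise ValidationError(
                    f"ratio {ratio!r}={d[ratio]!r} inconsistent with {num}/{den}={expected!r}"
                )


def _xy(subject: SubjectRecord, label: str) -> np.ndarray:
    p = subject.point(label)
    return np.array([p.x, p.y])


def _dist_to_border(subject: SubjectRecord, point: str, a: str, b: str) -> float:
    try:
        return point_line_distance(_xy(subject, point), _xy(subject, a), _xy(subject, b))
    except GeometryError as exc:
        raise GeometryError(
            f"subject {subject.subject_id!r}: landmarks {a} and {b} coincide"
        ) from exc


def extract_features(subject: SubjectRecord) -> FeatureVector:
    """Compute the 24 morphometric parameters from a subject's landmarks."""
    d = {}
    d["D2"] = _dist_to_border(subject, "C2d", "C2a", "C2p")
    for v in ("3", "4"):
        la, lp, ua, up = f"C{v}la", f"C{v}lp", f"C{v}ua", f"C{v}up"
        d[f"D{v}"] = _dist_to_border(subject, f"C{v}d", la, lp)
        d[f"AH{v}"] = _dist_to_border(subject, ua, la, lp)
        d[f"PH{v}"] = _dist_to_border(subject, up, la, lp)
        d[f"UW{v}"] = _dist_to_border(subject, ua, up, lp)
        d[f"LW{v}"] = _dist_to_border(subject, la, up, lp)
        for name, num in ((f"D{v}_AH{v}", f"D{v}"), (f"PH{v}_UW{v}", f"PH{v}"),
                          (f"PH{v}_LW{v}", f"PH{v}")):
            den = name.split("_")[1]
            if d[den] == 0.0:
                raise GeometryError(
                    f"subject {subject.subject_id!r}: {den} is zero, ratio {name} undefined"
                )
        d[f"D{v}_AH{v}"] = d[f"D{v}"] / d[f"AH{v}"]
        d[f"PH{v}_UW{v}"] = d[f"PH{v}"] / d[f"UW{v}"]
        d[f"PH{v}_LW{v}"] = d[f"PH{v}"] / d[f"LW{v}"]
    d["ang2"] = vertex_angle(_xy(subject, "C2p"), _xy(subject, "C2d"), _xy(subject, "C2a"))
    d["ang3"] = vertex_angle(_xy(subject, "C3lp"), _xy(subject, "C3d"), _xy(subject, "C3la"))
    d["ang4"] = vertex_angle(_xy(subject, "C4lp"), _xy(subject, "C4d"), _xy(subject, "C4la"))
    for name, (p1, p2) in {
        "C2a_C3ua": ("C2a", "C3ua"),
        "C2p_C3up": ("C2p", "C3up"),
        "C3la_C4ua": ("C3la", "C4ua"),
        "C3lp_C4up": ("C3lp", "C4up"),
    }.items():
        d[name] = float(np.hypot(*(_xy(subject, p1) - _xy(subject, p2))))
    return FeatureVector(age=subject.age, **d)


def signed_concavity_depths(subject: SubjectRecord) -> dict[str, float]:
    """Diagnostic signed depths: positive when the lower-border apex lies
    superior to the endpoint line (the anatomically expected direction),
    negative for an inferior (convex) displacement.  Never used by the
    staging models, which see the unsigned D2/D3/D4.
    """
    out = {}
    for name, (apex, a, b) in {
        "D2": ("C2d", "C2a", "C2p"),
        "D3": ("C3d", "C3la", "C3lp"),
        "D4": ("C4d", "C4la", "C4lp"),
    }.items():
        pa, pb, pp = _xy(subject, a), _xy(subject, b), _xy(subject, apex)
        ab = pb - pa
        norm = float(np.hypot(*ab))
        if norm == 0.0:
            raise GeometryError(f"subject {subject.subject_id!r}: landmarks {a} and {b} coincide")
        # unit normal with positive y-component = "superior" side
        n = np.array([-ab[1], ab[0]]) / norm
        if n[1] < 0:
            n = -n
        out[name] = float(np.dot(pp - pa, n))
    return out


def extract_features_frame(cohort: Cohort | Iterable[SubjectRecord]) -> pd.DataFrame:
    """Feature table for a cohort: one row per subject, columns
    ``subject_id, age, <24 features>[, true_stage]``."""
    rows = []
    for s in cohort:
        fv = extract_features(s)
        row: dict[str, object] = {"subject_id": s.subject_id, **fv.as_dict()}
        if s.true_stage is not None:
            row["true_stage"] = s.true_stage
        rows.append(row)
    cols = ["subject_id", "age", *FEATURE_NAMES]
    if any("true_stage" in r for r in rows):
        cols.append("true_stage")
    return pd.DataFrame(rows, columns=cols)
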