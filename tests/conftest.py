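import numpy as np
import pytest
from dataclasses import replace

from cvmstage import (
    Cohort,
    LandmarkPoint,
    SimulationConfig,
    SubjectRecord,
    simulate_landmarks,
)
from cvmstage.landmarks import LANDMARK_LABELS
from cvmstage.synthetic import DEFAULT_TEMPLATES


def make_subject(points_xy: dict[str, tuple[float, float]], subject_id="s1",
                 age=12.0, true_stage=None) -> SubjectRecord:
    points = {lbl: LandmarkPoint(lbl, float(x), float(y))
              for lbl, (x, y) in points_xy.items()}
    return SubjectRecord(subject_id, age, points, true_stage)


def rectangle_points(width=12.0, height=10.0, gap=5.0) -> dict[str, tuple[float, float]]:
    """Three stacked axis-aligned rectangular bodies with flat borders and
    d at the lower-border midpoint (immature morphology, zero concavity)."""
    pts: dict[str, tuple[float, float]] = {}
    for vert, y0 in (("C4", 0.0), ("C3", height + gap)):
        pts[f"{vert}la"] = (0.0, y0)
        pts[f"{vert}lp"] = (width, y0)
        pts[f"{vert}ua"] = (0.0, y0 + height)
        pts[f"{vert}up"] = (width, y0 + height)
        pts[f"{vert}um"] = (width / 2.0, y0 + height)
        pts[f"{vert}d"] = (width / 2.0, y0)
    y2 = 2 * (height + gap)
    pts["C2a"] = (0.0, y2)
    pts["C2p"] = (width, y2)
    pts["C2d"] = (width / 2.0, y2)
    return pts


@pytest.fixture
def rect_subject() -> SubjectRecord:
    return make_subject(rectangle_points(), subject_id="rect", age=8.0)


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """8 subjects per stage, default templates, fixed seed."""
    return simulate_landmarks(SimulationConfig(seed=11, n_per_stage=8))


@pytest.fixture(scope="session")
def noiseless_templates():
    return tuple(replace(t, sd_height=0.0, sd_width=0.0, sd_depth=0.0, sd_gap=0.0)
                 for t in DEFAULT_TEMPLATES)
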