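"""The cascade CVM staging model.

The primary model is a proportional-odds (cumulative-logit) model over the
four condensed maturation stages iCS1–iCS4:

    P(y <= j | x) = sigma(alpha_j - beta.x),   j = 1, 2, 3,

with strictly increasing thresholds alpha_1 < alpha_2 < alpha_3 and a single
slope vector beta, so a larger linear predictor beta.x means a more mature
stage.  Per-stage probabilities are the differences of consecutive
cumulative probabilities; the predicted stage is the argmax, ties broken
toward the more mature stage (mirroring the clinical rule that in-between
morphology is assigned to the later stage).

Because the pubertal-slowdown stage (iCS3) is the hardest to separate from
the adjacent post-pubertal stage, a second, binary logistic model
disambiguates iCS3 vs iCS4 whenever the primary prediction lands in {3, 4}:
P(iCS = 3 | x) = sigma(alpha - beta_c.x), decided at probability 0.5.

The published female-adolescent coefficients ship as ``PRIMARY_MODEL``
("primary-2024") and ``CORRECTION_MODEL`` ("correction-2024"); they apply to
raw feature values (years, millimetres, degrees, ratios), not z-scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ModelError
from .morphometry import MODEL_FEATURE_NAMES, FeatureVector

STAGES = (1, 2, 3, 4)

FeatureLike = FeatureVector | Mapping[str, float] | pd.Series


def _check_slope_keys(slopes: Mapping[str, float]) -> None:
    for key in slopes:
        if key not in MODEL_FEATURE_NAMES:
            raise ModelError(f"unknown feature {key!r} in model slopes")


@dataclass
class OrdinalStageModel:
    """Proportional-odds stage model: slopes + 3 ordered thresholds."""

    slopes: dict[str, float]
    thresholds: tuple[float, float, float]
    feature_scale: str = "raw"
    feature_means: dict[str, float] | None = None
    feature_sds: dict[str, float] | None = None

    def __post_init__(self) -> None:
        _check_slope_keys(self.slopes)
        t = tuple(float(v) for v in self.thresholds)
        if len(t) != 3 or not (t[0] < t[1] < t[2]):
            raise ModelError(f"thresholds must be 3 strictly increasing values, got {t}")
        self.thresholds = t
        if self.feature_scale not in ("raw", "zscored"):
            raise ModelError(f"feature_scale must be 'raw' or 'zscored', got {self.feature_scale!r}")


@dataclass
class BinaryCorrectionModel:
    """Binary logistic iCS3-vs-iCS4 disambiguator: P(iCS=3) = sigma(alpha - beta.x)."""

    slopes: dict[str, float]
    threshold: float
    decision_cut: float = 0.5

    def __post_init__(self) -> None:
        _check_slope_keys(self.slopes)
        self.threshold = float(self.threshold)
        if not (0.0 < self.decision_cut < 1.0):
            raise ModelError(f"decision_cut must lie in (0, 1), got {self.decision_cut!r}")


@dataclass
class StagePrediction:
    """One subject's staged prediction (probabilities over iCS1..iCS4)."""

    probabilities: np.ndarray
    linear_predictor_primary: float
    stage_primary: int
    stage_final: int
    correction_applied: bool = False
    linear_predictor_correction: float | None = None
    p_ics3: float | None = None


#: Published primary proportional-odds model (female adolescents, raw scale).
PRIMARY_MODEL = OrdinalStageModel(
    slopes={"age": 3.172, "D3_AH3": 28.642, "ang4": 0.727, "C3lp_C4up": 0.453},
    thresholds=(32.921, 45.460, 62.065),
)

#: Published binary iCS3-vs-iCS4 correction model.
CORRECTION_MODEL = BinaryCorrectionModel(
    slopes={"age": 2.139, "ang4": 0.313, "PH4": 1.444},
    threshold=51.828,
)

_REGISTRY: dict[str, OrdinalStageModel | BinaryCorrectionModel] = {
    "primary-2024": PRIMARY_MODEL,
    "correction-2024": CORRECTION_MODEL,
}


def get_model(name: str) -> OrdinalStageModel | BinaryCorrectionModel:
    """Look up a packaged model by name ('primary-2024', 'correction-2024')."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ModelError(
            f"unknown model name {name!r}; packaged models: {sorted(_REGISTRY)}"
        ) from None


def _feature_value(fv: FeatureLike, name: str) -> float:
    if isinstance(fv, FeatureVector):
        try:
            return float(getattr(fv, name))
        except AttributeError:
            raise ModelError(f"feature vector is missing model term {name!r}") from None
    try:
        return float(fv[name])
    except (KeyError, IndexError):
        raise ModelError(f"feature vector is missing model term {name!r}") from None


def linear_predictor(
    model: OrdinalStageModel | BinaryCorrectionModel, fv: FeatureLike
) -> float:
    """beta.x = sum of slope_k * feature_k on the model's feature scale."""
    total = 0.0
    for name, slope in model.slopes.items():
        value = _feature_value(fv, name)
        if isinstance(model, OrdinalStageModel) and model.feature_scale == "zscored":
            if not model.feature_means or not model.feature_sds:
                raise ModelError("zscored model lacks stored feature means/SDs")
            value = (value - model.feature_means[name]) / model.feature_sds[name]
        total += slope * value
    return total


def stage_probabilities(model: OrdinalStageModel, bx: float) -> np.ndarray:
    """Per-stage probabilities from the cumulative logits.

    gamma_j = P(y <= j) = sigma(alpha_j - bx), gamma_0 = 0, gamma_4 = 1;
    P(y = j) = gamma_j - gamma_{j-1}.  ``expit`` keeps this finite for any
    |bx| (saturating to a one-hot vector).
    """
    alpha = np.asarray(model.thresholds, dtype=float)
    gamma = np.concatenate(([0.0], expit(alpha - bx), [1.0]))
    probs = np.diff(gamma)
    # cumulative logits are ordered, so the diffs are nonnegative up to rounding
    return np.clip(probs, 0.0, 1.0)


def _argmax_mature(probs: np.ndarray) -> int:
    """Argmax over stages with ties resolved toward the more mature stage."""
    rev = probs[::-1]
    return int(len(probs) - np.argmax(rev))


def predict_primary(model: OrdinalStageModel, fv: FeatureLike) -> StagePrediction:
    """Apply the primary ordinal model alone."""
    bx = linear_predictor(model, fv)
    probs = stage_probabilities(model, bx)
    stage = _argmax_mature(probs)
    return StagePrediction(
        probabilities=probs,
        linear_predictor_primary=bx,
        stage_primary=stage,
        stage_final=stage,
    )


def correction_probability(model: BinaryCorrectionModel, fv: FeatureLike) -> float:
    """P(iCS = 3) = sigma(alpha - beta_c.x): the probability mass below the
    single cutpoint, in the same link convention as the primary model."""
    return float(expit(model.threshold - linear_predictor(model, fv)))


def predict_cascade(
    fv: FeatureLike,
    primary: OrdinalStageModel = PRIMARY_MODEL,
    correction: BinaryCorrectionModel = CORRECTION_MODEL,
    trigger_stages: tuple[int, ...] = (3, 4),
) -> StagePrediction:
    """Primary prediction, then the binary iCS3/iCS4 disambiguation whenever
    the primary stage falls in ``trigger_stages``.  Primary predictions of
    stage 1 or 2 are never altered."""
    pred = predict_primary(primary, fv)
    if pred.stage_primary in trigger_stages:
        bx_c = linear_predictor(correction, fv)
        p3 = float(expit(correction.threshold - bx_c))
        pred.linear_predictor_correction = bx_c
        pred.p_ics3 = p3
        pred.correction_applied = True
        pred.stage_final = 3 if p3 >= correction.decision_cut else 4
    return pred


def predict_table(
    features: pd.DataFrame,
    primary: OrdinalStageModel = PRIMARY_MODEL,
    correction: BinaryCorrectionModel | None = CORRECTION_MODEL,
) -> pd.DataFrame:
    """Predict every row of a feature table.

    Returns columns ``subject_id, bx_primary, P1..P4, stage_primary,
    bx_correction, P_iCS3, stage_final, correction_applied``.  Passing
    ``correction=None`` disables the cascade.
    """
    rows = []
    for _, row in features.iterrows():
        if correction is None:
            pred = predict_primary(primary, row)
        else:
            pred = predict_cascade(row, primary=primary, correction=correction)
        rows.append({
            "subject_id": row.get("subject_id", ""),
            "bx_primary": pred.linear_predictor_primary,
            "P1": pred.probabilities[0],
            "P2": pred.probabilities[1],
            "P3": pred.probabilities[2],
            "P4": pred.probabilities[3],
            "stage_primary": pred.stage_primary,
            "bx_correction": pred.linear_predictor_correction,
            "P_iCS3": pred.p_ics3,
            "stage_final": pred.stage_final,
            "correction_applied": pred.correction_applied,
        })
    return pd.DataFrame(rows)


def save_model(model: OrdinalStageModel | BinaryCorrectionModel, path: str | Path) -> None:
    """Serialize a model to JSON, preserving coefficients exactly
    (binary64 round-trips losslessly through repr)."""
    if isinstance(model, OrdinalStageModel):
        payload = {
            "kind": "ordinal",
            "slopes": model.slopes,
            "thresholds": list(model.thresholds),
            "scale": model.feature_scale,
        }
        if model.feature_means:
            payload["feature_means"] = model.feature_means
            payload["feature_sds"] = model.feature_sds
    else:
        payload = {
            "kind": "binary",
            "slopes": model.slopes,
            "thresholds": [model.threshold],
            "decision_cut": model.decision_cut,
            "scale": "raw",
        }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_model(path: str | Path) -> OrdinalStageModel | BinaryCorrectionModel:
    """Load a model JSON written by :func:`save_model`."""
    payload = json.loads(Path(path).read_text())
    kind = payload.get("kind")
    if kind == "ordinal":
        return OrdinalStageModel(
            slopes={k: float(v) for k, v in payload["slopes"].items()},
            thresholds=tuple(payload["thresholds"]),
            feature_scale=payload.get("scale", "raw"),
            feature_means=payload.get("feature_means"),
            feature_sds=payload.get("feature_sds"),
        )
    if kind == "binary":
        return BinaryCorrectionModel(
            slopes={k: float(v) for k, v in payload["slopes"].items()},
            threshold=float(payload["thresholds"][0]),
            decision_cut=float(payload.get("decision_cut", 0.5)),
        )
    raise ModelError(f"unknown model kind {kind!r} in {path}")
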