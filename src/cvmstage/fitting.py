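"""Model-development pipeline: screening, ordinal/binary MLE, diagnostics.

The pipeline mirrors how the staging model was developed:

1. univariate Spearman screen of every candidate feature against the
   expert stage (pass at p < 0.05; rank-based, so prior z-scoring of the
   features cannot change the outcome);
2. multivariable proportional-odds fit on the candidates, P(y<=j) =
   sigma(alpha_j - x.beta), with backward elimination of the largest
   non-significant Wald p until every retained term has p < 0.05;
3. diagnostics: the Brant test of the parallel-lines (proportional-odds)
   assumption and variance-inflation factors for multicollinearity
   (flag at VIF >= 5, i.e. tolerance < 0.2).

Maximum-likelihood fitting is delegated to statsmodels (``OrderedModel``
with the logit link — the same alpha_j - x.beta parameterization with
exp-increment threshold encoding — and ``Logit`` for the binary model).
The Brant test is implemented here following Brant (1990): the J-1
cumulative binary logits are fitted separately and a Wald chi-square
compares their slope vectors, using the joint covariance implied by the
overlapping binary responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .errors import FittingError, ValidationError
from .landmarks import Cohort
from .model import BinaryCorrectionModel, OrdinalStageModel
from .morphometry import extract_features_frame

_Z975 = 1.959963984540054  # Phi^{-1}(0.975)

#: |slope| on the standardized scale beyond which a fit is flagged as
#: quasi-separated (coefficients of that size mean near-deterministic
#: class assignment and unstable Wald statistics).
SEPARATION_SLOPE_LIMIT = 50.0


@dataclass
class Standardizer:
    """Stored column means/SDs for z-scoring and its inverse."""

    means: pd.Series
    sds: pd.Series

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        return (df[self.means.index] - self.means) / self.sds

    def inverse(self, zdf: pd.DataFrame) -> pd.DataFrame:
        return zdf[self.means.index] * self.sds + self.means


def zscore(features: pd.DataFrame) -> tuple[pd.DataFrame, Standardizer]:
    """Column-wise z-scoring; errors on any zero-variance column."""
    num = features.select_dtypes(include=[np.number])
    if len(num) < 2:
        raise FittingError("z-scoring needs at least 2 rows")
    sds = num.std(ddof=1)
    zero = sds.index[sds == 0.0].tolist()
    if zero:
        raise FittingError("zero-variance column(s): " + ", ".join(map(str, zero)))
    std = Standardizer(means=num.mean(), sds=sds)
    return std.transform(num), std


def spearman_screen(
    features: pd.DataFrame,
    stages: Sequence[int],
    alpha: float = 0.05,
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Univariate Spearman correlation of each feature with the stage.

    Returns a DataFrame indexed by feature with ``rho``, ``p_value`` and
    ``selected`` (p < alpha).  Average ranks for ties; p from the
    t-approximation (scipy's default).
    """
    stages = np.asarray(stages)
    if columns is None:
        columns = [c for c in features.columns
                   if c not in ("subject_id", "true_stage")
                   and pd.api.types.is_numeric_dtype(features[c])]
    rows = []
    for col in columns:
        rho, p = stats.spearmanr(features[col].to_numpy(dtype=float), stages)
        rows.append({"feature": col, "rho": float(rho), "p_value": float(p),
                     "selected": bool(p < alpha)})
    return pd.DataFrame(rows).set_index("feature")


@dataclass
class FitResult:
    """A fitted stage model with its inferential table.

    ``table`` mirrors the published coefficient layout: one row per
    threshold (``alpha_1``..) and per slope, with columns ``B, SE, Wald,
    p_value, ci_low, ci_high`` (CI = B ± 1.96·SE, Wald = (B/SE)^2).
    """

    slopes: dict[str, float]
    thresholds: list[float]
    table: pd.DataFrame
    loglik: float
    n: int
    levels: list[int]
    converged: bool
    separation_flag: bool = False

    def to_ordinal_model(self) -> OrdinalStageModel:
        if len(self.thresholds) != 3:
            raise FittingError(
                f"fit has {len(self.thresholds)} thresholds; a 4-stage model needs 3"
            )
        return OrdinalStageModel(slopes=dict(self.slopes),
                                 thresholds=tuple(self.thresholds))

    def to_correction_model(self) -> BinaryCorrectionModel:
        if len(self.thresholds) != 1:
            raise FittingError("a binary correction model needs exactly 1 threshold")
        return BinaryCorrectionModel(slopes=dict(self.slopes),
                                     threshold=self.thresholds[0])


def _check_design(X: pd.DataFrame) -> None:
    for col in X.columns:
        if X[col].std(ddof=1) == 0.0:
            raise FittingError(f"zero-variance feature {col!r} in the design")
        if not np.isfinite(X[col].to_numpy(dtype=float)).all():
            raise FittingError(f"non-finite values in feature {col!r}")


def _inference_table(names: list[str], est: np.ndarray, se: np.ndarray) -> pd.DataFrame:
    with np.errstate(invalid="ignore", divide="ignore"):
        wald = (est / se) ** 2
        p = np.where(np.isnan(wald), np.nan, stats.chi2.sf(wald, df=1))
    return pd.DataFrame({
        "B": est, "SE": se, "Wald": wald, "p_value": p,
        "ci_low": est - _Z975 * se, "ci_high": est + _Z975 * se,
    }, index=pd.Index(names, name="term"))


def _separation_flag(X: pd.DataFrame, slopes: dict[str, float]) -> bool:
    flagged = any(
        abs(slope) * X[name].std(ddof=1) > SEPARATION_SLOPE_LIMIT
        for name, slope in slopes.items()
    )
    if flagged:
        warnings.warn(
            "possible (quasi-)separation: a standardized slope exceeds "
            f"{SEPARATION_SLOPE_LIMIT}; estimates and SEs are unreliable",
            stacklevel=3,
        )
    return flagged


def fit_proportional_odds(
    features: pd.DataFrame,
    stages: Sequence[int],
    included: Sequence[str],
    maxiter: int = 200,
) -> FitResult:
    """Maximum-likelihood cumulative-logit fit on the included features.

    Thresholds are internally encoded as (alpha_1, alpha_1 + e^{d_2}, ...),
    so the fitted cutpoints are ordered by construction.  Threshold SEs are
    delta-method transforms of that encoding.
    """
    included = list(included)
    if not included:
        raise FittingError("no features included in the fit")
    X = features[included].astype(float).reset_index(drop=True)
    _check_design(X)
    y = np.asarray(stages, dtype=int)
    if len(y) != len(X):
        raise FittingError("features and stages differ in length")
    levels = sorted(np.unique(y))
    if len(levels) < 2:
        raise FittingError("stages must take at least 2 distinct values")
    endog = pd.Categorical(y, categories=levels, ordered=True)
    mod = OrderedModel(endog, X, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = mod.fit(method="bfgs", maxiter=maxiter, disp=False, gtol=1e-6)
    k = len(included)
    params = np.asarray(res.params, dtype=float)
    try:
        cov = np.asarray(res.cov_params(), dtype=float)
    except ValueError:
        # BFGS can stop without an invertible approximate Hessian (tiny n,
        # near-singular designs); fall back to the analytic one
        cov = np.linalg.pinv(-mod.hessian(params))
    slopes = dict(zip(included, params[:k]))
    thresholds = list(mod.transform_threshold_params(params)[1:-1])
    # delta method for the exp-increment threshold encoding
    q = len(thresholds)
    theta = params[k:]
    L = np.zeros((q, q))
    L[:, 0] = 1.0
    for i in range(1, q):
        L[i:, i] = np.exp(theta[i])
    cov_alpha = L @ cov[k:, k:] @ L.T

    def _se(diag: np.ndarray) -> np.ndarray:
        # non-positive variances (pseudo-inverse of a singular Hessian) -> NaN
        return np.where(diag > 0, np.sqrt(np.abs(diag)), np.nan)

    se = np.concatenate([_se(np.diag(cov_alpha)), _se(np.diag(cov))[:k]])
    names = [f"alpha_{j + 1}" for j in range(q)] + included
    est = np.concatenate([thresholds, params[:k]])
    table = _inference_table(names, est, se)
    converged = bool(res.mle_retvals.get("converged", False))
    if not converged:
        warnings.warn(f"proportional-odds fit did not converge in {maxiter} iterations",
                      stacklevel=2)
    return FitResult(
        slopes=slopes, thresholds=thresholds, table=table,
        loglik=float(res.llf), n=len(y), levels=list(levels),
        converged=converged, separation_flag=_separation_flag(X, slopes),
    )


def fit_binary_logistic(
    features: pd.DataFrame,
    is_lower: Sequence[int] | Sequence[bool],
    included: Sequence[str],
    maxiter: int = 200,
) -> FitResult:
    """Binary logistic MLE in the alpha - x.beta parameterization.

    ``is_lower`` marks the class below the cutpoint (e.g. iCS3 in the
    iCS3-vs-iCS4 correction problem): P(is_lower) = sigma(alpha - x.beta).
    """
    included = list(included)
    if not included:
        raise FittingError("no features included in the fit")
    X = features[included].astype(float).reset_index(drop=True)
    _check_design(X)
    y_low = np.asarray(is_lower).astype(int)
    if set(np.unique(y_low)) - {0, 1}:
        raise FittingError("is_lower labels must be binary")
    # fit on the complement so exog slopes carry the maturation sign
    y_high = 1 - y_low
    exog = sm.add_constant(X, prepend=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y_high, exog).fit(disp=0, maxiter=maxiter, method="newton")
    params = np.asarray(res.params, dtype=float)
    se_all = np.asarray(res.bse, dtype=float)
    slopes = dict(zip(included, params[:-1]))
    alpha = -params[-1]
    est = np.concatenate([[alpha], params[:-1]])
    se = np.concatenate([[se_all[-1]], se_all[:-1]])
    table = _inference_table(["alpha_1"] + included, est, se)
    return FitResult(
        slopes=slopes, thresholds=[float(alpha)], table=table,
        loglik=float(res.llf), n=len(y_low), levels=[0, 1],
        converged=bool(res.mle_retvals["converged"]),
        separation_flag=_separation_flag(X, slopes),
    )


def brant_test(
    features: pd.DataFrame,
    stages: Sequence[int],
    included: Sequence[str],
) -> pd.DataFrame:
    """Brant's Wald test of the parallel-lines assumption.

    Fits the J-1 cumulative binary logits P(y > j) separately, stacks their
    slope vectors, and tests equality across cutpoints with the joint
    covariance implied by the overlapping binary responses (Brant 1990).
    Returns a DataFrame with an ``omnibus`` row (df = (J-2)·k) and one row
    per variable (df = J-2).
    """
    included = list(included)
    y = np.asarray(stages, dtype=int)
    X = features[included].astype(float).reset_index(drop=True)
    _check_design(X)
    levels = sorted(np.unique(y))
    J = len(levels)
    k = len(included)
    if J < 3 or k < 1:
        raise FittingError(
            f"Brant test undefined for J={J} stage levels and k={k} features "
            "(needs J >= 3: with a single cutpoint there is nothing to compare)"
        )
    Xc = sm.add_constant(X, prepend=True).to_numpy(dtype=float)
    betas = []      # slope vector of each cumulative logit (intercept dropped)
    pis = []        # fitted P(y > level_j)
    for lev in levels[:-1]:
        z = (y > lev).astype(int)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(z, Xc).fit(disp=0, maxiter=200)
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
            raise FittingError(
                f"Brant test: the cumulative logit for y > {lev} is separated "
                "(singular information matrix); slopes at that cutpoint are not identifiable"
            ) from exc
        betas.append(np.asarray(res.params, dtype=float)[1:])
        pis.append(np.asarray(res.predict(Xc), dtype=float))
    m = J - 1
    # joint covariance of the stacked slope estimates
    V = np.zeros((m * k, m * k))
    xtwx_inv = []
    for j in range(m):
        w = pis[j] * (1.0 - pis[j])
        xtwx_inv.append(np.linalg.inv(Xc.T @ (Xc * w[:, None])))
    for j in range(m):
        for l in range(j, m):
            w_jl = pis[l] - pis[j] * pis[l]   # E[z_j z_l] = pi_l for j <= l
            block = (xtwx_inv[j] @ (Xc.T @ (Xc * w_jl[:, None])) @ xtwx_inv[l])[1:, 1:]
            V[j * k:(j + 1) * k, l * k:(l + 1) * k] = block
            if l != j:
                V[l * k:(l + 1) * k, j * k:(j + 1) * k] = block.T
    beta_stack = np.concatenate(betas)

    def wald(contrast_cols: list[int]) -> tuple[float, int, float]:
        rows = []
        for j in range(1, m):
            for c in contrast_cols:
                row = np.zeros(m * k)
                row[c] = 1.0
                row[j * k + c] = -1.0
                rows.append(row)
        D = np.array(rows)
        diff = D @ beta_stack
        stat = float(diff @ np.linalg.solve(D @ V @ D.T, diff))
        df = D.shape[0]
        return stat, df, float(stats.chi2.sf(stat, df))

    rows = []
    stat, df, p = wald(list(range(k)))
    rows.append({"term": "omnibus", "chi2": stat, "df": df, "p_value": p})
    for c, name in enumerate(included):
        stat, df, p = wald([c])
        rows.append({"term": name, "chi2": stat, "df": df, "p_value": p})
    return pd.DataFrame(rows).set_index("term")


def vif(features: pd.DataFrame, included: Sequence[str] | None = None,
        flag_threshold: float = 5.0) -> pd.DataFrame:
    """Variance inflation factors: VIF_k = 1/(1 - R^2_k) from regressing
    feature k on the other included features (with intercept); tolerance
    is 1/VIF.  Perfectly collinear features yield VIF = inf (flagged)."""
    if included is None:
        included = [c for c in features.columns
                    if c not in ("subject_id", "true_stage")
                    and pd.api.types.is_numeric_dtype(features[c])]
    included = list(included)
    X = features[included].astype(float)
    _check_design(X)
    rows = []
    for col in included:
        others = [c for c in included if c != col]
        if not others:
            v = 1.0
        else:
            exog = sm.add_constant(X[others], prepend=True)
            r2 = sm.OLS(X[col], exog).fit().rsquared
            v = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"feature": col, "vif": float(v),
                     "tolerance": 0.0 if np.isinf(v) else 1.0 / v,
                     "flagged": bool(v >= flag_threshold)})
    return pd.DataFrame(rows).set_index("feature")


@dataclass
class DiagnosticsReport:
    brant: pd.DataFrame | None
    vif: pd.DataFrame


@dataclass
class DevelopConfig:
    """Pipeline settings: screening and retention both at p < 0.05 by
    default (no multiplicity correction in the univariate screen)."""

    alpha_screen: float = 0.05
    alpha_retain: float = 0.05
    candidate_features: Sequence[str] | None = None
    vif_flag_threshold: float = 5.0


@dataclass
class DevelopmentReport:
    screening: pd.DataFrame
    fit: FitResult
    diagnostics: DiagnosticsReport
    retained: list[str]
    eliminated: list[tuple[str, float]]


def develop_model(
    data: Cohort | pd.DataFrame,
    stages: Sequence[int] | None = None,
    config: DevelopConfig | None = None,
) -> DevelopmentReport:
    """Run the full development pipeline on a cohort or feature table.

    Screen (Spearman p < alpha) -> multivariable proportional-odds fit ->
    backward elimination of the largest Wald p >= alpha until all retained
    terms are significant -> Brant + VIF diagnostics on the final model.
    """
    config = config or DevelopConfig()
    if isinstance(data, Cohort):
        features = extract_features_frame(data)
    else:
        features = data
    if stages is None:
        if "true_stage" not in features.columns:
            raise FittingError("develop_model needs stage labels "
                               "(true_stage column or `stages` argument)")
        stages = features["true_stage"].to_numpy(dtype=int)
    stages = np.asarray(stages, dtype=int)

    screening = spearman_screen(features, stages, alpha=config.alpha_screen,
                                columns=config.candidate_features)
    candidates = screening.index[screening["selected"]].tolist()
    if not candidates:
        raise FittingError("screening selected no candidate features "
                           f"(alpha={config.alpha_screen})")

    kept = list(candidates)
    eliminated: list[tuple[str, float]] = []
    while True:
        fit = fit_proportional_odds(features, stages, kept)
        # undefined p-values (singular information) count as non-significant
        pvals = fit.table.loc[kept, "p_value"].fillna(1.0)
        worst = str(pvals.idxmax())
        worst_p = float(pvals.max())
        if worst_p < config.alpha_retain:
            break
        if len(kept) == 1:
            raise FittingError(
                "backward elimination removed every candidate "
                f"(last term {worst!r} had p={worst_p:.3g})"
            )
        kept.remove(worst)
        eliminated.append((worst, worst_p))

    levels = sorted(np.unique(stages))
    brant = None
    if len(levels) >= 3:
        try:
            brant = brant_test(features, stages, kept)
        except FittingError as exc:
            warnings.warn(f"Brant test unavailable: {exc}", stacklevel=2)
    vif_table = vif(features, kept, flag_threshold=config.vif_flag_threshold)
    return DevelopmentReport(
        screening=screening, fit=fit,
        diagnostics=DiagnosticsReport(brant=brant, vif=vif_table),
        retained=kept, eliminated=eliminated,
    )
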