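"""Fisher linear discriminant between good and poor performers, and ROC
evaluation of its score.

The discriminant direction is w = S_pooled^-1 (mu_good - mu_poor) with the
pooled within-class covariance (n-2 denominator) and equal class priors;
the intercept centres the score at the midpoint of the class means, so
positive scores lean good. Priors only shift the decision threshold and
the ROC is threshold-free, so they do not affect any number reported here.

AUC is the Mann-Whitney pairwise-win probability (ties credited 1/2),
which equals the trapezoidal area under the empirical ROC curve; its 95%
confidence interval comes from a stratified bootstrap percentile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .cohort_pipeline import CohortTable, ParameterKey
from .errors import DegenerateInputError, InputError

logger = logging.getLogger(__name__)

GOOD, POOR = "good", "poor"


@dataclass
class DiscriminantModel:
    """Linear discriminant over a named feature subset."""

    features: list[ParameterKey]
    weights: np.ndarray
    intercept: float
    class_means: dict[str, np.ndarray] = field(default_factory=dict)
    pooled_covariance: np.ndarray | None = None


@dataclass
class ROCResult:
    """AUC with bootstrap 95% CI and the empirical ROC curve."""

    auc: float
    ci_low: float
    ci_high: float
    curve: np.ndarray  # (k, 2) columns fpr, tpr


def _feature_matrix(
    cohort: CohortTable, features: Sequence[ParameterKey]
) -> pd.DataFrame:
    missing = [k.label for k in features if k.label not in cohort.values.columns]
    if missing:
        raise InputError(f"cohort table lacks features {missing}")
    return cohort.values[[k.label for k in features]]


def fit_lda(cohort: CohortTable, features: Sequence[ParameterKey]) -> DiscriminantModel:
    """Fit the Fisher discriminant on labelled cohort rows. Surgeons with a
    missing value in any selected feature are dropped listwise (with a
    warning); a singular pooled covariance gets a small ridge
    (1e-8 * trace/dim), logged when applied."""
    if cohort.labels is None:
        raise InputError("cohort has no good/poor labels")
    X = _feature_matrix(cohort, features)
    y = cohort.labels.reindex(X.index)
    keep = X.notna().all(axis=1) & y.notna()
    if not keep.all():
        logger.warning(
            "dropping %d surgeons with missing feature values", (~keep).sum()
        )
    X, y = X[keep].to_numpy(float), y[keep]
    for lab in (GOOD, POOR):
        if (y == lab).sum() < 2:
            raise InputError(f"need >= 2 surgeons labelled {lab!r}")
    xg, xp = X[(y == GOOD).to_numpy()], X[(y == POOR).to_numpy()]
    mu_g, mu_p = xg.mean(axis=0), xp.mean(axis=0)
    n_g, n_p = len(xg), len(xp)
    cov = (
        (xg - mu_g).T @ (xg - mu_g) + (xp - mu_p).T @ (xp - mu_p)
    ) / (n_g + n_p - 2)
    if np.allclose(cov, 0):
        raise DegenerateInputError("all selected features are constant within class")
    d = cov.shape[0]
    try:
        weights = np.linalg.solve(cov, mu_g - mu_p)
    except np.linalg.LinAlgError:
        weights = None
    if weights is None or not np.all(np.isfinite(weights)) or \
            np.linalg.cond(cov) > 1e12:
        ridge = 1e-8 * np.trace(cov) / d
        logger.info("singular pooled covariance: adding ridge %.3e", ridge)
        weights = np.linalg.solve(cov + ridge * np.eye(d), mu_g - mu_p)
    intercept = float(-0.5 * weights @ (mu_g + mu_p))
    return DiscriminantModel(
        features=list(features),
        weights=weights,
        intercept=intercept,
        class_means={GOOD: mu_g, POOR: mu_p},
        pooled_covariance=cov,
    )


def discriminant_score(model: DiscriminantModel, cohort: CohortTable) -> pd.Series:
    """Per-surgeon discriminant score w.x + b (higher leans good)."""
    X = _feature_matrix(cohort, model.features)
    return pd.Series(
        X.to_numpy(float) @ model.weights + model.intercept,
        index=X.index,
        name="score",
    )


def pairwise_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: the probability that a random good outscores a
    random poor, ties counted 1/2 — computed from ranks, equivalent to the
    mean over all (good, poor) pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == GOOD]
    neg = scores[labels == POOR]
    if len(pos) == 0 or len(neg) == 0:
        raise InputError("both good and poor labels are required")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def roc_auc(
    scores: Sequence[float] | pd.Series,
    labels: Sequence[str] | pd.Series,
    n_bootstrap: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> ROCResult:
    """Empirical ROC curve with Mann-Whitney AUC and a stratified bootstrap
    percentile 95% CI (resampling good and poor groups separately)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    auc = pairwise_auc(scores, labels)
    fpr, tpr, _ = roc_curve(labels, scores, pos_label=GOOD)
    curve = np.column_stack([fpr, tpr])
    rng = np.random.default_rng(rng)
    pos = scores[labels == GOOD]
    neg = scores[labels == POOR]
    boot = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        bp = rng.choice(pos, size=len(pos), replace=True)
        bn = rng.choice(neg, size=len(neg), replace=True)
        boot[b] = pairwise_auc(
            np.concatenate([bp, bn]),
            np.array([GOOD] * len(bp) + [POOR] * len(bn)),
        )
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return ROCResult(
        auc=auc,
        ci_low=float(min(lo, auc)),
        ci_high=float(max(hi, auc)),
        curve=curve,
    )


def evaluate_models(
    cohort: CohortTable,
    model_features: dict[str, Sequence[ParameterKey]],
    n_bootstrap: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> dict[str, dict]:
    """Fit and ROC-evaluate several feature sets on a labelled cohort.
    Returns per model the fitted weights, scores, AUC and CI."""
    rng = np.random.default_rng(rng)
    out = {}
    for name, features in model_features.items():
        if not features:
            out[name] = {"features": [], "auc": None}
            continue
        model = fit_lda(cohort, features)
        scores = discriminant_score(model, cohort)
        keep = scores.notna() & cohort.labels.reindex(scores.index).notna()
        roc = roc_auc(
            scores[keep], cohort.labels.reindex(scores.index)[keep],
            n_bootstrap=n_bootstrap, rng=rng,
        )
        out[name] = {
            "features": [k.label for k in model.features],
            "weights": model.weights.tolist(),
            "intercept": model.intercept,
            "scores": scores.to_dict(),
            "auc": roc.auc,
            "ci": [roc.ci_low, roc.ci_high],
            "curve": roc.curve.tolist(),
        }
    return out
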