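"""Spearman screening of AI parameters against rubric categories, and the
rule that picks discriminant-model features from the screen.

Every (parameter, phase) cell is correlated against every rubric category
across surgeons (rank correlation, listwise deletion, no multiple-testing
correction). Feature selection then works per model family:

* Model 1 — vessel-deformation parameters (CV-VA, Max-dVA, No. of TDE);
* Model 2 — motion parameters (PD, NJI, per hand);
* Model 3 — the union of both.

Within a family, each parameter contributes its best (parameter, phase)
cell — the one significantly correlated with the most categories — and a
parameter with no significant cell contributes nothing. Ties are broken
by smaller median p, then by phase order (All, A, B, C, D).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_pipeline import (
    CohortTable,
    MOTION_METRICS,
    ParameterKey,
    VESSEL_METRICS,
)
from .errors import DegenerateInputError, InputError
from .io_formats import RUBRIC_CATEGORIES
from .rubric_scoring import SurgeonScore

DEFAULT_ALPHA = 0.05

#: Above this many permutations the permutation p-value switches from
#: exhaustive enumeration to Monte Carlo.
_EXACT_PERM_LIMIT = 50_000

_PHASE_PRIORITY = ("All", "A", "B", "C", "D")
_PARAMETER_PRIORITY = (
    "cv_va", "max_dva", "n_tde", "rt_pd", "lt_pd", "rt_nji", "lt_nji",
)


@dataclass(frozen=True)
class ScreenResult:
    """One cell of the screen: a parameter/phase against one category."""

    parameter: str
    phase: str
    category: str
    rho: float
    p: float
    significant: bool
    n: int


def _snap(rho: float) -> float:
    """Clamp float error so perfectly (anti)monotone pairs give exactly +-1."""
    if abs(abs(rho) - 1.0) < 1e-12:
        return math.copysign(1.0, rho)
    return rho


def _rank_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return float("nan")
    return _snap(float(np.corrcoef(rx, ry)[0, 1]))


def spearman_rho_p(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["t_approx", "permutation"] = "t_approx",
    rng: np.random.Generator | None = None,
    n_resamples: int = 20_000,
) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ranks use the mid-rank convention for ties; rho is the Pearson
    correlation of the ranks. The p-value comes from the usual t
    approximation, or from the permutation distribution of rho (exhaustive
    when n! is small, Monte Carlo otherwise) — preferable at the n ~ 14
    scale of a surgical cohort. Pairs with a missing value are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 4:
        raise InputError(f"need >= 4 complete pairs, have {n}")
    rho = _rank_rho(x, y)
    if math.isnan(rho):
        raise DegenerateInputError("constant input: Spearman rho is undefined")
    if method == "t_approx":
        res = stats.spearmanr(x, y)
        return _snap(float(res.statistic)), float(res.pvalue)
    if method != "permutation":
        raise InputError(f"unknown p-value method {method!r}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    tol = 1e-12
    if math.factorial(n) <= _EXACT_PERM_LIMIT:
        perm_rhos = np.array(
            [np.corrcoef(rx, np.asarray(p))[0, 1] for p in permutations(ry)]
        )
        p_val = float(np.mean(np.abs(perm_rhos) >= abs(rho) - tol))
    else:
        rng = rng or np.random.default_rng()
        count = 0
        for _ in range(n_resamples):
            r = np.corrcoef(rx, rng.permutation(ry))[0, 1]
            count += abs(r) >= abs(rho) - tol
        # add-one correction keeps the Monte-Carlo p-value valid
        p_val = (count + 1) / (n_resamples + 1)
    return rho, p_val


def screen_parameters(
    cohort: CohortTable,
    scores: Sequence[SurgeonScore],
    alpha: float = DEFAULT_ALPHA,
    method: Literal["t_approx", "permutation"] = "t_approx",
    rng: np.random.Generator | None = None,
) -> list[ScreenResult]:
    """Correlate every parameter/phase cell of the cohort table against
    every rubric category. Surgeons missing a cell are dropped pairwise for
    that cell; cells that end with fewer than 4 pairs, or that are constant,
    yield NaN and are never significant."""
    score_frame = pd.DataFrame(
        {s.surgeon_id: s.category_means for s in scores}
    ).T
    shared = [s for s in cohort.surgeons if s in score_frame.index]
    if len(shared) < 4:
        raise InputError(f"only {len(shared)} surgeons shared between cohort and scores")
    results = []
    for label in cohort.values.columns:
        param_vals = cohort.values.loc[shared, label].to_numpy(float)
        parameter, phase = label.rsplit(":", 1)
        for cat in RUBRIC_CATEGORIES:
            cat_vals = score_frame.loc[shared, cat].to_numpy(float)
            keep = np.isfinite(param_vals) & np.isfinite(cat_vals)
            try:
                rho, p = spearman_rho_p(
                    param_vals[keep], cat_vals[keep], method=method, rng=rng
                )
                sig = bool(p < alpha)
            except (InputError, DegenerateInputError):
                rho, p, sig = float("nan"), float("nan"), False
            results.append(
                ScreenResult(
                    parameter=parameter, phase=phase, category=cat,
                    rho=rho, p=p, significant=sig, n=int(keep.sum()),
                )
            )
    return results


def screen_to_frame(screen: Sequence[ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in screen])


def _family(parameter: str) -> str:
    metric = parameter.split("_", 1)[1] if parameter.startswith(("rt_", "lt_")) \
        else parameter
    if metric in VESSEL_METRICS:
        return "vessel"
    if metric in MOTION_METRICS:
        return "motion"
    raise InputError(f"unknown parameter {parameter!r}")


def select_model_features(
    screen: Sequence[ScreenResult] | pd.DataFrame,
) -> tuple[list[ParameterKey], list[ParameterKey], list[ParameterKey]]:
    """Pick discriminant features from a screen.

    Per family (vessel -> Model 1, motion -> Model 2), every parameter with
    at least one significant cell contributes its single best phase cell:
    most significant categories, ties broken by smaller median p across the
    nine categories, then by phase order (All, A, B, C, D). Model 3 is the
    union of Models 1 and 2. A family with no significant cell yields an
    empty model and a warning.
    """
    df = screen if isinstance(screen, pd.DataFrame) else screen_to_frame(screen)
    cells = (
        df.groupby(["parameter", "phase"])
        .agg(n_sig=("significant", "sum"), median_p=("p", "median"))
        .reset_index()
    )
    models: dict[str, list[ParameterKey]] = {"vessel": [], "motion": []}
    for parameter in _PARAMETER_PRIORITY:
        sub = cells[cells["parameter"] == parameter]
        if sub.empty or sub["n_sig"].max() == 0:
            continue
        sub = sub.assign(
            phase_rank=sub["phase"].map(_PHASE_PRIORITY.index)
        ).sort_values(
            ["n_sig", "median_p", "phase_rank"], ascending=[False, True, True]
        )
        best = sub.iloc[0]
        models[_family(parameter)].append(
            ParameterKey.from_parameter(parameter, best["phase"])
        )
    for family, name in (("vessel", "Model 1"), ("motion", "Model 2")):
        if not models[family]:
            warnings.warn(
                f"no significant {family} parameter: {name} is empty", stacklevel=2
            )
    model1, model2 = models["vessel"], models["motion"]
    model3 = model1 + [k for k in model2 if k not in model1]
    return model1, model2, model3
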