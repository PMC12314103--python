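"""Criteria-based rating-scale aggregation and interrater reliability.

Three blinded expert raters score each trial on nine technical categories
(1-5). A surgeon's representative score per category is the mean over the
first two trials and all raters; the total (sum of the nine category
means, range 9-45) stratifies the cohort into good (total >= 35) and poor
performers. Interrater agreement is quantified by Cronbach's alpha with
raters playing the role of items.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError
from .io_formats import RUBRIC_CATEGORIES, RubricScoreRecord

#: Total-score boundary between good and poor performance. The cohort's
#: total scores are bimodal around this value; a total exactly at the
#: cutoff is labelled good.
GOOD_POOR_CUTOFF = 35.0


@dataclass
class SurgeonScore:
    """Representative rubric score of one surgeon: per-category means over
    raters and the first trials, their total, and the good/poor label."""

    surgeon_id: str
    category_means: Mapping[str, float] = field(default_factory=dict)
    label: str | None = None

    @property
    def total(self) -> float:
        return float(sum(self.category_means.values()))


def average_scores(
    records: Sequence[RubricScoreRecord], trials: int = 2
) -> list[SurgeonScore]:
    """Per surgeon and category, the mean score over all raters and the
    first ``trials`` trials (by trial index). Every rater must have scored
    every counted trial."""
    if not records:
        raise InputError("no rubric records")
    by_surgeon: dict[str, list[RubricScoreRecord]] = {}
    for r in records:
        by_surgeon.setdefault(r.surgeon_id, []).append(r)
    out = []
    for surgeon in sorted(by_surgeon):
        recs = by_surgeon[surgeon]
        trial_ids = sorted({r.trial_index for r in recs})[:trials]
        if len(trial_ids) < trials:
            raise ValidationError(
                f"surgeon {surgeon!r} has {len(trial_ids)} trials, needs {trials}"
            )
        raters = sorted({r.rater_id for r in recs})
        counted = [r for r in recs if r.trial_index in trial_ids]
        missing = [
            (rater, t)
            for rater in raters
            for t in trial_ids
            if not any(r.rater_id == rater and r.trial_index == t for r in counted)
        ]
        if missing:
            raise ValidationError(
                f"surgeon {surgeon!r} missing rater/trial combinations: {missing}"
            )
        means = {
            cat: float(np.mean([r.scores[cat] for r in counted]))
            for cat in RUBRIC_CATEGORIES
        }
        out.append(SurgeonScore(surgeon_id=surgeon, category_means=means))
    return out


def cronbach_alpha(ratings: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha over a rater x performance matrix:

        alpha = k/(k-1) * (1 - sum(var_rater) / var(sum over raters))

    with k raters and sample (n-1) variances across performances. Returns
    NaN when the variance of the rater sum is zero (no performance
    variation to agree on).
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise InputError("ratings must be a 2D rater x performance matrix")
    k, n = m.shape
    if k < 2 or n < 2:
        raise InputError("need >= 2 raters and >= 2 rated performances")
    item_vars = m.var(axis=1, ddof=1)
    total_var = m.sum(axis=0).var(ddof=1)
    if total_var == 0:
        return float("nan")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def per_category_alpha(
    records: Sequence[RubricScoreRecord], trials: int = 2
) -> dict[str, float]:
    """Cronbach's alpha per rubric category, raters as items and surgeons'
    first-``trials`` mean scores as performances. A whole-scale alpha over
    rater totals is returned under the key ``"total"``."""
    if not records:
        raise InputError("no rubric records")
    df = pd.DataFrame(
        [
            {"surgeon": r.surgeon_id, "trial": r.trial_index, "rater": r.rater_id,
             **r.scores, "total": r.total}
            for r in records
        ]
    )
    first = df[
        df.groupby("surgeon")["trial"].rank(method="dense") <= trials
    ]
    out = {}
    for cat in (*RUBRIC_CATEGORIES, "total"):
        mat = first.pivot_table(index="rater", columns="surgeon", values=cat,
                                aggfunc="mean")
        out[cat] = cronbach_alpha(mat.to_numpy())
    return out


def label_good_poor(
    scores: Sequence[SurgeonScore], cutoff: float = GOOD_POOR_CUTOFF
) -> list[SurgeonScore]:
    """Assign good/poor labels by total score (total >= cutoff -> good)."""
    out = []
    for s in scores:
        if not np.isfinite(s.total):
            raise InputError(f"non-finite total for surgeon {s.surgeon_id!r}")
        out.append(
            SurgeonScore(
                surgeon_id=s.surgeon_id,
                category_means=dict(s.category_means),
                label="good" if s.total >= cutoff else "poor",
            )
        )
    return out


def scores_to_frame(scores: Sequence[SurgeonScore]) -> pd.DataFrame:
    """Tabular view: one row per surgeon with category means, total, label."""
    return pd.DataFrame(
        [
            {"surgeon": s.surgeon_id, **s.category_means,
             "total": s.total, "label": s.label}
            for s in scores
        ]
    ).set_index("surgeon")
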