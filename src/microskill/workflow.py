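"""End-to-end convenience: dataset directory -> extracted parameters,
rubric scores, screen, selected features and discriminant ROC results.

This is thin glue over the stage modules; each stage remains directly
usable on its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_pipeline import (
    AnalysisConfig,
    CohortTable,
    ParameterKey,
    build_cohort_table,
    trial_parameters,
)
from .correlation_screen import (
    ScreenResult,
    screen_parameters,
    screen_to_frame,
    select_model_features,
)
from .discriminant_roc import evaluate_models
from .errors import InputError
from .io_formats import (
    read_phase_csv,
    read_rubric_csv,
    read_tip_track,
    read_va_csv,
)
from .rubric_scoring import (
    GOOD_POOR_CUTOFF,
    SurgeonScore,
    average_scores,
    label_good_poor,
    per_category_alpha,
)
from .synthetic_data import parse_trial_identifier

logger = logging.getLogger(__name__)


def extract_dataset(
    dataset_dir: str | Path, config: AnalysisConfig | None = None
) -> dict[tuple[str, int], dict[ParameterKey, float]]:
    """Compute per-trial parameter maps for every trial in a dataset
    directory (``tracks.csv``, ``va.csv``, ``phases.csv``); trial ids are
    expected to carry the surgeon id and trial index."""
    dataset_dir = Path(dataset_dir)
    config = config or AnalysisConfig()
    tracks = read_tip_track(dataset_dir / "tracks.csv", fps=config.fps)
    series = {s.trial_id: s for s in read_va_csv(dataset_dir / "va.csv",
                                                 fps=config.fps)}
    annotations = read_phase_csv(dataset_dir / "phases.csv")
    by_trial: dict[str, dict[str, object]] = {}
    for t in tracks:
        by_trial.setdefault(t.trial_id, {})[t.hand] = t
    out = {}
    for trial_id, hands in sorted(by_trial.items()):
        if set(hands) != {"right", "left"}:
            raise InputError(f"trial {trial_id!r} lacks both hands")
        if trial_id not in series:
            raise InputError(f"trial {trial_id!r} has no vessel-area series")
        params = trial_parameters(
            hands["right"], hands["left"], series[trial_id], annotations, config
        )
        surgeon, trial_idx = parse_trial_identifier(trial_id)
        out[(surgeon, trial_idx)] = params
        logger.info(
            "trial %s: pd(right, All)=%.0f px, nji(right, All)=%.3g, n_tde(All)=%.0f",
            trial_id,
            params[ParameterKey("pd", hand="right")],
            params[ParameterKey("nji", hand="right")],
            params[ParameterKey("n_tde")],
        )
    return out


@dataclass
class AnalysisResult:
    """Everything the pipeline produces on one cohort."""

    cohort: CohortTable
    scores: list[SurgeonScore]
    alpha: dict[str, float]
    screen: list[ScreenResult]
    model_features: dict[str, list[ParameterKey]]
    models: dict[str, dict]

    @property
    def screen_frame(self) -> pd.DataFrame:
        return screen_to_frame(self.screen)


def analyze_dataset(
    dataset_dir: str | Path,
    config: AnalysisConfig | None = None,
    cutoff: float = GOOD_POOR_CUTOFF,
    alpha: float = 0.05,
    p_method: str = "t_approx",
    n_bootstrap: int = 2000,
    seed: int | None = None,
) -> AnalysisResult:
    """Full pipeline on a dataset directory: extract per-trial parameters,
    aggregate first-two-trial representatives, score the rubric, screen by
    Spearman correlation, select model features and evaluate discriminant
    ROC for Models 1-3."""
    dataset_dir = Path(dataset_dir)
    config = config or AnalysisConfig()
    rng = np.random.default_rng(seed)
    per_trial = extract_dataset(dataset_dir, config)
    cohort = build_cohort_table(per_trial)
    records = read_rubric_csv(dataset_dir / "rubric.csv")
    scores = label_good_poor(average_scores(records), cutoff=cutoff)
    cohort.labels = pd.Series(
        {s.surgeon_id: s.label for s in scores}, name="label"
    ).reindex(cohort.values.index)
    alpha_by_cat = per_category_alpha(records)
    screen = screen_parameters(cohort, scores, alpha=alpha, method=p_method, rng=rng)
    m1, m2, m3 = select_model_features(screen)
    features = {"model1": m1, "model2": m2, "model3": m3}
    models = evaluate_models(cohort, features, n_bootstrap=n_bootstrap, rng=rng)
    return AnalysisResult(
        cohort=cohort,
        scores=scores,
        alpha=alpha_by_cat,
        screen=screen,
        model_features=features,
        models=models,
    )
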