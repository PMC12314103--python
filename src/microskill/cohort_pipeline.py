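"""Per-trial parameter extraction, phase stratification and cohort assembly.

A trial is one complete stitch, annotated with four phases: A (grasp and
insert the needle), B (push and extract it), C (pull the threads to the
first knot), D (tie three knots and cut). Every parameter is computed per
phase and for the whole trial ("All"); the phase window is sliced out
*before* the metric is computed, so per-phase NJI uses phase-local
procedural time and path distance, and derivatives never span phase joins.

The representative value of a surgeon is the arithmetic mean of their
first two trials, which limits learning effects from repeated attempts.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InputError, MicroskillError, ValidationError
from .io_formats import (
    HANDS,
    PHASES,
    PhaseAnnotation,
    TipTrack,
    VASeries,
)
from .motion_metrics import (
    DEFAULT_POLYORDER,
    DEFAULT_SMOOTHING_WINDOW,
    normalized_jerk_index,
    path_distance,
    segment_and_smooth,
)
from .vessel_metrics import (
    Normalization,
    TDEConfig,
    cv_va,
    detect_tde,
    max_abs_delta_va,
    relative_delta_va,
)

VESSEL_METRICS = ("cv_va", "max_dva", "n_tde")
MOTION_METRICS = ("pd", "nji")
ALL_PHASES = (*PHASES, "All")


@dataclass(frozen=True, order=True)
class ParameterKey:
    """Identifies one cell of the parameter layout: a metric, the hand it
    applies to (vessel metrics are hand-independent) and a phase."""

    metric: str
    hand: str = "not_applicable"
    phase: str = "All"

    def __post_init__(self) -> None:
        if self.metric in VESSEL_METRICS:
            if self.hand != "not_applicable":
                raise ValidationError(f"{self.metric} does not take a hand")
        elif self.metric in MOTION_METRICS:
            if self.hand not in HANDS:
                raise ValidationError(f"{self.metric} requires hand right/left")
        else:
            raise ValidationError(f"unknown metric {self.metric!r}")
        if self.phase not in ALL_PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}")

    @property
    def parameter(self) -> str:
        """Flat parameter name, e.g. ``n_tde`` or ``rt_pd``."""
        if self.hand == "not_applicable":
            return self.metric
        return f"{'rt' if self.hand == 'right' else 'lt'}_{self.metric}"

    @property
    def label(self) -> str:
        return f"{self.parameter}:{self.phase}"

    @classmethod
    def from_parameter(cls, parameter: str, phase: str) -> "ParameterKey":
        if parameter.startswith(("rt_", "lt_")):
            hand = "right" if parameter.startswith("rt_") else "left"
            return cls(metric=parameter[3:], hand=hand, phase=phase)
        return cls(metric=parameter, phase=phase)


def all_parameter_keys() -> list[ParameterKey]:
    """The full 35-cell layout: 3 vessel metrics x 5 phases plus
    2 motion metrics x 2 hands x 5 phases."""
    keys = [ParameterKey(m, phase=p) for m in VESSEL_METRICS for p in ALL_PHASES]
    keys += [
        ParameterKey(m, hand=h, phase=p)
        for m in MOTION_METRICS
        for h in HANDS
        for p in ALL_PHASES
    ]
    return keys


@dataclass
class AnalysisConfig:
    """Tunable knobs of the extraction stage, loadable from TOML."""

    tde: TDEConfig = field(default_factory=TDEConfig)
    va_normalization: Normalization = "trial_mean"
    smoothing_window: int = DEFAULT_SMOOTHING_WINDOW
    polyorder: int = DEFAULT_POLYORDER
    min_segment_frames: int = 2
    fps: float = 30.0

    @classmethod
    def from_toml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        tde_raw = raw.get("tde", {})
        motion = raw.get("motion", {})
        va = raw.get("va", {})
        return cls(
            tde=TDEConfig(
                threshold=tde_raw.get("threshold", TDEConfig().threshold),
                counting_mode=tde_raw.get("counting_mode", TDEConfig().counting_mode),
            ),
            va_normalization=va.get("normalization", "trial_mean"),
            smoothing_window=motion.get("smoothing_window", DEFAULT_SMOOTHING_WINDOW),
            polyorder=motion.get("polyorder", DEFAULT_POLYORDER),
            min_segment_frames=motion.get("min_segment_frames", 2),
            fps=raw.get("fps", 30.0),
        )


# ---------------------------------------------------------------------------
# Phase slicing
# ---------------------------------------------------------------------------


def _phase_windows(
    annotations: list[PhaseAnnotation], trial_id: str, phase: str
) -> list[tuple[int, int]]:
    anns = [a for a in annotations if a.trial_id == trial_id]
    if not anns:
        raise InputError(f"no phase annotations for trial {trial_id!r}")
    if phase == "All":
        return sorted((a.start_frame, a.end_frame) for a in anns)
    match = [a for a in anns if a.phase == phase]
    if not match:
        raise InputError(f"phase {phase!r} not annotated for trial {trial_id!r}")
    return [(match[0].start_frame, match[0].end_frame)]


def slice_by_phase(
    obj: TipTrack | VASeries,
    annotations: list[PhaseAnnotation],
    phase: str,
):
    """Restrict a track or VA series to one phase window ("All" = the union
    of all annotated windows). Frame indices are re-anchored to the window
    start; gaps between non-contiguous windows survive as frame-number
    jumps, so downstream differentiation never spans them."""
    windows = _phase_windows(annotations, obj.trial_id, phase)
    frames = obj.frame_index
    mask = np.zeros(len(frames), dtype=bool)
    for start, end in windows:
        mask |= (frames >= start) & (frames < end)
    anchor = windows[0][0]
    if isinstance(obj, TipTrack):
        return TipTrack(
            trial_id=obj.trial_id,
            hand=obj.hand,
            frame_index=frames[mask] - anchor,
            x_px=obj.x_px[mask],
            y_px=obj.y_px[mask],
            valid=obj.valid[mask],
            fps=obj.fps,
        )
    return VASeries(
        trial_id=obj.trial_id,
        frame_index=frames[mask] - anchor,
        va_px=obj.va_px[mask],
        fps=obj.fps,
    )


# ---------------------------------------------------------------------------
# Per-trial parameters
# ---------------------------------------------------------------------------


def _mask_short_runs(track: TipTrack, min_frames: int) -> TipTrack:
    if min_frames <= 1 or len(track) == 0:
        return track
    valid = track.valid.copy()
    idx = np.flatnonzero(valid)
    if idx.size:
        breaks = np.flatnonzero(np.diff(track.frame_index[idx]) != 1)
        for run in np.split(idx, breaks + 1):
            if len(run) < min_frames:
                valid[run] = False
    return replace(track, valid=valid)


def _concat_kinematics(parts: list) -> "object":
    from .motion_metrics import KinematicSeries

    offset = 0
    segs = []
    for k in parts:
        segs.append(k.segment_id + offset)
        offset += k.segment_id.max() + 1
    return KinematicSeries(
        trial_id=parts[0].trial_id,
        hand=parts[0].hand,
        time_s=np.concatenate([k.time_s for k in parts]),
        position=np.concatenate([k.position for k in parts]),
        velocity=np.concatenate([k.velocity for k in parts]),
        acceleration=np.concatenate([k.acceleration for k in parts]),
        jerk=np.concatenate([k.jerk for k in parts]),
        segment_id=np.concatenate(segs),
    )


def _kinematics_for_phase(
    track: TipTrack,
    annotations: list[PhaseAnnotation],
    phase: str,
    config: AnalysisConfig,
):
    """Kinematics of a track restricted to a phase. For "All", each phase
    window is differentiated independently and the pieces concatenated as
    separate segments, so derivatives never span phase joins and path
    distance is exactly additive across phases."""
    if phase == "All":
        parts = []
        for p in PHASES:
            try:
                parts.append(_kinematics_for_phase(track, annotations, p, config))
            except MicroskillError:
                continue
        if not parts:
            raise InputError(f"no usable kinematics in any phase ({track.hand})")
        return _concat_kinematics(parts)
    track_slice = _mask_short_runs(
        slice_by_phase(track, annotations, phase), config.min_segment_frames
    )
    return segment_and_smooth(track_slice, config.smoothing_window, config.polyorder)


def trial_parameters(
    right: TipTrack,
    left: TipTrack,
    va: VASeries,
    annotations: list[PhaseAnnotation],
    config: AnalysisConfig | None = None,
) -> dict[ParameterKey, float]:
    """All parameters of one trial: vessel metrics and per-hand motion
    metrics, each per phase and whole-trial. Cells whose input is unusable
    in a window (e.g. a hand never detected during a phase) come back as
    NaN and stay missing downstream."""
    config = config or AnalysisConfig()
    out: dict[ParameterKey, float] = {}
    for phase in ALL_PHASES:
        try:
            va_slice = slice_by_phase(va, annotations, phase)
            dva = relative_delta_va(va_slice, config.va_normalization)
        except MicroskillError:
            va_slice = dva = None
        for metric in VESSEL_METRICS:
            key = ParameterKey(metric, phase=phase)
            try:
                if metric == "cv_va":
                    out[key] = cv_va(va_slice) if va_slice is not None else np.nan
                elif metric == "max_dva":
                    out[key] = max_abs_delta_va(dva) if dva is not None else np.nan
                else:
                    out[key] = (
                        float(detect_tde(dva, config.tde)[0])
                        if dva is not None
                        else np.nan
                    )
            except MicroskillError:
                out[key] = np.nan
        for track in (right, left):
            try:
                kin = _kinematics_for_phase(track, annotations, phase, config)
            except MicroskillError:
                kin = None
            for metric in MOTION_METRICS:
                key = ParameterKey(metric, hand=track.hand, phase=phase)
                try:
                    if kin is None:
                        out[key] = np.nan
                    elif metric == "pd":
                        out[key] = path_distance(kin)
                    else:
                        out[key] = normalized_jerk_index(kin)
                except MicroskillError:
                    out[key] = np.nan
    return out


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


@dataclass
class CohortTable:
    """Surgeon x parameter matrix of representative values (mean of the
    first two trials), with optional good/poor labels."""

    values: pd.DataFrame  # index: surgeon_id, columns: ParameterKey.label
    labels: pd.Series | None = None  # "good" / "poor"

    @property
    def surgeons(self) -> list[str]:
        return list(self.values.index)

    def column(self, key: ParameterKey) -> pd.Series:
        return self.values[key.label]

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for surgeon, row in self.values.iterrows():
            for label, value in row.items():
                parameter, phase = label.rsplit(":", 1)
                rows.append(
                    {"surgeon": surgeon, "parameter": parameter,
                     "phase": phase, "value": value}
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_tidy(cls, tidy: pd.DataFrame, labels: pd.Series | None = None):
        tidy = tidy.copy()
        tidy["label"] = tidy["parameter"].astype(str) + ":" + tidy["phase"].astype(str)
        wide = tidy.pivot_table(
            index="surgeon", columns="label", values="value", aggfunc="first",
            dropna=False,
        )
        wide.index = wide.index.astype(str)
        return cls(values=wide, labels=labels)


def build_cohort_table(
    per_trial: Mapping[tuple[str, int], Mapping[ParameterKey, float]],
    trials_per_surgeon: int = 2,
) -> CohortTable:
    """Aggregate per-trial parameter maps (keyed by surgeon id and 1-based
    trial index) into a cohort table. The representative value is the mean
    of the first ``trials_per_surgeon`` trials ordered by trial index;
    later trials are ignored, and a cell is missing when any contributing
    trial is missing it."""
    by_surgeon: dict[str, list[tuple[int, Mapping[ParameterKey, float]]]] = {}
    for (surgeon, trial_idx), params in per_trial.items():
        by_surgeon.setdefault(str(surgeon), []).append((trial_idx, params))
    short = sorted(
        s for s, trials in by_surgeon.items() if len(trials) < trials_per_surgeon
    )
    if short:
        raise ValidationError(
            f"surgeons with fewer than {trials_per_surgeon} trials: {short}"
        )
    rows = {}
    for surgeon, trials in sorted(by_surgeon.items()):
        first = [p for _, p in sorted(trials, key=lambda t: t[0])][:trials_per_surgeon]
        keys = set().union(*(set(p) for p in first))
        rows[surgeon] = {
            k.label: float(np.mean([p.get(k, np.nan) for p in first])) for k in keys
        }
    values = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    values = values[sorted(values.columns)]
    return CohortTable(values=values)
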