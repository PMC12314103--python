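"""On-disk formats and in-memory domain types.

The pipeline operates downstream of two perception models: a semantic
segmentation network that outputs per-frame vessel masks and an object
detector that outputs per-frame instrument-tip coordinates. This module
defines the domain containers (tip tracks, vessel-area series, phase
annotations, rubric score records) and reads/writes their plain-text
representations.

Conventions (fixed here, used everywhere downstream):

* pixel coordinates, origin top-left;
* frame indices are 0-based and strictly increasing;
* phase intervals are half-open ``[start_frame, end_frame)``;
* time is derived from a caller-supplied frame rate (default 30 fps).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import FormatError, InputError, ValidationError

DEFAULT_FPS = 30.0

HANDS = ("right", "left")
PHASES = ("A", "B", "C", "D")

#: The nine technical categories of the criteria-based rating scale,
#: each scored 1-5 by expert raters.
RUBRIC_CATEGORIES = (
    "instrument_handling",
    "respect_for_tissue",
    "efficiency",
    "suture_handling",
    "suturing_technique",
    "quality_of_knot",
    "final_product",
    "operation_flow",
    "overall_performance",
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TipTrack:
    """Per-frame 2D instrument-tip positions for one hand in one trial.

    ``valid`` is False on frames where the tool left the field of view;
    positions on invalid frames are retained but never differentiated
    across (see :mod:`microskill.motion_metrics`).
    """

    trial_id: str
    hand: str
    frame_index: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    valid: np.ndarray
    fps: float = DEFAULT_FPS

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.hand not in HANDS:
            raise ValidationError(f"unknown hand {self.hand!r}")
        if self.fps <= 0:
            raise ValidationError("fps must be > 0")
        if len(self.frame_index) and np.any(np.diff(self.frame_index) <= 0):
            raise ValidationError(
                f"frame_index not strictly increasing in trial {self.trial_id!r} "
                f"({self.hand})"
            )
        bad = self.valid & ~(np.isfinite(self.x_px) & np.isfinite(self.y_px))
        if np.any(bad):
            raise ValidationError(
                f"non-finite coordinates on valid frames in trial {self.trial_id!r}"
            )

    def __len__(self) -> int:
        return len(self.frame_index)

    @property
    def time_s(self) -> np.ndarray:
        """Frame times in seconds, ``frame_index / fps``."""
        return self.frame_index / self.fps


@dataclass
class VASeries:
    """Per-frame vessel-area pixel counts for one trial.

    The vessel area VA of a frame is the total number of pixels the
    segmentation model labels as vessel.
    """

    trial_id: str
    frame_index: np.ndarray
    va_px: np.ndarray
    fps: float = DEFAULT_FPS

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        self.va_px = np.asarray(self.va_px, dtype=float)
        if self.fps <= 0:
            raise ValidationError("fps must be > 0")
        if len(self.frame_index) and np.any(np.diff(self.frame_index) <= 0):
            raise ValidationError(
                f"frame_index not strictly increasing in trial {self.trial_id!r}"
            )
        if np.any(self.va_px < 0):
            raise ValidationError(f"negative vessel area in trial {self.trial_id!r}")

    def __len__(self) -> int:
        return len(self.frame_index)


@dataclass(frozen=True)
class PhaseAnnotation:
    """Half-open frame interval ``[start_frame, end_frame)`` labelling one
    phase (A: grasp/insert needle, B: push/extract needle, C: pull threads
    to first knot, D: tie knots and cut) of one trial."""

    trial_id: str
    phase: str
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}")
        if not self.start_frame < self.end_frame:
            raise ValidationError(
                f"empty phase interval {self.phase} in trial {self.trial_id!r}"
            )


@dataclass
class RubricScoreRecord:
    """One rater's nine category scores (1-5) for one trial of one surgeon."""

    surgeon_id: str
    trial_index: int
    rater_id: str
    scores: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.scores) != set(RUBRIC_CATEGORIES):
            missing = set(RUBRIC_CATEGORIES) - set(self.scores)
            extra = set(self.scores) - set(RUBRIC_CATEGORIES)
            raise ValidationError(
                f"rubric record must have exactly the 9 categories; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        if self.trial_index < 1:
            raise ValidationError("trial_index must be >= 1")
        for cat, s in self.scores.items():
            if not 1 <= s <= 5:
                raise ValidationError(
                    f"score {s} for {cat} outside [1, 5] "
                    f"(surgeon {self.surgeon_id!r}, trial {self.trial_index})"
                )

    @property
    def total(self) -> int:
        return sum(self.scores.values())


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"{path} is empty") from exc
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path} is missing required column {col!r}")
    if len(df) == 0:
        raise InputError(f"{path} contains no data rows")
    return df


def _check_phase_annotations(anns: Sequence[PhaseAnnotation]) -> None:
    by_trial: dict[str, list[PhaseAnnotation]] = {}
    for a in anns:
        by_trial.setdefault(a.trial_id, []).append(a)
    for trial_id, items in by_trial.items():
        items = sorted(items, key=lambda a: a.start_frame)
        for prev, cur in zip(items, items[1:]):
            if cur.start_frame < prev.end_frame:
                raise ValidationError(
                    f"overlapping phase intervals {prev.phase}/{cur.phase} "
                    f"in trial {trial_id!r}"
                )
        order = [a.phase for a in items]
        if order != sorted(order):
            raise ValidationError(
                f"phases out of temporal order {order} in trial {trial_id!r}"
            )
        if len(set(order)) != len(order):
            raise ValidationError(f"duplicate phase labels in trial {trial_id!r}")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_tip_track(path: str | Path, fps: float = DEFAULT_FPS) -> list[TipTrack]:
    """Read tip detections from a CSV with columns
    ``trial, hand, frame, x, y, valid`` into one :class:`TipTrack` per
    ``(trial, hand)``. Rows with ``valid=0`` are retained with the flag down.
    """
    df = _read_csv(path, ["trial", "hand", "frame", "x", "y", "valid"])
    tracks = []
    for (trial, hand), grp in df.groupby(["trial", "hand"], sort=True):
        if grp["frame"].duplicated().any():
            raise ValidationError(
                f"duplicate frame index in trial {trial!r} hand {hand!r}"
            )
        grp = grp.sort_values("frame")
        tracks.append(
            TipTrack(
                trial_id=str(trial),
                hand=str(hand),
                frame_index=grp["frame"].to_numpy(),
                x_px=grp["x"].to_numpy(float),
                y_px=grp["y"].to_numpy(float),
                valid=grp["valid"].to_numpy().astype(bool),
                fps=fps,
            )
        )
    return tracks


def write_tip_tracks(tracks: Iterable[TipTrack], path: str | Path) -> None:
    frames = []
    for t in tracks:
        frames.append(
            pd.DataFrame(
                {
                    "trial": t.trial_id,
                    "hand": t.hand,
                    "frame": t.frame_index,
                    "x": t.x_px,
                    "y": t.y_px,
                    "valid": t.valid.astype(int),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


_FRAME_NUM = re.compile(r"(\d+)")


def read_vessel_masks(
    directory: str | Path,
    vessel_label: int = 1,
    fps: float = DEFAULT_FPS,
    trial_id: str = "trial",
) -> VASeries:
    """Reduce a directory of single-channel label images (one per frame,
    zero-padded frame number in the filename) to a vessel-area series:
    ``va_px[f]`` = number of pixels equal to ``vessel_label`` in frame f.
    """
    directory = Path(directory)
    paths = sorted(
        (p for p in directory.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}),
        key=lambda p: int(_FRAME_NUM.search(p.stem).group(1)),
    ) if directory.is_dir() else []
    if not paths:
        raise InputError(f"no label images found in {directory}")
    shape = None
    counts, frames = [], []
    for p in paths:
        img = np.asarray(iio.imread(p))
        if img.ndim != 2:
            raise ValidationError(f"{p} is not single-channel")
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise ValidationError(
                f"inconsistent image dimensions: {p} is {img.shape}, expected {shape}"
            )
        frames.append(int(_FRAME_NUM.search(p.stem).group(1)))
        counts.append(int(np.count_nonzero(img == vessel_label)))
    return VASeries(trial_id=trial_id, frame_index=np.array(frames),
                    va_px=np.array(counts, float), fps=fps)


def read_va_csv(path: str | Path, fps: float = DEFAULT_FPS) -> list[VASeries]:
    """Read pre-reduced vessel-area series from a CSV with columns
    ``trial, frame, va`` (one series per trial)."""
    df = _read_csv(path, ["trial", "frame", "va"])
    out = []
    for trial, grp in df.groupby("trial", sort=True):
        grp = grp.sort_values("frame")
        out.append(
            VASeries(
                trial_id=str(trial),
                frame_index=grp["frame"].to_numpy(),
                va_px=grp["va"].to_numpy(float),
                fps=fps,
            )
        )
    return out


def write_va_csv(series: Iterable[VASeries], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"trial": s.trial_id, "frame": s.frame_index,
                      "va": s.va_px.astype(np.int64)})
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_phase_csv(path: str | Path) -> list[PhaseAnnotation]:
    """Read phase annotations from a CSV with columns
    ``trial, phase, start_frame, end_frame`` (half-open intervals)."""
    df = _read_csv(path, ["trial", "phase", "start_frame", "end_frame"])
    anns = [
        PhaseAnnotation(
            trial_id=str(r.trial),
            phase=str(r.phase),
            start_frame=int(r.start_frame),
            end_frame=int(r.end_frame),
        )
        for r in df.itertuples()
    ]
    _check_phase_annotations(anns)
    return anns


def write_phase_csv(anns: Iterable[PhaseAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"trial": a.trial_id, "phase": a.phase,
             "start_frame": a.start_frame, "end_frame": a.end_frame}
            for a in anns
        ]
    ).to_csv(path, index=False)


def read_rubric_csv(path: str | Path) -> list[RubricScoreRecord]:
    """Read rubric scores from a CSV with columns
    ``surgeon, trial, rater`` plus the nine category columns."""
    df = _read_csv(path, ["surgeon", "trial", "rater", *RUBRIC_CATEGORIES])
    return [
        RubricScoreRecord(
            surgeon_id=str(r["surgeon"]),
            trial_index=int(r["trial"]),
            rater_id=str(r["rater"]),
            scores={c: int(r[c]) for c in RUBRIC_CATEGORIES},
        )
        for _, r in df.iterrows()
    ]


def write_rubric_csv(records: Iterable[RubricScoreRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"surgeon": r.surgeon_id, "trial": r.trial_index, "rater": r.rater_id,
             **{c: r.scores[c] for c in RUBRIC_CATEGORIES}}
            for r in records
        ]
    ).to_csv(path, index=False)


def write_parameter_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy per-surgeon parameter table
    (columns ``surgeon, parameter, phase, value``)."""
    for col in ("surgeon", "parameter", "phase", "value"):
        if col not in table.columns:
            raise FormatError(f"parameter table is missing column {col!r}")
    table.to_csv(path, index=False)


def read_parameter_table(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, ["surgeon", "parameter", "phase", "value"])
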