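"""Synthetic cohorts with controllable skill structure.

The generator emulates the statistical structure the analysis assumes — a
latent per-surgeon skill in [0, 1] that simultaneously drives motion
smoothness, tissue-deformation events and rubric scores — and emits the
exact file formats the readers consume. It produces no imagery beyond
what the pipeline needs: tip tracks, vessel-area series, phase
annotations and rubric scores.

Construction, per trial:

* each phase is a chain of minimum-jerk submovements between waypoints
  (the Flash-Hogan quintic displacement profile), so a perfectly skilled
  surgeon moves smoothly by construction;
* low skill adds Poisson-distributed detour submovements (inflating path
  distance) and Gaussian jerk-level noise, triple-integrated into a
  position perturbation and tapered to zero at submovement boundaries
  (inflating the normalized jerk index without breaking the path);
* the vessel-area series is a baseline with slow drift and pixel noise,
  plus Poisson-distributed half-second deformation excursions whose
  rate scales with (1 - skill), placed preferentially in phases B and C
  where needle extraction and thread pulling stress the vessel wall;
* rubric category scores are 1 + 4*skill plus rater noise, rounded and
  clipped to the 1-5 scale, independently per rater, trial and category;
* tips occasionally leave the field of view, producing validity gaps.

The default cohort mirrors the assessment setting: 14 surgeons, two
trials each, three raters, and a bimodal skill distribution (half high,
half low) that yields both good and poor totals at the 35-point cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .io_formats import (
    PHASES,
    PhaseAnnotation,
    RUBRIC_CATEGORIES,
    RubricScoreRecord,
    TipTrack,
    VASeries,
    write_phase_csv,
    write_rubric_csv,
    write_tip_tracks,
    write_va_csv,
)

#: Quintic minimum-jerk displacement profile on tau in [0, 1].
def _quintic(tau: np.ndarray) -> np.ndarray:
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


@dataclass
class SyntheticConfig:
    """Knobs of the generator; rates and scales are the skill-0 values and
    shrink linearly to zero at skill 1."""

    n_surgeons: int = 14
    trials_per_surgeon: int = 2
    n_raters: int = 3
    fps: float = 30.0
    #: per-surgeon latent skill; None -> bimodal (half high, half low)
    skill: np.ndarray | None = None
    phase_durations_s: dict[str, float] = field(
        default_factory=lambda: {"A": 15.0, "B": 10.0, "C": 15.0, "D": 25.0}
    )
    jerk_noise_scale: float = 150.0  # px/s^3 at skill 0
    detour_rate: float = 3.0  # extra submovements per phase at skill 0
    tde_rate: float = 4.0  # deformation events per trial at skill 0
    tde_amplitude: float = 0.4  # relative-area excursion size
    tde_width_s: float = 0.5
    tde_recovery_s: float = 5.0
    va_baseline_px: float = 5000.0
    va_drift_rel: float = 0.015
    va_noise_rel: float = 0.002
    gap_rate: float = 1.0  # validity gaps per hand-trial at skill 0
    rater_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("jerk_noise_scale", "detour_rate", "tde_rate",
                     "tde_amplitude", "va_baseline_px", "rater_sd", "gap_rate"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if self.skill is not None:
            self.skill = np.asarray(self.skill, dtype=float)
            if np.any((self.skill < 0) | (self.skill > 1)):
                raise InputError("skill must lie in [0, 1]")


def default_skills(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Bimodal latent skills: the first half of the cohort drawn from a
    high cluster (0.80 +/- 0.06), the rest from a low one (0.25 +/- 0.08)."""
    n = config.n_surgeons
    n_high = n // 2
    high = rng.normal(0.80, 0.06, size=n_high)
    low = rng.normal(0.25, 0.08, size=n - n_high)
    return np.clip(np.concatenate([high, low]), 0.0, 1.0)


def min_jerk_segment(
    p0: np.ndarray, p1: np.ndarray, duration_s: float, fps: float
) -> np.ndarray:
    """Sample a straight-line minimum-jerk reach from p0 to p1: positions at
    frame times [0, 1/fps, ..., duration] inclusive (round(duration*fps)+1
    samples), endpoint velocity and acceleration approximately zero."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if duration_s <= 0:
        raise InputError("duration must be > 0")
    if np.allclose(p0, p1):
        raise InputError("zero-length reach: compose a dwell instead")
    n = max(int(round(duration_s * fps)), 2)
    tau = np.arange(0, n + 1) / n
    return p0 + np.outer(_quintic(tau), p1 - p0)


def _integrated_jerk_noise(
    n: int, dt: float, scale: float, rng: np.random.Generator
) -> np.ndarray:
    """White jerk noise triple-integrated into a position perturbation and
    tapered (sin^2) to vanish at both ends of the window."""
    if scale <= 0 or n < 4:
        return np.zeros((n, 2))
    j = rng.normal(0.0, scale, size=(n, 2))
    a = np.cumsum(j, axis=0) * dt
    v = np.cumsum(a, axis=0) * dt
    p = np.cumsum(v, axis=0) * dt
    taper = np.sin(np.pi * np.arange(n) / (n - 1)) ** 2
    return p * taper[:, None]


def _phase_waypoints(
    hand: str, phase: str, rng: np.random.Generator
) -> np.ndarray:
    """Work-area waypoints for one hand in one phase. The dominant (right)
    hand ranges wider; the left hand mostly stabilizes near the vessel."""
    center = np.array([360.0, 240.0]) + rng.normal(0, 15, 2)
    spread = 110.0 if hand == "right" else 65.0
    n_base = {"A": 10, "B": 8, "C": 12, "D": 18}[phase]
    pts = center + rng.uniform(-spread, spread, size=(n_base + 1, 2))
    # enforce a minimum hop so no submovement degenerates to a dwell
    for i in range(1, len(pts)):
        while np.linalg.norm(pts[i] - pts[i - 1]) < 15:
            pts[i] = center + rng.uniform(-spread, spread, size=2)
    return pts


def _synth_hand_track(
    trial_id: str,
    hand: str,
    skill: float,
    phase_frames: dict[str, int],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> TipTrack:
    fps = config.fps
    dt = 1.0 / fps
    pieces = []
    for phase in PHASES:
        n_frames = phase_frames[phase]
        pts = _phase_waypoints(hand, phase, rng)
        # detours: extra waypoints spliced into the chain
        n_detours = rng.poisson(config.detour_rate * (1.0 - skill))
        for _ in range(n_detours):
            at = rng.integers(1, len(pts))
            detour = pts[at - 1] + rng.uniform(-90, 90, 2)
            pts = np.insert(pts, at, detour, axis=0)
        # never allocate fewer than 4 frames to a submovement
        max_sub = max(n_frames // 4, 1)
        if len(pts) - 1 > max_sub:
            pts = pts[: max_sub + 1]
        n_sub = len(pts) - 1
        weights = rng.uniform(0.6, 1.4, size=n_sub)
        frames_per_sub = np.maximum(
            np.round(weights / weights.sum() * n_frames).astype(int), 4
        )
        # trim/pad the last submovement so the phase frame count is exact
        frames_per_sub[-1] += n_frames - frames_per_sub.sum()
        if frames_per_sub[-1] < 4:
            frames_per_sub = frames_per_sub[:-1]
            frames_per_sub[-1] += n_frames - frames_per_sub.sum()
        pos = []
        for i, nf in enumerate(frames_per_sub):
            seg = min_jerk_segment(pts[i], pts[i + 1], nf * dt, fps)[:nf]
            seg = seg + _integrated_jerk_noise(
                nf, dt, config.jerk_noise_scale * (1.0 - skill), rng
            )
            pos.append(seg)
        pieces.append(np.concatenate(pos)[:n_frames])
    position = np.concatenate(pieces)
    n_total = len(position)
    valid = np.ones(n_total, dtype=bool)
    n_gaps = rng.poisson(config.gap_rate * (0.3 + 0.7 * (1.0 - skill)))
    for _ in range(n_gaps):
        width = int(rng.uniform(0.3, 1.0) * fps)
        start = int(rng.integers(0, max(n_total - width, 1)))
        valid[start : start + width] = False
    return TipTrack(
        trial_id=trial_id,
        hand=hand,
        frame_index=np.arange(n_total),
        x_px=position[:, 0],
        y_px=position[:, 1],
        valid=valid,
        fps=fps,
    )


def _synth_va(
    trial_id: str,
    skill: float,
    phase_frames: dict[str, int],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> VASeries:
    fps = config.fps
    n_total = sum(phase_frames.values())
    t = np.arange(n_total) / fps
    base = config.va_baseline_px
    drift = np.zeros(n_total)
    for _ in range(2):
        freq = rng.uniform(0.01, 0.04)
        drift += config.va_drift_rel * base * np.sin(
            2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi)
        )
    noise = rng.normal(0.0, config.va_noise_rel * base, size=n_total)
    va = base + drift + noise

    # deformation excursions: half-second cosine bumps, preferentially in
    # phases B and C (needle extraction, thread pulling)
    n_events = rng.poisson(config.tde_rate * (1.0 - skill))
    width = max(int(config.tde_width_s * fps), 4)
    bounds = {}
    start = 0
    for phase in PHASES:
        bounds[phase] = (start, start + phase_frames[phase])
        start += phase_frames[phase]
    phase_probs = {"A": 0.1, "B": 0.35, "C": 0.45, "D": 0.1}
    taken: list[int] = []
    for _ in range(n_events):
        for _attempt in range(50):
            phase = rng.choice(PHASES, p=[phase_probs[p] for p in PHASES])
            lo, hi = bounds[phase]
            if hi - lo <= width + 2:
                continue
            s = int(rng.integers(lo, hi - width))
            if all(abs(s - u) > 2 * width for u in taken):
                taken.append(s)
                break
        else:
            continue
        sign = -1.0 if rng.random() < 0.7 else 1.0
        # fast cosine ramp (the above-threshold excursion) followed by a
        # slow sub-threshold recovery, so each event is one excursion
        ramp = 0.5 * config.tde_amplitude * base * (
            1 - np.cos(np.pi * np.arange(1, width + 1) / width)
        )
        n_rec = int(config.tde_recovery_s * fps)
        recovery = config.tde_amplitude * base * (
            1 - np.arange(1, n_rec + 1) / n_rec
        )
        shape = np.concatenate([ramp, recovery])[: n_total - s]
        va[s : s + len(shape)] += sign * shape
    va = np.maximum(np.round(va), 0.0)
    return VASeries(
        trial_id=trial_id, frame_index=np.arange(n_total), va_px=va, fps=fps
    )


def synth_trial(
    skill: float,
    config: SyntheticConfig,
    rng: np.random.Generator,
    trial_id: str = "trial",
) -> tuple[TipTrack, TipTrack, VASeries, list[PhaseAnnotation]]:
    """One complete trial: right/left tip tracks, vessel-area series and
    the four phase annotations."""
    if not 0.0 <= skill <= 1.0:
        raise InputError("skill must lie in [0, 1]")
    fps = config.fps
    phase_frames = {
        p: max(int(round(config.phase_durations_s[p]
                         * rng.uniform(0.85, 1.15) * fps)), 8)
        for p in PHASES
    }
    annotations = []
    start = 0
    for p in PHASES:
        annotations.append(
            PhaseAnnotation(
                trial_id=trial_id, phase=p,
                start_frame=start, end_frame=start + phase_frames[p],
            )
        )
        start += phase_frames[p]
    right = _synth_hand_track(trial_id, "right", skill, phase_frames, config, rng)
    left = _synth_hand_track(trial_id, "left", skill, phase_frames, config, rng)
    va = _synth_va(trial_id, skill, phase_frames, config, rng)
    return right, left, va, annotations


def synth_rubric(
    skill: float,
    config: SyntheticConfig,
    rng: np.random.Generator,
    surgeon_id: str,
    trial_index: int,
) -> list[RubricScoreRecord]:
    """One rubric record per rater for one trial: category score latent is
    1 + 4*skill plus rater noise, rounded and clipped to [1, 5]."""
    records = []
    for r in range(config.n_raters):
        latent = 1.0 + 4.0 * skill + rng.normal(0, config.rater_sd,
                                                len(RUBRIC_CATEGORIES))
        scores = np.clip(np.round(latent), 1, 5).astype(int)
        records.append(
            RubricScoreRecord(
                surgeon_id=surgeon_id,
                trial_index=trial_index,
                rater_id=f"R{r + 1}",
                scores=dict(zip(RUBRIC_CATEGORIES, (int(s) for s in scores))),
            )
        )
    return records


def trial_identifier(surgeon_id: str, trial_index: int) -> str:
    return f"{surgeon_id}-T{trial_index}"


def parse_trial_identifier(trial_id: str) -> tuple[str, int]:
    surgeon, _, t = trial_id.rpartition("-T")
    return surgeon, int(t)


def generate_cohort(config: SyntheticConfig, out_dir: str | Path) -> Path:
    """Generate a full on-disk cohort: ``tracks.csv``, ``va.csv``,
    ``phases.csv``, ``rubric.csv`` and ``truth.csv`` (per-surgeon latent
    skill and intended label). Deterministic for a fixed seed: one root
    seed with an independent substream per surgeon."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    skill_rng = np.random.default_rng(root.spawn(1)[0])
    skills = (
        config.skill
        if config.skill is not None
        else default_skills(config, skill_rng)
    )
    if len(skills) != config.n_surgeons:
        raise InputError("skill vector length must equal n_surgeons")
    substreams = root.spawn(config.n_surgeons + 1)[1:]
    tracks, series, annotations, rubric, truth = [], [], [], [], []
    n_high = config.n_surgeons // 2 if config.skill is None else None
    for i, (skill, ss) in enumerate(zip(skills, substreams)):
        rng = np.random.default_rng(ss)
        surgeon = f"S{i + 1:02d}"
        for t in range(1, config.trials_per_surgeon + 1):
            trial_id = trial_identifier(surgeon, t)
            right, left, va, anns = synth_trial(skill, config, rng, trial_id)
            tracks += [right, left]
            series.append(va)
            annotations += anns
            rubric += synth_rubric(skill, config, rng, surgeon, t)
        intended = (
            ("good" if i < n_high else "poor")
            if n_high is not None
            else ("good" if skill >= 0.5 else "poor")
        )
        truth.append({"surgeon": surgeon, "skill": skill, "label": intended})
    write_tip_tracks(tracks, out_dir / "tracks.csv")
    write_va_csv(series, out_dir / "va.csv")
    write_phase_csv(annotations, out_dir / "phases.csv")
    write_rubric_csv(rubric, out_dir / "rubric.csv")
    pd.DataFrame(truth).to_csv(out_dir / "truth.csv", index=False)
    return out_dir
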