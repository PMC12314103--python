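"""Instrument-tip kinematics: path distance and normalized jerk index.

The detector loses the tip whenever the tool leaves the microscope's
field of view, so a track is a sequence of valid runs separated by gaps.
All differentiation is gap-aware: derivatives never span a gap, path
distance sums Euclidean steps only within runs, and procedural time
excludes invalid intervals. Bridging a gap would fabricate motion that
was never observed.

The normalized jerk index (NJI) of Flash and Hogan's minimum-jerk
framework is

    NJI = 1/2 * t^5 / D^2 * integral ||da/dt||^2 dt

with t the procedural time, D the path distance and a the acceleration.
It is dimensionless and scale-free: an ideal single minimum-jerk reach
scores 360 regardless of amplitude or duration, and any irregularity
raises the score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import DegenerateInputError, InputError
from .io_formats import TipTrack

DEFAULT_SMOOTHING_WINDOW = 7
DEFAULT_POLYORDER = 2


@dataclass
class KinematicSeries:
    """Smoothed positions and their first three time derivatives over the
    valid frames of one track, with ``segment_id`` labelling maximal
    contiguous valid runs. Derivatives are defined only within segments."""

    trial_id: str
    hand: str
    time_s: np.ndarray
    position: np.ndarray  # (n, 2) px
    velocity: np.ndarray  # (n, 2) px/s
    acceleration: np.ndarray  # (n, 2) px/s^2
    jerk: np.ndarray  # (n, 2) px/s^3
    segment_id: np.ndarray  # (n,) int

    def __len__(self) -> int:
        return len(self.time_s)

    def segments(self) -> list[np.ndarray]:
        """Index arrays of the contiguous valid runs, in time order."""
        return [
            np.flatnonzero(self.segment_id == s)
            for s in np.unique(self.segment_id)
        ]


def _contiguous_valid_runs(track: TipTrack) -> list[np.ndarray]:
    idx = np.flatnonzero(track.valid)
    if idx.size == 0:
        return []
    # a run breaks on an invalid frame or a jump in frame numbering
    breaks = np.flatnonzero(np.diff(track.frame_index[idx]) != 1)
    return np.split(idx, breaks + 1)


def segment_and_smooth(
    track: TipTrack,
    window: int = DEFAULT_SMOOTHING_WINDOW,
    polyorder: int = DEFAULT_POLYORDER,
) -> KinematicSeries:
    """Partition a track into contiguous valid runs, smooth positions within
    each run by local polynomial (Savitzky-Golay) regression, and
    differentiate three times by central differences (one-sided at run ends).

    Runs shorter than ``window`` pass through unsmoothed; ``window=1``
    disables smoothing entirely. Triple differentiation amplifies detection
    jitter, which is why smoothing is on by default for measured tracks.
    """
    if window < 1 or window % 2 == 0:
        raise InputError("smoothing window must be a positive odd integer")
    if window > 1 and polyorder >= window:
        raise InputError("polyorder must be < window")
    runs = _contiguous_valid_runs(track)
    if not runs:
        raise InputError(
            f"track {track.trial_id!r} ({track.hand}) has no valid frames"
        )
    times, pos, vel, acc, jerk, seg = [], [], [], [], [], []
    for s, run in enumerate(runs):
        t = track.frame_index[run] / track.fps
        p = np.column_stack([track.x_px[run], track.y_px[run]])
        if window > 1 and len(run) >= window:
            p = savgol_filter(p, window, polyorder, axis=0)
        if len(run) >= 2:
            v = np.stack([np.gradient(p[:, k], t) for k in range(2)], axis=1)
            a = np.stack([np.gradient(v[:, k], t) for k in range(2)], axis=1)
            j = np.stack([np.gradient(a[:, k], t) for k in range(2)], axis=1)
        else:
            v = a = j = np.zeros_like(p)
        times.append(t)
        pos.append(p)
        vel.append(v)
        acc.append(a)
        jerk.append(j)
        seg.append(np.full(len(run), s))
    return KinematicSeries(
        trial_id=track.trial_id,
        hand=track.hand,
        time_s=np.concatenate(times),
        position=np.concatenate(pos),
        velocity=np.concatenate(vel),
        acceleration=np.concatenate(acc),
        jerk=np.concatenate(jerk),
        segment_id=np.concatenate(seg),
    )


def path_distance(kin: KinematicSeries) -> float:
    """Total distance travelled by the tip: Euclidean steps between
    consecutive positions within each valid run; gaps contribute zero."""
    if len(kin) == 0:
        raise InputError("empty kinematic series")
    total = 0.0
    for run in kin.segments():
        steps = np.diff(kin.position[run], axis=0)
        total += float(np.hypot(steps[:, 0], steps[:, 1]).sum())
    return total


def procedural_time(kin: KinematicSeries) -> float:
    """Total valid duration: the sum of segment durations, in seconds."""
    return float(sum(kin.time_s[r[-1]] - kin.time_s[r[0]] for r in kin.segments()))


def normalized_jerk_index(kin: KinematicSeries) -> float:
    """Dimensionless smoothness score 1/2 * t^5/D^2 * integral ||jerk||^2 dt,
    the squared-jerk integral accumulated by the trapezoid rule within
    segments. Lower is smoother; an ideal minimum-jerk reach scores 360.
    """
    t = procedural_time(kin)
    if t <= 0:
        raise InputError("zero procedural time")
    d = path_distance(kin)
    if d <= 0:
        raise DegenerateInputError("stationary tip: path distance is zero")
    integral = 0.0
    for run in kin.segments():
        if len(run) < 2:
            continue
        j2 = np.sum(kin.jerk[run] ** 2, axis=1)
        integral += float(np.trapezoid(j2, kin.time_s[run]))
    return 0.5 * t**5 / d**2 * integral
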