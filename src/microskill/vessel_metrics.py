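"""Vessel-area (VA) deformation parameters.

From a per-frame vessel pixel-count series the segmentation arm of the
pipeline derives four parameters:

* **CV-VA** — coefficient of variation of VA, sigma/mu;
* **dVA** — relative change of VA per unit time. VA is first normalized
  by its within-trial mean so the series is dimensionless; the forward
  difference is then scaled by the frame rate, giving units of 1/s;
* **Max-dVA** — the largest absolute dVA over the analysed window;
* **No. of TDE** — tissue-deformation errors, excursions of dVA beyond a
  threshold. The default threshold 1.13 is the mean +/- 1.96 SD of dVA
  pooled over a reference training cohort; :func:`cohort_tde_threshold`
  recomputes it for a new cohort.

Normalizing by the trial mean makes dVA invariant to absolute vessel size
and image resolution, which is what puts the threshold on an order-1 scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .errors import InputError, ValidationError
from .io_formats import VASeries

#: Threshold on |dVA| defining a tissue-deformation error, from the
#: mean +/- 1.96 SD of dVA pooled across a reference cohort's trials.
DEFAULT_TDE_THRESHOLD = 1.13

Normalization = Literal["trial_mean", "first_frame", "none"]


@dataclass
class DeltaVASeries:
    """Forward-difference series dVA; one sample per frame pair, so length
    is one less than the parent VA series."""

    trial_id: str
    frame_index: np.ndarray
    dva: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        self.dva = np.asarray(self.dva, dtype=float)
        if not np.all(np.isfinite(self.dva)):
            raise ValidationError("non-finite dVA values")

    def __len__(self) -> int:
        return len(self.dva)


@dataclass(frozen=True)
class TDEEvent:
    """One deformation excursion: a maximal run of consecutive dVA samples
    beyond the threshold with a common sign."""

    trial_id: str
    start_frame: int
    end_frame: int  # half-open
    peak_dva: float
    sign: str  # "positive" | "negative"


@dataclass(frozen=True)
class TDEConfig:
    """Threshold and counting convention for tissue-deformation errors.

    ``excursion`` counts each above-threshold run once (an error event);
    ``per_sample`` counts every above-threshold frame pair. Samples exactly
    at the threshold never trigger.
    """

    threshold: float = DEFAULT_TDE_THRESHOLD
    counting_mode: Literal["excursion", "per_sample"] = "excursion"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValidationError("TDE threshold must be > 0")
        if self.counting_mode not in ("excursion", "per_sample"):
            raise ValidationError(f"unknown counting_mode {self.counting_mode!r}")


def relative_delta_va(
    series: VASeries, normalization: Normalization = "trial_mean"
) -> DeltaVASeries:
    """Relative VA change per second: forward differences of the normalized
    VA series, scaled by the frame rate.

    A constant series maps to all zeros, and scaling ``va_px`` by any
    positive constant leaves the result unchanged (under the default
    trial-mean normalization).
    """
    if len(series) < 2:
        raise InputError("need at least 2 frames to difference VA")
    va = series.va_px
    if normalization == "trial_mean":
        mean = va.mean()
        if mean <= 0:
            raise InputError("zero-mean VA series cannot be normalized")
        norm = va / mean
    elif normalization == "first_frame":
        if va[0] <= 0:
            raise InputError("zero first-frame VA cannot be normalized")
        norm = va / va[0]
    elif normalization == "none":
        norm = va
    else:
        raise ValidationError(f"unknown normalization {normalization!r}")
    dva = np.diff(norm) * series.fps
    return DeltaVASeries(
        trial_id=series.trial_id,
        frame_index=series.frame_index[:-1],
        dva=dva,
        fps=series.fps,
    )


def cv_va(series: VASeries) -> float:
    """Coefficient of variation sigma/mu of the VA series (sample SD,
    n-1 denominator)."""
    if len(series) < 2:
        raise InputError("need at least 2 frames for CV-VA")
    mean = series.va_px.mean()
    if mean <= 0:
        raise InputError("zero-mean VA series has undefined CV")
    return float(series.va_px.std(ddof=1) / mean)


def max_abs_delta_va(dva: DeltaVASeries) -> float:
    """Largest absolute dVA over the analysed window."""
    if len(dva) == 0:
        raise InputError("empty dVA series")
    return float(np.max(np.abs(dva.dva)))


def detect_tde(
    dva: DeltaVASeries, config: TDEConfig = TDEConfig()
) -> tuple[int, list[TDEEvent]]:
    """Count tissue-deformation errors in a dVA series.

    In ``excursion`` mode each maximal run of consecutive samples with
    ``|dva| > threshold`` and a common sign counts once; in ``per_sample``
    mode every above-threshold sample counts.
    """
    x = dva.dva
    over = np.abs(x) > config.threshold
    signs = np.sign(x)
    events: list[TDEEvent] = []
    i = 0
    n = len(x)
    while i < n:
        if not over[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and over[j + 1] and signs[j + 1] == signs[i]:
            j += 1
        run = x[i : j + 1]
        peak = run[np.argmax(np.abs(run))]
        events.append(
            TDEEvent(
                trial_id=dva.trial_id,
                start_frame=int(dva.frame_index[i]),
                end_frame=int(dva.frame_index[j]) + 1,
                peak_dva=float(peak),
                sign="positive" if peak > 0 else "negative",
            )
        )
        i = j + 1
    if config.counting_mode == "per_sample":
        count = int(np.count_nonzero(over))
    else:
        count = len(events)
    return count, events


def cohort_tde_threshold(all_dva: Iterable[DeltaVASeries]) -> float:
    """Refresh the TDE threshold on a new cohort: the mean +/- 1.96 SD band
    of dVA pooled across all trials by all surgeons, returned as the larger
    absolute band edge (sample SD)."""
    chunks = [
        np.atleast_1d(np.asarray(getattr(d, "dva", d), dtype=float)) for d in all_dva
    ]
    pooled = np.concatenate(chunks) if chunks else np.empty(0)
    if pooled.size < 2:
        raise InputError("need at least 2 pooled dVA samples")
    mean = pooled.mean()
    sd = pooled.std(ddof=1)
    return float(max(abs(mean - 1.96 * sd), abs(mean + 1.96 * sd)))
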