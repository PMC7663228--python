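"""Accelerometer count processing: epochs -> weekday activity summaries.

Raw count streams are collapsed to 10 s epochs, non-wear is removed as runs
of >=60 min of zero counts, wear epochs are classified as sedentary / light /
MVPA with youth count thresholds scaled proportionally from counts-per-minute
(sedentary <= 100 cpm, MVPA >= 2296 cpm), days are valid with >=500 wear
minutes between 06:00 and midnight, and participants contribute weekday
MVPA/sedentary averages when they have two or more valid days. The
moderate-to-vigorous guideline flag uses the mean over all valid days
(weekday and weekend) against 60 min/day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

# Epoch intensity codes.
NONWEAR, SEDENTARY, LIGHT, MVPA = -1, 0, 1, 2


@dataclass
class CutPoints:
    """Count thresholds per epoch; sedentary <= sedentary_max < mvpa_min."""

    epoch_s: int = 10
    sedentary_max: float = 100.0 * 10 / 60
    mvpa_min: float = 2296.0 * 10 / 60

    def __post_init__(self):
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")
        if not self.sedentary_max < self.mvpa_min:
            raise ValueError("sedentary_max must be < mvpa_min")

    @classmethod
    def youth_cpm(cls, epoch_s: int = 10, sedentary_cpm: float = 100.0,
                  mvpa_cpm: float = 2296.0) -> "CutPoints":
        """Proportionally scale counts-per-minute thresholds to an epoch."""
        return cls(epoch_s=epoch_s,
                   sedentary_max=sedentary_cpm * epoch_s / 60.0,
                   mvpa_min=mvpa_cpm * epoch_s / 60.0)


@dataclass
class EpochSeries:
    """A uniform, strictly increasing stream of accelerometer counts."""

    participant_id: str
    start: pd.DatetimeIndex     # epoch start times (local)
    epoch_s: int
    counts: np.ndarray          # non-negative integers
    truth: Optional[np.ndarray] = None  # generator ground-truth codes

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if len(self.start) != len(self.counts):
            raise ValueError("start and counts must align")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(self.start) > 1:
            deltas = np.diff(self.start.asi8) / 1e9
            if not np.allclose(deltas, self.epoch_s):
                raise ValueError(
                    "epochs must be uniform, non-overlapping and strictly "
                    f"increasing with duration {self.epoch_s}s"
                )

    def __len__(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "timestamp": self.start.strftime("%Y-%m-%dT%H:%M:%S"),
            "counts": self.counts.astype(int),
        })

    @classmethod
    def from_frame(cls, participant_id: str, df: pd.DataFrame) -> "EpochSeries":
        ts = pd.DatetimeIndex(pd.to_datetime(df["timestamp"]))
        if len(ts) < 2:
            raise ValueError("need at least two epochs to infer duration")
        epoch_s = int(round((ts[1] - ts[0]).total_seconds()))
        return cls(participant_id, ts, epoch_s, df["counts"].to_numpy())


@dataclass
class DaySummary:
    date: object
    wear_min: float
    valid: bool
    sedentary_min: float
    mvpa_min: float
    is_weekday: bool
    light_min: float = 0.0
    nonwear_min: float = 0.0
    out_window_min: float = 0.0


def collapse_epochs(series: EpochSeries, target_epoch_s: int = 10) -> EpochSeries:
    """Sum counts into consecutive windows of ``target_epoch_s`` seconds.

    The trailing partial window is dropped (and logged); total counts are
    conserved up to that tail.
    """
    if target_epoch_s % series.epoch_s != 0:
        raise ValueError(
            f"target epoch {target_epoch_s}s is not an integer multiple of "
            f"native epoch {series.epoch_s}s"
        )
    factor = target_epoch_s // series.epoch_s
    if factor == 1:
        return series
    n_win = len(series) // factor
    tail = len(series) - n_win * factor
    if tail:
        log.info("collapse_epochs[%s]: dropped %d-epoch tail",
                 series.participant_id, tail)
    counts = series.counts[: n_win * factor].reshape(n_win, factor).sum(axis=1)
    start = series.start[: n_win * factor : factor]
    return EpochSeries(series.participant_id, start, target_epoch_s, counts)


def detect_nonwear(series: EpochSeries, min_zero_run_min: float = 60.0) -> np.ndarray:
    """Wear mask: maximal zero-count runs of >= ``min_zero_run_min`` are non-wear."""
    zero = series.counts == 0
    min_epochs = int(np.ceil(min_zero_run_min * 60.0 / series.epoch_s))
    wear = np.ones(len(series), dtype=bool)
    if not zero.any():
        return wear
    # Run-length encode the zero mask.
    boundaries = np.flatnonzero(np.diff(zero.astype(np.int8))) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(zero)]))
    for s, e in zip(starts, ends):
        if zero[s] and (e - s) >= min_epochs:
            wear[s:e] = False
    return wear


def classify_epochs(series: EpochSeries, wear_mask: np.ndarray,
                    cut: CutPoints) -> np.ndarray:
    """Intensity code per epoch; non-wear epochs are coded NONWEAR."""
    if cut.epoch_s != series.epoch_s:
        raise ValueError(
            f"cut points are for {cut.epoch_s}s epochs but series has "
            f"{series.epoch_s}s epochs"
        )
    if len(wear_mask) != len(series):
        raise ValueError("wear mask must align with series")
    labels = np.full(len(series), LIGHT, dtype=np.int8)
    labels[series.counts <= cut.sedentary_max] = SEDENTARY
    labels[series.counts >= cut.mvpa_min] = MVPA
    labels[~wear_mask] = NONWEAR
    return labels


def summarize_days(series: EpochSeries, labels: np.ndarray,
                   wear_mask: np.ndarray,
                   window_min: tuple = (360, 1440),
                   min_wear_min: float = 500.0) -> list:
    """Per calendar day wear/sedentary/MVPA minutes inside the window.

    Epochs belong to the day and minute-of-day of their start time
    (half-open [start, start+duration) intervals); a day is valid when wear
    time inside the window reaches ``min_wear_min``.
    """
    lo, hi = window_min
    epm = series.epoch_s / 60.0  # minutes per epoch
    minute_of_day = (series.start.hour * 60 + series.start.minute
                     + series.start.second / 60.0)
    in_window = (minute_of_day >= lo) & (minute_of_day < hi)
    dates = series.start.normalize()
    out = []
    for date in dates.unique():
        sel = dates == date
        selw = sel & in_window
        wear = wear_mask & selw
        wear_min = wear.sum() * epm
        sed_min = ((labels == SEDENTARY) & selw).sum() * epm
        light_min = ((labels == LIGHT) & selw).sum() * epm
        mvpa_min = ((labels == MVPA) & selw).sum() * epm
        nonwear_min = ((labels == NONWEAR) & selw).sum() * epm
        out_window = (sel & ~in_window).sum() * epm
        out.append(DaySummary(
            date=date.date(),
            wear_min=float(wear_min),
            valid=bool(wear_min >= min_wear_min - 1e-9),
            sedentary_min=float(sed_min),
            mvpa_min=float(mvpa_min),
            is_weekday=bool(date.dayofweek < 5),
            light_min=float(light_min),
            nonwear_min=float(nonwear_min),
            out_window_min=float(out_window),
        ))
    return out


def participant_summary(days: list, min_valid_days: int = 2,
                        guideline_min: float = 60.0) -> dict:
    """Weekday averages and guideline flag from a participant's day summaries.

    Included participants need >= ``min_valid_days`` valid days; weekday
    averages use valid weekdays only (missing, not zero, if none exist); the
    guideline flag averages MVPA over all valid days.
    """
    if not days:
        raise ValueError("days must be nonempty")
    valid = [d for d in days if d.valid]
    included = len(valid) >= min_valid_days
    res = {
        "included": included,
        "n_valid_days": len(valid),
        "weekday_mvpa_min": np.nan,
        "weekday_sed_min": np.nan,
        "meets_guideline": np.nan,
    }
    if not included:
        return res
    weekdays = [d for d in valid if d.is_weekday]
    if weekdays:
        res["weekday_mvpa_min"] = float(np.mean([d.mvpa_min for d in weekdays]))
        res["weekday_sed_min"] = float(np.mean([d.sedentary_min for d in weekdays]))
    else:
        log.warning("participant included but has no valid weekdays; "
                    "weekday averages left missing")
    res["meets_guideline"] = bool(
        np.mean([d.mvpa_min for d in valid]) >= guideline_min)
    return res


def process_series(series: EpochSeries, cut: Optional[CutPoints] = None,
                   target_epoch_s: int = 10,
                   min_zero_run_min: float = 60.0,
                   window_min: tuple = (360, 1440),
                   min_wear_min: float = 500.0,
                   min_valid_days: int = 2) -> dict:
    """Full chain: collapse -> non-wear -> classify -> days -> participant."""
    cut = cut or CutPoints.youth_cpm(epoch_s=target_epoch_s)
    s = collapse_epochs(series, target_epoch_s)
    wear = detect_nonwear(s, min_zero_run_min)
    labels = classify_epochs(s, wear, cut)
    days = summarize_days(s, labels, wear, window_min, min_wear_min)
    out = participant_summary(days, min_valid_days)
    out["participant_id"] = series.participant_id
    out["days"] = days
    return out
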