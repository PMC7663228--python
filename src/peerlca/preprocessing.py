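"""Questionnaire scoring, dichotomization, rescaling and matrix assembly.

Scale scores are item means (with a minimum-answered rule). Amotivation is
dichotomized at <=0.25 (very low vs comparatively high) and the three
peer-norm scores at low (0-2) vs high (3-6). Continuous indicators are
affinely rescaled to [0,1] with declared (data-independent) ranges, and the
n x 12 analysis matrix keeps every participant: missing cells are masked,
never deleted, because the model consumes partial rows via full-information
maximum likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (ALL_COLUMNS, BINARY_COLUMNS, CONTINUOUS_COLUMNS,
                     DECLARED_RANGES)

log = logging.getLogger(__name__)


@dataclass
class ScaleDefinition:
    name: str
    items: tuple
    item_range: tuple  # (min, max), inclusive
    min_items_answered: int = 1

    def __post_init__(self):
        lo, hi = self.item_range
        if not np.isfinite([lo, hi]).all() or lo >= hi:
            raise ValueError("item_range must be finite with min < max")
        if self.min_items_answered < 1:
            raise ValueError("min_items_answered must be >= 1")


def score_scale(responses: pd.DataFrame, definition: ScaleDefinition) -> pd.Series:
    """Mean of answered items, missing when too few items were answered."""
    items = responses[list(definition.items)]
    lo, hi = definition.item_range
    bad = (items < lo - 1e-12) | (items > hi + 1e-12)
    if bad.any().any():
        rows = responses.index[bad.any(axis=1)].tolist()
        raise ValueError(
            f"out-of-range responses for scale {definition.name!r} in rows "
            f"{rows[:10]} (range {definition.item_range})"
        )
    n_answered = items.notna().sum(axis=1)
    score = items.mean(axis=1)
    score[n_answered < definition.min_items_answered] = np.nan
    return score


def dichotomize_amotivation(score, cut: float = 0.25):
    """0 = very low amotivation (score <= cut), 1 = comparatively high."""
    arr = np.asarray(score, dtype=float)
    if np.nanmin(arr, initial=0.0) < 0:
        raise ValueError("amotivation scores must be >= 0")
    out = np.where(arr <= cut, 0.0, 1.0)
    out = np.where(np.isnan(arr), np.nan, out)
    return out if out.ndim else float(out)


def dichotomize_peer_norm(score, low_max: float = 2.0):
    """0 = low (0-2), 1 = high (3-6) on the 0-6 peer-norm score.

    Scores strictly above the low band (e.g. 2.5) are high: the cut sits at
    the midpoint of the instrument range.
    """
    arr = np.asarray(score, dtype=float)
    with np.errstate(invalid="ignore"):
        if ((arr < -1e-12) | (arr > 6 + 1e-12)).any():
            raise ValueError("peer-norm scores must be in [0, 6]")
    out = np.where(arr <= low_max, 0.0, 1.0)
    out = np.where(np.isnan(arr), np.nan, out)
    return out if out.ndim else float(out)


def rescale_unit(values, declared_range) -> np.ndarray:
    """Affine map of ``values`` onto [0,1] given a declared finite range.

    Observed values outside the declared range are an error (never clipped):
    the transform is meant to be data-independent and invertible.
    """
    lo, hi = map(float, declared_range)
    if not np.isfinite([lo, hi]).all() or lo >= hi:
        raise ValueError("declared range must be finite with min < max")
    arr = np.asarray(values, dtype=float)
    with np.errstate(invalid="ignore"):
        outside = (arr < lo - 1e-9) | (arr > hi + 1e-9)
    if outside.any():
        raise ValueError(
            f"{int(outside.sum())} observed values fall outside the declared "
            f"range ({lo}, {hi}); refusing to clip"
        )
    return (arr - lo) / (hi - lo)


@dataclass
class IndicatorMatrix:
    """The n x 12 analysis matrix: 8 continuous on [0,1] + 4 binary columns.

    Missing cells are NaN in ``values``; ``mask`` is True where observed.
    """

    values: np.ndarray
    school_ids: np.ndarray
    participant_ids: np.ndarray
    columns: tuple = ALL_COLUMNS
    n_continuous: int = len(CONTINUOUS_COLUMNS)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise ValueError("values must be n x len(columns)")
        cont = self.values[:, : self.n_continuous]
        with np.errstate(invalid="ignore"):
            if np.nanmin(cont, initial=0.0) < -1e-9 or np.nanmax(cont, initial=0.0) > 1 + 1e-9:
                raise ValueError("continuous columns must lie in [0,1]")
            binv = self.values[:, self.n_continuous:]
            obs = binv[~np.isnan(binv)]
            if not np.isin(obs, (0.0, 1.0)).all():
                raise ValueError("binary columns must be 0/1")

    @property
    def mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.columns))
        for col in self.columns:
            df[f"{col}_observed"] = (~df[col].isna()).astype(int)
        df.insert(0, "participant_id", self.participant_ids)
        df.insert(1, "school_id", self.school_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IndicatorMatrix":
        values = df[list(ALL_COLUMNS)].to_numpy(dtype=float)
        return cls(values=values,
                   school_ids=df["school_id"].to_numpy(),
                   participant_ids=df["participant_id"].to_numpy())


def build_indicator_matrix(cohort: pd.DataFrame,
                           pa_summary: pd.DataFrame | None = None,
                           declared_ranges: dict = DECLARED_RANGES) -> IndicatorMatrix:
    """Assemble the 12-column analysis matrix from a processed cohort.

    ``pa_summary`` (participant_id, weekday_mvpa_min, weekday_sed_min), when
    given, replaces the cohort's mvpa/sedentary columns — participants
    excluded by the wear-time rules get those cells masked. No rows are
    dropped; participants missing all 12 indicators are retained and flagged
    non-informative.
    """
    df = cohort.copy()
    if pa_summary is not None:
        pa = pa_summary.set_index("participant_id")
        df = df.drop(columns=[c for c in ("mvpa", "sedentary") if c in df],
                     errors="ignore")
        df["mvpa"] = df["participant_id"].map(pa["weekday_mvpa_min"])
        df["sedentary"] = df["participant_id"].map(pa["weekday_sed_min"])
    n = len(df)
    values = np.full((n, len(ALL_COLUMNS)), np.nan)
    for j, col in enumerate(CONTINUOUS_COLUMNS):
        values[:, j] = rescale_unit(df[col].to_numpy(dtype=float),
                                    declared_ranges[col])
    for j, col in enumerate(BINARY_COLUMNS):
        values[:, len(CONTINUOUS_COLUMNS) + j] = df[col].to_numpy(dtype=float)
    mat = IndicatorMatrix(
        values=values,
        school_ids=df["school_id"].to_numpy(),
        participant_ids=df["participant_id"].to_numpy(),
    )
    empty = (~mat.mask).all(axis=1)
    if empty.any():
        log.warning("%d participants have no observed indicators "
                    "(retained, non-informative)", int(empty.sum()))
    return mat
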