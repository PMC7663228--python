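"""Synthetic cohorts, nomination ballots and accelerometer count streams.

Everything downstream is testable without any external data: participants
are drawn from a configured latent class mixture (continuous indicators from
class-specific normals, the MVPA/sedentary pair jointly with one shared
covariance, binary indicators from class Bernoulli probabilities), ballots
follow a class-dependent nomination-attractiveness model within schools, and
epoch-level count streams realize intended wear/intensity profiles with
ground-truth labels retained for oracle tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .accelerometry import CutPoints, EpochSeries
from .config import (ALL_COLUMNS, BINARY_COLUMNS, CONTINUOUS_COLUMNS,
                     DECLARED_RANGES, MVPA_INDEX, NOMINATION_QUESTIONS,
                     SEDENTARY_INDEX, NominationModel, SimulationConfig)
from .rng import as_rng, child_rng

log = logging.getLogger(__name__)


def _assign_classes(mixing: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF class assignment from uniforms (transparent, testable)."""
    cum = np.cumsum(mixing)
    cls = np.searchsorted(cum, u)
    return np.minimum(cls, len(mixing) - 1)


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw one cohort from the configured class mixture.

    Deterministic under the config seed. Bounded columns are clipped to their
    declared range; the clipped fraction is logged and stored in
    ``df.attrs['clip_fraction']``.
    """
    config.validate()
    rng = child_rng(config.seed, "cohort")
    sizes = np.asarray(config.school_sizes, dtype=int)
    n = int(sizes.sum())
    k = config.n_classes
    school_id = np.repeat(np.arange(1, config.n_schools + 1), sizes)
    cls = _assign_classes(np.asarray(config.mixing, float), rng.random(n))

    means = np.asarray(config.class_means, float)
    sds = np.asarray(config.class_sds, float)
    values = means[cls] + sds[cls] * rng.standard_normal((n, 8))

    # MVPA/sedentary drawn jointly with the shared covariance (overwrites
    # the independent draws above for those two columns).
    c = float(config.shared_mvpa_sed_cov)
    va = sds[cls, MVPA_INDEX] ** 2
    vb = sds[cls, SEDENTARY_INDEX] ** 2
    z = rng.standard_normal((n, 2))
    l11 = np.sqrt(va)
    l21 = c / l11
    l22 = np.sqrt(vb - c * c / va)
    values[:, MVPA_INDEX] = means[cls, MVPA_INDEX] + l11 * z[:, 0]
    values[:, SEDENTARY_INDEX] = (means[cls, SEDENTARY_INDEX]
                                  + l21 * z[:, 0] + l22 * z[:, 1])

    clipped = 0
    for j, col in enumerate(CONTINUOUS_COLUMNS):
        lo, hi = DECLARED_RANGES[col]
        out = (values[:, j] < lo) | (values[:, j] > hi)
        clipped += int(out.sum())
        values[:, j] = np.clip(values[:, j], lo, hi)
    clip_fraction = clipped / (n * 8)
    if clipped:
        log.info("generate_cohort: clipped %d/%d continuous draws (%.2f%%)",
                 clipped, n * 8, 100 * clip_fraction)

    probs = np.asarray(config.binary_probs, float)
    binary = (rng.random((n, 4)) < probs[cls]).astype(float)

    fas = rng.binomial(9, np.asarray(config.fas_probs)[cls])
    fsm = rng.random(n) < np.asarray(config.fsm_probs)[cls]
    ethnicity = np.where(rng.random(n) < config.nonwhite_rate,
                         "Non-white", "White")
    accel_compliant = rng.random(n) >= config.accel_noncompliance_rate

    df = pd.DataFrame({
        "participant_id": [f"p{i:04d}" for i in range(1, n + 1)],
        "school_id": school_id,
        "true_class": cls + 1,
    })
    for j, col in enumerate(CONTINUOUS_COLUMNS):
        df[col] = values[:, j]
    for j, col in enumerate(BINARY_COLUMNS):
        df[col] = binary[:, j]
    df["fas"] = fas
    df["fsm"] = fsm.astype(int)
    df["ethnicity"] = ethnicity
    df["accel_compliant"] = accel_compliant.astype(int)
    df["supporter"] = np.nan  # filled by the nomination stage
    df.attrs["clip_fraction"] = clip_fraction
    return df


@dataclass
class MissingnessResult:
    data: pd.DataFrame       # cohort with masked cells set to NaN
    original: pd.DataFrame   # pre-masking cohort (oracle)
    mask: pd.DataFrame       # True where masked


def inject_missingness(cohort: pd.DataFrame, rates: dict,
                       mechanism: str = "mcar",
                       class_multipliers: dict | None = None,
                       seed: int = 0) -> MissingnessResult:
    """Mask indicator cells at the configured per-column rates.

    ``mechanism``: 'mcar' masks uniformly; 'mar-class' multiplies each
    column's rate by ``class_multipliers[true_class]`` (missing at random
    given the latent class). Rates above 0.95 are refused.
    """
    for col, rate in rates.items():
        if not 0 <= rate <= 0.95:
            raise ValueError(f"rate for {col!r} must be in [0, 0.95] "
                             "(higher leaves the pipeline untestable)")
        if col not in cohort.columns:
            raise ValueError(f"unknown column {col!r}")
    if mechanism not in ("mcar", "mar-class"):
        raise ValueError("mechanism must be 'mcar' or 'mar-class'")
    rng = child_rng(seed, "missingness")
    data = cohort.copy()
    mask = pd.DataFrame(False, index=cohort.index,
                        columns=[c for c in ALL_COLUMNS if c in rates])
    n = len(cohort)
    for col in mask.columns:
        rate = np.full(n, rates[col])
        if mechanism == "mar-class":
            mult = np.ones(n)
            for klass, m in (class_multipliers or {}).items():
                mult[cohort["true_class"].to_numpy() == klass] = m
            rate = np.minimum(rate * mult, 0.95)
        hit = rng.random(n) < rate
        mask[col] = hit
        data.loc[hit, col] = np.nan
    return MissingnessResult(data=data, original=cohort.copy(), mask=mask)


def generate_ballots(cohort: pd.DataFrame, model: NominationModel,
                     seed: int = 0) -> pd.DataFrame:
    """Nomination ballots: up to five names per question, four questions.

    Nominees are sampled within school (without replacement per question,
    self excluded) with probability proportional to the nominee's class
    propensity. A configurable fraction of slots is replaced by
    out-of-roster or cross-school names to exercise ballot cleaning.
    Non-consenting nominators (ballot-only) are spread across schools
    proportionally to size.
    """
    model.validate()
    if cohort.empty:
        raise ValueError("cohort is empty")
    rng = child_rng(seed, "ballots")
    prop = np.asarray(model.class_propensity, float)
    questions = NOMINATION_QUESTIONS[: model.n_questions]

    # nomination attractiveness: class propensity x individual popularity
    attract = prop[cohort["true_class"].to_numpy() - 1]
    if model.individual_log_sd > 0:
        attract = attract * np.exp(
            model.individual_log_sd * rng.standard_normal(len(cohort)))
    attract_by_id = pd.Series(attract, index=cohort["participant_id"])

    schools = cohort.groupby("school_id")
    sizes = schools.size()
    extra = np.zeros(len(sizes), dtype=int)
    if model.n_nonconsenting_nominators:
        share = sizes.to_numpy() / sizes.sum()
        extra = rng.multinomial(model.n_nonconsenting_nominators, share)

    records = []
    all_school_ids = sizes.index.to_numpy()
    ext_counter = 0
    for si, (school, grp) in enumerate(schools):
        ids = grp["participant_id"].to_numpy()
        if len(ids) < 2:
            log.warning("school %s has %d pupil(s); no ballots generated",
                        school, len(ids))
            continue
        w = attract_by_id[ids].to_numpy()
        nominators = list(ids) + [f"nc_{school}_{i}" for i in range(extra[si])]
        for nominator in nominators:
            not_self = ids != nominator
            wn = w * not_self
            if wn.sum() <= 0:
                continue
            pn = wn / wn.sum()
            for q in questions:
                k_names = int(rng.integers(1, model.max_names_per_question + 1))
                k_names = min(k_names, int(not_self.sum()))
                chosen = rng.choice(ids, size=k_names, replace=False, p=pn)
                for name in chosen:
                    u = rng.random()
                    if u < model.out_of_roster_rate:
                        ext_counter += 1
                        name = f"ext_{ext_counter:05d}"
                    elif u < model.out_of_roster_rate + model.cross_school_rate \
                            and len(all_school_ids) > 1:
                        other = all_school_ids[all_school_ids != school]
                        osch = other[rng.integers(len(other))]
                        oids = cohort.loc[cohort["school_id"] == osch,
                                          "participant_id"].to_numpy()
                        name = oids[rng.integers(len(oids))]
                    records.append((nominator, school, q, name))
    return pd.DataFrame(records, columns=["nominator_id", "school_id",
                                          "question", "nominee_name"])


def roster_from_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Roster mapping names to participant ids (names are the ids here)."""
    return pd.DataFrame({
        "participant_id": cohort["participant_id"],
        "school_id": cohort["school_id"],
        "name": cohort["participant_id"],
    })


# ---------------------------------------------------------------------------
# Epoch-level count streams
# ---------------------------------------------------------------------------

#: block label -> (band_lo_frac, band_hi_frac) of the cut-point thresholds;
#: margins keep generated counts strictly inside their intensity band.
_BAND_MARGIN = 0.2


def _count_band(label: str, cut: CutPoints, native_epoch_s: int) -> tuple:
    scale = native_epoch_s / cut.epoch_s
    sed_max = cut.sedentary_max * scale
    mvpa_min = cut.mvpa_min * scale
    if label == "nonwear":
        return (0, 0)
    if label == "sedentary":
        return (0, int(np.floor((1 - _BAND_MARGIN) * sed_max)))
    if label == "light":
        return (int(np.ceil((1 + _BAND_MARGIN) * sed_max)),
                int(np.floor((1 - _BAND_MARGIN) * mvpa_min)))
    if label == "mvpa":
        return (int(np.ceil((1 + _BAND_MARGIN) * mvpa_min)),
                int(np.floor(1.8 * mvpa_min)))
    raise ValueError(f"unknown block label {label!r}")


def generate_count_stream(daily_profile, n_days: int, seed: int = 0,
                          native_epoch_s: int = 1,
                          start_date: str = "2018-11-05",
                          participant_id: str = "sim",
                          cut: CutPoints | None = None,
                          min_zero_run_min: float = 60.0) -> EpochSeries:
    """Realize a daily block profile as an epoch-level count stream.

    ``daily_profile`` is a list of (start_min, duration_min, label) blocks
    with labels in {nonwear, sedentary, light, mvpa}; blocks must not
    overlap; uncovered minutes are zero counts. Counts are drawn strictly
    inside the intensity band implied by the cut points. Ground-truth labels
    per epoch are retained in ``series.truth``; zero runs shorter than the
    non-wear rule are truth-labelled sedentary (zero counts on wear time),
    consistent with the rule the processing stage applies.
    """
    cut = cut or CutPoints.youth_cpm(epoch_s=10)
    rng = as_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    epd = int(round(1440 * 60 / native_epoch_s))  # epochs per day
    if 1440 * 60 % native_epoch_s:
        raise ValueError("native epoch must divide the day")
    per_min = 60 // native_epoch_s

    cover = np.zeros(1440, dtype=bool)
    blocks = []
    for start_min, dur_min, label in daily_profile:
        s, e = int(start_min), int(start_min + dur_min)
        if not (0 <= s < e <= 1440):
            raise ValueError(f"block ({start_min}, {dur_min}) outside the day")
        if cover[s:e].any():
            raise ValueError("overlapping blocks in daily profile")
        cover[s:e] = True
        blocks.append((s, e, label))

    day_labels = np.full(1440, "nonwear", dtype=object)
    for s, e, label in blocks:
        day_labels[s:e] = label

    labels = np.tile(np.repeat(day_labels, per_min), n_days)
    counts = np.zeros(len(labels), dtype=int)
    for label in ("sedentary", "light", "mvpa"):
        sel = labels == label
        if sel.any():
            lo, hi = _count_band(label, cut, native_epoch_s)
            counts[sel] = rng.integers(lo, hi + 1, size=int(sel.sum()))

    # rule-consistent truth: zero runs shorter than the non-wear rule are wear
    truth = labels.copy()
    zero = counts == 0
    min_epochs = int(np.ceil(min_zero_run_min * 60 / native_epoch_s))
    boundaries = np.flatnonzero(np.diff(zero.astype(np.int8))) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(zero)]))
    for s, e in zip(starts, ends):
        if zero[s]:
            truth[s:e] = "nonwear" if (e - s) >= min_epochs else "sedentary"

    start = pd.date_range(start=start_date, periods=n_days * epd,
                          freq=f"{native_epoch_s}s")
    return EpochSeries(participant_id, start, native_epoch_s, counts,
                       truth=truth)


def simulate_week(participant_id: str, weekday_mvpa: float,
                  weekday_sed: float, compliant: bool,
                  rng: np.random.Generator,
                  cut: CutPoints | None = None,
                  native_epoch_s: int = 10,
                  start_date: str = "2018-11-05",
                  weekend_factor: float = 0.8,
                  day_noise_sd: float = 3.0) -> EpochSeries:
    """One participant's 7-day count stream realizing target weekday minutes.

    Compliant wearers wear 06:30-22:30 every day (960 min, all valid);
    non-compliant wearers wear 10:00-17:00 (420 min < the 500-min rule, so no
    valid days and the participant is excluded downstream). The week starts
    on a Monday; weekend activity is scaled by ``weekend_factor``.
    """
    cut = cut or CutPoints.youth_cpm(epoch_s=10)
    per_min = 60 // native_epoch_s
    wear = (390, 1350) if compliant else (600, 1020)
    wear_min = wear[1] - wear[0]
    day_label_list = []
    for d in range(7):
        weekend = d >= 5
        factor = weekend_factor if weekend else 1.0
        mvpa = int(np.clip(round(factor * weekday_mvpa
                                 + rng.normal(0, day_noise_sd)), 0, wear_min))
        sed = int(np.clip(round(factor * weekday_sed
                                + rng.normal(0, 2 * day_noise_sd)),
                          0, wear_min - mvpa))
        light = wear_min - mvpa - sed
        lab = np.array(["sedentary"] * sed + ["light"] * light
                       + ["mvpa"] * mvpa, dtype=object)
        lab = lab[rng.permutation(wear_min)]
        day = np.full(1440, "nonwear", dtype=object)
        day[wear[0]:wear[1]] = lab
        day_label_list.append(day)
    labels = np.repeat(np.concatenate(day_label_list), per_min)
    counts = np.zeros(len(labels), dtype=int)
    for label in ("sedentary", "light", "mvpa"):
        sel = labels == label
        if sel.any():
            lo, hi = _count_band(label, cut, native_epoch_s)
            counts[sel] = rng.integers(lo, hi + 1, size=int(sel.sum()))
    start = pd.date_range(start=start_date, periods=len(labels),
                          freq=f"{native_epoch_s}s")
    return EpochSeries(participant_id, start, native_epoch_s, counts,
                       truth=labels)
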