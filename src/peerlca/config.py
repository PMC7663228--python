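"""Study configuration: indicator layout, simulation parameters, validation.

The default configuration encodes the study conditions of the cohort the
package emulates: ~1,558 Year-9 girls in 20 schools (sizes 31-142), a
five-class population with mixing (0.19, 0.18, 0.28, 0.23, 0.12), eight
continuous indicators (five psychosocial scores on [0,1]; weekday MVPA,
sedentary and screen minutes) with a single MVPA-sedentary covariance shared
across classes, four binary indicators (high amotivation and three peer-norm
flags), low questionnaire missingness (2-4%) and ~8% accelerometry
missingness, and peer-nomination ballots of up to five names for each of
four questions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

# Canonical indicator layout: 8 continuous then 4 binary columns.
CONTINUOUS_COLUMNS = (
    "self_esteem",
    "self_efficacy",
    "autonomous",
    "controlled",
    "peer_support",
    "mvpa",
    "sedentary",
    "screen",
)
BINARY_COLUMNS = (
    "amotivation_hi",
    "norm_prevalence_hi",
    "norm_importance_hi",
    "norm_acceptance_hi",
)
ALL_COLUMNS = CONTINUOUS_COLUMNS + BINARY_COLUMNS

# Index of the jointly-modelled pair within the continuous block.
MVPA_INDEX = CONTINUOUS_COLUMNS.index("mvpa")
SEDENTARY_INDEX = CONTINUOUS_COLUMNS.index("sedentary")

# Declared ranges used for the affine rescaling of continuous indicators to
# [0,1]. Psychosocial scores are generated on the unit interval already;
# activity minutes use fixed physiological maxima so the transform is
# data-independent.
DECLARED_RANGES = {
    "self_esteem": (0.0, 1.0),
    "self_efficacy": (0.0, 1.0),
    "autonomous": (0.0, 1.0),
    "controlled": (0.0, 1.0),
    "peer_support": (0.0, 1.0),
    "mvpa": (0.0, 300.0),
    "sedentary": (0.0, 1080.0),
    "screen": (0.0, 960.0),
}

NOMINATION_QUESTIONS = ("respect", "leader", "trust", "lookup")

# 20 school sizes within [31, 142] summing to 1558 (the default cohort size).
DEFAULT_SCHOOL_SIZES = (
    31, 142, 47, 121, 58, 104, 66, 96, 73, 89,
    52, 110, 61, 83, 70, 92, 38, 128, 44, 53,
)


@dataclass
class NominationModel:
    """How nomination ballots are generated for a synthetic cohort."""

    max_names_per_question: int = 5
    n_questions: int = 4
    # Relative nomination attractiveness per latent class (length K).
    class_propensity: tuple = (2.2, 1.35, 1.0, 0.7, 0.5)
    # SD of individual log-attractiveness within class: popularity varies a
    # lot between pupils of the same profile, which keeps supporter selection
    # class-skewed but far from deterministic.
    individual_log_sd: float = 1.0
    within_school_only: bool = True
    # Fraction of nominee slots replaced by an out-of-roster name / a pupil
    # from another school, to exercise ballot cleaning.
    out_of_roster_rate: float = 0.02
    cross_school_rate: float = 0.01
    # Anonymous nominators who are not themselves study participants.
    n_nonconsenting_nominators: int = 54

    def validate(self) -> None:
        if self.max_names_per_question < 1:
            raise ValueError("max_names_per_question must be >= 1")
        if self.n_questions < 1:
            raise ValueError("n_questions must be >= 1")
        prop = np.asarray(self.class_propensity, dtype=float)
        if (prop < 0).any() or prop.sum() <= 0:
            raise ValueError("class propensities must be >= 0 and not all zero")
        for name in ("out_of_roster_rate", "cross_school_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        if self.individual_log_sd < 0:
            raise ValueError("individual_log_sd must be >= 0")


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic cohort generator."""

    n_schools: int
    school_sizes: tuple
    n_classes: int
    mixing: tuple
    class_means: tuple          # K x 8, columns in CONTINUOUS_COLUMNS order
    class_sds: tuple            # K x 8
    shared_mvpa_sed_cov: float  # min^2, common to all classes
    binary_probs: tuple         # K x 4, columns in BINARY_COLUMNS order
    missing_rates: dict = field(default_factory=dict)   # column -> rate
    nomination: NominationModel = field(default_factory=NominationModel)
    seed: int = 0
    # Demographic passenger covariates (class-linked contrasts only).
    fas_probs: tuple = (0.833, 0.800, 0.755, 0.720, 0.678)  # Binomial(9, p)
    fsm_probs: tuple = (0.05, 0.08, 0.10, 0.15, 0.21)
    nonwhite_rate: float = 0.11
    # Fraction of participants whose accelerometer wear yields <2 valid days.
    accel_noncompliance_rate: float = 0.08

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        k = self.n_classes
        mix = np.asarray(self.mixing, dtype=float)
        if mix.shape != (k,):
            raise ValueError("mixing must have length n_classes")
        if abs(mix.sum() - 1.0) > 1e-12:
            raise ValueError("mixing must sum to 1 within 1e-12")
        if (mix < 0).any() or (mix > 1).any():
            raise ValueError("mixing entries must be probabilities")
        means = np.asarray(self.class_means, dtype=float)
        sds = np.asarray(self.class_sds, dtype=float)
        if means.shape != (k, 8) or sds.shape != (k, 8):
            raise ValueError("class_means/class_sds must be K x 8")
        if (sds <= 0).any():
            raise ValueError("class_sds must be positive")
        probs = np.asarray(self.binary_probs, dtype=float)
        if probs.shape != (k, 4):
            raise ValueError("binary_probs must be K x 4")
        if (probs < 0).any() or (probs > 1).any():
            raise ValueError("binary_probs must be in [0,1]")
        sizes = np.asarray(self.school_sizes, dtype=int)
        if len(sizes) != self.n_schools:
            raise ValueError("school_sizes must have length n_schools")
        if (sizes < 2).any():
            raise ValueError("school_sizes must all be >= 2")
        c = float(self.shared_mvpa_sed_cov)
        for kk in range(k):
            v1 = sds[kk, MVPA_INDEX] ** 2
            v2 = sds[kk, SEDENTARY_INDEX] ** 2
            if c * c >= v1 * v2:
                raise ValueError(
                    f"MVPA/sedentary covariance block for class {kk} is not "
                    f"positive definite (c={c}, var_mvpa={v1}, var_sed={v2})"
                )
        for col, rate in self.missing_rates.items():
            if col not in ALL_COLUMNS:
                raise ValueError(f"missing rate for unknown column {col!r}")
            if not 0 <= rate <= 1:
                raise ValueError(f"missing rate for {col!r} must be in [0,1]")
        if not 0 <= self.accel_noncompliance_rate <= 1:
            raise ValueError("accel_noncompliance_rate must be in [0,1]")
        self.nomination.validate()
        if len(np.asarray(self.nomination.class_propensity)) != k:
            raise ValueError("nomination.class_propensity must have length K")

    @property
    def n_participants(self) -> int:
        return int(np.sum(self.school_sizes))

    # -- (de)serialization ---------------------------------------------
    def to_dict(self) -> dict:
        return _pythonize(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        nom = d.get("nomination", {})
        if isinstance(nom, dict):
            nom = {k: tuple(v) if isinstance(v, list) else v for k, v in nom.items()}
            d["nomination"] = NominationModel(**nom)
        for key in ("school_sizes", "mixing", "fas_probs", "fsm_probs"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        for key in ("class_means", "class_sds", "binary_probs"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(tuple(row) for row in d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _pythonize(obj):
    """Recursively coerce numpy scalars/containers to plain Python types."""
    if isinstance(obj, dict):
        return {k: _pythonize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pythonize(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return _pythonize(obj.tolist())
    return obj


def _centre(offsets: Sequence[float], mixing: Sequence[float]) -> np.ndarray:
    """Shift class offsets so their mixing-weighted mean is exactly zero."""
    off = np.asarray(offsets, dtype=float)
    w = np.asarray(mixing, dtype=float)
    return off - float(w @ off)


def default_config(seed: int = 0) -> SimulationConfig:
    """The default five-class study configuration.

    Class means are chosen so mixing-weighted marginal means reproduce the
    whole-sample descriptive table (self-esteem 0.67, self-efficacy 0.69,
    autonomous 0.62, controlled 0.33, peer support 0.48, MVPA 51 min,
    sedentary 591 min, screen 390 min). Within-class SDs for bounded scores
    are capped so boundary clipping stays rare; the class ordering follows
    the narrative gradient from an autonomous/confident class (19%) down to
    an amotivated/low-confidence class (12%).
    """
    mixing = (0.19, 0.18, 0.28, 0.23, 0.12)
    targets = {  # marginal means from the descriptive table
        "self_esteem": 0.67, "self_efficacy": 0.69, "autonomous": 0.62,
        "controlled": 0.33, "peer_support": 0.48,
        "mvpa": 51.0, "sedentary": 591.0, "screen": 390.0,
    }
    # Narrative class offsets around the marginal mean (C1..C5).
    offsets = {
        "self_esteem": (0.150, 0.110, 0.000, -0.110, -0.200),
        "self_efficacy": (0.150, 0.110, 0.000, -0.110, -0.210),
        "autonomous": (0.220, 0.100, -0.020, -0.130, -0.320),
        "controlled": (-0.050, -0.150, 0.120, 0.100, -0.170),
        "peer_support": (0.120, -0.020, 0.040, -0.080, -0.180),
        "mvpa": (7.0, 4.0, 1.0, -5.0, -10.0),
        "sedentary": (-16.0, -6.0, -1.0, 9.0, 14.0),
        "screen": (-105.0, -60.0, -15.0, 80.0, 170.0),
    }
    sds = {
        "self_esteem": (0.075, 0.090, 0.120, 0.120, 0.120),
        "self_efficacy": (0.065, 0.080, 0.120, 0.120, 0.120),
        "autonomous": (0.060, 0.100, 0.130, 0.130, 0.120),
        "controlled": (0.100, 0.070, 0.140, 0.130, 0.100),
        "peer_support": (0.120, 0.110, 0.130, 0.110, 0.100),
        "mvpa": (19.0, 19.0, 19.0, 18.0, 17.0),
        "sedentary": (90.0, 90.0, 92.0, 92.0, 90.0),
        "screen": (160.0, 180.0, 205.0, 215.0, 220.0),
    }
    class_means = []
    class_sds = []
    for col in CONTINUOUS_COLUMNS:
        mu = targets[col] + _centre(offsets[col], mixing)
        class_means.append(mu)
        class_sds.append(np.asarray(sds[col], dtype=float))
    class_means = tuple(map(tuple, np.array(class_means).T))  # -> K x 8
    class_sds = tuple(map(tuple, np.array(class_sds).T))

    binary_probs = (
        # amot_hi, prev_hi, imp_hi, acc_hi
        (0.05, 0.85, 0.80, 0.75),
        (0.15, 0.45, 0.40, 0.40),
        (0.35, 0.70, 0.65, 0.55),
        (0.60, 0.35, 0.30, 0.30),
        (0.95, 0.15, 0.12, 0.12),
    )
    missing_rates = {
        "self_esteem": 0.02, "self_efficacy": 0.02, "autonomous": 0.02,
        "controlled": 0.02, "peer_support": 0.02, "screen": 0.03,
        "mvpa": 0.08, "sedentary": 0.08,
        "amotivation_hi": 0.02, "norm_prevalence_hi": 0.02,
        "norm_importance_hi": 0.02, "norm_acceptance_hi": 0.02,
    }
    cfg = SimulationConfig(
        n_schools=len(DEFAULT_SCHOOL_SIZES),
        school_sizes=DEFAULT_SCHOOL_SIZES,
        n_classes=5,
        mixing=mixing,
        class_means=class_means,
        class_sds=class_sds,
        shared_mvpa_sed_cov=-600.0,
        binary_probs=binary_probs,
        missing_rates=missing_rates,
        nomination=NominationModel(),
        seed=seed,
    )
    cfg.validate()
    return cfg


def save_config(cfg: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        return SimulationConfig.from_dict(yaml.safe_load(fh))
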