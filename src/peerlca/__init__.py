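"""Latent class profiling of school cohorts and peer-nominated supporters.

A reusable pipeline from synthetic school cohorts (questionnaires,
accelerometer counts, peer-nomination ballots) through indicator
construction and peer-supporter identification to mixed-indicator latent
class models (EM with full-information missing data), class enumeration
(BIC, entropy, LMR, bootstrap LRT) and BCH-corrected class-specific
supporter proportions with school-clustered bootstrap intervals.
"""

__version__ = "0.1.0"

from .config import SimulationConfig, NominationModel, default_config
from .preprocessing import IndicatorMatrix, build_indicator_matrix
from .lca import ModelSpec, LcaParameters, FitResult, fit, count_parameters
from .selection import bic, relative_entropy, smallest_class, blrt, lmr_test, select_classes
from .bch import classification_error_matrix, bch_weights, class_outcome_proportions
from .pipeline import PipelineConfig, run_pipeline

__all__ = [
    "SimulationConfig", "NominationModel", "default_config",
    "IndicatorMatrix", "build_indicator_matrix",
    "ModelSpec", "LcaParameters", "FitResult", "fit", "count_parameters",
    "bic", "relative_entropy", "smallest_class", "blrt", "lmr_test",
    "select_classes",
    "classification_error_matrix", "bch_weights", "class_outcome_proportions",
    "PipelineConfig", "run_pipeline",
]
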