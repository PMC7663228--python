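"""Shared configuration for the numbered analysis drivers.

All drivers operate on one artifact directory (results/analysis) with one
root seed, so each can be run in order (01, 02, ...) or re-run individually
once its inputs exist.
"""

from pathlib import Path

from peerlca.pipeline import PipelineConfig

SEED = 1
OUT_DIR = Path(__file__).resolve().parent.parent / "results" / "analysis"


def analysis_config() -> PipelineConfig:
    return PipelineConfig(
        seed=SEED,
        out_dir=str(OUT_DIR),
        fit_k=5,
        fit_n_starts=12,
        select_kmin=2,
        select_kmax=8,
        select_n_starts=8,
        select_blrt_reps=0,   # pass --blrt to 05_select_model.py to enable
        bch_n_boot=500,
    )
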