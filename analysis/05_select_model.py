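#!/usr/bin/env python
"""Fit the 5-class model and build the 2-8 class enumeration table
(BIC, relative entropy, smallest class, LMR; BLRT with --blrt)."""

import sys

import pandas as pd

from _common import OUT_DIR, analysis_config
from peerlca.pipeline import run_pipeline

cfg = analysis_config()
if "--blrt" in sys.argv:
    cfg.select_blrt_reps = 49
run_pipeline(cfg, stages=["fit", "select"])

table = pd.read_csv(OUT_DIR / "selection.csv")
cols = ["n_classes", "log_likelihood", "bic", "relative_entropy",
        "smallest_class_share", "lmr_p", "blrt_p", "converged", "min_bic"]
print(table[cols].round(3).to_string(index=False))
best = table.loc[table["min_bic"], "n_classes"]
print(f"\nmin-BIC model: {int(best.iloc[0])} classes"
      if len(best) else "\nno converged fit")
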