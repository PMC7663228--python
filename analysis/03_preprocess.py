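#!/usr/bin/env python
"""Assemble the n x 12 analysis matrix: rescaled continuous indicators plus
the four binary indicators, with the missingness mask."""

import pandas as pd

from _common import OUT_DIR, analysis_config
from peerlca.pipeline import run_pipeline

run_pipeline(analysis_config(), stages=["preprocess"])
ind = pd.read_csv(OUT_DIR / "indicators.csv")
obs = ind[[c for c in ind.columns if c.endswith("_observed")]]

print(f"indicator matrix: {len(ind)} x 12")
print("observed fraction per indicator:")
print((obs.mean().round(3)).to_string())
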