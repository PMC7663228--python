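#!/usr/bin/env python
"""Simulate 7-day count streams per participant and reduce them to weekday
MVPA/sedentary summaries with the valid-day and non-wear rules."""

import pandas as pd

from _common import OUT_DIR, analysis_config
from peerlca.pipeline import run_pipeline

run_pipeline(analysis_config(), stages=["accel"])
pa = pd.read_csv(OUT_DIR / "pa_summary.csv")

print(f"{pa['included'].mean():.1%} of participants provided >=2 valid days")
print(f"weekday MVPA mean {pa['weekday_mvpa_min'].mean():.1f} min "
      f"(SD {pa['weekday_mvpa_min'].std():.1f})")
print(f"weekday sedentary mean {pa['weekday_sed_min'].mean():.0f} min")
print(f"{pa['meets_guideline'].mean():.1%} meet the 60 min/day guideline")
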