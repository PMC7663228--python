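#!/usr/bin/env python
"""Generate the synthetic study cohort, questionnaire missingness and
nomination ballots (20 schools, 1558 girls, 5 latent classes)."""

import pandas as pd

from _common import OUT_DIR, analysis_config
from peerlca.pipeline import run_pipeline

manifest = run_pipeline(analysis_config(), stages=["simulate"])
cohort = pd.read_csv(OUT_DIR / "cohort_complete.csv")
ballots = pd.read_csv(OUT_DIR / "ballots.csv")

print(f"cohort: {len(cohort)} girls in {cohort['school_id'].nunique()} schools")
print("class prevalences:",
      cohort["true_class"].value_counts(normalize=True).sort_index()
      .round(3).to_dict())
print(f"ballots: {len(ballots)} nominations from "
      f"{ballots['nominator_id'].nunique()} nominators")
print(f"artifacts in {OUT_DIR}")
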