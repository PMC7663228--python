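#!/usr/bin/env python
"""Clean ballots, tally one-vote-per-nominator counts and identify peer
supporters with the per-school top-18% cutoff."""

import pandas as pd

from _common import OUT_DIR, analysis_config
from peerlca.pipeline import run_pipeline

run_pipeline(analysis_config(), stages=["nominate"])
tally = pd.read_csv(OUT_DIR / "tally.csv")

print(f"supporters: {tally['supporter'].sum()} of {len(tally)} "
      f"({tally['supporter'].mean():.1%} of the cohort)")
print("per-school cutoffs:",
      tally.groupby('school_id')['cutoff_votes'].first().to_dict())
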