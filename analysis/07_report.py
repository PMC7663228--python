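#!/usr/bin/env python
"""Descriptive surfaces: cohort summary, centred class profiles, class
distributions overall vs among supporters, per-school breakdowns."""

import json

import pandas as pd

from _common import OUT_DIR, analysis_config
from peerlca.pipeline import run_pipeline

run_pipeline(analysis_config(), stages=["report"])

report = json.loads((OUT_DIR / "report.json").read_text())
dist = report["class_distribution"]
print("class shares overall:     ",
      [round(x, 3) for x in dist["overall_share"]])
print("class shares (supporters):",
      [round(x, 3) for x in dist["supporter_share"]])
print("within-class supporter rate:",
      [round(x, 3) for x in dist["within_class_supporter_rate"]])
print("relative entropy:", round(report["relative_entropy"], 3))
print("schools with zero supporters per class:",
      report["schools_without_supporters"])

profiles = pd.read_csv(OUT_DIR / "profile_table.csv")
wide = profiles.pivot(index="indicator", columns="class", values="centered")
print("\ncentred class profiles (class mean - overall mean):")
print(wide.round(3).to_string())
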