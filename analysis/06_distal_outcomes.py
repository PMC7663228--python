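#!/usr/bin/env python
"""BCH classification-error-corrected supporter proportions per class with
school-clustered bootstrap intervals."""

import json

from _common import OUT_DIR, analysis_config
from peerlca.pipeline import run_pipeline

run_pipeline(analysis_config(), stages=["bch"])
distal = json.loads((OUT_DIR / "distal.json").read_text())

print("class  supporter proportion  95% CI")
for e in distal["estimates"]:
    flags = " (unstable)" if e["unstable"] else ""
    print(f"  {e['class_index'] + 1}      {e['proportion']:.3f}       "
          f"[{e['lower']:.3f}, {e['upper']:.3f}]{flags}")
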