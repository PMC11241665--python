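#!/usr/bin/env python
"""Full pipeline run: every protocol, both cohorts, figures and manifest.

Equivalent to `ipsckit run --seed 1 --out results/full_run`; collects all
stage outputs, applies the normality-gated group comparisons and writes the
result bundle (tables, comparison JSON, figures, reproducibility manifest).
Run from the repository root:  python analysis/05_group_statistics.py
"""
import os

from ipsckit import pipeline

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "full_run")

cfg = pipeline.RunConfig(seed=1, out_dir=OUT)
result = pipeline.run_pipeline(cfg)

print(f"Result bundle written to {os.path.abspath(OUT)}")
print("Group comparisons (median [IQR], test, p):")
for comp in result.comparisons.values():
    print(" ", comp.summary())
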