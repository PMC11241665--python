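#!/usr/bin/env python
"""Detect spontaneous mIPSCs in both cohorts and compare frequency/kinetics.

Reproduces the spontaneous-release comparison: event frequency drops to
about 60% in the BBBd condition while the fast decay constant shortens.
Run from the repository root:  python analysis/02_mini_analysis.py
"""
import os

import pandas as pd

from ipsckit import minis, stats, synthgen

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
SEED = 1
N_CELLS = {"sham": 9, "bbbd": 8}

os.makedirs(OUT, exist_ok=True)

rows = []
for cond, n_cells in N_CELLS.items():
    params = synthgen.preset(cond)
    cfg = minis.DetectionConfig(kinetics=params.kernel)
    for i, ss in enumerate(synthgen.cell_seeds(SEED, n_cells, stream=0)):
        trace, _ = synthgen.simulate_minis(params, 100.0, 0.1, seed=ss)
        trace.cell_id, trace.condition = f"{cond}_{i:02d}", cond
        events = minis.detect_minis(trace, cfg)
        summ = minis.summarize_cell(trace, events)
        rows.append({
            "condition": cond, "cell": trace.cell_id,
            "frequency_hz": summ.frequency, "n_events": summ.n_events,
            "amplitude_pa": summ.median_amplitude,
            "rise_20_80_ms": summ.median_rise_time,
            "tau1_ms": summ.tau1, "tau2_ms": summ.tau2, "a1": summ.a1,
        })

cells = pd.DataFrame(rows)
cells.to_csv(os.path.join(OUT, "mini_cell_summaries.tsv"), sep="\t",
             index=False)

print("Per-cell spontaneous-event summaries "
      f"({len(cells)} cells) -> mini_cell_summaries.tsv")
for metric in ("frequency_hz", "tau1_ms", "amplitude_pa", "rise_20_80_ms"):
    a = cells.loc[cells.condition == "sham", metric].to_numpy(float)
    b = cells.loc[cells.condition == "bbbd", metric].to_numpy(float)
    comp = stats.compare_groups(metric, a, b)
    print(" ", comp.summary())
print("note: cohort cells share one parameter set, so between-cell spread is"
      " sampling noise only; tiny kernel-driven amplitude/rise differences"
      " reach significance here that real cohort variance would swamp"
      " (see docs/methods.md).")
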