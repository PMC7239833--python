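#!/usr/bin/env python
"""Simulate a training cohort on the conflict task and titrate foot shock.

Six synthetic rats run five sessions each.  Between sessions the shock
intensity follows the titration policy (start 0.35 mA, hold at >= 20/30
stimulus successes, step 0.05 mA otherwise).  Writes per-session
summaries and the intensity trajectory to results/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from conflictpipe.synth import AgentParams, simulate_agent_session
from conflictpipe.task import (
    SessionConfig, classify_session, summarize, titrate_intensity,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

rng = np.random.default_rng(2020)
rows = []
for animal in range(6):
    intensity = 0.35
    for session in range(5):
        seed = int(rng.integers(2**31 - 1))
        cfg = SessionConfig(shock_intensity=intensity, rng_seed=seed)
        agent = AgentParams()  # logistic sensitivity: waits more as shocks harden
        events, _, sched = simulate_agent_session(cfg, agent, seed)
        summary = summarize(classify_session(events, sched, cfg))
        rows.append({"animal": animal, "session": session,
                     "intensity_ma": intensity, **{
                         k: v for k, v in summary.to_dict().items()
                         if not isinstance(v, dict)}})
        intensity = titrate_intensity(intensity, summary)

table = pd.DataFrame(rows)
table.to_csv(OUT / "behavior_training.csv", index=False)

final = table[table["session"] == 4]
print(f"wrote {OUT/'behavior_training.csv'} ({len(table)} sessions)")
print(f"final intensities (mA): {sorted(final['intensity_ma'].round(2))}")
print(f"final shock index: mean {final['shock_index'].mean():.1f}%, "
      f"range {final['shock_index'].min():.1f}-{final['shock_index'].max():.1f}%")
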