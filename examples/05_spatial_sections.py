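"""Spot-level signature enrichment on simulated brain sections.

Control sections contain only background tissue; disease sections hide
5% infiltrate spots whose expression is a 50/50 mixture of background
and the homing-cell profile. Spots are scored with the same AUC-ratio
statistic as cells and pseudobulks, and enrichment is called above the
99.9th percentile of the control-section ratio distribution."""

import dataclasses

import pandas as pd

from homingtrack import (
    SpatialConfig,
    control_percentile_cutoff,
    score_spots,
    simulate_spots,
    spatial_map,
    threshold_spots,
)
from homingtrack.simdata import make_section_profiles

genes = pd.Index([f"G{i:04d}" for i in range(1000)])
background, t09, sig = make_section_profiles(genes, seed=1)
cfg = SpatialConfig()

frames, truth_ids = [], set()
for i in range(3):
    spots, _ = simulate_spots(800, 0, 0.0, t09, background, seed=10 + i,
                              section=f"ctrl{i}", condition="control")
    frames.append(score_spots(spots, sig, cfg, seed=1))
spots, truth = simulate_spots(800, 40, 0.5, t09, background, seed=20,
                              section="ms0", condition="disease")
frames.append(score_spots(spots, sig, cfg, seed=1))
truth_ids = set(truth.infiltrate_fraction[truth.infiltrate_fraction > 0].index)

scores = pd.concat(frames)
cutoff = control_percentile_cutoff(scores, ["ctrl0", "ctrl1", "ctrl2"], q=0.999)
cfg_cut = dataclasses.replace(cfg, cutoff=cutoff)
enriched, summary = threshold_spots(scores, cfg_cut)
print(f"data-driven cutoff (99.9th pct of control ratios): {cutoff:.2f}")
print(summary.to_string(index=False))

called = {s for s in enriched if s.startswith("ms0")}
tp = len(called & truth_ids)
print(f"\nrecall {tp / len(truth_ids):.2f}, precision {tp / max(len(called), 1):.2f}")
m = spatial_map(scores, cfg_cut)
print(f"map table: {len(m)} rows, columns {list(m.columns)}")
# control sections stay at ~0.1% enriched spots by construction; the
# disease section lights up at its infiltrate spots.
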