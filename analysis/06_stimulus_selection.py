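#!/usr/bin/env python
"""Stimulus pre-screen on a synthetic candidate set.

Simulates 50 grayscale candidate renders per class (class-specific
template blob + pixel noise; no real stimulus renders are shipped),
scores every candidate by its mean pixelwise Pearson correlation with
the other class, keeps the 30 least cross-correlated per class, and runs
the size / black-area confound check on the selection. Writes
results/stimulus_selection.csv and .json.
"""

import json
from pathlib import Path

from pecktrack.stimuli import select_stimuli, synthetic_stimulus_set

ROOT = Path(__file__).resolve().parent.parent / "results"

class_a, class_b = synthetic_stimulus_set(n_per_class=50, seed=60)
report = select_stimuli(class_a, class_b, n_select=30)

report.scores.to_csv(ROOT / "stimulus_selection.csv", index=False)
payload = {
    "selected_X": list(report.selected_a),
    "selected_Y": list(report.selected_b),
    "confound": {
        "t_object": report.confound.t_object,
        "p_object": report.confound.p_object,
        "t_black": report.confound.t_black,
        "p_black": report.confound.p_black,
        "black_threshold": report.confound.black_threshold,
    },
}
(ROOT / "stimulus_selection.json").write_text(json.dumps(payload, indent=2))

sel = report.scores.query("selected")
print(
    f"selected {len(report.selected_a)}/{len(class_a)} class-X and "
    f"{len(report.selected_b)}/{len(class_b)} class-Y candidates"
)
print(
    "mean cross-class correlation of the selected set: "
    f"{sel['mean_cross_correlation'].mean():.3f} "
    f"(rejected: {report.scores.query('~selected')['mean_cross_correlation'].mean():.3f})"
)
c = payload["confound"]
print(
    f"confound check: object size t = {c['t_object']:.2f} (p = {c['p_object']:.3f}), "
    f"black area t = {c['t_black']:.2f} (p = {c['p_black']:.3f})"
)
print(f"wrote {ROOT / 'stimulus_selection.csv'} and .json")
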