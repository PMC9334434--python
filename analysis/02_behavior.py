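#!/usr/bin/env python
"""Choice-performance battery on the simulated subjects.

Per subject: percent correct pooled and split by known/transfer trial
type and stimulus class; across subjects: a one-sample t-test of
performance against the 50% chance level of the binary choice and a
paired t-test of known vs transfer performance. Writes
results/behavior_performance.csv and prints the group tests.
"""

from pathlib import Path

import pandas as pd

from pecktrack.data import read_peck_log
from pecktrack.stats import one_sample_t, paired_t, percent_correct

ROOT = Path(__file__).resolve().parent.parent / "results"
LOGS = sorted((ROOT / "logs").glob("pecklog_*.csv"))

rows = []
for path in LOGS:
    (session,) = read_peck_log(str(path))
    for tt in (None, "known", "transfer"):
        for cls in (None, "X", "Y"):
            try:
                s = percent_correct(session.trials, trial_type=tt, stimulus_class=cls)
            except ValueError:
                continue
            rows.append(
                {
                    "subject": session.subject_id,
                    "trial_type": tt or "pooled",
                    "stimulus_class": cls or "pooled",
                    "n_trials": s.n_trials,
                    "percent_correct": round(s.percent_correct, 2),
                }
            )
perf = pd.DataFrame(rows)
perf.to_csv(ROOT / "behavior_performance.csv", index=False)

pooled = perf.query("trial_type == 'pooled' and stimulus_class == 'pooled'")
print("per-subject percent correct (pooled):")
print(pooled[["subject", "n_trials", "percent_correct"]].to_string(index=False))

# group tests across the default-archetype subjects (shared p_correct .92)
defaults = pooled[~pooled["subject"].str.contains("errorrich")]
res = one_sample_t(defaults["percent_correct"], mu0=50.0)
print(
    f"\nvs 50% chance: t({res.df}) = {res.t:.2f}, p = {res.p:.2g}, "
    f"Cohen's d = {res.cohen_d:.2f}"
)

known = perf.query("trial_type == 'known' and stimulus_class == 'pooled'")
transfer = perf.query("trial_type == 'transfer' and stimulus_class == 'pooled'")
merged = known.merge(transfer, on="subject", suffixes=("_known", "_transfer"))
res = paired_t(merged["percent_correct_known"], merged["percent_correct_transfer"])
print(
    f"known vs transfer: t({res.df}) = {res.t:.2f}, p = {res.p:.3f}, "
    f"Cohen's d = {res.cohen_d:.2f}"
)
print(f"\nwrote {ROOT / 'behavior_performance.csv'}")
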