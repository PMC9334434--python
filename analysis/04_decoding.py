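#!/usr/bin/env python
"""kNN decoding of stimulus class from peck location: CC, CE, EE.

Per subject: ten-iteration CC decoding (k = 15, 250/250 events) against
the shuffled-label null, plus CE and EE where the error pool clears the
>500-event rule, and a one-peck-per-trial CC control. Writes
results/decoding_summary.csv.
"""

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from pecktrack.data import read_peck_log, select_pool
from pecktrack.decoder import ClassifierConfig, InsufficientEventsError, run_decoding

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 30

rows = []
for path in sorted((ROOT / "logs").glob("pecklog_*.csv")):
    (session,) = read_peck_log(str(path))
    name = session.subject_id.removeprefix("sim_")
    correct = select_pool(session, outcomes={"correct"})
    error = select_pool(session, outcomes={"error"})
    config = ClassifierConfig(seed=SEED)

    # the one-peck control has only as many candidates as correct trials
    # (~370 here), so it runs at 150/150 instead of 250/250
    jobs = {
        "CC": (correct, None, config),
        "CC_one_peck_per_trial": (
            correct,
            None,
            replace(config, one_peck_per_trial=True, n_train=150, n_test=150),
        ),
        "CE": (correct, error, config),
        "EE": (error, None, config),
    }
    for label, (train, test, cfg) in jobs.items():
        mode = label.split("_")[0]
        try:
            rep = run_decoding(
                train, test, mode=mode, config=cfg, rng=np.random.default_rng(SEED)
            )
            rows.append(
                {
                    "subject": name,
                    "analysis": label,
                    "mean_accuracy": round(rep.mean_accuracy, 2),
                    "mean_shuffled": round(rep.mean_shuffled, 2),
                    "t": round(rep.t, 2),
                    "p": rep.p,
                    "cohen_d": round(rep.cohen_d, 2),
                    "verdict": rep.verdict,
                }
            )
        except InsufficientEventsError as exc:
            rows.append({"subject": name, "analysis": label, "verdict": f"skipped ({exc})"})

table = pd.DataFrame(rows)
table.to_csv(ROOT / "decoding_summary.csv", index=False)

shown = table[table["verdict"].isin(["above_chance", "below_chance", "at_chance"])]
print("decoding summary (k=15, 250/250 events, 10 iterations, alpha 0.00625):")
print(
    shown[["subject", "analysis", "mean_accuracy", "mean_shuffled", "verdict"]]
    .to_string(index=False)
)
skipped = table[~table.index.isin(shown.index)]
if len(skipped):
    print("\nskipped analyses (insufficient events):")
    for _, r in skipped.iterrows():
        print(f"  {r['subject']:22s} {r['analysis']}")
print(f"\nwrote {ROOT / 'decoding_summary.csv'}")
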