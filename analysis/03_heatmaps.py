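#!/usr/bin/env python
"""Spatial analysis: heatmaps, difference maps, and correct-vs-error KS.

Per subject: 15x15 relative heatmaps for correct pecks by class (CSV +
PNG), the class X - Y difference map, and the KS comparison of
correct- vs error-trial peck-concentration curves at the adjusted alpha
0.05/8. Writes per-subject matrices under results/heatmaps/ and a
summary table results/ks_correct_vs_error.csv.
"""

from pathlib import Path

import pandas as pd

from pecktrack.data import read_peck_log, select_pool
from pecktrack.heatmap import (
    bin_pecks,
    compare_correct_error,
    difference_map,
    relative_heatmap,
)
from pecktrack.pipeline import export_heatmap_csv, render_heatmap

ROOT = Path(__file__).resolve().parent.parent / "results"
HM = ROOT / "heatmaps"
HM.mkdir(parents=True, exist_ok=True)

rows = []
for path in sorted((ROOT / "logs").glob("pecklog_*.csv")):
    (session,) = read_peck_log(str(path))
    name = session.subject_id.removeprefix("sim_")
    geometry = session.geometry

    grids = {}
    for cls in ("X", "Y"):
        pool = select_pool(session, outcomes={"correct"}, classes={cls})
        grids[cls] = relative_heatmap(bin_pecks(pool, geometry), geometry)
        export_heatmap_csv(grids[cls].values, HM / f"{name}_correct_{cls}.csv")
        render_heatmap(
            grids[cls].values, HM / f"{name}_correct_{cls}.png", f"{name} correct/{cls}"
        )
    diff = difference_map(grids["X"], grids["Y"])
    export_heatmap_csv(diff, HM / f"{name}_diff_X_minus_Y.csv")

    pool_c = select_pool(session, outcomes={"correct"})
    pool_e = select_pool(session, outcomes={"error"})
    ks = compare_correct_error(pool_c, pool_e, geometry)
    rows.append(
        {
            "subject": name,
            "n_correct_pecks": len(pool_c),
            "n_error_pecks": len(pool_e),
            "D": round(ks.D, 4),
            "p": ks.p,
            "significant_at_0.00625": ks.significant,
        }
    )

table = pd.DataFrame(rows)
table.to_csv(ROOT / "ks_correct_vs_error.csv", index=False)
print("correct-vs-error concentration (curve-based two-sample KS):")
print(table.to_string(index=False))
print(
    "\nNote: D compares cumulative concentration profiles over ranked"
    " squares; archetypes whose errors mirror correct pecking"
    " (lapse, confusion at matched spread) give small D, dispersed or"
    " uniform error models give large D."
)
print(f"wrote {ROOT / 'ks_correct_vs_error.csv'} and per-subject maps in {HM}/")
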