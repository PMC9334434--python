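#!/usr/bin/env python
"""Generate the strategy-archetype peck logs.

Writes one CSV peck log per archetype under results/logs/, plus an
error-rich confusion subject (p_correct 0.70 over 600 trials, so the
error pool clears the >500-event rule for CE/EE decoding). Defaults per
subject: 400 trials, ~8 pecks per trial, 92% correct.
"""

from pathlib import Path

from pecktrack.data import write_peck_log
from pecktrack.pipeline import cmd_simulate
from pecktrack.simulate import ARCHETYPES, GeneratorConfig, generate_session, make_archetype

OUT = Path(__file__).resolve().parent.parent / "results" / "logs"
SEED = 20

paths = cmd_simulate(OUT, tuple(ARCHETYPES), seed=SEED)

rich = generate_session(
    make_archetype("confusion", p_correct=0.70, n_trials=600),
    GeneratorConfig(seed=SEED * 1000 + 99),
    subject_id="sim_confusion_errorrich",
    session_id=f"seed{SEED * 1000 + 99}",
)
rich_path = OUT / "pecklog_confusion_errorrich.csv"
write_peck_log([rich], str(rich_path))
paths["confusion_errorrich"] = rich_path

print("wrote peck logs:")
for name, path in sorted(paths.items()):
    n_rows = sum(1 for _ in open(path)) - 1
    print(f"  {name:22s} {n_rows:6d} pecks  {path.name}")
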