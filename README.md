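# pecktrack

Peck-tracking analytics for touchscreen categorization experiments.

When pigeons (or other animals) categorize visual stimuli on a touchscreen,
they must peck the stimulus several times before reporting their choice.
The x/y location of every stimulus-directed peck is a continuous readout of
where the animal's attention lands — and of *how* it solved the category
problem. `pecktrack` turns per-peck logs (one CSV row per peck, nested in
trials with class, choice and outcome metadata) into the standard analysis
battery for such data:

- **Choice performance** — percent correct by trial type and class, with
  one-sample t-tests against the 50 % chance level of the binary choice
  and Cohen's d = (mean − 50)/sd, and paired t-tests between conditions.
- **Spatial peck statistics** — 15 × 15 heatmaps of relative pecks,
  relPecks = (100/allPecks) · pecks/square, on the 5 × 5 cm registration
  region (each square ≈ 0.11 cm²); class difference maps; cumulative
  peck-concentration curves over ranked squares; a two-sample
  Kolmogorov–Smirnov comparison of correct- vs error-trial concentration
  at a Bonferroni-adjusted α = 0.05/8 = 0.00625.
- **kNN decoding of stimulus class from peck location** — k = 15 nearest
  neighbours on 250 train / 250 test pecking events over 10 iterations,
  against a shuffled-label chance estimate, with a dependent t-test and
  effect size per analysis. Three regimes: **CC** (train and test on
  correct trials: is pecking class-specific?), **CE** (train on correct,
  test on error trials: below chance ⇒ the animal pecked the *other*
  class's features — class confusion), and **EE** (error trials only:
  internal consistency of error pecking). CE/EE require > 500 error
  events. Controls: one-peck-per-trial sampling and decoding restricted
  to the i-th peck of each trial (i = 1..5).
- **A synthetic session generator** — strategy archetypes (`two_class`,
  `one_class`, `lateralized`, `confusion`, `lapse`, `random_error`) with
  known peck-field structure, so the whole pipeline is validated against
  ground truth without raw experimental data.
- **A stimulus pre-screen** — pixelwise Pearson correlation between
  candidate renders, keeping the 30 of 50 per class least correlated with
  the other class, plus a size/black-area confound check.

## Worked example

Simulate a subject that learned class-specific peck locations for both
stimulus classes, then decode the class from peck coordinates:

```python
import numpy as np
from pecktrack import (
    GeneratorConfig, generate_session, make_archetype,
    select_pool, run_decoding,
)

profile = make_archetype("two_class")      # centres 2 cm apart, sd 0.4 cm
session = generate_session(profile, GeneratorConfig(seed=42))
pool = select_pool(session, outcomes={"correct"})
report = run_decoding(pool, mode="CC", rng=np.random.default_rng(42))
print(f"CC accuracy {report.mean_accuracy:.2f}% "
      f"(shuffled {report.mean_shuffled:.2f}%), "
      f"t({report.df}) = {report.t:.2f}, p = {report.p:.2g} -> {report.verdict}")
```

```
CC accuracy 92.52% (shuffled 49.52%), t(9) = 24.26, p = 1.6e-09 -> above_chance
```

The decoder reads the class from peck location far above the shuffled-label
chance estimate (~50 %): this simulated subject pecked class-informative
features. The same call on the `lateralized` archetype — one fixed peck
location regardless of the stimulus — returns 50.7 % and `at_chance`, even
though that subject answers 91.5 % of trials correctly: good categorization
without informative pecking.

The numbered scripts under `analysis/` run the full battery end to end and
write their tables under `results/`:

```bash
python analysis/01_simulate.py            # archetype peck logs
python analysis/02_behavior.py            # percent correct + t battery
python analysis/03_heatmaps.py            # heatmaps, difference maps, KS
python analysis/04_decoding.py            # CC/CE/EE + one-peck control
python analysis/05_peck_order.py          # accuracy by within-trial peck rank
python analysis/06_stimulus_selection.py  # pixelwise-correlation pre-screen
```

A `pecktrack` console command exposes the same stages
(`simulate`, `analyze`, `heatmap`, `classify`, `select-stimuli`);
see `pecktrack --help`.

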