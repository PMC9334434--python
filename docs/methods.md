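# Methods

## The analysis problem

In touchscreen two-alternative categorization tasks, an animal views a
stimulus, pecks (or touches) it a minimum number of times, and then reports
its category decision on a choice key. The stimulus-directed pecks are not
the response, but their x/y locations are a continuous behavioral readout of
where the animal's attention lands. `pecktrack` implements the standard
analysis battery for such per-peck logs: choice-performance statistics,
spatial peck statistics, and a decoding analysis that asks whether peck
location alone predicts the presented stimulus class.

All analyses operate on a *registration region*, the stimulus plus its
surrounding border. Defaults model a 4 × 4 cm stimulus with a 0.5 cm gray
border: a 5 × 5 cm region. Coordinates are continuous cm with the origin at
the region's bottom-left corner, x rightward, y upward. Bounds are closed on
both axes: a peck exactly on the edge is in-bounds; pecks outside the region
are discarded (and counted). Valid trials have at least five pecks; trials
with a recorded choice but fewer than five pecks are retained with a
warning, since the task apparatus itself would have aborted them. Aborted
and no-choice trials never enter any analysis.

## Spatial statistics

**Heatmaps.** The region is sectioned into `grid_n × grid_n` equal squares
(15 × 15 by default; each square covers (5/15)² ≈ 0.11 cm²). Cells are
half-open, with the top/right region edge folded into the last cell, so
every in-bounds peck lands in exactly one square. Because total peck counts
differ between subjects, heatmaps show relative pecks,

    relPecks = (100 / allPecks) · pecks per square,

which sum to 100 by construction. Class differences are shown as the
elementwise difference of two relative heatmaps (entries in [−100, 100],
summing to 0).

**Concentration curves and the KS comparison.** Squares are ranked by
descending peck count (ties broken by row-major cell index, which cannot
change the curve's values) and the cumulative share of pecks is accumulated
over the 225 ranks. A focused pecker saturates the curve within a few
squares; a dispersed pecker does not. Correct- versus error-trial
concentration is compared by D = max_r |C_correct(r) − C_error(r)| over
ranks, with each pool ranked by its own descending order. The p-value uses
Smirnov's asymptotic two-sample formula with effective sample size
nm/(n+m) at n = m = 225 squares (the same convention scipy's `ks_2samp`
uses in asymptotic mode, cross-checked in the tests). Two caveats are
deliberate and documented in the report output: (i) treating the 225-square
curves as the two samples is one defensible reading of a correct-vs-error
cumulative comparison, and p-values under other constructions will differ;
(ii) the ranked curve is location-blind — it measures how *concentrated*
pecking is, not *where* it is, so a subject that pecks equally tightly at
different places in correct and error trials yields D ≈ 0.

Significance uses a Bonferroni-adjusted α = 0.05/8 = 0.00625 throughout,
the family correction for a typical eight-subject cohort; both the family α
and the divisor are configurable.

## Decoding peck location (kNN, CC/CE/EE)

Each pecking event is a point (x, y) labeled with the presented class
(X or Y). Per iteration, 250 training and 250 test events are drawn without
replacement (disjointly when both come from the same pool), the test events
are labeled by majority vote of their k = 15 Euclidean-nearest training
events, and accuracy is the percentage of test events whose predicted label
matches the presented class. k = 15 follows the odd-k and k ≈ √n heuristics
at n = 250. Ten iterations with fresh samples estimate the accuracy
distribution. Chance is estimated empirically: each iteration is re-run
with class labels randomly permuted against coordinates in both the
training and the test sample (permuting only training labels is available
as an option). A dependent t-test between the ten empirical and ten
shuffled accuracies, with Cohen's d = mean(diff)/sd(diff), gives the
verdict: above-chance, below-chance (p < α on the corresponding side), or
at-chance.

Modes: **CC** trains and tests on correct-trial pecks; **CE** trains on
correct and tests on error-trial pecks; **EE** trains and tests on error
pecks. CE semantics: above chance means errors preserved the "right" peck
features (lapses); below chance means the animal pecked the *other* class's
features (class confusion); at chance means error pecking was unrelated to
the learned features. CE and EE require an error pool of more than 500
events; smaller pools are refused and recorded as "insufficient errors".

Implementation notes. The kNN is an exact all-pairs distance computation
with a stable argsort, so distance ties resolve by training-event insertion
order (ties have measure zero on continuous coordinates); it is verified in
the tests against both a brute-force loop and scikit-learn's
`KNeighborsClassifier`. Train/test samples are drawn class-balanced
whenever both classes have enough events (achieved balance is recorded in
the report), falling back to unbalanced draws otherwise; the per-class
draws are ordered by first row index rather than by label, which makes the
whole analysis exactly invariant under a global X↔Y relabeling. Events may
recur across iterations (each iteration is an independent split); within an
iteration train and test never share an event.

**One-peck-per-trial control.** Pecks within a trial are not independent.
The control reduces the pool to one uniformly chosen peck per trial before
sampling, removing within-trial dependence; with the generator's defaults
it reproduces the all-pecks accuracies to within ~1 point (driver 04 runs
it at 150/150 samples, since 400-trial sessions leave only ~370 correct
trials as candidates).

**Peck-order analysis.** CC decoding restricted to pecks with within-trial
index r = 1..5 probes how quickly attention reaches class-informative
features. Ranks with fewer than 100 events are skipped; between 100 and 500
events the train/test sizes fall to half the available events each
(minimum 50), recorded in the report.

## The synthetic generator

No raw peck data ship with the package, so validation rests on a generator
that produces sessions with the statistical structure the analyses assume,
parameterized as interpretable *strategy archetypes*:

| archetype | learned classes | error model | expected signature |
|---|---|---|---|
| `two_class` | both | dispersed | CC high, CE > 50, EE > 50 |
| `one_class` | only X | dispersed | CC intermediate |
| `lateralized` | neither (one centre) | none | CC ≈ 50 at high % correct |
| `confusion` | both | swapped | CE < 50 (class confusion) |
| `lapse` | both | none | CE high (right features, wrong choice) |
| `random_error` | both | uniform | CE ≈ EE ≈ 50 |

Per trial: class is Bernoulli(0.5); the outcome is correct with
probability `p_correct` (default 0.92, matching the high-performance regime
the analyses target) and the choice is set consistently; the peck count is
5 + Poisson(mean − 5) (default mean 8), guaranteeing validity; a fraction
0.11 of trials is flagged as transfer (novel exemplars, non-differentially
reinforced). Peck placement is an isotropic Gaussian at the learned class
centre — defaults (1.5, 2.5) and (3.5, 2.5) cm, i.e. 2 cm apart — with
sd_correct = 0.4 cm, truncated to the region by resampling (bounded at 1000
attempts, then an error). The first `orienting_pecks` pecks of every trial
(default 1) are drawn from a broad Gaussian at the display centre with
orienting_sd = 1.5 cm, chosen so orienting pecks are genuinely broad yet
mostly in-bounds; this reproduces the empirical first-peck deficit in the
peck-order analysis. Error trials substitute the archetype's error model;
`dispersed` uses sd_error = 1.2 cm (three times the correct spread — "same
features, less focused"). The unlearned class of `one_class` is pecked
uniformly over the region, whether the trial ends correct or not.

Determinism: a (profile, config) pair with a fixed seed yields an
identical session, byte-identical on disk.

**What the generator does and does not emulate.** It reproduces the
features the analyses consume: balanced classes, ≥5 in-bounds pecks per
valid trial, class-dependent unimodal 2D peck fields, outcome-dependent
peck models, orienting pecks, transfer flags. It does not model
session-by-session learning, reward schedules, stimulus-image-conditioned
peck placement within a class, temporal peck dynamics, or multimodal peck
fields. Passing recovery tests therefore show that the *pipeline* detects
the structures it claims to detect — not that real pigeons match any
archetype. Two quantitative consequences of the simplifications are worth
noting: with a 5σ centre separation the synthetic two-class CC accuracy
(~93%) sits above the ~80% band typical of real two-class learners (real
peck fields overlap more), and the one-class archetype decodes at ~84%
rather than an intermediate 60–70%, because uniform pecks are easy for a
kNN to separate from a tight cluster. The validated property is the
ordering two_class > one_class > lateralized ≈ 50%, and the CE/EE sign
structure, not absolute levels.

## Statistical conventions

One-sample t against the 50% chance level of a binary choice:
t = (mean − μ₀)/(sd/√n), d = (mean − μ₀)/sd, so t = d·√n exactly. Paired
t on differences with d = mean(diff)/sd(diff). All p-values two-sided; sd
uses ddof = 1. Zero-variance inputs are refused with a diagnostic rather
than returning infinities. Both functions are cross-checked against scipy
in the tests.

## Stimulus pre-screen

Candidate grayscale renders are scored by the mean Pearson correlation of
their flattened pixel vectors with every member of the other class; the
`n_select` lowest-scoring per class are kept (ties by id). Mean aggregation
is the default (a max option exists) — the aggregation over other-class
members is a genuine design choice. The confound check counts object
pixels (> threshold) and background black pixels (≤ threshold) per selected
stimulus, default threshold 10/255 for near-black backgrounds, and runs
between-class two-sample t-tests on both measures; a sound selection shows
no significant difference on either. The package ships only a synthetic
stimulus generator (template blobs plus pixel noise, labelled synthetic);
correlating raw renders versus binarized silhouettes is left to the user,
as both readings are defensible.

## Problem sizes and reproducibility

Default validation runs use 400-trial sessions (~3200 pecks) for CC
analyses and 600-trial sessions at p_correct = 0.70 (>500 error pecks) for
CE/EE, ten decoder iterations each — sizes at which every recovery property
is stable across seeds while the full suite runs in well under a minute.
Every stochastic component takes an explicit seed or `numpy` Generator;
`scripts/acceptance.py --seed N --out results/acceptance.json` regenerates
the headline decoding numbers from scratch for any seed.
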