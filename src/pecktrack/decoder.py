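"""k-nearest-neighbour decoding of stimulus class from peck coordinates.

The decoder asks whether peck *location* carries information about the
presented stimulus class. Pecking events (x, y, class label) are sampled
from a pool, a kNN classifier (k = 15 by default, matching the odd-k and
k ~ sqrt(n) heuristics for n = 250 training events) labels held-out test
pecks, and accuracy is the percentage of test pecks whose predicted
label matches the presented class. Each analysis runs over ten
iterations with fresh random train/test samples; chance level is
estimated by re-running each iteration with class labels randomly
permuted against coordinates in both the training and test samples, and
a dependent t-test between the empirical and shuffled iteration
accuracies gives the significance of the decoding (Bonferroni-adjusted
alpha, 0.05/8 by default).

Three train/test regimes probe different questions:

CC (correct-correct)
    train and test on correct-trial pecks — is pecking class-specific?
CE (correct-error)
    train on correct, test on error trials — above chance means errors
    keep the "right" peck features; *below* chance means the animal
    pecked the other class's features (class confusion).
EE (error-error)
    train and test on error trials — are errors internally consistent?

CE and EE require a sufficiently large error pool (> 500 events by
default); smaller pools raise :class:`InsufficientEventsError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from pecktrack.data import PeckPool
from pecktrack.heatmap import DEFAULT_ALPHA_ADJUSTED

MODES = ("CC", "CE", "EE")
VERDICTS = ("above_chance", "below_chance", "at_chance")


class InsufficientEventsError(ValueError):
    """The pool cannot supply the requested train/test sample sizes."""


@dataclass(frozen=True)
class ClassifierConfig:
    k: int = 15
    n_train: int = 250
    n_test: int = 250
    iterations: int = 10
    min_error_events: int = 500
    one_peck_per_trial: bool = False
    seed: int = 0
    alpha_adjusted: float = DEFAULT_ALPHA_ADJUSTED
    #: "both" permutes labels in train and test samples; "train_only" is
    #: offered for sensitivity analyses
    shuffle_scope: str = "both"

    def __post_init__(self) -> None:
        if self.k % 2 == 0:
            raise ValueError("k must be odd (avoids vote ties on two classes)")
        if self.k > self.n_train:
            raise ValueError("k cannot exceed n_train")
        if self.iterations < 2:
            raise ValueError("need at least two iterations for the paired test")
        if self.shuffle_scope not in ("both", "train_only"):
            raise ValueError("shuffle_scope must be 'both' or 'train_only'")


@dataclass(frozen=True)
class IterationResult:
    accuracy_empirical: float
    accuracy_shuffled: float


@dataclass(frozen=True)
class DecoderReport:
    mode: str
    iterations: tuple[IterationResult, ...]
    mean_accuracy: float
    mean_shuffled: float
    t: float
    df: int
    p: float
    cohen_d: float
    verdict: str
    trial_type: Optional[str] = None
    #: achieved class-X fraction in the sampled train sets, and any
    #: reduction of the requested sample sizes
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "trial_type": self.trial_type,
            "iterations": [
                {
                    "accuracy_empirical": it.accuracy_empirical,
                    "accuracy_shuffled": it.accuracy_shuffled,
                }
                for it in self.iterations
            ],
            "mean_accuracy": self.mean_accuracy,
            "mean_shuffled": self.mean_shuffled,
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "cohen_d": self.cohen_d,
            "verdict": self.verdict,
            "notes": self.notes,
        }


def knn_predict(
    train_points: np.ndarray,
    train_labels: Sequence[str],
    test_points: np.ndarray,
    k: int,
) -> np.ndarray:
    """Label each test point by majority vote of its k nearest neighbours.

    Distances are Euclidean; distance ties are broken by training-point
    insertion order (stable sort). With odd k and binary labels there are
    no vote ties.
    """
    train_points = np.asarray(train_points, dtype=float)
    test_points = np.asarray(test_points, dtype=float)
    train_labels = np.asarray(train_labels)
    if len(train_points) < k:
        raise ValueError(
            f"need at least k={k} training points, got {len(train_points)}"
        )
    dists = cdist(test_points, train_points)
    # stable argsort keeps insertion order among tied distances
    nearest = np.argsort(dists, axis=1, kind="stable")[:, :k]
    classes = np.unique(train_labels)
    if len(classes) == 1:
        return np.full(len(test_points), classes[0])
    votes = (train_labels[nearest] == classes[1]).sum(axis=1)
    return np.where(votes * 2 > k, classes[1], classes[0])


def _one_peck_per_trial(pool: PeckPool, rng: np.random.Generator) -> PeckPool:
    """Keep one uniformly chosen peck per trial."""
    ev = pool.events
    keep = ev.groupby("trial_index", sort=True).sample(n=1, random_state=_np_seed(rng))
    return PeckPool(events=keep.reset_index(drop=True), selector=dict(pool.selector))


def _np_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def _balanced_sample(
    pool: PeckPool, n: int, rng: np.random.Generator, exclude: np.ndarray | None = None
) -> np.ndarray:
    """Sample n event row indices, class-balanced when both classes allow.

    Falls back to unbalanced sampling if either class is short. Sampling
    is without replacement and never touches rows in ``exclude``.
    """
    labels = pool.labels
    all_idx = np.arange(len(pool))
    if exclude is not None:
        mask = np.ones(len(pool), dtype=bool)
        mask[exclude] = False
        all_idx = all_idx[mask]
    if len(all_idx) < n:
        raise InsufficientEventsError(
            f"pool supplies {len(all_idx)} events, {n} requested "
            f"(shortfall {n - len(all_idx)})"
        )
    classes = np.unique(labels[all_idx])
    if len(classes) == 2:
        half = n // 2
        per_class = {c: all_idx[labels[all_idx] == c] for c in classes}
        # draw groups in order of their first row, not their label, so a
        # global X<->Y relabeling leaves the sampled rows unchanged
        ordered = sorted(classes, key=lambda c: int(per_class[c].min()))
        quota = {ordered[0]: half, ordered[1]: n - half}
        if all(len(per_class[c]) >= quota[c] for c in classes):
            picks = [
                rng.choice(per_class[c], size=quota[c], replace=False) for c in ordered
            ]
            return np.concatenate(picks)
    return rng.choice(all_idx, size=n, replace=False)


def sample_train_test(
    pool: PeckPool,
    config: ClassifierConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw disjoint train/test row-index samples from one pool.

    Sampling is without replacement, class-balanced when possible. With
    ``one_peck_per_trial`` the pool is first reduced to one uniformly
    chosen peck per trial, then sampled.
    """
    if config.one_peck_per_trial:
        pool = _one_peck_per_trial(pool, rng)
    need = config.n_train + config.n_test
    if len(pool) < need:
        raise InsufficientEventsError(
            f"pool supplies {len(pool)} events, {need} requested "
            f"(shortfall {need - len(pool)})"
        )
    train_idx = _balanced_sample(pool, config.n_train, rng)
    test_idx = _balanced_sample(pool, config.n_test, rng, exclude=train_idx)
    return pool.xy, pool.labels, train_idx, test_idx


def _accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    return 100.0 * float(np.mean(pred == truth))


def run_decoding(
    train_pool: PeckPool,
    test_pool: PeckPool | None = None,
    mode: str = "CC",
    config: ClassifierConfig | None = None,
    rng: np.random.Generator | None = None,
    trial_type: Optional[str] = None,
) -> DecoderReport:
    """Run the full iterated decoding analysis for one CC/CE/EE mode.

    ``test_pool`` defaults to ``train_pool`` (CC and EE draw disjoint
    train/test samples from the single pool; CE passes the correct pool
    as train and the error pool as test). Each iteration resamples train
    and test events, computes the empirical accuracy, then recomputes it
    after permuting labels against coordinates (the shuffled-label chance
    estimate). The report carries the dependent t-test between empirical
    and shuffled accuracies across iterations.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    config = config or ClassifierConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    same_pool = test_pool is None or test_pool is train_pool
    test_pool = train_pool if same_pool else test_pool

    if mode in ("CE", "EE"):
        error_pool = test_pool if mode == "CE" else train_pool
        if len(error_pool) < config.min_error_events:
            raise InsufficientEventsError(
                f"{mode} requires > {config.min_error_events} error events, "
                f"pool has {len(error_pool)} (insufficient errors)"
            )

    results = []
    train_balances = []
    for _ in range(config.iterations):
        if same_pool:
            xy, labels, train_idx, test_idx = sample_train_test(train_pool, config, rng)
            xtr, ltr = xy[train_idx], labels[train_idx]
            xte, lte = xy[test_idx], labels[test_idx]
        else:
            tr = train_pool
            if config.one_peck_per_trial:
                tr = _one_peck_per_trial(tr, rng)
            tr_idx = _balanced_sample(tr, config.n_train, rng)
            te = test_pool
            if config.one_peck_per_trial:
                te = _one_peck_per_trial(te, rng)
            te_idx = _balanced_sample(te, config.n_test, rng)
            xtr, ltr = tr.xy[tr_idx], tr.labels[tr_idx]
            xte, lte = te.xy[te_idx], te.labels[te_idx]
        train_balances.append(float(np.mean(ltr == "X")))

        pred = knn_predict(xtr, ltr, xte, config.k)
        acc_emp = _accuracy(pred, lte)

        ltr_sh = ltr[rng.permutation(len(ltr))]
        lte_sh = (
            lte if config.shuffle_scope == "train_only" else lte[rng.permutation(len(lte))]
        )
        pred_sh = knn_predict(xtr, ltr_sh, xte, config.k)
        acc_sh = _accuracy(pred_sh, lte_sh)
        results.append(IterationResult(accuracy_empirical=acc_emp, accuracy_shuffled=acc_sh))

    emp = np.array([r.accuracy_empirical for r in results])
    shuf = np.array([r.accuracy_shuffled for r in results])
    diff = emp - shuf
    df = config.iterations - 1
    sd = float(np.std(diff, ddof=1))
    if sd == 0.0:
        t = 0.0 if float(np.mean(diff)) == 0.0 else np.inf * np.sign(np.mean(diff))
        p = 1.0 if t == 0.0 else 0.0
        d = 0.0 if t == 0.0 else np.inf * np.sign(np.mean(diff))
    else:
        t = float(np.mean(diff) / (sd / np.sqrt(config.iterations)))
        p = float(2.0 * stats.t.sf(abs(t), df))
        d = float(np.mean(diff) / sd)

    if p < config.alpha_adjusted and emp.mean() > shuf.mean():
        verdict = "above_chance"
    elif p < config.alpha_adjusted and emp.mean() < shuf.mean():
        verdict = "below_chance"
    else:
        verdict = "at_chance"

    return DecoderReport(
        mode=mode,
        iterations=tuple(results),
        mean_accuracy=float(emp.mean()),
        mean_shuffled=float(shuf.mean()),
        t=t,
        df=df,
        p=p,
        cohen_d=d,
        verdict=verdict,
        trial_type=trial_type,
        notes={
            "train_fraction_X": float(np.mean(train_balances)),
            "n_train": config.n_train,
            "n_test": config.n_test,
        },
    )


def peck_order_decoding(
    pool: PeckPool,
    config: ClassifierConfig | None = None,
    ranks: Sequence[int] = (1, 2, 3, 4, 5),
    rng: np.random.Generator | None = None,
) -> list[tuple[int, Optional[DecoderReport], str]]:
    """CC decoding restricted to the i-th peck of each trial.

    Probes how quickly the animal's attention reaches class-informative
    features: if early pecks are orienting pecks, rank-1 accuracy falls
    below later ranks. For each rank the pool is restricted to pecks
    with that within-trial index; if fewer than the default 2 x 250
    events are available, train/test sizes are reduced to half the
    available events each (minimum 50, recorded in the report notes).
    Ranks with fewer than 100 events are skipped with a notice.
    """
    config = config or ClassifierConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    out: list[tuple[int, Optional[DecoderReport], str]] = []
    for rank in ranks:
        sub = pool.events[pool.events["peck_index"] == rank].reset_index(drop=True)
        sub_pool = PeckPool(events=sub, selector={**pool.selector, "peck_index": rank})
        n_avail = len(sub_pool)
        if n_avail < 100:
            out.append((rank, None, f"skipped: only {n_avail} events (< 100)"))
            continue
        half = n_avail // 2
        n_train = min(config.n_train, max(50, half))
        n_test = min(config.n_test, max(50, n_avail - n_train))
        cfg = replace(config, n_train=n_train, n_test=n_test, k=min(config.k, n_train | 1))
        report = run_decoding(sub_pool, mode="CC", config=cfg, rng=rng)
        note = (
            f"reduced sample sizes to {n_train}/{n_test}"
            if (n_train, n_test) != (config.n_train, config.n_test)
            else "full sample sizes"
        )
        out.append((rank, report, note))
    return out
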