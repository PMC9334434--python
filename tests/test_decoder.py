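"""kNN correctness, sampling contracts, null calibration and strategy recovery."""

import numpy as np
import pandas as pd
import pytest

from pecktrack.data import PeckPool, select_pool
from pecktrack.decoder import (
    ClassifierConfig,
    InsufficientEventsError,
    knn_predict,
    peck_order_decoding,
    run_decoding,
    sample_train_test,
)
from pecktrack.simulate import GeneratorConfig, generate_session, make_archetype


def brute_force_knn(train, labels, test, k):
    """Independent loop-based oracle for the vectorised implementation."""
    out = []
    for q in np.asarray(test, dtype=float):
        d = [float(np.hypot(*(q - t))) for t in np.asarray(train, dtype=float)]
        order = sorted(range(len(d)), key=lambda i: (d[i], i))[:k]
        vote = [labels[i] for i in order]
        out.append(max(sorted(set(vote)), key=vote.count))
    return np.array(out)


def make_pool(xy, labels, trial_index=None, peck_index=None):
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    events = pd.DataFrame(
        {
            "x": xy[:, 0],
            "y": xy[:, 1],
            "trial_index": np.arange(n) if trial_index is None else trial_index,
            "stimulus_class": labels,
            "outcome": "correct",
            "peck_index": 1 if peck_index is None else peck_index,
        }
    )
    return PeckPool(events=events, selector={})


def balanced_uniform_pool(n, rng):
    """Pool with coordinates carrying no class information."""
    xy = rng.uniform(0, 5, size=(n, 2))
    labels = np.array(["X", "Y"])[rng.integers(0, 2, size=n)]
    return make_pool(xy, labels)


class TestKnnPredict:
    def test_unanimous_training_labels(self):
        pred = knn_predict([[0, 0], [1, 1], [2, 2]], ["X", "X", "X"], [[5, 5]], k=3)
        assert list(pred) == ["X"]

    def test_small_majority_vote(self):
        train = [[0, 0], [0.1, 0], [5, 5]]
        pred = knn_predict(train, ["X", "X", "Y"], [[0.2, 0.1]], k=3)
        assert list(pred) == ["X"]

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            train = rng.uniform(0, 5, size=(50, 2))
            labels = np.array(["X", "Y"])[rng.integers(0, 2, size=50)]
            test = rng.uniform(0, 5, size=(20, 2))
            mine = knn_predict(train, labels, test, k=15)
            assert (mine == brute_force_knn(train, labels, test, 15)).all()

    def test_matches_sklearn_reference(self, rng):
        sklearn = pytest.importorskip("sklearn.neighbors")
        train = rng.uniform(0, 5, size=(100, 2))
        labels = np.array(["X", "Y"])[rng.integers(0, 2, size=100)]
        test = rng.uniform(0, 5, size=(40, 2))
        clf = sklearn.KNeighborsClassifier(n_neighbors=15).fit(train, labels)
        assert (knn_predict(train, labels, test, 15) == clf.predict(test)).all()

    def test_insufficient_training_points_rejected(self):
        with pytest.raises(ValueError, match="k=15"):
            knn_predict([[0, 0]], ["X"], [[1, 1]], k=15)


class TestSampleTrainTest:
    def test_exact_pool_splits_disjointly(self, rng):
        pool = balanced_uniform_pool(500, rng)
        _, _, train_idx, test_idx = sample_train_test(pool, ClassifierConfig(), rng)
        assert len(train_idx) == 250 and len(test_idx) == 250
        assert set(train_idx).isdisjoint(test_idx)

    def test_one_short_rejected(self, rng):
        pool = balanced_uniform_pool(499, rng)
        with pytest.raises(InsufficientEventsError, match="shortfall"):
            sample_train_test(pool, ClassifierConfig(), rng)

    def test_one_peck_per_trial_reduces_candidates(self, rng):
        # 600 trials x 8 pecks -> 600 candidates, then 250/250
        n_trials, per = 600, 8
        xy = rng.uniform(0, 5, size=(n_trials * per, 2))
        labels = np.repeat(np.array(["X", "Y"])[rng.integers(0, 2, n_trials)], per)
        trial_index = np.repeat(np.arange(n_trials), per)
        peck_index = np.tile(np.arange(1, per + 1), n_trials)
        pool = make_pool(xy, labels, trial_index, peck_index)
        cfg = ClassifierConfig(one_peck_per_trial=True)
        xys, labs, train_idx, test_idx = sample_train_test(pool, cfg, rng)
        assert len(xys) == n_trials  # reduced pool
        assert len(train_idx) == 250 and len(test_idx) == 250

    def test_balanced_sampling_when_possible(self, rng):
        pool = balanced_uniform_pool(600, rng)
        _, labels, train_idx, _ = sample_train_test(pool, ClassifierConfig(), rng)
        n_x = int((labels[train_idx] == "X").sum())
        assert n_x == 125


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            ({"k": 14}, "odd"),
            ({"k": 251}, "exceed"),
            ({"iterations": 1}, "two iterations"),
        ],
    )
    def test_invalid_configs(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            ClassifierConfig(**kwargs)


class TestRunDecoding:
    def test_no_signal_pool_is_at_chance(self, rng):
        pool = balanced_uniform_pool(1500, rng)
        rep = run_decoding(pool, mode="CC", rng=rng)
        assert rep.verdict == "at_chance"
        assert rep.mean_accuracy == pytest.approx(50.0, abs=6.0)

    def test_shuffled_null_calibrated_to_chance(self, two_class_correct_pool, rng):
        rep = run_decoding(two_class_correct_pool, mode="CC", rng=rng)
        assert rep.mean_shuffled == pytest.approx(50.0, abs=3.0)

    def test_two_class_cc_reaches_eighty_percent(self, two_class_correct_pool, rng):
        rep = run_decoding(two_class_correct_pool, mode="CC", rng=rng)
        assert rep.mean_accuracy >= 80.0
        assert rep.verdict == "above_chance"
        assert rep.df == 9

    def test_confusion_ce_below_chance(self, rng):
        session = generate_session(
            make_archetype("confusion", p_correct=0.70, n_trials=600),
            GeneratorConfig(seed=21),
        )
        correct = select_pool(session, outcomes={"correct"})
        error = select_pool(session, outcomes={"error"})
        rep = run_decoding(correct, error, mode="CE", rng=rng)
        assert rep.mean_accuracy < 50.0
        assert rep.verdict == "below_chance"

    def test_ce_insufficient_errors_refused(self, rng):
        session = generate_session(
            make_archetype("two_class", p_correct=0.995), GeneratorConfig(seed=4)
        )
        correct = select_pool(session, outcomes={"correct"})
        error = select_pool(session, outcomes={"error"})
        assert len(error) < 500
        with pytest.raises(InsufficientEventsError, match="insufficient errors"):
            run_decoding(correct, error, mode="CE", rng=rng)

    def test_deterministic_under_fixed_seed(self, two_class_correct_pool):
        cfg = ClassifierConfig(seed=77)
        a = run_decoding(two_class_correct_pool, mode="CC", config=cfg)
        b = run_decoding(two_class_correct_pool, mode="CC", config=cfg)
        assert a == b

    def test_label_swap_symmetry(self, two_class_correct_pool):
        cfg = ClassifierConfig(seed=31)
        rep = run_decoding(two_class_correct_pool, mode="CC", config=cfg)
        swapped_events = two_class_correct_pool.events.copy()
        swapped_events["stimulus_class"] = swapped_events["stimulus_class"].map(
            {"X": "Y", "Y": "X"}
        )
        swapped = PeckPool(events=swapped_events, selector={})
        rep_swapped = run_decoding(swapped, mode="CC", config=cfg)
        assert rep_swapped.mean_accuracy == pytest.approx(rep.mean_accuracy, abs=1e-9)


class TestStrategyRecovery:
    """Decoding separates the strategy archetypes as designed."""

    @staticmethod
    def _cc(name, seed):
        session = generate_session(make_archetype(name), GeneratorConfig(seed=seed))
        pool = select_pool(session, outcomes={"correct"})
        return run_decoding(pool, mode="CC", rng=np.random.default_rng(seed)).mean_accuracy

    def test_cc_ordering_two_class_one_class_lateralized(self):
        two = self._cc("two_class", 101)
        one = self._cc("one_class", 102)
        lat = self._cc("lateralized", 103)
        assert two > one > lat
        assert lat == pytest.approx(50.0, abs=6.0)

    @staticmethod
    def _error_pools(name, seed):
        session = generate_session(
            make_archetype(name, p_correct=0.70, n_trials=600),
            GeneratorConfig(seed=seed),
        )
        return (
            select_pool(session, outcomes={"correct"}),
            select_pool(session, outcomes={"error"}),
        )

    def test_ce_direction_by_error_model(self):
        rng = np.random.default_rng(0)
        correct, error = self._error_pools("confusion", 201)
        assert run_decoding(correct, error, "CE", rng=rng).mean_accuracy < 50.0
        correct, error = self._error_pools("two_class", 202)  # dispersed errors
        assert run_decoding(correct, error, "CE", rng=rng).mean_accuracy > 50.0
        correct, error = self._error_pools("random_error", 203)
        uni = run_decoding(correct, error, "CE", rng=rng).mean_accuracy
        assert uni == pytest.approx(50.0, abs=6.0)

    def test_ee_direction_by_error_model(self):
        rng = np.random.default_rng(0)
        for name in ("confusion", "two_class"):  # swapped / dispersed
            _, error = self._error_pools(name, 301)
            assert run_decoding(error, mode="EE", rng=rng).mean_accuracy > 50.0
        _, error = self._error_pools("random_error", 302)
        assert run_decoding(error, mode="EE", rng=rng).mean_accuracy == pytest.approx(
            50.0, abs=6.0
        )


class TestPeckOrder:
    def test_orienting_peck_depresses_rank_one(self):
        session = generate_session(
            make_archetype("two_class", orienting_pecks=1), GeneratorConfig(seed=51)
        )
        pool = select_pool(session, outcomes={"correct"})
        results = peck_order_decoding(pool, rng=np.random.default_rng(51))
        by_rank = {r: rep for r, rep, _ in results if rep is not None}
        assert by_rank[1].mean_accuracy < by_rank[3].mean_accuracy

    def test_flat_without_orienting_pecks(self):
        session = generate_session(
            make_archetype("two_class", orienting_pecks=0), GeneratorConfig(seed=52)
        )
        pool = select_pool(session, outcomes={"correct"})
        results = peck_order_decoding(pool, rng=np.random.default_rng(52))
        accs = [rep.mean_accuracy for _, rep, _ in results if rep is not None]
        assert max(accs) - min(accs) < 10.0

    def test_sparse_rank_skipped_with_notice(self, rng):
        pool = balanced_uniform_pool(600, rng)  # all pecks have index 1
        results = peck_order_decoding(pool, rng=rng)
        notes = {r: note for r, rep, note in results if rep is None}
        assert 2 in notes and "skipped" in notes[2]
        rank1 = next(rep for r, rep, _ in results if r == 1)
        assert rank1 is not None
        assert rank1.notes["n_train"] <= 300  # reduced from the default 250+250
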