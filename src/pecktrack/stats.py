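"""Choice-performance summaries and t-test / effect-size statistics.

Performance is the percentage of correct choices among countable trials
(aborted and no-choice trials never count). Group performance is tested
against the 50% chance level of a binary choice with a one-sample t-test
(Cohen's d = (mean - mu0) / sd), and conditions are compared with a
paired t-test (Cohen's d = mean(diff) / sd(diff)). p-values are
two-sided throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from pecktrack.data import Trial

CHANCE_LEVEL = 50.0  # % correct for a binary choice


@dataclass(frozen=True)
class PerformanceSummary:
    grouping: dict
    n_trials: int
    percent_correct: float


@dataclass(frozen=True)
class TTestResult:
    kind: str  # "one_sample" | "paired"
    t: float
    df: int
    p: float
    cohen_d: float
    mu0: Optional[float] = None


def percent_correct(
    trials: Iterable[Trial],
    trial_type: Optional[str] = None,
    stimulus_class: Optional[str] = None,
) -> PerformanceSummary:
    """Percentage of correct choices in a trial group.

    ``trial_type``/``stimulus_class`` of ``None`` pool across that
    dimension. Aborted and no-choice trials are excluded; an empty group
    is an error.
    """
    group = [
        t
        for t in trials
        if t.countable
        and (trial_type is None or t.trial_type == trial_type)
        and (stimulus_class is None or t.stimulus_class == stimulus_class)
    ]
    if not group:
        raise ValueError(
            f"no countable trials for trial_type={trial_type!r}, "
            f"stimulus_class={stimulus_class!r}"
        )
    n_correct = sum(t.outcome == "correct" for t in group)
    return PerformanceSummary(
        grouping={"trial_type": trial_type or "pooled", "stimulus_class": stimulus_class or "pooled"},
        n_trials=len(group),
        percent_correct=100.0 * n_correct / len(group),
    )


def one_sample_t(values: Sequence[float], mu0: float = CHANCE_LEVEL) -> TTestResult:
    """One-sample t-test of a set of per-subject values against mu0.

    t = (mean - mu0) / (sd / sqrt(n)), df = n - 1, two-sided p,
    Cohen's d = (mean - mu0) / sd. Note t = d * sqrt(n) exactly.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two values")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise ValueError(
            "zero variance: all values identical, the t statistic is undefined"
        )
    n = len(x)
    d = float((x.mean() - mu0) / sd)
    t = d * np.sqrt(n)
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return TTestResult(kind="one_sample", t=float(t), df=n - 1, p=p, cohen_d=d, mu0=mu0)


def paired_t(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Paired t-test on a - b; Cohen's d = mean(diff) / sd(diff)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) < 2:
        raise ValueError("need at least two pairs")
    diff = a - b
    sd = float(np.std(diff, ddof=1))
    if sd == 0.0:
        raise ValueError(
            "zero variance of differences: no difference between conditions "
            "(or perfectly constant offset), the t statistic is undefined"
        )
    n = len(a)
    d = float(diff.mean() / sd)
    t = d * np.sqrt(n)
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return TTestResult(kind="paired", t=float(t), df=n - 1, p=p, cohen_d=d)
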