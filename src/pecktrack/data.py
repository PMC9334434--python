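"""Data model, log format, validation and filtering for per-peck records.

The unit of observation is a single peck on the stimulus display, located
in continuous centimetres on the registration region (the stimulus plus
its surrounding border, by default a 4 cm stimulus with a 0.5 cm border,
giving a 5 x 5 cm region). Pecks are nested in trials; trials carry the
presented stimulus class, the animal's choice and the trial outcome.

Coordinate convention: origin at the bottom-left corner of the
registration region, x rightward, y upward, in cm. Bounds are closed on
both axes, so a peck exactly on the region edge counts as in-bounds.

The on-disk format is a flat CSV, one row per peck, with trial-level
fields repeated on every row (see :data:`LOG_COLUMNS`).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

PHASES = ("learning", "transfer_test")
TRIAL_TYPES = ("known", "transfer")
CLASSES = ("X", "Y")
CHOICES = ("X", "Y", "none")
OUTCOMES = ("correct", "error", "aborted", "no_choice")
REINFORCEMENTS = ("differential", "nondifferential", "none")

#: trials with these outcomes never enter any analysis
EXCLUDED_OUTCOMES = frozenset({"aborted", "no_choice"})

#: minimum pecks for a valid (non-aborted) trial
MIN_PECKS_PER_TRIAL = 5

LOG_COLUMNS = [
    "subject_id",
    "session_id",
    "phase",
    "trial_index",
    "trial_type",
    "stimulus_id",
    "stimulus_class",
    "reinforcement",
    "choice",
    "outcome",
    "peck_index",
    "x_cm",
    "y_cm",
    "timestamp_ms",
]


class PeckLogError(ValueError):
    """Malformed peck log: missing columns, bad values, duplicate pecks."""


class PeckLogWarning(UserWarning):
    """Recoverable oddity in a peck log (e.g. an undersized valid trial)."""


@dataclass(frozen=True)
class DisplayGeometry:
    """Physical layout of the stimulus display.

    The stimulus square of side ``stimulus_side`` cm sits centred in a
    registration region extended by ``border`` cm on every side; pecks
    anywhere on the region are recorded. For heatmap analyses the region
    is sectioned into ``grid_n`` x ``grid_n`` equal squares.
    """

    stimulus_side: float = 4.0
    border: float = 0.5
    grid_n: int = 15

    def __post_init__(self) -> None:
        if self.region_side <= 0:
            raise ValueError("region_side must be positive")
        if self.grid_n < 1:
            raise ValueError("grid_n must be >= 1")

    @property
    def region_side(self) -> float:
        return self.stimulus_side + 2.0 * self.border

    @property
    def square_side(self) -> float:
        return self.region_side / self.grid_n

    @property
    def square_area(self) -> float:
        return self.square_side**2


@dataclass(frozen=True)
class PeckEvent:
    """One peck: location in cm and its order within the trial (1-based)."""

    x: float
    y: float
    peck_index: int
    timestamp_ms: Optional[int] = None

    def __post_init__(self) -> None:
        if self.peck_index < 1:
            raise ValueError("peck_index must be >= 1")

    def in_bounds(self, geometry: DisplayGeometry) -> bool:
        s = geometry.region_side
        return 0.0 <= self.x <= s and 0.0 <= self.y <= s


@dataclass
class Trial:
    trial_index: int
    phase: str
    trial_type: str
    stimulus_id: str
    stimulus_class: str
    choice: str
    outcome: str
    reinforcement: str
    pecks: list[PeckEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_enum("phase", self.phase, PHASES)
        _check_enum("trial_type", self.trial_type, TRIAL_TYPES)
        _check_enum("stimulus_class", self.stimulus_class, CLASSES)
        _check_enum("choice", self.choice, CHOICES)
        _check_enum("outcome", self.outcome, OUTCOMES)
        _check_enum("reinforcement", self.reinforcement, REINFORCEMENTS)

    @property
    def countable(self) -> bool:
        """True when the trial enters analyses (a real correct/error choice)."""
        return self.outcome not in EXCLUDED_OUTCOMES


@dataclass
class Session:
    subject_id: str
    session_id: str
    geometry: DisplayGeometry = field(default_factory=DisplayGeometry)
    trials: list[Trial] = field(default_factory=list)

    def __post_init__(self) -> None:
        indices = [t.trial_index for t in self.trials]
        if len(indices) != len(set(indices)):
            raise PeckLogError(
                f"duplicate trial indices in session {self.subject_id}/{self.session_id}"
            )


@dataclass
class PeckPool:
    """A flat, filtered collection of in-bounds pecks ready for analysis.

    ``events`` has columns x, y, trial_index, stimulus_class, outcome,
    peck_index; ``selector`` records the filters that produced the pool.
    """

    events: pd.DataFrame
    selector: dict

    def __len__(self) -> int:
        return len(self.events)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) float array of peck coordinates in cm."""
        return self.events[["x", "y"]].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        """(n,) array of stimulus-class labels ('X'/'Y')."""
        return self.events["stimulus_class"].to_numpy()


def _check_enum(name: str, value: str, allowed: Sequence[str]) -> None:
    if value not in allowed:
        raise PeckLogError(f"invalid {name} {value!r}; expected one of {allowed}")


def read_peck_log(
    source: Union[str, io.IOBase],
    geometry: Optional[DisplayGeometry] = None,
) -> list[Session]:
    """Read a peck-log CSV into sessions.

    Rows are grouped by (subject_id, session_id, trial_index); pecks are
    ordered by peck_index. Enumerated fields are validated. A trial with
    fewer than five pecks whose outcome is not ``aborted`` raises a
    :class:`PeckLogWarning` (the apparatus aborts such trials, so foreign
    data containing them is suspect but usable).

    Raises
    ------
    PeckLogError
        On a missing column, a non-numeric coordinate (reported with its
        row number), or a duplicate (trial_index, peck_index) pair.
    """
    geometry = geometry or DisplayGeometry()
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise PeckLogError(f"peck log missing column(s): {', '.join(missing)}")

    for col in ("x_cm", "y_cm"):
        # Python's float() is correctly rounded, so repr-written
        # coordinates round-trip exactly (pandas' fast parser may not)
        parsed = []
        for pos, raw in enumerate(df[col]):
            try:
                parsed.append(float(raw))
            except ValueError:
                raise PeckLogError(
                    f"non-numeric {col} value {raw!r} at line {pos + 2}"
                ) from None
        df[col] = parsed
    df["trial_index"] = pd.to_numeric(df["trial_index"]).astype(int)
    df["peck_index"] = pd.to_numeric(df["peck_index"]).astype(int)

    sessions: list[Session] = []
    for (subject, session_id), sgroup in df.groupby(
        ["subject_id", "session_id"], sort=False
    ):
        trials: list[Trial] = []
        for trial_index, tgroup in sgroup.groupby("trial_index", sort=True):
            if tgroup["peck_index"].duplicated().any():
                dup = int(tgroup["peck_index"][tgroup["peck_index"].duplicated()].iloc[0])
                raise PeckLogError(
                    f"duplicate peck_index {dup} in trial {trial_index} "
                    f"of session {subject}/{session_id}"
                )
            tgroup = tgroup.sort_values("peck_index")
            first = tgroup.iloc[0]
            pecks = [
                PeckEvent(
                    x=float(r.x_cm),
                    y=float(r.y_cm),
                    peck_index=int(r.peck_index),
                    timestamp_ms=int(r.timestamp_ms) if r.timestamp_ms != "" else None,
                )
                for r in tgroup.itertuples()
            ]
            trial = Trial(
                trial_index=int(trial_index),
                phase=first["phase"],
                trial_type=first["trial_type"],
                stimulus_id=first["stimulus_id"],
                stimulus_class=first["stimulus_class"],
                choice=first["choice"],
                outcome=first["outcome"],
                reinforcement=first["reinforcement"],
                pecks=pecks,
            )
            if trial.outcome != "aborted" and len(pecks) < MIN_PECKS_PER_TRIAL:
                warnings.warn(
                    f"trial {trial_index} of {subject}/{session_id} has "
                    f"{len(pecks)} pecks (< {MIN_PECKS_PER_TRIAL}) but outcome "
                    f"{trial.outcome!r}; the task aborts such trials",
                    PeckLogWarning,
                    stacklevel=2,
                )
            trials.append(trial)
        sessions.append(
            Session(
                subject_id=str(subject),
                session_id=str(session_id),
                geometry=geometry,
                trials=trials,
            )
        )
    return sessions


def write_peck_log(
    sessions: Iterable[Session], target: Union[str, io.IOBase]
) -> None:
    """Write sessions to the one-row-per-peck CSV format."""
    rows = []
    for s in sessions:
        for t in s.trials:
            for p in t.pecks:
                rows.append(
                    {
                        "subject_id": s.subject_id,
                        "session_id": s.session_id,
                        "phase": t.phase,
                        "trial_index": t.trial_index,
                        "trial_type": t.trial_type,
                        "stimulus_id": t.stimulus_id,
                        "stimulus_class": t.stimulus_class,
                        "reinforcement": t.reinforcement,
                        "choice": t.choice,
                        "outcome": t.outcome,
                        "peck_index": p.peck_index,
                        "x_cm": repr(float(p.x)),
                        "y_cm": repr(float(p.y)),
                        "timestamp_ms": "" if p.timestamp_ms is None else p.timestamp_ms,
                    }
                )
    pd.DataFrame(rows, columns=LOG_COLUMNS).to_csv(target, index=False)


def filter_pecks_in_bounds(session: Session) -> tuple[Session, int]:
    """Drop pecks outside the registration region.

    Pecks with 0 <= x, y <= region_side (closed bounds) are kept; the
    count of discarded pecks is returned alongside the filtered session.
    Idempotent.
    """
    discarded = 0
    new_trials = []
    for t in session.trials:
        kept = [p for p in t.pecks if p.in_bounds(session.geometry)]
        discarded += len(t.pecks) - len(kept)
        new_trials.append(replace(t, pecks=kept))
    return (
        Session(
            subject_id=session.subject_id,
            session_id=session.session_id,
            geometry=session.geometry,
            trials=new_trials,
        ),
        discarded,
    )


def select_pool(
    sessions: Union[Session, Iterable[Session]],
    phase: Optional[str] = None,
    trial_type: Optional[str] = None,
    outcomes: Optional[Iterable[str]] = None,
    classes: Optional[Iterable[str]] = None,
) -> PeckPool:
    """Collapse the in-bounds pecks of matching trials into one flat pool.

    ``None`` for a filter means "any". Aborted and no-choice trials are
    always excluded regardless of the ``outcomes`` filter. An empty pool
    is a valid result; downstream analyses enforce their own minima.
    """
    if isinstance(sessions, Session):
        sessions = [sessions]
    outcome_set = (
        {"correct", "error"} if outcomes is None else set(outcomes) - EXCLUDED_OUTCOMES
    )
    class_set = set(CLASSES) if classes is None else set(classes)

    rows = []
    for s in sessions:
        for t in s.trials:
            if not t.countable:
                continue
            if phase is not None and t.phase != phase:
                continue
            if trial_type is not None and t.trial_type != trial_type:
                continue
            if t.outcome not in outcome_set:
                continue
            if t.stimulus_class not in class_set:
                continue
            for p in t.pecks:
                if p.in_bounds(s.geometry):
                    rows.append(
                        (p.x, p.y, t.trial_index, t.stimulus_class, t.outcome, p.peck_index)
                    )
    events = pd.DataFrame(
        rows, columns=["x", "y", "trial_index", "stimulus_class", "outcome", "peck_index"]
    )
    selector = {
        "phase": phase,
        "trial_type": trial_type,
        "outcomes": sorted(outcome_set),
        "classes": sorted(class_set),
    }
    return PeckPool(events=events, selector=selector)
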