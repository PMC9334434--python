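"""Synthetic peck-session generator parameterised as strategy archetypes.

Real peck-tracking datasets from two-alternative categorization tasks
show a small set of qualitatively distinct pecking strategies: animals
that learned feature locations for both stimulus classes, animals that
learned only one class, animals that peck one fixed spot regardless of
the stimulus, and animals whose error trials reveal class confusion.
This module generates sessions with exactly that statistical structure,
so every downstream analysis (heatmaps, KS comparison, CC/CE/EE
decoding) can be validated against known ground truth.

The peck model is deliberately simple: on each trial the animal emits a
fixed number (>= 5) of pecks; the first ``orienting_pecks`` pecks of a
trial are drawn from a broad isotropic Gaussian around the display
centre (orienting/approach pecks carrying little class information), the
remainder from an isotropic Gaussian around the learned feature location
of the presented class, truncated to the registration region by
resampling. Error trials substitute an archetype-specific error model:

``none``
    error-trial pecks look exactly like correct-trial pecks (the animal
    pecked the "right" features but chose wrongly — a lapse),
``dispersed``
    pecks around the same class centre but with a larger spread,
``swapped``
    pecks around the *opposite* class centre (class confusion),
``uniform``
    pecks uniform over the region (pecking unrelated to the stimulus).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from pecktrack.data import (
    MIN_PECKS_PER_TRIAL,
    DisplayGeometry,
    PeckEvent,
    Session,
    Trial,
)

ERROR_MODELS = ("none", "dispersed", "swapped", "uniform")
LEARNED_CLASSES = ("both", "only_X", "neither")

_RESAMPLE_ATTEMPTS = 1000


@dataclass(frozen=True)
class StrategyProfile:
    """Generative description of one simulated subject's pecking strategy.

    Parameters
    ----------
    center_X, center_Y:
        Learned feature locations (cm) for the two stimulus classes.
    sd_correct:
        Isotropic Gaussian spread (cm) of focused pecks in correct trials.
    error_model:
        How error-trial pecks are placed (see module docstring).
    sd_error:
        Spread (cm) used by the ``dispersed`` error model.
    learned_classes:
        ``both`` — class-specific centres; ``only_X`` — class-Y pecks are
        uniform over the region (the class was never learned);
        ``neither`` — a single class-independent centre (lateralized
        pecker; ``center_Y`` is forced equal to ``center_X``).
    orienting_pecks, orienting_sd:
        Number of initial pecks per trial drawn from a broad Gaussian
        around the display centre, and its spread (cm).
    p_correct:
        Per-trial probability of a correct choice.
    pecks_per_trial_mean:
        Mean pecks per trial; realised as 5 + Poisson(mean - 5) so every
        trial meets the five-peck validity rule.
    n_trials, transfer_fraction:
        Session length and the fraction of trials flagged as transfer
        (novel-exemplar) trials.
    """

    center_X: tuple[float, float] = (1.5, 2.5)
    center_Y: tuple[float, float] = (3.5, 2.5)
    sd_correct: float = 0.4
    error_model: str = "dispersed"
    sd_error: float = 1.2
    learned_classes: str = "both"
    orienting_pecks: int = 1
    orienting_sd: float = 1.5
    p_correct: float = 0.92
    pecks_per_trial_mean: float = 8.0
    n_trials: int = 400
    transfer_fraction: float = 0.11

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_correct <= 1.0:
            raise ValueError("p_correct must be a probability")
        if self.sd_correct < 0:
            raise ValueError("sd_correct must be >= 0")
        if self.error_model not in ERROR_MODELS:
            raise ValueError(f"unknown error_model {self.error_model!r}")
        if self.learned_classes not in LEARNED_CLASSES:
            raise ValueError(f"unknown learned_classes {self.learned_classes!r}")
        if self.pecks_per_trial_mean < MIN_PECKS_PER_TRIAL:
            raise ValueError(
                f"pecks_per_trial_mean must be >= {MIN_PECKS_PER_TRIAL}"
            )
        if self.orienting_pecks < 0:
            raise ValueError("orienting_pecks must be >= 0")
        if self.learned_classes == "neither" and self.center_X != self.center_Y:
            raise ValueError(
                "learned_classes='neither' requires a single shared centre"
            )


@dataclass(frozen=True)
class GeneratorConfig:
    """Reproducibility wrapper: identical (profile, config) pairs yield
    identical sessions."""

    seed: int = 0
    geometry: DisplayGeometry = field(default_factory=DisplayGeometry)
    class_balance: float = 0.5


#: archetype name -> profile overrides relative to StrategyProfile defaults
ARCHETYPES: dict[str, dict] = {
    # learned feature locations for both classes; errors at the same
    # features but less focused
    "two_class": {"learned_classes": "both", "error_model": "dispersed"},
    # learned one class only; the other class is pecked indiscriminately
    "one_class": {"learned_classes": "only_X", "error_model": "dispersed"},
    # pecks one fixed spot irrespective of the stimulus (e.g. a strongly
    # lateralized animal); still performs the choice well
    "lateralized": {
        "learned_classes": "neither",
        "center_Y": (1.5, 2.5),
        "error_model": "none",
    },
    # errors are class confusions: pecks land on the other class's features
    "confusion": {"learned_classes": "both", "error_model": "swapped"},
    # errors are pure lapses: peck placement identical to correct trials
    "lapse": {"learned_classes": "both", "error_model": "none"},
    # errors are spatially random pecking
    "random_error": {"learned_classes": "both", "error_model": "uniform"},
}


def make_archetype(name: str, **overrides) -> StrategyProfile:
    """Return the fully specified profile for a named strategy archetype.

    Extra keyword arguments override individual profile fields (e.g.
    ``make_archetype("confusion", p_correct=0.7, n_trials=600)``).
    """
    try:
        params = dict(ARCHETYPES[name])
    except KeyError:
        raise ValueError(
            f"unknown archetype {name!r}; choose from {sorted(ARCHETYPES)}"
        ) from None
    params.update(overrides)
    return StrategyProfile(**params)


def _truncated_gaussian(
    center: tuple[float, float],
    sd: float,
    geometry: DisplayGeometry,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Sample one in-bounds point from an isotropic Gaussian by resampling."""
    s = geometry.region_side
    if sd == 0.0:
        x, y = center
        if not (0.0 <= x <= s and 0.0 <= y <= s):
            raise ValueError(f"degenerate centre {center} outside the region")
        return float(x), float(y)
    for _ in range(_RESAMPLE_ATTEMPTS):
        x, y = rng.normal(loc=center, scale=sd)
        if 0.0 <= x <= s and 0.0 <= y <= s:
            return float(x), float(y)
    raise ValueError(
        f"could not draw an in-bounds peck around {center} (sd={sd}) in "
        f"{_RESAMPLE_ATTEMPTS} attempts; centre too far outside the region?"
    )


def _correct_peck(
    profile: StrategyProfile,
    stimulus_class: str,
    geometry: DisplayGeometry,
    rng: np.random.Generator,
) -> tuple[float, float]:
    if profile.learned_classes == "neither":
        center = profile.center_X
    elif profile.learned_classes == "only_X" and stimulus_class == "Y":
        s = geometry.region_side
        x, y = rng.uniform(0.0, s, size=2)
        return float(x), float(y)
    else:
        center = profile.center_X if stimulus_class == "X" else profile.center_Y
    return _truncated_gaussian(center, profile.sd_correct, geometry, rng)


def sample_peck(
    profile: StrategyProfile,
    stimulus_class: str,
    outcome: str,
    peck_index: int,
    rng: np.random.Generator,
    geometry: DisplayGeometry | None = None,
) -> PeckEvent:
    """Draw one in-bounds peck for the given trial context."""
    geometry = geometry or DisplayGeometry()
    if stimulus_class not in ("X", "Y"):
        raise ValueError(f"stimulus_class must be 'X' or 'Y', got {stimulus_class!r}")
    s = geometry.region_side

    if peck_index <= profile.orienting_pecks:
        center = (s / 2.0, s / 2.0)
        x, y = _truncated_gaussian(center, profile.orienting_sd, geometry, rng)
    elif outcome == "correct" or profile.error_model == "none":
        x, y = _correct_peck(profile, stimulus_class, geometry, rng)
    elif profile.error_model == "dispersed":
        if profile.learned_classes == "only_X" and stimulus_class == "Y":
            x, y = (float(v) for v in rng.uniform(0.0, s, size=2))
        else:
            center = (
                profile.center_X
                if (stimulus_class == "X" or profile.learned_classes == "neither")
                else profile.center_Y
            )
            x, y = _truncated_gaussian(center, profile.sd_error, geometry, rng)
    elif profile.error_model == "swapped":
        center = profile.center_Y if stimulus_class == "X" else profile.center_X
        x, y = _truncated_gaussian(center, profile.sd_correct, geometry, rng)
    elif profile.error_model == "uniform":
        x, y = (float(v) for v in rng.uniform(0.0, s, size=2))
    else:  # pragma: no cover - guarded by StrategyProfile validation
        raise ValueError(f"unknown error_model {profile.error_model!r}")
    return PeckEvent(x=x, y=y, peck_index=peck_index)


def generate_session(
    profile: StrategyProfile,
    config: GeneratorConfig,
    subject_id: str = "sim",
    session_id: str = "s1",
) -> Session:
    """Generate one full session for a simulated subject.

    Each trial draws its stimulus class with ``config.class_balance``,
    its outcome with ``profile.p_correct`` (the choice is then set
    consistently: the presented class on correct trials, the other class
    on errors), its peck count as 5 + Poisson(mean - 5), and its pecks
    via :func:`sample_peck`. A ``transfer_fraction`` of trials is flagged
    as transfer trials (novel exemplars, non-differentially reinforced).
    """
    rng = np.random.default_rng(config.seed)
    geometry = config.geometry
    trials = []
    for trial_index in range(1, profile.n_trials + 1):
        stimulus_class = "X" if rng.random() < config.class_balance else "Y"
        correct = rng.random() < profile.p_correct
        outcome = "correct" if correct else "error"
        choice = (
            stimulus_class
            if correct
            else ("Y" if stimulus_class == "X" else "X")
        )
        is_transfer = rng.random() < profile.transfer_fraction
        trial_type = "transfer" if is_transfer else "known"
        # known exemplars 1-20, transfer exemplars 21-30 per class
        exemplar = (
            int(rng.integers(21, 31)) if is_transfer else int(rng.integers(1, 21))
        )
        n_pecks = MIN_PECKS_PER_TRIAL + int(
            rng.poisson(profile.pecks_per_trial_mean - MIN_PECKS_PER_TRIAL)
        )
        pecks = [
            sample_peck(profile, stimulus_class, outcome, i, rng, geometry)
            for i in range(1, n_pecks + 1)
        ]
        trials.append(
            Trial(
                trial_index=trial_index,
                phase="transfer_test",
                trial_type=trial_type,
                stimulus_id=f"{stimulus_class}{exemplar:02d}",
                stimulus_class=stimulus_class,
                choice=choice,
                outcome=outcome,
                reinforcement="nondifferential" if is_transfer else "differential",
                pecks=pecks,
            )
        )
    return Session(
        subject_id=subject_id, session_id=session_id, geometry=geometry, trials=trials
    )
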