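"""One-up/one-down adaptive staircase and presentation-level rules.

The anechoic variant of the test calibrates presentation level per listener
from a "just audible level": the level supporting 50% identification of a
male target in quiet.  That level is estimated with a one-up/one-down track —
level drops after a correct response and rises after an error — run with two
reversals at a 4-dB step (discarded) followed by six reversals at a 2-dB step
whose levels are averaged.  A one-up/one-down rule converges on the 50% point
of a symmetric psychometric function.

Presentation levels are then fixed sensation-level offsets: the headphone
test presents the target 39.5 dB above the listener's speech reception
threshold (SRT); the chamber test presents 30 dB above the just audible
level.  Maskers sit at ``target − TMR`` and a safety rule excludes any
configuration whose maskers would exceed 85 dB SPL.

Levels here are symbolic dB references (dB HL / dB SPL are opaque affine
scales); the package makes no acoustic-calibration claim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .exceptions import ConfigurationError, NonConvergenceError

__all__ = [
    "StaircaseSpec",
    "StaircaseTrial",
    "StaircaseResult",
    "LevelRule",
    "StimulusLevels",
    "run_staircase",
    "logistic_responder",
    "step_responder",
    "presentation_levels",
]

MASKER_CAP_DB_SPL = 85.0


@dataclass(frozen=True)
class StaircaseSpec:
    """One-up/one-down staircase parameters.

    Defaults implement the standard protocol: two 4-dB reversals discarded,
    six 2-dB reversals averaged.  ``max_trials`` is a safety cap; exceeding it
    raises :class:`NonConvergenceError`.
    """

    start_level_db: float
    phase1_step_db: float = 4.0
    phase1_reversals: int = 2
    phase2_step_db: float = 2.0
    phase2_reversals: int = 6
    max_trials: int = 400

    def __post_init__(self) -> None:
        if self.phase1_step_db <= 0 or self.phase2_step_db <= 0:
            raise ConfigurationError("step sizes must be positive")
        if self.phase1_reversals < 1 or self.phase2_reversals < 1:
            raise ConfigurationError("reversal counts must be >= 1")
        if self.max_trials < self.phase1_reversals + self.phase2_reversals:
            raise ConfigurationError("max_trials too small to log all reversals")


@dataclass(frozen=True)
class StaircaseTrial:
    trial_index: int
    level_db: float
    correct: bool
    reversal: bool
    phase: int  # 1 while the 4-dB reversals are being collected, else 2


@dataclass(frozen=True)
class StaircaseResult:
    """All reversal levels, the averaged estimate, and the full trial log."""

    reversal_levels_db: tuple[float, ...]
    just_audible_db: float
    trials: tuple[StaircaseTrial, ...]


def run_staircase(
    responder: Callable[[float], bool], spec: StaircaseSpec
) -> StaircaseResult:
    """Run a one-up/one-down track against ``responder``.

    ``responder(level_db) -> bool`` decides each trial; stochastic responders
    should close over their own seeded RNG (see :func:`logistic_responder`).
    A reversal is logged at the level where the movement direction changes
    (the turnaround level itself).  The step drops from ``phase1_step_db`` to
    ``phase2_step_db`` once ``phase1_reversals`` reversals have occurred, and
    the track ends after ``phase2_reversals`` further reversals, whose levels
    are averaged into ``just_audible_db``.
    """
    n_total = spec.phase1_reversals + spec.phase2_reversals
    level = float(spec.start_level_db)
    direction: Optional[int] = None  # last movement: -1 down, +1 up
    reversals: list[float] = []
    log: list[StaircaseTrial] = []

    for trial_index in range(spec.max_trials):
        correct = bool(responder(level))
        move = -1 if correct else +1
        is_reversal = direction is not None and move != direction
        phase = 1 if len(reversals) < spec.phase1_reversals else 2
        if is_reversal:
            reversals.append(level)
        log.append(
            StaircaseTrial(
                trial_index=trial_index,
                level_db=level,
                correct=correct,
                reversal=is_reversal,
                phase=phase,
            )
        )
        if len(reversals) >= n_total:
            phase2 = reversals[spec.phase1_reversals :]
            return StaircaseResult(
                reversal_levels_db=tuple(reversals),
                just_audible_db=float(np.mean(phase2)),
                trials=tuple(log),
            )
        step = (
            spec.phase1_step_db
            if len(reversals) < spec.phase1_reversals
            else spec.phase2_step_db
        )
        level += move * step
        direction = move

    raise NonConvergenceError(
        f"staircase logged only {len(reversals)}/{n_total} reversals "
        f"within {spec.max_trials} trials"
    )


def logistic_responder(
    midpoint_db: float, slope_db: float, seed: int | np.random.Generator
) -> Callable[[float], bool]:
    """Stochastic responder with P(correct) = logistic((level − midpoint)/slope).

    50%-correct point at ``midpoint_db``; ``slope_db`` is the logistic scale
    parameter in dB.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )

    def respond(level_db: float) -> bool:
        p = 1.0 / (1.0 + math.exp(-(level_db - midpoint_db) / slope_db))
        return bool(rng.random() < p)

    return respond


def step_responder(threshold_db: float) -> Callable[[float], bool]:
    """Deterministic responder: correct iff level ≥ ``threshold_db``."""

    def respond(level_db: float) -> bool:
        return level_db >= threshold_db

    return respond


@dataclass(frozen=True)
class LevelRule:
    """Presentation-level rule for one test variant.

    The target is placed ``sl_offset_db`` above a per-listener reference: the
    SRT for the headphone test (offset 39.5 dB), the staircase's just audible
    level for the chamber test (offset 30 dB).
    """

    test: str
    sl_offset_db: float
    srt_db_hl: Optional[float] = None
    just_audible_db: Optional[float] = None
    masker_cap_db_spl: float = MASKER_CAP_DB_SPL

    @classmethod
    def sr2(cls, srt_db_hl: float) -> "LevelRule":
        if srt_db_hl is None:
            raise ConfigurationError("SR2 level rule requires a measured SRT")
        return cls(test="SR2", sl_offset_db=39.5, srt_db_hl=float(srt_db_hl))

    @classmethod
    def sr2a(cls, just_audible_db: float) -> "LevelRule":
        return cls(test="SR2A", sl_offset_db=30.0, just_audible_db=float(just_audible_db))

    @property
    def reference_db(self) -> float:
        if self.test == "SR2":
            if self.srt_db_hl is None:
                raise ConfigurationError("SR2 level rule requires a measured SRT")
            return self.srt_db_hl
        if self.just_audible_db is None:
            raise ConfigurationError("SR2A level rule requires a just audible level")
        return self.just_audible_db


@dataclass(frozen=True)
class StimulusLevels:
    """Target/masker levels for one trial; ``excluded`` flags a cap violation."""

    target_level_db: float
    masker_level_db: float
    excluded: bool


def presentation_levels(rule: LevelRule, tmr_db: float) -> StimulusLevels:
    """Target at reference + SL offset; maskers at ``target − TMR``.

    ``excluded`` is set when the masker level would exceed the 85 dB SPL
    safety cap — such listeners are not tested.
    """
    target = rule.reference_db + rule.sl_offset_db
    masker = target - tmr_db
    return StimulusLevels(
        target_level_db=float(target),
        masker_level_db=float(masker),
        excluded=bool(masker > rule.masker_cap_db_spl),
    )
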