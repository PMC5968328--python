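"""Progressive-track engine: TMR sequence, trial scoring, threshold, SRM.

The rapid spatial-release test presents a fixed, descending ladder of
target-to-masker ratios (TMRs) — by default 20 trials, two at each of ten
levels from +10 dB down to −8 dB in 2-dB steps.  Because performance starts
near ceiling and ends near chance, the number of correct responses locates
the ~50%-correct point directly and the threshold is simply

    threshold_db = start_tmr_db − n_correct.

Spatial release from masking (SRM) is the threshold improvement when the two
maskers are moved from colocated (0°) to a symmetric ±separation:

    srm_db = colocated_threshold_db − separated_threshold_db.

Stimuli come from the closed-set Coordinate Response Measure (CRM) corpus:
the listener reports a color (4 alternatives) and a number (8 alternatives),
giving a 1/32 chance floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .exceptions import (
    ConfigurationError,
    MalformedSessionError,
    PairingError,
    ValidationError,
)

__all__ = [
    "COLORS",
    "NUMBERS",
    "GUESS_RATE",
    "Condition",
    "TrackSpec",
    "TrialRecord",
    "TrackResult",
    "SrmRecord",
    "build_tmr_sequence",
    "score_trial",
    "score_track",
    "compute_srm",
]

#: CRM response alternatives: 4 colors × 8 numbers = 32-alternative closed set.
COLORS: tuple[str, ...] = ("blue", "red", "white", "green")
NUMBERS: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
GUESS_RATE: float = 1.0 / (len(COLORS) * len(NUMBERS))

#: Masker separations available in each test variant (degrees, symmetric ±).
SEPARATIONS: dict[str, tuple[int, ...]] = {
    "SR2": (0, 45),
    "SR2A": (0, 15, 30, 45, 90, 135),
}


@dataclass(frozen=True, order=True)
class Condition:
    """A test variant plus masker separation.

    ``test`` is ``"SR2"`` (headphone, virtual array) or ``"SR2A"`` (anechoic
    chamber loudspeakers).  ``separation_deg`` is the symmetric masker offset;
    0 means colocated with the target.
    """

    test: str
    separation_deg: int

    def __post_init__(self) -> None:
        if self.test not in SEPARATIONS:
            raise ConfigurationError(
                f"unknown test {self.test!r}; expected one of {sorted(SEPARATIONS)}"
            )
        if self.separation_deg not in SEPARATIONS[self.test]:
            raise ConfigurationError(
                f"{self.test} does not include a ±{self.separation_deg}° condition; "
                f"allowed separations: {SEPARATIONS[self.test]}"
            )

    @property
    def colocated(self) -> bool:
        return self.separation_deg == 0


@dataclass(frozen=True)
class TrackSpec:
    """Geometry of one progressive track.

    Defaults give the standard 20-trial track: 10 levels from +10 to −8 dB in
    2-dB steps, two trials per level.
    """

    condition: Condition
    start_tmr_db: float = 10.0
    end_tmr_db: float = -8.0
    step_db: float = 2.0
    trials_per_level: int = 2

    def __post_init__(self) -> None:
        if self.step_db <= 0:
            raise ConfigurationError("step_db must be positive")
        if self.trials_per_level < 1:
            raise ConfigurationError("trials_per_level must be >= 1")
        if self.end_tmr_db > self.start_tmr_db:
            raise ConfigurationError("end_tmr_db must not exceed start_tmr_db")
        span = self.start_tmr_db - self.end_tmr_db
        n_steps = span / self.step_db
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ConfigurationError(
                f"step {self.step_db} dB does not divide the range "
                f"[{self.end_tmr_db}, {self.start_tmr_db}] dB"
            )

    @property
    def n_levels(self) -> int:
        return int(round((self.start_tmr_db - self.end_tmr_db) / self.step_db)) + 1

    @property
    def total_trials(self) -> int:
        return self.n_levels * self.trials_per_level

    def with_condition(self, condition: Condition) -> "TrackSpec":
        return replace(self, condition=condition)


@dataclass(frozen=True)
class TrialRecord:
    """One trial: presented TMR, target coordinate, and the response."""

    trial_index: int
    tmr_db: float
    target_color: str
    target_number: int
    response_color: str
    response_number: int

    @property
    def correct(self) -> bool:
        return score_trial(
            self.target_color,
            self.target_number,
            self.response_color,
            self.response_number,
        )


@dataclass(frozen=True)
class TrackResult:
    """Count-based threshold for one listener × run × condition."""

    listener_id: str
    run_index: int
    condition: Condition
    n_correct: int
    threshold_db: float


@dataclass(frozen=True)
class SrmRecord:
    """Spatial release for one listener × run × separation."""

    listener_id: str
    run_index: int
    separation_deg: int
    colocated_threshold_db: float
    separated_threshold_db: float
    srm_db: float


def build_tmr_sequence(spec: TrackSpec) -> list[float]:
    """Return the ordered TMR ladder for ``spec``.

    Levels descend from ``start_tmr_db`` to ``end_tmr_db`` in ``step_db``
    decrements, each level repeated ``trials_per_level`` times consecutively.
    """
    levels = spec.start_tmr_db - spec.step_db * np.arange(spec.n_levels)
    return [float(lv) for lv in np.repeat(levels, spec.trials_per_level)]


def _validate_token(color: str, number: int, kind: str) -> None:
    if color not in COLORS:
        raise ValidationError(f"{kind} color {color!r} not in CRM set {COLORS}")
    if number not in NUMBERS:
        raise ValidationError(f"{kind} number {number!r} not in CRM set {NUMBERS}")


def score_trial(
    target_color: str,
    target_number: int,
    response_color: str,
    response_number: int,
) -> bool:
    """True iff the response matches the target on *both* color and number."""
    _validate_token(target_color, int(target_number), "target")
    _validate_token(response_color, int(response_number), "response")
    return (response_color == target_color) and (
        int(response_number) == int(target_number)
    )


def score_track(
    trials: Sequence[TrialRecord],
    spec: TrackSpec,
    *,
    listener_id: str = "anonymous",
    run_index: int = 1,
) -> TrackResult:
    """Score a complete track: ``threshold = start_tmr − n_correct``.

    The trial list must have exactly ``spec.total_trials`` entries whose TMRs
    match the progressive ladder (order included); anything else raises
    :class:`MalformedSessionError`.
    """
    expected = build_tmr_sequence(spec)
    if len(trials) != len(expected):
        raise MalformedSessionError(
            f"expected {len(expected)} trials, got {len(trials)}"
        )
    got = [t.tmr_db for t in trials]
    if not np.allclose(got, expected):
        raise MalformedSessionError(
            f"trial TMRs {got} do not match the progressive ladder {expected}"
        )
    n_correct = sum(t.correct for t in trials)
    return TrackResult(
        listener_id=listener_id,
        run_index=run_index,
        condition=spec.condition,
        n_correct=n_correct,
        threshold_db=float(spec.start_tmr_db - n_correct),
    )


def compute_srm(colocated: TrackResult, separated: TrackResult) -> SrmRecord:
    """Release = colocated threshold − separated threshold, per listener per run."""
    if colocated.listener_id != separated.listener_id:
        raise PairingError(
            f"listener mismatch: {colocated.listener_id!r} vs {separated.listener_id!r}"
        )
    if colocated.run_index != separated.run_index:
        raise PairingError(
            f"run mismatch: {colocated.run_index} vs {separated.run_index}"
        )
    if not colocated.condition.colocated:
        raise PairingError("first argument must be the colocated (0°) result")
    if separated.condition.colocated:
        raise PairingError("second argument must be a separated (>0°) result")
    return SrmRecord(
        listener_id=colocated.listener_id,
        run_index=colocated.run_index,
        separation_deg=separated.condition.separation_deg,
        colocated_threshold_db=colocated.threshold_db,
        separated_threshold_db=separated.threshold_db,
        srm_db=colocated.threshold_db - separated.threshold_db,
    )


def expected_threshold(spec: TrackSpec, prob_correct) -> float:
    """Closed-form expectation of the scored threshold for a known listener.

    For a listener whose probability of a correct response at TMR ``x`` is
    ``prob_correct(x)``, the expected number correct is the sum of the
    per-trial probabilities over the ladder, so

        E[threshold] = start_tmr − Σ_trials P(correct | TMR).

    Used as the independent oracle for Monte-Carlo track simulations.
    """
    seq = build_tmr_sequence(spec)
    return float(spec.start_tmr_db - sum(prob_correct(x) for x in seq))
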