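"""Virtual listeners: psychometric functions, cohorts, and study simulation.

The simulator produces trial-level behavior with the statistical structure a
real cohort shows on the rapid spatial-release test, so that every scoring
and analysis stage can be exercised without human data:

* each listener × condition has a *true* 50%-correct TMR (``midpoint_db``)
  and responds via a logistic psychometric function with a 1/32 guessing
  floor (the CRM closed set) and a small lapse rate;
* true midpoints are a linear function of standardized covariates — age,
  standard pure-tone average (PTA, 0.5/1/2 kHz), and high-frequency PTA
  (2/4/8 kHz) — plus a Gaussian residual, so standardized regression on
  simulated thresholds recovers the generating coefficients;
* run 1 carries a practice offset (thresholds are worse before the task is
  learned) and every run carries independent Gaussian jitter.

Cohort factories mirror two reference subject screens (29 listeners aged
21–77 with standard PTA < 30 dB HL; 40 listeners aged 22–79 with PTA
< 41 dB HL) and the canonical schedules (2 headphone runs + 4 chamber runs;
8 headphone runs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .session import TRIAL_COLUMNS, SessionTable
from .track_engine import (
    COLORS,
    GUESS_RATE,
    NUMBERS,
    Condition,
    TrackSpec,
    TrialRecord,
    build_tmr_sequence,
    score_track,
)

__all__ = [
    "PsychometricFunction",
    "ListenerProfile",
    "CovariateSpec",
    "CohortModel",
    "sample_cohort",
    "simulate_track",
    "simulate_study",
    "experiment1_schedule",
    "experiment2_schedule",
]

#: Default true-threshold intercepts per condition (dB TMR): run-averaged
#: group means observed for each test × separation.
DEFAULT_INTERCEPTS: dict[Condition, float] = {
    Condition("SR2A", 0): 1.975,
    Condition("SR2A", 15): -2.405,
    Condition("SR2A", 30): -4.26,
    Condition("SR2A", 45): -5.8975,
    Condition("SR2A", 90): -6.5025,
    Condition("SR2A", 135): -6.3375,
    Condition("SR2", 0): 1.965,
    Condition("SR2", 45): -4.035,
}

#: Default standardized effect structure (age, standard PTA, high-frequency
#: PTA) per condition: age drives colocated thresholds, high-frequency PTA
#: drives small separations (15°–30°), standard PTA drives large separations.
DEFAULT_COEFFS: dict[Condition, tuple[float, float, float]] = {
    Condition("SR2", 0): (0.54, 0.0, 0.0),
    Condition("SR2", 45): (0.0, 0.69, 0.0),
    Condition("SR2A", 0): (0.34, 0.0, 0.0),
    Condition("SR2A", 15): (0.0, 0.0, 0.42),
    Condition("SR2A", 30): (0.0, 0.0, 0.62),
    Condition("SR2A", 45): (0.0, 0.54, 0.0),
    Condition("SR2A", 90): (0.0, 0.60, 0.0),
    Condition("SR2A", 135): (0.0, 0.52, 0.0),
}

#: Default covariate correlation structure (age, standard PTA, HF PTA):
#: age and standard PTA only weakly related by recruitment design; both
#: moderately related to high-frequency PTA.
DEFAULT_COVARIATE_CORR = np.array(
    [
        [1.000, 0.213, 0.642],
        [0.213, 1.000, 0.649],
        [0.642, 0.649, 1.000],
    ]
)


@dataclass(frozen=True)
class PsychometricFunction:
    """Logistic P(correct | TMR) with guessing floor and lapse ceiling.

    ``midpoint_db`` is defined as the TMR at which P = 0.5 exactly, so the
    count-based track estimator and the model's threshold parameter coincide.
    ``slope_db`` is the logistic scale parameter (smaller = steeper).
    """

    midpoint_db: float
    slope_db: float = 2.0
    guess_rate: float = GUESS_RATE
    lapse_rate: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 <= self.guess_rate < 0.5):
            raise ConfigurationError("guess_rate must be in [0, 0.5)")
        if not (0.0 <= self.lapse_rate < 0.5):
            raise ConfigurationError("lapse_rate must be in [0, 0.5)")
        if self.slope_db < 0:
            raise ConfigurationError("slope_db must be nonnegative")

    def prob_correct(self, tmr_db) -> np.ndarray | float:
        """Vectorized P(correct | TMR); P(midpoint_db) = 0.5 exactly."""
        x = np.asarray(tmr_db, dtype=float)
        lo, hi = self.guess_rate, 1.0 - self.lapse_rate
        if self.slope_db == 0.0:  # step-function limit
            core = np.where(x >= self.midpoint_db, 1.0, 0.0)
            core = np.where(np.isclose(x, self.midpoint_db), _half_quantile(lo, hi), core)
        else:
            # shift the logistic so the full function crosses 0.5 at midpoint
            p_half = _half_quantile(lo, hi)
            x0 = self.midpoint_db - self.slope_db * math.log(p_half / (1.0 - p_half))
            core = 1.0 / (1.0 + np.exp(-(x - x0) / self.slope_db))
        p = lo + (hi - lo) * core
        return float(p) if np.isscalar(tmr_db) else p


def _half_quantile(lo: float, hi: float) -> float:
    """Core-scale proportion at which lo + (hi-lo)*q = 0.5."""
    if hi <= 0.5:
        raise ConfigurationError("lapse_rate too large: function cannot reach 0.5")
    return (0.5 - lo) / (hi - lo)


@dataclass(frozen=True)
class ListenerProfile:
    """One simulated listener: covariates plus generative response parameters."""

    listener_id: str
    age: float
    pta_standard: float
    pta_hf: float
    srt: float
    true_thresholds: dict[Condition, float]
    practice_colocated_db: float = 1.3
    practice_separated_db: float = 2.0
    run_jitter_sd_db: float = 1.0
    slope_db: float = 2.0
    guess_rate: float = GUESS_RATE
    lapse_rate: float = 0.01

    def practice_offset_db(self, condition: Condition) -> float:
        return (
            self.practice_colocated_db
            if condition.colocated
            else self.practice_separated_db
        )


@dataclass(frozen=True)
class CovariateSpec:
    """Truncated-normal marginal for one covariate (bounds are a hard screen)."""

    mean: float
    sd: float
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigurationError("covariate sd must be nonnegative")
        if self.lower >= self.upper:
            raise ConfigurationError("covariate bounds are infeasible")

    def screened_moments(self) -> tuple[float, float]:
        """Mean and SD of the covariate *after* the screening truncation.

        Standardized effect sizes are defined with respect to the screened
        population (that is the population a study samples), so the linear
        predictor standardizes covariates by these moments rather than the
        untruncated ones.
        """
        from scipy import stats

        if self.sd == 0:
            return self.mean, 0.0
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        dist = stats.truncnorm(a, b, loc=self.mean, scale=self.sd)
        return float(dist.mean()), float(dist.std())


@dataclass(frozen=True)
class CohortModel:
    """Generative model for a cohort of virtual listeners.

    Covariates (age, standard PTA, HF PTA) are drawn from a correlated
    Gaussian and rejection-sampled against the screening bounds; condition
    thresholds are ``intercept + scale × (β·z + residual)`` with ``z`` the
    standardized covariate draws, so ``β`` are generating standardized
    regression coefficients.
    """

    n: int
    age: CovariateSpec = CovariateSpec(46.14, 16.0, 21.0, 77.0)
    pta_standard: CovariateSpec = CovariateSpec(10.92, 6.77, -5.0, 30.0)
    pta_hf: CovariateSpec = CovariateSpec(20.04, 14.1, -5.0, 57.5)
    srt_bounds: tuple[float, float] = (0.0, 30.0)
    covariate_corr: np.ndarray = field(
        default_factory=lambda: DEFAULT_COVARIATE_CORR.copy()
    )
    coeffs: dict[Condition, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COEFFS)
    )
    intercepts: dict[Condition, float] = field(
        default_factory=lambda: dict(DEFAULT_INTERCEPTS)
    )
    threshold_scale_db: float = 2.5
    practice_colocated_db: float = 1.3
    practice_separated_db: float = 2.0
    run_jitter_sd_db: float = 1.0
    slope_db: float = 2.0
    guess_rate: float = GUESS_RATE
    lapse_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError("cohort size must be >= 1")
        R = np.asarray(self.covariate_corr, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R, R.T):
            raise ConfigurationError("covariate_corr must be a symmetric 3×3 matrix")
        if np.linalg.eigvalsh(R).min() < -1e-9:
            raise ConfigurationError("covariate_corr is not positive semidefinite")
        for cond, beta in self.coeffs.items():
            b = np.asarray(beta, dtype=float)
            explained = float(b @ R @ b)
            if explained > 1.0 + 1e-9:
                raise ConfigurationError(
                    f"effect structure for {cond} explains >100% of variance"
                )
            if cond not in self.intercepts:
                raise ConfigurationError(f"no intercept for condition {cond}")

    @classmethod
    def experiment1(cls, n: int = 29, **overrides) -> "CohortModel":
        """Cohort screen of the first (validity) experiment."""
        return cls(n=n, **overrides)

    @classmethod
    def experiment2(cls, n: int = 40, **overrides) -> "CohortModel":
        """Cohort screen of the second (test–retest) experiment."""
        defaults = dict(
            age=CovariateSpec(55.35, 15.0, 22.0, 79.0),
            pta_standard=CovariateSpec(14.90, 9.93, -5.0, 41.0),
            pta_hf=CovariateSpec(23.25, 17.26, -5.0, 60.0),
            srt_bounds=(3.0, 43.0),
        )
        defaults.update(overrides)
        return cls(n=n, **defaults)

    @classmethod
    def single_effect(
        cls,
        n: int,
        condition: Condition,
        predictor: str,
        beta: float,
        **overrides,
    ) -> "CohortModel":
        """A cohort where one predictor alone drives one condition's threshold.

        Useful for parameter-recovery studies: all other coefficients are 0 and
        covariates are mutually independent.
        """
        idx = {"age": 0, "pta_standard": 1, "pta_hf": 2}
        if predictor not in idx:
            raise ConfigurationError(f"unknown predictor {predictor!r}")
        b = [0.0, 0.0, 0.0]
        b[idx[predictor]] = beta
        coeffs = {c: (0.0, 0.0, 0.0) for c in DEFAULT_COEFFS}
        coeffs[condition] = tuple(b)
        overrides.setdefault("covariate_corr", np.eye(3))
        return cls(n=n, coeffs=coeffs, **overrides)


_MAX_REJECTIONS = 10_000


def _draw_covariates(model: CohortModel, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One accepted standardized triple z and its covariate-scale values."""
    L = np.linalg.cholesky(model.covariate_corr + 1e-12 * np.eye(3))
    specs = (model.age, model.pta_standard, model.pta_hf)
    for _ in range(_MAX_REJECTIONS):
        z = L @ rng.standard_normal(3)
        vals = np.array([s.mean + s.sd * zi for s, zi in zip(specs, z)])
        if all(s.lower <= v <= s.upper for s, v in zip(specs, vals)):
            return z, vals
    raise ConfigurationError(
        "screening bounds rejected 10,000 consecutive draws; "
        "distribution support and bounds are incompatible"
    )


def sample_cohort(model: CohortModel, seed: int | np.random.Generator) -> list[ListenerProfile]:
    """Draw ``model.n`` listeners; reproducible given the seed."""
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    R = np.asarray(model.covariate_corr, dtype=float)
    specs = (model.age, model.pta_standard, model.pta_hf)
    screened = [s.screened_moments() for s in specs]
    profiles = []
    for i in range(model.n):
        _, (age, pta_std, pta_hf) = _draw_covariates(model, rng)
        # standardize against the screened population so the β are its
        # standardized regression coefficients
        z = np.array(
            [
                (v - m) / s if s > 0 else 0.0
                for v, (m, s) in zip((age, pta_std, pta_hf), screened)
            ]
        )
        # SRT tracks standard PTA with a small positive offset, clipped to
        # the observed range
        srt = float(
            np.clip(pta_std + rng.normal(2.0, 3.0), *model.srt_bounds)
        )
        thresholds = {}
        for cond, beta in model.coeffs.items():
            b = np.asarray(beta, dtype=float)
            resid_sd = math.sqrt(max(0.0, 1.0 - float(b @ R @ b)))
            z_resp = float(b @ z) + resid_sd * rng.standard_normal()
            thresholds[cond] = model.intercepts[cond] + model.threshold_scale_db * z_resp
        profiles.append(
            ListenerProfile(
                listener_id=f"L{i + 1:03d}",
                age=float(age),
                pta_standard=float(pta_std),
                pta_hf=float(pta_hf),
                srt=srt,
                true_thresholds=thresholds,
                practice_colocated_db=model.practice_colocated_db,
                practice_separated_db=model.practice_separated_db,
                run_jitter_sd_db=model.run_jitter_sd_db,
                slope_db=model.slope_db,
                guess_rate=model.guess_rate,
                lapse_rate=model.lapse_rate,
            )
        )
    return profiles


def effective_psychometric(
    profile: ListenerProfile,
    condition: Condition,
    run_index: int,
    rng: np.random.Generator,
) -> PsychometricFunction:
    """Per-run function: true midpoint + practice offset (run 1) + jitter."""
    if condition not in profile.true_thresholds:
        raise ConfigurationError(
            f"listener {profile.listener_id} has no true threshold for {condition}"
        )
    midpoint = profile.true_thresholds[condition]
    if run_index == 1:
        midpoint += profile.practice_offset_db(condition)
    if profile.run_jitter_sd_db > 0:
        midpoint += rng.normal(0.0, profile.run_jitter_sd_db)
    return PsychometricFunction(
        midpoint_db=midpoint,
        slope_db=profile.slope_db,
        guess_rate=profile.guess_rate,
        lapse_rate=profile.lapse_rate,
    )


def _random_wrong_response(
    target_color: str, target_number: int, rng: np.random.Generator
) -> tuple[str, int]:
    while True:
        color = COLORS[rng.integers(len(COLORS))]
        number = NUMBERS[rng.integers(len(NUMBERS))]
        if (color, number) != (target_color, target_number):
            return color, number


def simulate_track(
    profile: ListenerProfile,
    condition: Condition,
    run_index: int,
    seed: int | np.random.Generator,
    spec: Optional[TrackSpec] = None,
) -> list[TrialRecord]:
    """Bernoulli responses through the listener's psychometric function."""
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    if spec is None:
        spec = TrackSpec(condition=condition)
    pf = effective_psychometric(profile, condition, run_index, rng)
    trials = []
    for idx, tmr in enumerate(build_tmr_sequence(spec)):
        target_color = COLORS[rng.integers(len(COLORS))]
        target_number = int(NUMBERS[rng.integers(len(NUMBERS))])
        correct = bool(rng.random() < pf.prob_correct(tmr))
        if correct:
            response_color, response_number = target_color, target_number
        else:
            response_color, response_number = _random_wrong_response(
                target_color, target_number, rng
            )
        trials.append(
            TrialRecord(
                trial_index=idx,
                tmr_db=tmr,
                target_color=target_color,
                target_number=target_number,
                response_color=response_color,
                response_number=int(response_number),
            )
        )
    return trials


def experiment1_schedule() -> list[tuple[Condition, int]]:
    """Two headphone runs of both conditions + four chamber runs of all six."""
    schedule = []
    for run in (1, 2):
        for sep in (0, 45):
            schedule.append((Condition("SR2", sep), run))
    for run in (1, 2, 3, 4):
        for sep in (0, 15, 30, 45, 90, 135):
            schedule.append((Condition("SR2A", sep), run))
    return schedule


def experiment2_schedule(n_runs: int = 8) -> list[tuple[Condition, int]]:
    """``n_runs`` headphone runs of the colocated and ±45° conditions."""
    return [
        (Condition("SR2", sep), run)
        for run in range(1, n_runs + 1)
        for sep in (0, 45)
    ]


def simulate_study(
    cohort: Sequence[ListenerProfile],
    schedule: Sequence[tuple[Condition, int]],
    seed: int,
    *,
    keep_trials: bool = True,
) -> SessionTable:
    """Run every listener through every (condition, run) of the schedule.

    Returns a :class:`SessionTable` with one scored :class:`TrackResult` per
    listener × condition × run (and, optionally, the full trial log).
    Deterministic given ``seed``.
    """
    if not schedule:
        raise ConfigurationError("schedule must be non-empty")
    rng = np.random.default_rng(seed)
    results = []
    trial_rows: list[dict] = []
    for profile in cohort:
        for condition, run in schedule:
            spec = TrackSpec(condition=condition)
            trials = simulate_track(profile, condition, run, rng, spec=spec)
            results.append(
                score_track(
                    trials, spec, listener_id=profile.listener_id, run_index=run
                )
            )
            if keep_trials:
                for t in trials:
                    trial_rows.append(
                        {
                            "listener_id": profile.listener_id,
                            "run": run,
                            "test": condition.test,
                            "separation_deg": condition.separation_deg,
                            "trial_index": t.trial_index,
                            "tmr_db": t.tmr_db,
                            "target_color": t.target_color,
                            "target_number": t.target_number,
                            "response_color": t.response_color,
                            "response_number": t.response_number,
                        }
                    )
    trials_df = (
        pd.DataFrame(trial_rows, columns=TRIAL_COLUMNS) if keep_trials else None
    )
    return SessionTable.from_track_results(results, trials=trials_df)


def covariate_frame(cohort: Sequence[ListenerProfile]) -> pd.DataFrame:
    """Tidy covariate table (one row per listener) for regression analyses."""
    return pd.DataFrame(
        [
            {
                "listener_id": p.listener_id,
                "age": p.age,
                "pta_standard": p.pta_standard,
                "pta_hf": p.pta_hf,
                "srt": p.srt,
            }
            for p in cohort
        ]
    )
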