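"""File I/O: session/threshold/covariate tables, configs, fixtures, manifests.

CSV is the canonical interchange format (JSON mirrors it for programmatic
use).  Schemas are those documented in :mod:`sr2kit.session`; readers fail
loudly on missing columns or empty files and warn on unrecognized columns.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import MalformedSessionError, SchemaError
from .session import (
    SRM_COLUMNS,
    THRESHOLD_COLUMNS,
    TRIAL_COLUMNS,
    SessionTable,
)
from .track_engine import Condition, TrackSpec, TrialRecord, score_track

logger = logging.getLogger(__name__)

__all__ = [
    "read_session",
    "write_session",
    "read_trials",
    "write_trials",
    "read_covariates",
    "score_session",
    "read_config",
    "make_fixtures",
    "RunManifest",
]


def _read_table(path: Path | str, required: list[str], what: str) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".json":
        try:
            df = pd.read_json(path, orient="records")
        except ValueError as exc:
            raise SchemaError(f"cannot parse {path} as a JSON record table: {exc}")
    else:
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            raise SchemaError(f"{what} file {path} is empty")
    if df.empty:
        raise SchemaError(f"{what} file {path} contains no rows")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file {path} is missing columns: {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{what} file {path} has unrecognized columns: {extra}")
    return df[required]


def read_trials(path: Path | str) -> pd.DataFrame:
    """Read a trial-level session table (CSV or JSON)."""
    return _read_table(path, TRIAL_COLUMNS, "session")


def read_session(
    thresholds_path: Path | str, trials_path: Optional[Path | str] = None
) -> SessionTable:
    """Read a threshold table (and optionally its trial table)."""
    thresholds = _read_table(thresholds_path, THRESHOLD_COLUMNS, "threshold")
    trials = read_trials(trials_path) if trials_path is not None else None
    return SessionTable(thresholds=thresholds, trials=trials)


def _write_table(df: pd.DataFrame, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".json":
        path.write_text(df.to_json(orient="records", indent=2))
    else:
        df.to_csv(path, index=False)
    return path


def write_trials(trials: pd.DataFrame, path: Path | str) -> Path:
    return _write_table(trials[TRIAL_COLUMNS], path)


def write_session(
    session: SessionTable,
    thresholds_path: Path | str,
    trials_path: Optional[Path | str] = None,
) -> None:
    _write_table(session.thresholds[THRESHOLD_COLUMNS], thresholds_path)
    if trials_path is not None:
        if session.trials is None:
            raise SchemaError("session has no trial-level table to write")
        write_trials(session.trials, trials_path)


COVARIATE_COLUMNS = ["listener_id", "age", "pta_standard", "pta_hf", "srt"]


def read_covariates(path: Path | str) -> pd.DataFrame:
    return _read_table(path, COVARIATE_COLUMNS, "covariate")


def score_session(trials: pd.DataFrame) -> SessionTable:
    """Score every track in a trial-level table.

    Groups rows by listener × run × test × separation, checks each group
    against the progressive ladder, and emits one threshold row per track.
    """
    results = []
    for (listener, run, test, sep), grp in trials.groupby(
        ["listener_id", "run", "test", "separation_deg"], sort=True
    ):
        condition = Condition(str(test), int(sep))
        spec = TrackSpec(condition=condition)
        grp = grp.sort_values("trial_index")
        recs = [
            TrialRecord(
                trial_index=int(r.trial_index),
                tmr_db=float(r.tmr_db),
                target_color=str(r.target_color),
                target_number=int(r.target_number),
                response_color=str(r.response_color),
                response_number=int(r.response_number),
            )
            for r in grp.itertuples(index=False)
        ]
        results.append(
            score_track(recs, spec, listener_id=str(listener), run_index=int(run))
        )
    if not results:
        raise MalformedSessionError("no tracks found in trial table")
    return SessionTable.from_track_results(results, trials=trials)


def read_config(path: Path | str) -> dict:
    """Read a YAML (or JSON) keyed configuration file."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise SchemaError(f"config file {path} must contain a mapping")
    return data


@dataclass
class RunManifest:
    """Provenance record written next to every CLI output set."""

    seed: int
    command: str
    outputs: list[str] = field(default_factory=list)
    config_path: Optional[str] = None
    schedule: Optional[list] = None
    version: str = __version__
    timestamp: Optional[str] = None

    def write(self, path: Path | str) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")
        return path


# ---------------------------------------------------------------------------
# fixtures


def worked_example_trials() -> pd.DataFrame:
    """The canonical worked example: correct only at the four highest levels.

    Twenty trials; the two trials at each of the four highest TMRs (10, 8, 6,
    4 dB) are answered correctly and all others incorrectly (a wrong color),
    so the scored threshold is 10 − 8 = 2 dB.
    """
    spec = TrackSpec(condition=Condition("SR2", 0))
    from .track_engine import build_tmr_sequence

    rows = []
    for idx, tmr in enumerate(build_tmr_sequence(spec)):
        correct = idx < 8
        rows.append(
            {
                "listener_id": "EX1",
                "run": 1,
                "test": "SR2",
                "separation_deg": 0,
                "trial_index": idx,
                "tmr_db": tmr,
                "target_color": "blue",
                "target_number": 2,
                "response_color": "blue" if correct else "red",
                "response_number": 2,
            }
        )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def make_fixtures(seed: int, outdir: Path | str) -> dict[str, Path]:
    """Write the bundled small datasets; byte-identical for a given seed.

    Emits (a) the worked-example track, (b) a 5-listener × 2-run headphone
    mini-study (trials + thresholds), and (c) a deterministic staircase log.
    """
    from .listener_sim import CohortModel, sample_cohort, simulate_study
    from .staircase import StaircaseSpec, run_staircase, step_responder
    from .track_engine import Condition

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["worked_example"] = _write_table(
        worked_example_trials(), outdir / "worked_example_trials.csv"
    )

    model = CohortModel.experiment2(n=5)
    cohort = sample_cohort(model, seed)
    schedule = [
        (Condition("SR2", sep), run) for run in (1, 2) for sep in (0, 45)
    ]
    session = simulate_study(cohort, schedule, seed=seed + 1)
    paths["mini_study_trials"] = _write_table(
        session.trials, outdir / "mini_study_trials.csv"
    )
    paths["mini_study_thresholds"] = _write_table(
        session.thresholds, outdir / "mini_study_thresholds.csv"
    )

    result = run_staircase(
        step_responder(20.0), StaircaseSpec(start_level_db=50.0)
    )
    log = pd.DataFrame(
        [
            {
                "trial": t.trial_index,
                "level_db": t.level_db,
                "correct": t.correct,
                "reversal_flag": t.reversal,
                "phase": t.phase,
            }
            for t in result.trials
        ]
    )
    paths["staircase_log"] = _write_table(log, outdir / "staircase_log.csv")
    return paths
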