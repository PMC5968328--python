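"""Tidy tabular containers for trial- and threshold-level records.

A :class:`SessionTable` holds one or many listeners × runs × conditions in
two tidy pandas frames: an optional trial-level table (one row per presented
trial) and a threshold-level table (one row per scored track).  CSV is the
canonical interchange format; the column schemas below are the contract.
Separations are stored as a single nonnegative degree value (symmetric ±
maskers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .exceptions import PairingError, SchemaError
from .track_engine import Condition, SrmRecord, TrackResult, compute_srm

TRIAL_COLUMNS = [
    "listener_id",
    "run",
    "test",
    "separation_deg",
    "trial_index",
    "tmr_db",
    "target_color",
    "target_number",
    "response_color",
    "response_number",
]

THRESHOLD_COLUMNS = [
    "listener_id",
    "run",
    "test",
    "separation_deg",
    "n_correct",
    "threshold_db",
]

SRM_COLUMNS = [
    "listener_id",
    "run",
    "test",
    "separation_deg",
    "colocated_threshold_db",
    "separated_threshold_db",
    "srm_db",
]


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing required columns: {missing}")


@dataclass
class SessionTable:
    """Trial- and threshold-level records for one or many sessions."""

    thresholds: pd.DataFrame
    trials: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        _require_columns(self.thresholds, THRESHOLD_COLUMNS, "threshold")
        if self.trials is not None:
            _require_columns(self.trials, TRIAL_COLUMNS, "trial")

    @classmethod
    def from_track_results(
        cls, results: Iterable[TrackResult], trials: Optional[pd.DataFrame] = None
    ) -> "SessionTable":
        rows = [
            {
                "listener_id": r.listener_id,
                "run": r.run_index,
                "test": r.condition.test,
                "separation_deg": r.condition.separation_deg,
                "n_correct": r.n_correct,
                "threshold_db": r.threshold_db,
            }
            for r in results
        ]
        return cls(thresholds=pd.DataFrame(rows, columns=THRESHOLD_COLUMNS), trials=trials)

    def track_results(self) -> list[TrackResult]:
        return [
            TrackResult(
                listener_id=str(row.listener_id),
                run_index=int(row.run),
                condition=Condition(str(row.test), int(row.separation_deg)),
                n_correct=int(row.n_correct),
                threshold_db=float(row.threshold_db),
            )
            for row in self.thresholds.itertuples(index=False)
        ]

    def srm_table(self) -> pd.DataFrame:
        """Per-listener, per-run spatial release for every separated condition.

        Raises :class:`PairingError` when a separated track has no colocated
        partner for the same listener × test × run.
        """
        th = self.thresholds
        coloc = th[th.separation_deg == 0]
        sep = th[th.separation_deg != 0]
        merged = sep.merge(
            coloc[["listener_id", "run", "test", "threshold_db"]],
            on=["listener_id", "run", "test"],
            how="left",
            suffixes=("", "_colocated"),
        )
        if merged.threshold_db_colocated.isna().any():
            bad = merged[merged.threshold_db_colocated.isna()][
                ["listener_id", "run", "test"]
            ].drop_duplicates()
            raise PairingError(
                f"separated tracks without a colocated partner:\n{bad.to_string(index=False)}"
            )
        out = pd.DataFrame(
            {
                "listener_id": merged.listener_id,
                "run": merged.run,
                "test": merged.test,
                "separation_deg": merged.separation_deg,
                "colocated_threshold_db": merged.threshold_db_colocated,
                "separated_threshold_db": merged.threshold_db,
                "srm_db": merged.threshold_db_colocated - merged.threshold_db,
            },
            columns=SRM_COLUMNS,
        )
        return out.reset_index(drop=True)

    def concat(self, other: "SessionTable") -> "SessionTable":
        trials = None
        if self.trials is not None and other.trials is not None:
            trials = pd.concat([self.trials, other.trials], ignore_index=True)
        return SessionTable(
            thresholds=pd.concat(
                [self.thresholds, other.thresholds], ignore_index=True
            ),
            trials=trials,
        )
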