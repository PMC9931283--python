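"""Steady-walking session detection and participant inclusion rules.

A steady-walking session is a maximal run of consecutive walking-labeled
30-second epochs of length >= 12 (six minutes — the daily-living analogue of
the Six Minute Walk Test).  A single non-walking epoch breaks a run; there is
no gap tolerance.  Participants are excluded first for insufficient device
wear (too few labeled epochs) and then for the absence of any qualifying
session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal_io import WALKING

__all__ = [
    "SessionCriteria",
    "SessionSet",
    "find_walking_runs",
    "select_steady_sessions",
    "apply_inclusion",
    "walking_distribution",
    "session_table",
]

#: 72 hours of labeled 30-s epochs — standard accelerometry wear-time QC floor.
DEFAULT_MIN_WEAR_EPOCHS = 8640

REASON_OK = "ok"
REASON_WEAR = "insufficient_wear"
REASON_WALKING = "insufficient_walking"


@dataclass(frozen=True)
class SessionCriteria:
    min_run_epochs: int = 12
    epoch_s: float = 30.0
    min_wear_epochs: int = DEFAULT_MIN_WEAR_EPOCHS

    def __post_init__(self) -> None:
        if self.min_run_epochs < 1:
            raise ValueError("min_run_epochs must be >= 1")

    @property
    def min_session_minutes(self) -> float:
        return self.min_run_epochs * self.epoch_s / 60.0


@dataclass
class SessionSet:
    """Detected runs and inclusion status for one participant."""

    participant_id: object
    runs: list[tuple[int, int]]  # all maximal walking runs (start, length)
    sessions: list[tuple[int, int]] = field(default_factory=list)  # qualifying runs
    included_epochs: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    n_labeled_epochs: int = 0
    reason: str = REASON_OK

    @property
    def included(self) -> bool:
        return self.reason == REASON_OK

    @property
    def walking_minutes(self) -> float:
        return len(self.included_epochs) * 0.5


def _is_walking(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind == "b":
        return arr
    return arr == WALKING


def find_walking_runs(epoch_labels) -> list[tuple[int, int]]:
    """All maximal runs of consecutive walking labels as (start, length)."""
    walking = _is_walking(epoch_labels).astype(np.int8)
    if walking.size == 0:
        return []
    padded = np.concatenate(([0], walking, [0]))
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def select_steady_sessions(
    runs, criteria: SessionCriteria | None = None
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Keep runs of length >= min_run_epochs; every epoch of a kept run counts.

    Returns (qualifying runs, sorted array of included epoch indices).
    """
    criteria = criteria or SessionCriteria()
    kept = [(s, ln) for s, ln in runs if ln >= criteria.min_run_epochs]
    if kept:
        included = np.concatenate([np.arange(s, s + ln) for s, ln in kept])
    else:
        included = np.empty(0, dtype=int)
    return kept, included


def build_session_set(
    participant_id, epoch_labels, criteria: SessionCriteria | None = None
) -> SessionSet:
    """Run detection + selection for one participant's label sequence."""
    criteria = criteria or SessionCriteria()
    runs = find_walking_runs(epoch_labels)
    sessions, included = select_steady_sessions(runs, criteria)
    return SessionSet(
        participant_id=participant_id,
        runs=runs,
        sessions=sessions,
        included_epochs=included,
        n_labeled_epochs=len(epoch_labels),
    )


def apply_inclusion(
    session_sets: list[SessionSet], criteria: SessionCriteria | None = None
) -> tuple[list[SessionSet], dict[str, int]]:
    """Apply the exclusion cascade: wear time first, then walking sufficiency.

    Mutates each SessionSet's reason code and returns (session_sets, tally).
    """
    criteria = criteria or SessionCriteria()
    tally = {REASON_OK: 0, REASON_WEAR: 0, REASON_WALKING: 0}
    for ss in session_sets:
        if ss.n_labeled_epochs < criteria.min_wear_epochs:
            ss.reason = REASON_WEAR
        elif not ss.sessions:
            ss.reason = REASON_WALKING
        else:
            ss.reason = REASON_OK
        tally[ss.reason] += 1
    return session_sets, tally


def walking_distribution(
    session_sets: list[SessionSet], bins=None
) -> tuple[pd.Series, np.ndarray, np.ndarray]:
    """Total steady-walking minutes per included participant, plus a histogram.

    Each included epoch contributes 0.5 minutes.  Returns
    (per-participant minutes, histogram counts, bin edges).
    """
    included = [ss for ss in session_sets if ss.included]
    minutes = pd.Series(
        {ss.participant_id: ss.walking_minutes for ss in included}, dtype=float
    )
    if bins is None:
        upper = max(float(minutes.max()) if len(minutes) else 6.0, 6.0)
        bins = np.arange(0.0, upper + 6.0, 6.0)
    counts, edges = np.histogram(minutes.to_numpy() if len(minutes) else [], bins=bins)
    return minutes, counts, edges


def session_table(session_sets: list[SessionSet]) -> pd.DataFrame:
    """Per-participant session summary (CSV-ready)."""
    return pd.DataFrame(
        {
            "participant_id": [ss.participant_id for ss in session_sets],
            "n_sessions": [len(ss.sessions) for ss in session_sets],
            "total_epochs": [len(ss.included_epochs) for ss in session_sets],
            "walking_minutes": [ss.walking_minutes for ss in session_sets],
            "included_flag": [ss.included for ss in session_sets],
            "exclusion_reason": [ss.reason for ss in session_sets],
        }
    )
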