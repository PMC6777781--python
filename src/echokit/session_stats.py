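"""Participant-level summaries of staircase sessions.

Aggregates single-session thresholds into the quantities reported per
participant: the mean threshold over a block of sessions, the Spearman rank
correlation between session order and threshold (a training-effect probe),
and per-day means with standard errors for multi-day testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .staircase import (
    StaircaseConfig,
    next_distance,
    read_trial_log,
    threshold_from_reversals,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ParticipantSummary",
    "mean_threshold",
    "spearman_session_trend",
    "per_day_summary",
    "thresholds_from_trial_log",
    "summarize_participant",
    "write_summary",
]


def mean_threshold(session_thresholds: Sequence[float]) -> float:
    """Arithmetic mean of single-session thresholds (metres)."""
    if len(session_thresholds) == 0:
        raise ValueError("session_thresholds must be nonempty")
    return float(np.mean(session_thresholds))


def spearman_session_trend(session_thresholds: Sequence[float]) -> float:
    """Spearman rank correlation between session order (1..n) and threshold.

    Ties receive average ranks.  Positive values indicate improvement over
    sessions (thresholds growing with practice).  Constant thresholds leave
    the correlation undefined; NaN is returned and a warning logged.
    """
    thresholds = np.asarray(session_thresholds, dtype=float)
    if thresholds.size < 3:
        raise ValueError("need at least 3 sessions for a rank correlation")
    if np.all(thresholds == thresholds[0]):
        logger.warning("constant thresholds: Spearman correlation is undefined")
        return float("nan")
    rho = stats.spearmanr(np.arange(1, thresholds.size + 1), thresholds).statistic
    return float(rho)


def per_day_summary(
    session_thresholds: Sequence[float], sessions_per_day: int
) -> pd.DataFrame:
    """Per-day mean and standard error of the mean.

    Sessions are grouped into consecutive blocks of ``sessions_per_day``;
    a ragged final block is an error.  SE uses the sample standard deviation
    (n-1 denominator) divided by sqrt(n).
    """
    thresholds = np.asarray(session_thresholds, dtype=float)
    if sessions_per_day < 1:
        raise ValueError("sessions_per_day must be positive")
    if thresholds.size == 0 or thresholds.size % sessions_per_day != 0:
        raise ValueError(
            f"{thresholds.size} sessions do not divide into days of {sessions_per_day}"
        )
    days = thresholds.reshape(-1, sessions_per_day)
    return pd.DataFrame(
        {
            "day": np.arange(1, days.shape[0] + 1),
            "mean_m": days.mean(axis=1),
            "se_m": days.std(axis=1, ddof=1) / np.sqrt(sessions_per_day),
        }
    )


@dataclass
class ParticipantSummary:
    """Summary statistics for one participant's block of sessions."""

    participant_id: str
    session_thresholds: list[float]
    mean_threshold: float
    spearman_rho: float
    per_day_means: pd.DataFrame | None = None


def thresholds_from_trial_log(
    trials: pd.DataFrame,
    n_avg: int = 10,
    config: StaircaseConfig | None = None,
) -> pd.Series:
    """Recompute per-session thresholds from a trial log.

    For each session the reversal trials are collected in order; each
    reversal contributes the distance the staircase moved to after that
    trial (reconstructed from the trial's outcome and the step matrix in
    ``config``, or the presented distance under the pre-step convention),
    and the threshold is the mean of the last ``n_avg`` of them.
    """
    if config is None:
        config = StaircaseConfig()
    post_step = config.reversal_distance == "post_step"
    out = {}
    for session_id, group in trials.groupby("session_id", sort=True):
        group = group.sort_values("trial")
        rev = group.loc[group["is_reversal"]]
        if post_step:
            reversal_distances = [
                next_distance(d, outcome, config)
                for d, outcome in zip(rev["distance_m"], rev["outcome"])
            ]
        else:
            reversal_distances = rev["distance_m"].to_list()
        out[session_id] = threshold_from_reversals(
            reversal_distances, n_avg, allow_partial=True
        )
    return pd.Series(out, name="threshold_m")


def summarize_participant(
    session_thresholds: Sequence[float],
    participant_id: str = "P1",
    sessions_per_day: int | None = None,
) -> ParticipantSummary:
    """Bundle mean, rank-order trend, and optional per-day summary."""
    per_day = (
        per_day_summary(session_thresholds, sessions_per_day)
        if sessions_per_day
        else None
    )
    return ParticipantSummary(
        participant_id=participant_id,
        session_thresholds=list(map(float, session_thresholds)),
        mean_threshold=mean_threshold(session_thresholds),
        spearman_rho=spearman_session_trend(session_thresholds),
        per_day_means=per_day,
    )


def write_summary(summaries: Sequence[ParticipantSummary], path) -> pd.DataFrame:
    """Write a per-participant summary CSV (participant, mean threshold, rho)."""
    df = pd.DataFrame(
        {
            "participant": [s.participant_id for s in summaries],
            "mean_threshold_m": [s.mean_threshold for s in summaries],
            "spearman_rho": [s.spearman_rho for s in summaries],
        }
    )
    df.to_csv(path, index=False)
    return df


def summarize_trial_log(path, sessions_per_day: int | None = None, n_avg: int = 10):
    """Read a trial-log CSV and summarize it as a single participant."""
    trials = read_trial_log(path)
    thresholds = thresholds_from_trial_log(trials, n_avg=n_avg)
    return summarize_participant(
        thresholds.to_list(), participant_id="from_log", sessions_per_day=sessions_per_day
    )
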