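"""SIAM adaptive yes-no staircase for echo-detection distance thresholds.

The staircase moves a sound-reflecting disk along a rail: correct detections
("hits") push the disk further away (harder), misses bring it closer, false
alarms bring it closer twice as fast, and correct rejections leave it in
place.  This is Kaernbach's single-interval adjustment matrix (SIAM) with
target t = 0.5, expressed in metres of disk distance.  A session ends after a
fixed number of reversals of the direction of movement, and the threshold is
the mean disk distance over the last few reversals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Protocol, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from numpy.random import Generator

logger = logging.getLogger(__name__)

__all__ = [
    "DiskState",
    "Response",
    "Outcome",
    "StaircaseConfig",
    "TrialRecord",
    "SessionResult",
    "ReversalDetector",
    "classify_outcome",
    "next_distance",
    "threshold_from_reversals",
    "run_session",
    "write_trial_log",
    "read_trial_log",
]


class DiskState(str, Enum):
    """Orientation of the reflecting disk: face-on or edge-on to the listener."""

    REFLECTING = "reflecting"
    NONREFLECTING = "nonreflecting"


class Response(str, Enum):
    """The listener's yes/no answer ("yes, the disk reflected")."""

    YES = "yes"
    NO = "no"


class Outcome(str, Enum):
    """The four cells of the yes-no detection table."""

    HIT = "hit"
    MISS = "miss"
    CORRECT_REJECTION = "correct_rejection"
    FALSE_ALARM = "false_alarm"


_OUTCOME_TABLE = {
    (DiskState.REFLECTING, Response.YES): Outcome.HIT,
    (DiskState.REFLECTING, Response.NO): Outcome.MISS,
    (DiskState.NONREFLECTING, Response.NO): Outcome.CORRECT_REJECTION,
    (DiskState.NONREFLECTING, Response.YES): Outcome.FALSE_ALARM,
}


def classify_outcome(disk_state: DiskState | str, response: Response | str) -> Outcome:
    """Classify a trial into hit / miss / correct rejection / false alarm.

    Parameters
    ----------
    disk_state
        Whether the disk was in reflecting or non-reflecting mode.
    response
        The listener's "yes" or "no" answer.
    """
    disk_state = DiskState(disk_state)
    response = Response(response)
    return _OUTCOME_TABLE[(disk_state, response)]


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameterization of the SIAM distance staircase.

    Distances are in metres.  The step sizes follow the SIAM t = 0.5
    adjustment matrix: a hit makes the task harder by ``step_hit``, a miss
    easier by ``step_miss``, a false alarm easier by twice that, and a
    correct rejection leaves the distance unchanged.  All distances are
    quantized to the rail's positioning grid and clipped to the rail's
    physical travel range.

    ``reversal_distance`` selects which distance a reversal contributes to
    the threshold estimate: ``"post_step"`` (default) records the distance
    the staircase moved to after the direction-changing trial — the level at
    which the new direction starts — while ``"pre_step"`` records the
    distance presented on that trial (the excursion's extremum).  The
    post-step convention reproduces the published chance-level bands of the
    original control script.
    """

    d_min: float = 0.7
    d_max: float = 3.9
    grid_step: float = 0.005
    start_distance: float = 0.7
    step_hit: float = 0.25
    step_miss: float = -0.25
    step_cr: float = 0.0
    step_fa: float = -0.50
    n_reversals_stop: int = 12
    n_reversals_avg: int = 10
    p_reflect: float = 0.5
    max_trials: int = 500
    reversal_distance: str = "post_step"

    def __post_init__(self) -> None:
        if not self.d_min < self.d_max:
            raise ValueError("d_min must be strictly less than d_max")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if not self.d_min <= self.start_distance <= self.d_max:
            raise ValueError("start_distance must lie within [d_min, d_max]")
        for name in ("step_hit", "step_miss", "step_cr", "step_fa"):
            step = getattr(self, name)
            ratio = step / self.grid_step
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(f"{name}={step} is not a multiple of grid_step")
        if not 1 <= self.n_reversals_avg <= self.n_reversals_stop:
            raise ValueError("need 1 <= n_reversals_avg <= n_reversals_stop")
        if not 0 < self.p_reflect < 1:
            raise ValueError("p_reflect must be in (0, 1)")
        if self.max_trials < 1:
            raise ValueError("max_trials must be positive")
        if self.reversal_distance not in ("post_step", "pre_step"):
            raise ValueError("reversal_distance must be 'post_step' or 'pre_step'")

    def step_for(self, outcome: Outcome) -> float:
        """Signed distance change prescribed by the adjustment matrix."""
        return {
            Outcome.HIT: self.step_hit,
            Outcome.MISS: self.step_miss,
            Outcome.CORRECT_REJECTION: self.step_cr,
            Outcome.FALSE_ALARM: self.step_fa,
        }[Outcome(outcome)]

    def snap(self, distance: float) -> float:
        """Quantize a distance onto the rail's positioning grid."""
        return round(round(distance / self.grid_step) * self.grid_step, 9)


def next_distance(
    current_distance: float, outcome: Outcome | str, config: StaircaseConfig
) -> float:
    """Distance of the next trial: step per the matrix, clip to the rail, snap.

    Steps that would leave ``[d_min, d_max]`` are clipped to the bound — the
    rail cannot move further.
    """
    stepped = current_distance + config.step_for(Outcome(outcome))
    return config.snap(min(max(stepped, config.d_min), config.d_max))


class ReversalDetector:
    """Tracks the staircase's direction of movement and flags reversals.

    Zero steps (correct rejections) are transparent: they neither establish a
    direction nor clear the remembered one.  A clipped step at a rail bound
    still counts with its intended sign, so a responder pinned at a bound can
    reverse and the session can terminate.
    """

    def __init__(self) -> None:
        self._pending: int = 0

    def update(self, direction: int) -> bool:
        """Feed the sign of the latest intended step; return True on a reversal."""
        if direction == 0:
            return False
        is_reversal = self._pending != 0 and direction != self._pending
        self._pending = direction
        return is_reversal


@dataclass(frozen=True, slots=True)
class TrialRecord:
    """One staircase trial."""

    index: int  # 1-based trial ordinal
    distance: float  # metres, on the positioning grid
    disk_state: DiskState
    response: Response
    outcome: Outcome
    is_reversal: bool


@dataclass
class SessionResult:
    """One completed staircase session.

    ``threshold`` is the arithmetic mean of the last ``n_reversals_avg``
    reversal distances when the session stopped normally.  If the safety cap
    on trials fired first, ``stopped_normally`` is False and the threshold is
    computed from whatever reversals accumulated (NaN if none).
    """

    trials: list[TrialRecord]
    reversal_distances: list[float]
    threshold: float
    stopped_normally: bool
    config: StaircaseConfig = field(repr=False, default_factory=StaircaseConfig)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def to_frame(self, session_id: int | str = 1) -> pd.DataFrame:
        """Trial log as a DataFrame (one row per trial)."""
        return pd.DataFrame(
            {
                "session_id": session_id,
                "trial": [t.index for t in self.trials],
                "distance_m": [round(t.distance, 3) for t in self.trials],
                "disk_state": [t.disk_state.value for t in self.trials],
                "response": [t.response.value for t in self.trials],
                "outcome": [t.outcome.value for t in self.trials],
                "is_reversal": [t.is_reversal for t in self.trials],
            }
        )


class ObserverProtocol(Protocol):  # pragma: no cover - typing aid
    def respond(
        self, distance: float, disk_state: DiskState, rng: "Generator"
    ) -> Response: ...


def threshold_from_reversals(
    reversal_distances: Sequence[float],
    n_avg: int,
    *,
    allow_partial: bool = False,
) -> float:
    """Mean of the final ``n_avg`` reversal distances.

    With ``allow_partial`` the mean is taken over whatever reversals exist
    (NaN for an empty list); otherwise fewer than ``n_avg`` reversals is an
    error.
    """
    n = len(reversal_distances)
    if n < n_avg:
        if not allow_partial:
            raise ValueError(
                f"need at least {n_avg} reversals, got {n} "
                "(pass allow_partial=True to average what is available)"
            )
        if n == 0:
            return float("nan")
        return float(np.mean(reversal_distances))
    return float(np.mean(np.asarray(reversal_distances)[-n_avg:]))


def run_session(
    observer: ObserverProtocol,
    config: StaircaseConfig | None = None,
    rng: "Generator | int | None" = None,
    *,
    record_trials: bool = True,
) -> SessionResult:
    """Run one SIAM staircase session against a response-generating observer.

    Each trial draws the disk state (Bernoulli ``p_reflect``), queries the
    observer, classifies the outcome, flags reversals of the movement
    direction, and steps the distance.  The session stops once
    ``n_reversals_stop`` reversals have accumulated; a safety cap of
    ``max_trials`` guards degenerate observers and is flagged via
    ``stopped_normally=False``.

    Parameters
    ----------
    observer
        Object with ``respond(distance, disk_state, rng) -> Response``.
    config
        Staircase parameterization; defaults to the standard rail setup.
    rng
        ``numpy.random.Generator`` or integer seed.  Equal seeds give
        bit-identical sessions.
    record_trials
        If False, skip building per-trial records (used by large Monte-Carlo
        calibrations; reversals and threshold are unaffected).
    """
    if config is None:
        config = StaircaseConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    distance = config.snap(config.start_distance)
    detector = ReversalDetector()
    reversals: list[float] = []
    trials: list[TrialRecord] = []
    stopped_normally = False
    p_reflect = config.p_reflect

    post_step = config.reversal_distance == "post_step"

    for index in range(1, config.max_trials + 1):
        disk_state = (
            DiskState.REFLECTING
            if rng.random() < p_reflect
            else DiskState.NONREFLECTING
        )
        response = observer.respond(distance, disk_state, rng)
        outcome = _OUTCOME_TABLE[(disk_state, Response(response))]
        step = config.step_for(outcome)
        direction = (step > 0) - (step < 0)
        is_reversal = detector.update(direction)
        new_distance = next_distance(distance, outcome, config)
        if is_reversal:
            reversals.append(new_distance if post_step else distance)
        if record_trials:
            trials.append(
                TrialRecord(index, distance, disk_state, response, outcome, is_reversal)
            )
        if len(reversals) >= config.n_reversals_stop:
            stopped_normally = True
            break
        distance = new_distance

    if not stopped_normally:
        logger.warning(
            "session hit the %d-trial safety cap with %d/%d reversals",
            config.max_trials,
            len(reversals),
            config.n_reversals_stop,
        )
        warnings.warn(
            "staircase session terminated by the max-trials safety cap",
            RuntimeWarning,
            stacklevel=2,
        )
    threshold = threshold_from_reversals(
        reversals, config.n_reversals_avg, allow_partial=not stopped_normally
    )
    return SessionResult(trials, reversals, threshold, stopped_normally, config)


# -- trial-log serialization -------------------------------------------------

_LOG_COLUMNS = [
    "session_id",
    "trial",
    "distance_m",
    "disk_state",
    "response",
    "outcome",
    "is_reversal",
]


def write_trial_log(
    sessions: Sequence[SessionResult],
    path,
    session_ids: Sequence[int | str] | None = None,
) -> pd.DataFrame:
    """Write one or more sessions to a trial-log CSV (one row per trial)."""
    if session_ids is None:
        session_ids = list(range(1, len(sessions) + 1))
    frames = [s.to_frame(sid) for s, sid in zip(sessions, session_ids, strict=True)]
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False, float_format="%.3f")
    return df


def read_trial_log(path) -> pd.DataFrame:
    """Read a trial-log CSV, validating the column layout."""
    df = pd.read_csv(path)
    missing = set(_LOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial log is missing columns: {sorted(missing)}")
    df["is_reversal"] = df["is_reversal"].astype(bool)
    return df
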