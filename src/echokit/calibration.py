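"""Monte-Carlo calibration of the SIAM staircase.

Two questions are answered by simulation rather than analysis (the staircase's
stationary distribution near a rail bound has no convenient closed form):

* What threshold does a stimulus-blind ("random") responder earn?  Simulating
  many virtual participants, each completing a block of sessions, yields the
  central 95% bands of single-session thresholds and of per-participant mean
  thresholds — the gray chance regions against which human performance is
  judged.
* Does the staircase recover a known sensitivity threshold?  For a
  signal-detection observer whose d' crosses the procedure's equilibrium
  sensitivity at a known distance, session thresholds should concentrate
  there.

Note on the procedure's target: with the step matrix (hit +s, miss -s, CR 0,
false alarm -2s) and equiprobable disk states, the expected step vanishes
where hit rate minus false-alarm rate equals 0.5 — Kaernbach's SIAM t = 0.5.
For an unbiased equal-variance Gaussian observer that is d' = 2 z(0.75)
≈ 1.35 (75% correct), not d' = 1; :func:`equilibrium_dprime` computes the
crossing for any step configuration and criterion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .observers import RandomObserver, SDTObserver, _phi
from .staircase import StaircaseConfig, run_session

__all__ = [
    "CalibrationResult",
    "calibrate_random_responder",
    "recover_threshold_distance",
    "equilibrium_dprime",
    "dprime_crossing_distance",
]

#: Percentile pair defining the central 95% band; empirical quantiles with
#: linear interpolation (numpy's default method).
_BAND = (2.5, 97.5)


@dataclass
class CalibrationResult:
    """Chance-level calibration of the staircase for a given observer.

    ``interval_single`` brackets 95% of single-session thresholds;
    ``interval_mean12`` brackets 95% of per-participant means over
    ``sessions_per_participant`` sessions.  Both underlying distributions are
    retained so either reading of "10,000 runs" (sessions or participants)
    can be checked.
    """

    single_session_thresholds: np.ndarray = field(repr=False)
    mean12_thresholds: np.ndarray = field(repr=False)
    interval_single: tuple[float, float]
    interval_mean12: tuple[float, float]
    n_reps: int
    sessions_per_participant: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "interval_single_m": list(self.interval_single),
            "interval_mean_m": list(self.interval_mean12),
            "percentiles": list(_BAND),
            "n_participants": self.n_reps,
            "sessions_per_participant": self.sessions_per_participant,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _band(values: np.ndarray) -> tuple[float, float]:
    lo, hi = np.percentile(values, _BAND)
    return float(lo), float(hi)


def calibrate_random_responder(
    config: StaircaseConfig | None = None,
    n_reps: int = 10_000,
    seed: int | None = None,
    *,
    sessions_per_participant: int = 12,
    observer=None,
) -> CalibrationResult:
    """Simulate chance-level performance under the staircase.

    Runs ``n_reps`` independent virtual participants, each completing
    ``sessions_per_participant`` staircase sessions with a stimulus-blind
    responder (p_yes = 0.5 unless another observer is given), and returns the
    central 95% bands of the single-session thresholds and of the
    per-participant mean thresholds.

    ``n_reps`` of at least ~1000 is recommended for stable percentiles.
    """
    if config is None:
        config = StaircaseConfig()
    if observer is None:
        observer = RandomObserver(0.5)
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    singles = np.empty((n_reps, sessions_per_participant))
    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        for j in range(sessions_per_participant):
            singles[i, j] = run_session(
                observer, config, rng, record_trials=False
            ).threshold
    means = singles.mean(axis=1)
    flat = singles.ravel()
    return CalibrationResult(
        single_session_thresholds=flat,
        mean12_thresholds=means,
        interval_single=_band(flat),
        interval_mean12=_band(means),
        n_reps=n_reps,
        sessions_per_participant=sessions_per_participant,
        seed=seed,
    )


def equilibrium_dprime(
    config: StaircaseConfig | None = None, criterion: float = 0.0
) -> float:
    """Sensitivity at which the staircase's expected step is zero.

    Solves, in d', the balance equation

        p_reflect * [H(d') * step_hit + (1 - H) * step_miss]
          + (1 - p_reflect) * [F(d') * step_fa + (1 - F) * step_cr] = 0

    with H = Phi(d'/2 - c) and F = Phi(-d'/2 - c).  For the default matrix
    and c = 0 this is d' = 2 z(0.75) ≈ 1.349.
    """
    if config is None:
        config = StaircaseConfig()

    def expected_step(d: float) -> float:
        h = _phi(d / 2.0 - criterion)
        f = _phi(-d / 2.0 - criterion)
        return config.p_reflect * (h * config.step_hit + (1 - h) * config.step_miss) + (
            1 - config.p_reflect
        ) * (f * config.step_fa + (1 - f) * config.step_cr)

    lo, hi = 0.0, 20.0
    if expected_step(lo) * expected_step(hi) > 0:
        raise ValueError("expected step does not change sign for d' in [0, 20]")
    return float(brentq(expected_step, lo, hi, xtol=1e-10))


def dprime_crossing_distance(observer: SDTObserver, target_dprime: float) -> float:
    """Distance at which the linear-decay observer's d' equals ``target_dprime``."""
    if observer.dprime_fn is not None:
        raise ValueError("analytic crossing is defined only for the linear decay form")
    if observer.decay_per_m <= 0:
        raise ValueError("decay_per_m must be positive for a crossing to exist")
    return observer.ref_distance + (observer.dprime_at_ref - target_dprime) / observer.decay_per_m


def recover_threshold_distance(
    sdt_observer: SDTObserver,
    config: StaircaseConfig | None = None,
    n_sessions: int = 200,
    seed: int | None = None,
    *,
    return_sessions: bool = False,
):
    """Mean staircase threshold over repeated sessions with an SDT observer.

    The staircase converges where the observer's d'(distance) crosses the
    procedure's equilibrium sensitivity (see :func:`equilibrium_dprime`); the
    observer's decay should place that crossing strictly inside
    (d_min, d_max), otherwise the recovered value piles up at a rail bound.
    """
    if config is None:
        config = StaircaseConfig()
    rng = np.random.default_rng(seed)
    thresholds = np.array(
        [
            run_session(sdt_observer, config, rng, record_trials=False).threshold
            for _ in range(n_sessions)
        ]
    )
    mean = float(thresholds.mean())
    if return_sessions:
        return mean, thresholds
    return mean
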