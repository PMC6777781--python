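"""Staircase engine: outcome table, stepping, reversals, sessions."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from echokit import (
    DiskState,
    Outcome,
    RandomObserver,
    Response,
    SDTObserver,
    StaircaseConfig,
    classify_outcome,
    next_distance,
    run_session,
    threshold_from_reversals,
)
from echokit.observers import FixedResponseObserver, PerfectObserver
from echokit.staircase import ReversalDetector

OUTCOME_TABLE = [
    (DiskState.REFLECTING, Response.YES, Outcome.HIT),
    (DiskState.REFLECTING, Response.NO, Outcome.MISS),
    (DiskState.NONREFLECTING, Response.NO, Outcome.CORRECT_REJECTION),
    (DiskState.NONREFLECTING, Response.YES, Outcome.FALSE_ALARM),
]


@pytest.mark.parametrize("disk_state,response,expected", OUTCOME_TABLE)
def test_outcome_classification(disk_state, response, expected):
    assert classify_outcome(disk_state, response) is expected
    # string inputs are accepted too
    assert classify_outcome(disk_state.value, response.value) is expected


def test_outcome_classification_is_bijective():
    outcomes = {classify_outcome(d, r) for d, r, _ in OUTCOME_TABLE}
    assert outcomes == set(Outcome)


def test_invalid_enum_rejected():
    with pytest.raises(ValueError):
        classify_outcome("sideways", "yes")
    with pytest.raises(ValueError):
        classify_outcome("reflecting", "maybe")


@pytest.mark.parametrize(
    "current,outcome,expected",
    [
        (1.50, Outcome.FALSE_ALARM, 1.00),  # false alarm steps down 50 cm
        (0.70, Outcome.MISS, 0.70),  # clipped at the near rail end
        (3.80, Outcome.HIT, 3.90),  # 4.05 clipped to the far rail end
        (2.00, Outcome.HIT, 2.25),
        (2.00, Outcome.CORRECT_REJECTION, 2.00),
    ],
)
def test_next_distance(current, outcome, expected, config):
    assert next_distance(current, outcome, config) == pytest.approx(expected)


@given(
    outcomes=st.lists(st.sampled_from(list(Outcome)), min_size=1, max_size=200),
    start_steps=st.integers(min_value=0, max_value=640),
)
def test_distances_stay_on_grid_within_bounds(outcomes, start_steps):
    """Folding any outcome sequence keeps the distance on the 0.5 cm grid in [0.7, 3.9]."""
    config = StaircaseConfig(start_distance=round(0.7 + 0.005 * start_steps, 9))
    d = config.start_distance
    for outcome in outcomes:
        d = next_distance(d, outcome, config)
        assert config.d_min - 1e-12 <= d <= config.d_max + 1e-12
        assert round(d / config.grid_step) * config.grid_step == pytest.approx(d)


@pytest.mark.parametrize(
    "directions,expected_flags",
    [
        ([+1, +1, -1], [False, False, True]),
        ([+1, 0, 0, +1], [False, False, False, False]),
        ([+1, 0, -1], [False, False, True]),  # zeros are transparent
        ([-1, +1, -1, +1], [False, True, True, True]),
        ([0, 0, -1], [False, False, False]),  # no pending direction yet
    ],
)
def test_reversal_detection(directions, expected_flags):
    det = ReversalDetector()
    assert [det.update(d) for d in directions] == expected_flags


@given(st.lists(st.sampled_from([-1, 0, 1]), max_size=50))
def test_zero_steps_transparent_to_reversals(directions):
    """A direction sequence and the same sequence with zeros removed flag identically."""
    with_zeros = ReversalDetector()
    without = ReversalDetector()
    flags_a = [with_zeros.update(d) for d in directions if True]
    flags_b = [without.update(d) for d in directions if d != 0]
    assert [f for d, f in zip(directions, flags_a) if d != 0] == flags_b
    assert not any(f for d, f in zip(directions, flags_a) if d == 0)


@pytest.mark.parametrize(
    "reversals,n_avg,expected",
    [
        ([2.40] * 12, 10, 2.40),
        ([0.95, 0.70] * 6, 10, 0.825),
        (list(range(1, 13)), 10, 7.5),
    ],
)
def test_threshold_from_reversals(reversals, n_avg, expected):
    assert threshold_from_reversals(reversals, n_avg) == pytest.approx(expected)


def test_threshold_needs_enough_reversals():
    with pytest.raises(ValueError):
        threshold_from_reversals([1.0, 2.0], 10)
    assert threshold_from_reversals([1.0, 2.0], 10, allow_partial=True) == 1.5
    assert np.isnan(threshold_from_reversals([], 10, allow_partial=True))


def test_config_validation():
    with pytest.raises(ValueError):
        StaircaseConfig(d_min=2.0, d_max=1.0)
    with pytest.raises(ValueError):
        StaircaseConfig(start_distance=5.0)
    with pytest.raises(ValueError):
        StaircaseConfig(step_hit=0.2501)
    with pytest.raises(ValueError):
        StaircaseConfig(n_reversals_avg=13)
    with pytest.raises(ValueError):
        StaircaseConfig(p_reflect=0.0)
    with pytest.raises(ValueError):
        StaircaseConfig(reversal_distance="midpoint")


def test_run_session_is_reproducible(config):
    a = run_session(RandomObserver(0.5), config, rng=42)
    b = run_session(RandomObserver(0.5), config, rng=42)
    assert a.trials == b.trials
    assert a.reversal_distances == b.reversal_distances
    assert a.threshold == b.threshold


def test_session_threshold_matches_reversal_mean(config):
    res = run_session(SDTObserver(), config, rng=7)
    assert res.stopped_normally
    assert len(res.reversal_distances) == config.n_reversals_stop
    assert res.threshold == pytest.approx(
        np.mean(res.reversal_distances[-config.n_reversals_avg :])
    )
    # reversal flags in the trial log agree with the reversal count
    assert sum(t.is_reversal for t in res.trials) == config.n_reversals_stop


def test_near_ceiling_observer_ends_near_far_rail(config):
    """A near-perfect observer's threshold sits within one step of d_max."""
    observer = SDTObserver(dprime_fn=lambda d: 4.0)
    cfg = StaircaseConfig(max_trials=2000)
    res = run_session(observer, cfg, rng=3)
    assert res.threshold >= cfg.d_max - cfg.step_hit - 1e-9


def test_perfect_observer_never_reverses(config):
    """Only hits and correct rejections: the staircase climbs and never turns."""
    with pytest.warns(RuntimeWarning):
        res = run_session(PerfectObserver(), config, rng=0)
    assert not res.stopped_normally
    assert res.reversal_distances == []
    assert np.isnan(res.threshold)
    assert res.trials[-1].distance == pytest.approx(config.d_max)


def test_always_no_observer_pins_at_near_rail(config):
    """No hits ever: the distance stays at d_min and the trial cap fires."""
    with pytest.warns(RuntimeWarning):
        res = run_session(FixedResponseObserver(Response.NO), config, rng=0)
    assert not res.stopped_normally
    assert res.reversal_distances == []
    assert all(t.distance == pytest.approx(config.d_min) for t in res.trials)


def test_random_responder_mean_step_drift():
    """Away from the rails, the expected step of a p(yes)=.5 random responder
    is .25(+.25) + .25(-.25) + .25(0) + .25(-.50) = -0.125 m per trial."""
    cfg = StaircaseConfig(
        d_min=-200.0,
        d_max=200.0,
        start_distance=0.0,
        n_reversals_stop=10_000,
        n_reversals_avg=1,
        max_trials=500,
    )
    steps = []
    rng = np.random.default_rng(2024)
    for _ in range(20):
        with pytest.warns(RuntimeWarning):
            res = run_session(RandomObserver(0.5), cfg, rng)
        d = [t.distance for t in res.trials]
        steps.extend(np.diff(d))
    assert np.mean(steps) == pytest.approx(-0.125, abs=0.01)


def test_trial_log_round_trip(tmp_path, config):
    from echokit import read_trial_log, write_trial_log

    sessions = [run_session(SDTObserver(), config, rng=s) for s in (1, 2)]
    path = tmp_path / "trials.csv"
    write_trial_log(sessions, path)
    df = read_trial_log(path)
    assert sorted(df.session_id.unique()) == [1, 2]
    assert len(df) == sum(s.n_trials for s in sessions)
    assert df.is_reversal.dtype == bool
    # distances survive the 3-decimal serialization exactly (5 mm grid)
    first = sessions[0].trials
    logged = df[df.session_id == 1].sort_values("trial").distance_m.to_numpy()
    assert np.allclose(logged, [t.distance for t in first])
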