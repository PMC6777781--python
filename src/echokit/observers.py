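"""Synthetic observers: response-generating stand-ins for human listeners.

Two models matter here.  A :class:`RandomObserver` answers "yes" with a fixed
probability regardless of the stimulus — the chance-level reference used to
calibrate what a staircase threshold means when the listener cannot hear the
reflection at all.  An :class:`SDTObserver` is an equal-variance Gaussian
signal-detection observer whose sensitivity d' falls off with disk distance,
so the staircase has a genuine threshold to find.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Callable

from .staircase import DiskState, Response

if TYPE_CHECKING:  # pragma: no cover
    from numpy.random import Generator

__all__ = [
    "RandomObserver",
    "SDTObserver",
    "PerfectObserver",
    "FixedResponseObserver",
    "proportion_correct_unbiased",
    "observer_from_spec",
]


def _phi(x: float) -> float:
    """Standard normal CDF."""
    return 0.5 * math.erfc(-x / math.sqrt(2.0))


def proportion_correct_unbiased(dprime: float) -> float:
    """Percent correct of an unbiased yes-no observer at sensitivity ``dprime``.

    Under the equal-variance Gaussian model with equal priors and criterion
    c = 0, both the hit rate and the correct-rejection rate equal
    Phi(d'/2), so that is also the overall proportion correct.
    d' = 1.0 gives Phi(0.5) = 0.6915, i.e. 69% correct.
    """
    if dprime < 0:
        raise ValueError("dprime must be non-negative")
    return _phi(dprime / 2.0)


@dataclass(frozen=True)
class RandomObserver:
    """Stimulus-blind responder: "yes" with probability ``p_yes`` on every trial."""

    p_yes: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_yes <= 1.0:
            raise ValueError("p_yes must be in [0, 1]")

    def respond(
        self, distance: float, disk_state: DiskState, rng: "Generator"
    ) -> Response:
        return Response.YES if rng.random() < self.p_yes else Response.NO


@dataclass(frozen=True)
class SDTObserver:
    """Equal-variance Gaussian observer with distance-dependent sensitivity.

    Sensitivity decays linearly with distance and is floored at zero:

        d'(x) = max(0, dprime_at_ref - decay_per_m * (x - ref_distance))

    With decision criterion ``criterion`` (c = 0 is unbiased):

        p(yes | reflecting)     = Phi(d'(x)/2 - c)
        p(yes | non-reflecting) = Phi(-d'(x)/2 - c)

    A custom ``dprime_fn`` (distance -> d') overrides the linear form.
    """

    dprime_at_ref: float = 3.0
    ref_distance: float = 0.7
    decay_per_m: float = 1.0
    criterion: float = 0.0
    dprime_fn: Callable[[float], float] | None = None

    def dprime(self, distance: float) -> float:
        """Sensitivity at a given disk distance (never negative)."""
        if self.dprime_fn is not None:
            return max(0.0, self.dprime_fn(distance))
        return max(
            0.0, self.dprime_at_ref - self.decay_per_m * (distance - self.ref_distance)
        )

    def p_yes(self, distance: float, disk_state: DiskState) -> float:
        """Model probability of a "yes" at this distance and disk state."""
        d = self.dprime(distance)
        sign = 1.0 if DiskState(disk_state) is DiskState.REFLECTING else -1.0
        return _phi(sign * d / 2.0 - self.criterion)

    def respond(
        self, distance: float, disk_state: DiskState, rng: "Generator"
    ) -> Response:
        return (
            Response.YES
            if rng.random() < self.p_yes(distance, disk_state)
            else Response.NO
        )


@dataclass(frozen=True)
class PerfectObserver:
    """Always answers correctly (infinite sensitivity); a limit-case probe."""

    def respond(
        self, distance: float, disk_state: DiskState, rng: "Generator"
    ) -> Response:
        return (
            Response.YES
            if DiskState(disk_state) is DiskState.REFLECTING
            else Response.NO
        )


@dataclass(frozen=True)
class FixedResponseObserver:
    """Always gives the same answer; a degenerate-input probe."""

    response: Response = Response.NO

    def respond(
        self, distance: float, disk_state: DiskState, rng: "Generator"
    ) -> Response:
        return Response(self.response)


def observer_from_spec(spec: str | dict):
    """Build an observer from a JSON string or dict, e.g.

    ``{"kind": "random", "p_yes": 0.5}`` or
    ``{"kind": "sdt", "dprime_at_ref": 3, "ref_distance": 0.7,
    "decay_per_m": 1.0, "criterion": 0}``.
    """
    if isinstance(spec, str):
        spec = json.loads(spec)
    spec = dict(spec)
    kind = spec.pop("kind", None)
    kinds = {
        "random": RandomObserver,
        "sdt": SDTObserver,
        "perfect": PerfectObserver,
        "fixed": FixedResponseObserver,
    }
    if kind not in kinds:
        raise ValueError(f"unknown observer kind {kind!r}; expected one of {sorted(kinds)}")
    return kinds[kind](**spec)
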