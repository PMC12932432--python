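"""Global mechanical tension of the network.

Tension is a single spatially uniform scalar eps(t), represented as a
piecewise-constant schedule. It enters the synaptic model in two places:

* the baseline release potential J(eps) = J + c1 * (1 - exp(-c2 * x)),
  with x = (eps - eps0) / eps0 the relative tension excursion, which
  grows with tension (more vesicles clustered at the terminal);
* the vesicle recovery time constant tau_R(eps) = tau0 * exp(-x), which
  shrinks with tension (faster replenishment of the releasable pool).

Tension changes are treated as instantaneous condition switches, not as
a relaxing mechanical variable.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp
from typing import Sequence

import numpy as np

from .params import ConfigurationError, SynapseParams


class ScheduleError(ValueError):
    """Raised when a time falls outside the schedule span."""


@dataclass(frozen=True)
class TensionSchedule:
    """Piecewise-constant tension trajectory.

    ``segments`` is an ordered sequence of ``(t_start_ms, t_end_ms, eps)``
    with half-open intervals ``[t_start, t_end)``, contiguous and
    non-overlapping. ``eps0`` is the resting tension used to express
    relative excursions.
    """

    segments: tuple
    eps0: float = 0.001

    def __post_init__(self) -> None:
        segs = tuple((float(a), float(b), float(e)) for a, b, e in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ConfigurationError("schedule needs at least one segment")
        for (a, b, e) in segs:
            if b <= a:
                raise ConfigurationError("segment must have t_end > t_start")
            if e <= 0:
                raise ConfigurationError("tension must be positive")
        for (_, b0, _), (a1, _, _) in zip(segs[:-1], segs[1:]):
            if a1 != b0:
                raise ConfigurationError("segments must be contiguous and ordered")

    @classmethod
    def constant(cls, eps: float, t_end_ms: float, eps0: float = 0.001,
                 t_start_ms: float = 0.0) -> "TensionSchedule":
        return cls(segments=((t_start_ms, t_end_ms, eps),), eps0=eps0)

    @classmethod
    def from_relative(cls, segments_rel: Sequence, eps0: float = 0.001) -> "TensionSchedule":
        """Build from ``(t_start, t_end, eps_rel)`` with eps = eps_rel * eps0."""
        return cls(tuple((a, b, r * eps0) for a, b, r in segments_rel), eps0=eps0)

    @property
    def t_start(self) -> float:
        return self.segments[0][0]

    @property
    def t_end(self) -> float:
        return self.segments[-1][1]

    def eps_at(self, t_ms: float) -> float:
        """Tension at time ``t_ms`` (half-open segment convention)."""
        for a, b, e in self.segments:
            if a <= t_ms < b:
                return e
        raise ScheduleError(f"t={t_ms} ms outside schedule span "
                            f"[{self.t_start}, {self.t_end})")

    def boundaries_between(self, t0: float, t1: float) -> np.ndarray:
        """Segment start times strictly inside (t0, t1)."""
        starts = np.array([a for a, _, _ in self.segments])
        return starts[(starts > t0) & (starts < t1)]


def eps_at(schedule: TensionSchedule, t_ms: float) -> float:
    return schedule.eps_at(t_ms)


def relative_excursion(eps: float, eps0: float) -> float:
    """(eps - eps0) / eps0: 0 at rest, +0.5 at 150% of baseline."""
    return (eps - eps0) / eps0


def baseline_release(eps: float, params: SynapseParams) -> float:
    """Tension-dependent history-independent release potential J(eps), mV."""
    if eps <= 0:
        raise ConfigurationError("tension must be positive")
    x = relative_excursion(eps, params.eps0)
    return params.j_base + params.c1 * (1.0 - exp(-params.c2 * x))


def recovery_tau(eps: float, params: SynapseParams) -> float:
    """Tension-dependent vesicle recovery time constant tau_R(eps), ms."""
    if eps <= 0:
        raise ConfigurationError("tension must be positive")
    x = relative_excursion(eps, params.eps0)
    return params.tau0 * exp(-x)
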