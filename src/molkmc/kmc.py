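"""Rejection-free kinetic Monte Carlo.

One step of the rejection-free algorithm: draw u1 uniform on (0, 1], choose
the event i satisfying F(p_{i-1}) < u1 <= F(p_i) on the cumulative
probability function F, draw u2 uniform on (0, 1], and advance time by
Δt = -ln(u2) / R where R is the total rate. The boundary rule is the "<="
exactly; zero-rate events can never satisfy it and are never chosen.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field
from itertools import accumulate
from typing import Any, Iterable

from .errors import MolkmcError


@dataclass
class Event:
    """A candidate reaction with its first-order rate (s⁻¹)."""

    recipe: Any
    rate: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.rate >= 0.0) or math.isinf(self.rate):
            raise MolkmcError(f"event rate must be finite and >= 0, got {self.rate}")


class EventList:
    """Ordered candidate events with cached total rate and cumulative law.

    The total rate uses compensated summation (math.fsum), so it is exact
    for long event lists; the last cumulative entry is pinned to 1 so the
    (0, 1] draw can never fall off the end.
    """

    def __init__(self, events: Iterable[Event] = ()):
        self.events: list[Event] = list(events)
        self._rates = [e.rate for e in self.events]
        self.total_rate: float = math.fsum(self._rates)
        if self.total_rate > 0.0:
            self.probabilities = [r / self.total_rate for r in self._rates]
            cum = list(accumulate(self.probabilities))
            cum[-1] = 1.0
            self.cumulative = cum
        else:
            self.probabilities = [0.0] * len(self._rates)
            self.cumulative = []

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


def total_rate(el: EventList) -> float:
    """Sum of all event rates, R (compensated summation)."""
    return el.total_rate


@dataclass
class KMCResult:
    """Outcome of one rejection-free kMC step."""

    chosen_index: int
    delta_t: float
    u1: float
    u2: float


def rf_kmc_step(el: EventList, rng) -> KMCResult | None:
    """One rejection-free kMC step; None signals an empty event list (R = 0).

    ``rng`` must provide ``random()`` returning uniforms on [0, 1); exactly
    two draws are consumed (u1 then u2), each mapped onto (0, 1] so the
    logarithm is always finite.
    """
    if el.total_rate <= 0.0:
        return None
    u1 = 1.0 - rng.random()
    u2 = 1.0 - rng.random()
    chosen = bisect_left(el.cumulative, u1)
    delta_t = -math.log(u2) / el.total_rate
    return KMCResult(chosen_index=chosen, delta_t=delta_t, u1=u1, u2=u2)
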