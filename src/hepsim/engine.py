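"""Simulation clock, seeded randomness, and the delayed-event queue.

Both analogs advance in synchronous simulation cycles.  Every stochastic
decision is a comparison of a uniform draw on [0, 1) against an event
probability, and all draws for one Monte Carlo trial come from a single
seeded stream, which makes trials bit-reproducible.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field
from typing import Any, Iterator

import numpy as np

__all__ = [
    "RngStream",
    "ScheduledEvent",
    "EventQueue",
    "SimulationClock",
    "bernoulli",
]


class RngStream:
    """A seeded uniform random stream backing one Monte Carlo trial.

    Thin wrapper around :class:`numpy.random.Generator` that fixes the
    seeding contract: identical seeds produce identical draw sequences.
    Trial ``i`` of a protocol uses ``base_seed + i``.
    """

    def __init__(self, seed: int) -> None:
        if seed < 0:
            raise ValueError("seed must be non-negative")
        self.seed = int(seed)
        self._gen = np.random.default_rng(self.seed)

    @property
    def generator(self) -> np.random.Generator:
        return self._gen

    def uniform(self, size: int | None = None):
        """Draw from U[0, 1)."""
        return self._gen.random(size)

    def bernoulli(self, p: float) -> bool:
        return bernoulli(p, self)

    def binomial(self, n, p):
        return self._gen.binomial(n, p)

    def integers(self, low, high=None, size=None):
        return self._gen.integers(low, high, size=size)

    def multinomial(self, n, pvals, size=None):
        return self._gen.multinomial(n, pvals, size=size)

    def shuffle(self, x) -> None:
        self._gen.shuffle(x)

    def permutation(self, x):
        return self._gen.permutation(x)

    def choice(self, a, size=None, replace=True, p=None):
        return self._gen.choice(a, size=size, replace=replace, p=p)


def bernoulli(p: float, rng: RngStream) -> bool:
    """True iff the next uniform draw is < ``p``; consumes exactly one draw.

    ``p = 0`` can never fire (a draw is still consumed) and ``p = 1``
    always fires, since draws lie on [0, 1).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {p}")
    return float(rng.uniform()) < p


@dataclass(frozen=True)
class ScheduledEvent:
    """A deferred action: a bound-solute release or a queued enzyme removal.

    ``payload`` identifies the affected component; its structure is owned
    by whichever handler scheduled the event.
    """

    fire_cycle: int
    action: str
    payload: Any = None


class EventQueue:
    """Min-heap of :class:`ScheduledEvent`, ordered by fire cycle.

    Ties fire in insertion order.  Events fire exactly once, at the start
    of their fire cycle, before any handler executes.
    """

    def __init__(self) -> None:
        self._heap: list[tuple[int, int, ScheduledEvent]] = []
        self._counter = itertools.count()

    def __len__(self) -> int:
        return len(self._heap)

    def schedule(self, event: ScheduledEvent, current_cycle: int) -> None:
        if event.fire_cycle < current_cycle:
            raise ValueError(
                f"cannot schedule event in the past "
                f"(fire_cycle={event.fire_cycle} < cycle={current_cycle})"
            )
        heapq.heappush(self._heap, (event.fire_cycle, next(self._counter), event))

    def pop_due(self, cycle: int) -> Iterator[ScheduledEvent]:
        """Yield and remove every event with ``fire_cycle <= cycle``."""
        while self._heap and self._heap[0][0] <= cycle:
            yield heapq.heappop(self._heap)[2]

    def peek_cycle(self) -> int | None:
        return self._heap[0][0] if self._heap else None


@dataclass
class SimulationClock:
    """Cycle counter with the analog-to-referent time mapping.

    The culture analog maps 1 cycle to 1 minute; the liver analog maps
    1 cycle to 1 second (a 60-fold finer temporal grain, needed to resolve
    hepatic transit times).
    """

    cycle_limit: int
    seconds_per_cycle: float = 60.0
    cycle: int = field(default=0)

    def __post_init__(self) -> None:
        if self.cycle_limit <= 0:
            raise ValueError("cycle_limit must be positive")

    @property
    def done(self) -> bool:
        return self.cycle >= self.cycle_limit

    def advance(self) -> None:
        if self.done:
            raise RuntimeError("clock advanced past cycle_limit")
        self.cycle += 1

    def to_seconds(self, cycle: int | None = None) -> float:
        c = self.cycle if cycle is None else cycle
        return c * self.seconds_per_cycle
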