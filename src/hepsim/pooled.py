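"""Count-based (pooled-binomial) primitives for the production simulators.

Pools of identical unbound solutes sharing a compartment are advanced with
binomial/multinomial draws instead of per-object Bernoulli draws; the
resulting distributions are identical, which the test suite checks against
the agent-per-object mode on small populations.
"""

from __future__ import annotations

import heapq

import numpy as np

__all__ = ["split_counts", "PooledDownReg", "sequential_bind"]


def split_counts(
    gen: np.random.Generator, counts: np.ndarray, pvals: np.ndarray
) -> list[np.ndarray]:
    """Split each entry of ``counts`` multinomially among len(pvals) bins.

    Conditional-binomial construction, vectorized over the counts array;
    ``pvals`` must sum to 1.  Returns one array per bin.
    """
    counts = np.asarray(counts, dtype=np.int64)
    pvals = np.asarray(pvals, dtype=float)
    out: list[np.ndarray] = []
    remaining = counts.copy()
    mass = 1.0
    for j in range(len(pvals) - 1):
        p = pvals[j] / mass if mass > 1e-12 else 0.0
        draw = gen.binomial(remaining, min(max(p, 0.0), 1.0))
        out.append(draw)
        remaining = remaining - draw
        mass -= pvals[j]
    out.append(remaining)
    return out


def sequential_bind(
    gen: np.random.Generator,
    n_solutes: int,
    total: int,
    bound: int,
    initial: int,
    pBind: float,
    bindExponent: float,
    mode: str,
) -> int:
    """Number of binds when ``n_solutes`` each attempt one bind in turn.

    The probability is re-evaluated after every success (it depends on the
    current bound count in variable mode); draws are consumed one per
    attempting solute, matching the object-level handler.
    """
    if n_solutes <= 0 or total - bound <= 0:
        return 0
    draws = gen.random(n_solutes)
    n_binds = 0
    for u in draws:
        unbound = total - (bound + n_binds)
        if unbound <= 0:
            break
        if mode == "stepwise":
            p = pBind
        else:
            p = pBind * (unbound / initial) ** bindExponent if initial > 0 else 0.0
        if u < p:
            n_binds += 1
    return n_binds


class PooledDownReg:
    """Vectorized down-regulation state for one enzyme type across cells.

    Mirrors the object-level handler exactly: per cell, at most one removal
    queued per cycle; queued removals fire ``delay`` cycles after the queue
    tail; a firing with every enzyme bound defers to the next release; and
    replenishment needs zero cytokines, an empty queue, and a count below
    the basal (initial) level.
    """

    def __init__(
        self,
        initial: np.ndarray,
        pRemove: float,
        delay: int,
        pReplenish: float,
    ) -> None:
        self.initial = np.asarray(initial, dtype=np.int64).copy()
        n = len(self.initial)
        self.total = self.initial.copy()
        self.pending = np.zeros(n, dtype=np.int64)
        self.deferred = np.zeros(n, dtype=np.int64)
        self.tail_fire = np.zeros(n, dtype=np.int64)
        self.pRemove = float(pRemove)
        self.delay = int(delay)
        self.pReplenish = float(pReplenish)
        self._heap: list[tuple[int, int]] = []  # (fire_cycle, cell index)

    # -- event phase -------------------------------------------------------
    def fire_due(self, now: int, bound: np.ndarray) -> None:
        """Execute queued removals due at ``now`` (start of cycle)."""
        while self._heap and self._heap[0][0] <= now:
            _, i = heapq.heappop(self._heap)
            self.pending[i] -= 1
            if self.total[i] - bound[i] > 0:
                self.total[i] -= 1
            elif self.total[i] > 0:
                # all bound: defer until the next release frees an enzyme
                self.deferred[i] += 1
                self.pending[i] += 1
            # else nothing left to remove; the event evaporates

    def on_release(self, idx: np.ndarray, bound: np.ndarray) -> None:
        """Execute deferred removals for cells that just freed enzymes."""
        for i in np.atleast_1d(idx):
            while self.deferred[i] > 0 and self.total[i] - bound[i] > 0:
                self.total[i] -= 1
                self.deferred[i] -= 1
                self.pending[i] -= 1

    # -- handler phase -----------------------------------------------------
    def step(self, now: int, n_cytokines: np.ndarray, gen: np.random.Generator) -> None:
        n_cyt = np.asarray(n_cytokines)
        # removal-scheduling path
        with_cyt = np.flatnonzero(n_cyt > 0)
        if with_cyt.size:
            # first success among n independent Bernoulli(pRemove) chances
            p_sched = 1.0 - (1.0 - self.pRemove) ** n_cyt[with_cyt]
            hits = with_cyt[gen.random(with_cyt.size) < p_sched]
            for i in hits:
                fire = max(now, int(self.tail_fire[i])) + self.delay
                heapq.heappush(self._heap, (fire, int(i)))
                self.tail_fire[i] = fire
                self.pending[i] += 1
        # replenish path
        if self.pReplenish > 0.0:
            eligible = (n_cyt == 0) & (self.pending == 0) & (self.total < self.initial)
            idx = np.flatnonzero(eligible)
            if idx.size:
                created = idx[gen.random(idx.size) < self.pReplenish]
                self.total[created] += 1
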