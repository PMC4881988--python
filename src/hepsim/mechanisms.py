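"""The five cell-mechanism handlers and the binding-probability modes.

Each mechanism is probabilistic: an event with probability *p* occurs iff a
uniform draw on [0, 1) is below *p*.  Handlers act only on the contents of
the cell executing them:

* binding — unbound bindable solutes attach to unbound enzymes and are
  released after *bindCycles* cycles (hepatocytes, endothelial cells);
* metabolism — bound solutes on metabolic enzymes are converted to their
  metabolite, freeing the enzyme (hepatocytes);
* inflammation — Kupffer cells produce at most one cytokine per cycle when
  the resident inflammatory-stimulus count exceeds a threshold;
* down-regulation — cytokines inside a hepatocyte schedule delayed enzyme
  removals (a growing queue when cytokine is sustained); enzymes slowly
  replenish toward basal once cytokine clears and the queue drains;
* degradation — unbound solutes whose type defines *pDegrade* are removed.

This module gives the per-cell, object-level semantics; ``pooled`` holds
the distribution-equivalent vectorized forms used by production runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .components import (
    Cell,
    Enzyme,
    EnzymeType,
    Solute,
    TypeRegistry,
    HEPATOCYTE,
    KUPFFER,
)
from .engine import EventQueue, RngStream, ScheduledEvent, SimulationClock, bernoulli

__all__ = [
    "BindingConfig",
    "InflammationConfig",
    "DownRegConfig",
    "binding_probability",
    "binding_handler",
    "metabolism_handler",
    "cytokine_probability",
    "inflammation_handler",
    "downregulation_handler",
    "degradation_handler",
    "fire_due_removals",
    "release_bound_pair",
    "HANDLER_NAMES",
]

HANDLER_NAMES = (
    "binding",
    "metabolism",
    "inflammation",
    "downregulation",
    "degradation",
)

STEPWISE = "stepwise"
VARIABLE = "variable"


@dataclass(frozen=True)
class BindingConfig:
    mode: str = STEPWISE
    pBind: float = 0.25
    bindCycles: int = 10

    def __post_init__(self) -> None:
        if self.mode not in (STEPWISE, VARIABLE):
            raise ValueError(f"bindingMode must be stepwise or variable, got {self.mode!r}")
        if not 0.0 <= self.pBind <= 1.0:
            raise ValueError("pBind must lie in [0, 1]")
        if self.bindCycles < 1:
            raise ValueError("bindCycles must be a positive integer")


@dataclass(frozen=True)
class InflammationConfig:
    """Cytokine-production parameters.

    ``form`` selects the reading of the production-probability equation:
    "ratio" (default) uses lambda = (n - threshold)/cytokineExponent, the
    Poisson-style reading; "power" uses (n - threshold)**(1/cytokineExponent)
    and is retained for sensitivity analysis.
    """

    inflammatoryThreshold: int = 1
    cytokineThreshold: int = 2
    cytokineExponent: float = 3.0
    form: str = "ratio"

    def __post_init__(self) -> None:
        if self.inflammatoryThreshold < 0 or self.cytokineThreshold < 0:
            raise ValueError("thresholds must be non-negative")
        if self.cytokineExponent <= 0:
            raise ValueError("cytokineExponent must be positive")
        if self.form not in ("ratio", "power"):
            raise ValueError("form must be 'ratio' or 'power'")


@dataclass(frozen=True)
class DownRegConfig:
    """Down-regulation parameters for one enzyme type.

    ``pRemove`` falls back to the enzyme type's own value when None
    (the liver analog keys it per type; the culture analog sets it here).
    """

    delay: int = 30
    pReplenish: float = 0.007
    pRemove: float | None = None

    def __post_init__(self) -> None:
        if self.delay < 0:
            raise ValueError("delay must be non-negative")
        if not 0.0 <= self.pReplenish <= 1.0:
            raise ValueError("pReplenish must lie in [0, 1]")
        if self.pRemove is not None and not 0.0 <= self.pRemove <= 1.0:
            raise ValueError("pRemove must lie in [0, 1]")

    def premove_for(self, enzyme_type: EnzymeType) -> float:
        if self.pRemove is not None:
            return self.pRemove
        if enzyme_type.pRemove is None:
            raise ValueError(f"no pRemove for enzyme type {enzyme_type.name!r}")
        return enzyme_type.pRemove


def binding_probability(
    mode: str,
    pBind: float,
    n_bound: int,
    n_total: int,
    n_initial: int,
    bindExponent: float = 1.0,
) -> float:
    """Probability of one binding event against one enzyme type.

    Stepwise mode recapitulates the generation-1 enzymes: the probability
    is *pBind* whenever at least one enzyme is unbound, else zero —
    insensitive to enzyme abundance, which is why simulated down-regulation
    had no effect on clearance under that ontology.  Variable mode makes
    the probability occupancy- and abundance-dependent:

        p = pBind * ((total - bound) / total_initial) ** bindExponent

    It reaches zero at full occupancy, and removing enzymes (lowering
    ``total``) shifts the whole curve down.
    """
    if not 0 <= n_bound <= n_total:
        raise ValueError(f"inconsistent enzyme state: bound={n_bound}, total={n_total}")
    if n_initial < 1:
        # A cell that never had this enzyme type cannot bind.
        return 0.0
    unbound = n_total - n_bound
    if mode == STEPWISE:
        return pBind if unbound > 0 else 0.0
    if mode == VARIABLE:
        return pBind * (unbound / n_initial) ** bindExponent
    raise ValueError(f"unknown binding mode {mode!r}")


def release_bound_pair(solute: Solute, enzyme: Enzyme, cell: Cell) -> None:
    """Unbind a solute/enzyme pair (scheduled release), leaving both in place."""
    if enzyme.bound_solute is not solute:
        return  # pair already separated (e.g. by metabolism); stale event
    enzyme.bound_solute = None
    solute.bound_to = None
    _execute_deferred_removals(cell)


def binding_handler(
    cell: Cell,
    config: BindingConfig,
    registry: TypeRegistry,
    rng: RngStream,
    event_queue: EventQueue,
    clock: SimulationClock,
) -> int:
    """Attempt binds for every unbound bindable solute in the cell.

    Solutes are visited in shuffled order; each tries one bind against each
    enzyme type that accepts it (shuffled), stopping once bound.  A success
    schedules the release *bindCycles* cycles later.  Returns the number of
    binds formed.
    """
    if cell.cell_type == KUPFFER:
        return 0
    candidates = [s for s in cell.solutes if s.type.bindable and not s.bound]
    if not candidates:
        return 0
    rng.shuffle(candidates)
    n_binds = 0
    for solute in candidates:
        accepting = [
            et
            for et in registry.enzymes_accepting(solute.type.name)
            if et.name in cell.enzymes
        ]
        if len(accepting) > 1:
            rng.shuffle(accepting)
        for et in accepting:
            total = cell.enzyme_count(et.name)
            unbound = cell.unbound_enzymes(et.name)
            p = binding_probability(
                config.mode,
                config.pBind,
                total - len(unbound),
                total,
                cell.initial_enzyme_count.get(et.name, 0),
                et.bindExponent,
            )
            if unbound and bernoulli(p, rng):
                enzyme = unbound[0]
                enzyme.bound_solute = solute
                solute.bound_to = enzyme
                event_queue.schedule(
                    ScheduledEvent(
                        fire_cycle=clock.cycle + config.bindCycles,
                        action="solute-release",
                        payload=(solute, enzyme, cell),
                    ),
                    clock.cycle,
                )
                n_binds += 1
                break
    return n_binds


def metabolism_handler(cell: Cell, registry: TypeRegistry, rng: RngStream) -> int:
    """Metabolize bound solutes held by metabolic enzymes.

    Each bound solute converts with its (zonated) ``pMetabolize``: the
    solute is removed, one metabolite of its product type is created in the
    same cell (none if the product list is empty), and the enzyme is freed.
    Returns the number of metabolism events.
    """
    if cell.cell_type != HEPATOCYTE:
        return 0
    n_events = 0
    for solute in list(cell.solutes):
        enzyme = solute.bound_to
        if enzyme is None or not enzyme.type.metabolic:
            continue
        p = solute.type.pmetabolize_at(cell.d)
        if bernoulli(p, rng):
            enzyme.bound_solute = None
            solute.bound_to = None
            cell.remove_solute(solute)
            products = solute.type.metabolicProduct
            if products:
                name = products[0] if len(products) == 1 else str(rng.choice(list(products)))
                cell.add_solute(Solute(registry.solute(name)))
            n_events += 1
    if n_events:
        _execute_deferred_removals(cell)
    return n_events


def cytokine_probability(n_stimuli: int, cfg: InflammationConfig) -> float:
    """Probability a Kupffer cell produces one cytokine this cycle.

    Zero at or below the inflammatory threshold; above it,
    1 - exp(-excess / cytokineExponent), strictly increasing in the excess
    stimulus and saturating at one.
    """
    if n_stimuli < 0:
        raise ValueError("stimulus count must be non-negative")
    excess = n_stimuli - cfg.inflammatoryThreshold
    if excess <= 0:
        return 0.0
    if cfg.form == "ratio":
        lam = excess / cfg.cytokineExponent
    else:  # power
        lam = excess ** (1.0 / cfg.cytokineExponent)
    return 1.0 - math.exp(-lam)


def inflammation_handler(
    cell: Cell,
    cfg: InflammationConfig,
    registry: TypeRegistry,
    rng: RngStream,
    cytokine_type: str = "cytokine",
) -> bool:
    """Kupffer-cell cytokine production; at most one cytokine per cycle.

    Production requires stimulus above ``inflammatoryThreshold`` and at
    most ``cytokineThreshold`` cytokines already resident (the
    coarse-grain stand-in for feedback suppression of cytokine signaling).
    """
    if cell.cell_type != KUPFFER:
        return False
    n_stimuli = sum(1 for s in cell.solutes if s.type.inflammatory)
    if n_stimuli <= cfg.inflammatoryThreshold:
        return False
    n_cyt = cell.solute_count(cytokine_type)
    if n_cyt > cfg.cytokineThreshold:
        return False
    if bernoulli(cytokine_probability(n_stimuli, cfg), rng):
        cell.add_solute(Solute(registry.solute(cytokine_type)))
        return True
    return False


def downregulation_handler(
    cell: Cell,
    enzyme_type: EnzymeType,
    cfg: DownRegConfig,
    rng: RngStream,
    clock: SimulationClock,
    cytokine_type: str = "cytokine",
) -> None:
    """One enzyme type's removal/replenish pathway inside one hepatocyte.

    Removal path: each resident cytokine grants one Bernoulli(pRemove)
    chance; the first success queues a removal firing ``delay`` cycles
    after the queue tail (at most one scheduled per cycle — the damper
    that prevents abrupt enzyme loss).  Replenish path: only with zero
    cytokines, an empty queue, and a count below basal may one enzyme be
    created with probability ``pReplenish``.
    """
    if cell.cell_type != HEPATOCYTE or not enzyme_type.downRegulated:
        return
    state = cell.downreg.get(enzyme_type.name)
    if state is None:
        return
    n_cyt = cell.solute_count(cytokine_type, include_bound=False)
    if n_cyt >= 1:
        p_remove = cfg.premove_for(enzyme_type)
        for _ in range(n_cyt):
            if bernoulli(p_remove, rng):
                tail = (
                    state.pending_removals[-1]
                    if state.pending_removals
                    else clock.cycle
                )
                state.pending_removals.append(max(clock.cycle, tail) + cfg.delay)
                for enz in cell.enzymes.get(enzyme_type.name, []):
                    if not enz.marked_for_removal and not enz.bound:
                        enz.marked_for_removal = True
                        break
                break  # at most one scheduled per cycle
    else:
        below_basal = (
            cell.enzyme_count(enzyme_type.name)
            < cell.initial_enzyme_count.get(enzyme_type.name, 0)
        )
        if state.queue_empty and below_basal and bernoulli(cfg.pReplenish, rng):
            cell.enzymes[enzyme_type.name].append(Enzyme(enzyme_type))


def fire_due_removals(cell: Cell, clock: SimulationClock) -> int:
    """Execute queued enzyme removals whose fire cycle has arrived.

    A firing removes one unbound enzyme; if every enzyme of the type is
    bound, the removal defers and executes on the next release (bound
    enzymes are never removed).  Returns the number of enzymes removed.
    """
    removed = 0
    for type_name, state in cell.downreg.items():
        while state.pending_removals and state.pending_removals[0] <= clock.cycle:
            state.pending_removals.pop(0)
            if _remove_one_unbound(cell, type_name):
                removed += 1
            elif cell.enzyme_count(type_name) > 0:
                state.deferred += 1
            # else: nothing left to remove; the event evaporates
    return removed


def degradation_handler(cell: Cell, rng: RngStream) -> int:
    """Remove unbound degradable solutes resident in the cell.

    Applies in every cell type, with no per-cycle cap.  Bound solutes and
    types without ``pDegrade`` are untouched.  Returns the removal count.
    """
    n_removed = 0
    for solute in list(cell.solutes):
        if solute.bound or solute.type.pDegrade is None:
            continue
        if bernoulli(solute.type.pDegrade, rng):
            cell.remove_solute(solute)
            n_removed += 1
    return n_removed


def _remove_one_unbound(cell: Cell, type_name: str) -> bool:
    enzymes = cell.enzymes.get(type_name, [])
    pick = None
    for enz in enzymes:
        if not enz.bound and (pick is None or enz.marked_for_removal):
            pick = enz
            if enz.marked_for_removal:
                break
    if pick is None:
        return False
    enzymes.remove(pick)
    return True


def _execute_deferred_removals(cell: Cell) -> None:
    for type_name, state in cell.downreg.items():
        while state.deferred > 0 and _remove_one_unbound(cell, type_name):
            state.deferred -= 1
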