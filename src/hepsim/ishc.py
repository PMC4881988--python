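"""In silico hepatocyte/Kupffer-cell culture (ISHC).

Two stacked rectangular grids: *cell space* maps to the cell monolayer
(each point holds at most one cell) and *media space* maps to the culture
media above it.  Solutes hop vertically between the grids with asymmetric
probabilities (*pExitCell* up, *pExitMedia* down — media is the much larger
volume) or step laterally to a von Neumann neighbor with toroidal wrap.
One simulation cycle maps to one minute.  Measurements sample the whole
system.

Two representations are provided with identical stochastic semantics:
``mode="pooled"`` advances per-point solute counts with binomial draws
(fast; used by production protocols), ``mode="agent"`` advances individual
solute objects with one uniform draw per decision (slow; used to verify
the pooled distributions at small N).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .components import TypeRegistry
from .engine import RngStream, SimulationClock
from .mechanisms import DownRegConfig, InflammationConfig
from .pooled import PooledDownReg, split_counts

__all__ = ["ISHCSettings", "CultureModel", "build_ishc"]

EMPTY, HEP, KC = 0, 1, 2


@dataclass
class ISHCSettings:
    """Whole-model culture parameters (defaults follow the validating runs)."""

    registry: TypeRegistry
    width: int = 25
    height: int = 25
    kcDensity: float = 0.0
    hepDensity: float = 0.0
    enzymesPerCellMin: int = 4
    enzymesPerCellMax: int = 8
    inflammation: InflammationConfig = field(default_factory=InflammationConfig)
    downreg: DownRegConfig = field(default_factory=DownRegConfig)
    cytokine_type: str = "cytokine"
    mode: str = "pooled"

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("grid dimensions must be positive")
        if not (0.0 <= self.kcDensity <= 1.0 and 0.0 <= self.hepDensity <= 1.0):
            raise ValueError("densities must lie in [0, 1]")
        if self.kcDensity + self.hepDensity > 1.0 + 1e-12:
            raise ValueError("kcDensity + hepDensity must not exceed 1")
        if self.enzymesPerCellMin > self.enzymesPerCellMax:
            raise ValueError("enzymesPerCellMin exceeds enzymesPerCellMax")
        if self.mode not in ("pooled", "agent"):
            raise ValueError("mode must be 'pooled' or 'agent'")


class CultureModel:
    """The two-grid culture world, its cells, and per-cycle dynamics."""

    def __init__(self, settings: ISHCSettings, rng: RngStream) -> None:
        self.settings = settings
        self.rng = rng
        self.registry = settings.registry
        self.type_names = list(self.registry.solutes)
        self.type_index = {n: i for i, n in enumerate(self.type_names)}
        self.n_types = len(self.type_names)
        H, W = settings.height, settings.width
        self.clock = SimulationClock(cycle_limit=10**9, seconds_per_cycle=60.0)

        # cell layout: independent per-point draws against the densities
        u = rng.uniform((H, W))
        self.cell_kind = np.where(
            u < settings.kcDensity,
            KC,
            np.where(u < settings.kcDensity + settings.hepDensity, HEP, EMPTY),
        ).astype(np.int8)
        self.kc_points = np.flatnonzero((self.cell_kind == KC).ravel())
        self.hep_points = np.flatnonzero((self.cell_kind == HEP).ravel())

        # solute state: counts[space, y, x, type]; space 0 = cell, 1 = media
        self.counts = np.zeros((2, H, W, self.n_types), dtype=np.int64)
        self.degraded = np.zeros(self.n_types, dtype=np.int64)

        # per-hepatocyte enzymes (single culture enzyme type per registry)
        self.enzyme_pools: dict[str, PooledDownReg] = {}
        self.static_enzymes: dict[str, np.ndarray] = {}
        gen = rng.generator
        n_hep = len(self.hep_points)
        for et in self.registry.enzymes.values():
            if "hepatocyte" not in et.expressingCellTypes:
                continue
            initial = gen.integers(
                settings.enzymesPerCellMin,
                settings.enzymesPerCellMax + 1,
                size=n_hep,
            )
            if et.downRegulated:
                self.enzyme_pools[et.name] = PooledDownReg(
                    initial,
                    settings.downreg.premove_for(et),
                    settings.downreg.delay,
                    settings.downreg.pReplenish,
                )
            else:
                self.static_enzymes[et.name] = initial.astype(np.int64)

        self._inflammatory_idx = [
            self.type_index[n]
            for n, st in self.registry.solutes.items()
            if st.inflammatory
        ]
        self._cyt_idx = self.type_index.get(settings.cytokine_type)
        # agent mode keeps explicit per-solute coordinates
        self._agent_solutes: list[list[int]] = []  # [type_idx, space, y, x]

    # -- dosing ------------------------------------------------------------
    def dose(self, solute_type: str, amount: int) -> None:
        """Scatter ``amount`` solutes uniformly over both grids' points."""
        if amount < 0:
            raise ValueError("dose amount must be non-negative")
        if amount == 0:
            return
        t = self.type_index[solute_type]
        if self.settings.mode == "agent":
            H, W = self.settings.height, self.settings.width
            gen = self.rng.generator
            for _ in range(amount):
                space = int(gen.integers(2))
                y = int(gen.integers(H))
                x = int(gen.integers(W))
                self._agent_solutes.append([t, space, y, x])
                self.counts[space, y, x, t] += 1
        else:
            if self.registry.solute(solute_type).bindable:
                raise NotImplementedError(
                    "pooled culture runs do not support bindable solutes; "
                    "use mode='agent'"
                )
            H, W = self.settings.height, self.settings.width
            flat = self.rng.generator.multinomial(
                amount, np.full(2 * H * W, 1.0 / (2 * H * W))
            )
            self.counts[..., t] += flat.reshape(2, H, W)

    # -- per-cycle dynamics --------------------------------------------------
    def run_cycle(self) -> None:
        """Advance one cycle: events, movement, cell handlers, clock."""
        now = self.clock.cycle + 1
        zeros = None
        for pool in self.enzyme_pools.values():
            if zeros is None:
                zeros = np.zeros(len(pool.total), dtype=np.int64)
            pool.fire_due(now, zeros)  # culture enzymes are never bound
        if self.settings.mode == "agent":
            self._move_agent()
        else:
            self._move_pooled()
        order = self.rng.permutation(3)
        for h in order:
            if h == 0:
                self._inflammation(now)
            elif h == 1:
                self._downregulation(now)
            else:
                self._degradation()
        self.clock.advance()

    def run(self, cycles: int) -> None:
        for _ in range(cycles):
            self.run_cycle()

    # -- measurement ---------------------------------------------------------
    def measure(self, selector: str) -> int:
        """Whole-system count of a solute type or enzyme type."""
        if selector in self.type_index:
            return int(self.counts[..., self.type_index[selector]].sum())
        if selector in self.enzyme_pools:
            return int(self.enzyme_pools[selector].total.sum())
        if selector in self.static_enzymes:
            return int(self.static_enzymes[selector].sum())
        raise KeyError(f"unknown selector {selector!r}")

    def total_solutes(self) -> int:
        return int(self.counts.sum())

    # -- internals -----------------------------------------------------------
    def _exit_probs(self, t: int) -> tuple[float, float]:
        st = self.registry.solute(self.type_names[t])
        return (st.pExitCell or 0.0, st.pExitMedia or 0.0)

    def _move_pooled(self) -> None:
        gen = self.rng.generator
        for t in range(self.n_types):
            if not self.counts[..., t].any():
                continue
            pec, pem = self._exit_probs(t)
            C = self.counts[0, :, :, t]
            M = self.counts[1, :, :, t]
            up = gen.binomial(C, pec)
            down = gen.binomial(M, pem)
            lat_c = self._lateral(gen, C - up)
            lat_m = self._lateral(gen, M - down)
            self.counts[0, :, :, t] = lat_c + down
            self.counts[1, :, :, t] = lat_m + up

    @staticmethod
    def _lateral(gen: np.random.Generator, movers: np.ndarray) -> np.ndarray:
        """Uniform step to one of the 4 toroidal neighbors, for all movers."""
        parts = split_counts(gen, movers, np.full(4, 0.25))
        return (
            np.roll(parts[0], 1, axis=0)
            + np.roll(parts[1], -1, axis=0)
            + np.roll(parts[2], 1, axis=1)
            + np.roll(parts[3], -1, axis=1)
        )

    def _move_agent(self) -> None:
        gen = self.rng.generator
        H, W = self.settings.height, self.settings.width
        for s in self._agent_solutes:
            t, space, y, x = s
            self.counts[space, y, x, t] -= 1
            pec, pem = self._exit_probs(t)
            p_vert = pec if space == 0 else pem
            if gen.random() < p_vert:
                space = 1 - space
            else:
                step = int(gen.integers(4))
                if step == 0:
                    y = (y + 1) % H
                elif step == 1:
                    y = (y - 1) % H
                elif step == 2:
                    x = (x + 1) % W
                else:
                    x = (x - 1) % W
            s[1], s[2], s[3] = space, y, x
            self.counts[space, y, x, t] += 1

    def _inflammation(self, now: int) -> None:
        if self._cyt_idx is None or not self.kc_points.size:
            return
        cfg = self.settings.inflammation
        gen = self.rng.generator
        cellspace = self.counts[0].reshape(-1, self.n_types)
        stim = sum(cellspace[self.kc_points, i] for i in self._inflammatory_idx)
        stim = np.asarray(stim)
        ncyt = cellspace[self.kc_points, self._cyt_idx]
        eligible = (stim > cfg.inflammatoryThreshold) & (
            ncyt <= cfg.cytokineThreshold
        )
        idx = np.flatnonzero(eligible)
        if not idx.size:
            return
        excess = stim[idx] - cfg.inflammatoryThreshold
        if cfg.form == "ratio":
            p = 1.0 - np.exp(-excess / cfg.cytokineExponent)
        else:
            p = 1.0 - np.exp(-(excess ** (1.0 / cfg.cytokineExponent)))
        produced = idx[gen.random(idx.size) < p]
        if produced.size:
            pts = self.kc_points[produced]
            np.add.at(cellspace, (pts, self._cyt_idx), 1)
            if self.settings.mode == "agent":
                H, W = self.settings.height, self.settings.width
                for p_ in pts:
                    self._agent_solutes.append(
                        [self._cyt_idx, 0, int(p_) // W, int(p_) % W]
                    )

    def _downregulation(self, now: int) -> None:
        if self._cyt_idx is None or not self.hep_points.size:
            return
        cellspace = self.counts[0].reshape(-1, self.n_types)
        ncyt = cellspace[self.hep_points, self._cyt_idx]
        for pool in self.enzyme_pools.values():
            pool.step(now, ncyt, self.rng.generator)

    def _degradation(self) -> None:
        gen = self.rng.generator
        occupied = (self.cell_kind > 0).ravel()
        cellspace = self.counts[0].reshape(-1, self.n_types)
        for t in range(self.n_types):
            p = self.registry.solute(self.type_names[t]).pDegrade
            if p is None or p == 0.0:
                continue
            if self.settings.mode == "agent":
                removed: list[int] = []
                W = self.settings.width
                for k, s in enumerate(self._agent_solutes):
                    ti, space, y, x = s
                    if ti != t or space != 0:
                        continue
                    if self.cell_kind[y, x] == EMPTY:
                        continue
                    if gen.random() < p:
                        removed.append(k)
                        self.counts[0, y, x, t] -= 1
                        self.degraded[t] += 1
                for k in reversed(removed):
                    self._agent_solutes.pop(k)
            else:
                resident = cellspace[:, t] * occupied
                deg = gen.binomial(resident, p)
                cellspace[:, t] -= deg
                self.degraded[t] += int(deg.sum())


def build_ishc(settings: ISHCSettings, rng: RngStream) -> CultureModel:
    """Construct a culture model from settings (cells drawn per density)."""
    return CultureModel(settings, rng)
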