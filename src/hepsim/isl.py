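"""In silico liver (ISL): body compartment plus a lobule sinusoid network.

The lobule is a layered directed graph from the portal vein (PV) to the
central vein (CV).  Each node is a *sinusoid segment*: an innermost core
(plug flow, ``flowRate`` grid points per cycle), then concentric spaces in
fixed radial order — blood-cell interface, endothelial space (endothelial
and Kupffer cells), space of Disse, hepatocyte space (hepatocytes), and a
terminal bile canal.  Body holds the injected solute pools and transfers a
fraction ``sampleRatio * sampleRatioFactor`` of each to first-layer cores
every cycle; solutes surviving to the CV return to body the next cycle.
Hepatocyte metabolic capacity is zonated: ``pMetabolize`` interpolates
linearly from its minimum at the PV to its maximum at the CV.  One cycle
maps to one second.

Solutes are represented as pooled per-compartment counts advanced with
binomial/multinomial draws (distributionally identical to per-object
Bernoulli stepping; see ``pooled``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .components import TypeRegistry
from .engine import RngStream, SimulationClock
from .mechanisms import BindingConfig, DownRegConfig, InflammationConfig
from .pooled import PooledDownReg, sequential_bind, split_counts

__all__ = ["ISLSettings", "LiverModel", "build_lobule", "apply_vd_change"]


@dataclass
class ISLSettings:
    """Whole-model liver parameters (defaults follow the validating runs).

    The lobule graph dimensions are declared assumptions (the analog's
    referent lobule geometry is configurable, not data): ``layers`` x
    ``segments_per_layer`` segments, each with a ``core_length``-point core
    and ``space_circumference`` x ``core_length`` cellular lattices.
    """

    registry: TypeRegistry
    layers: int = 5
    segments_per_layer: int = 9
    core_length: int = 10
    space_circumference: int = 2
    ecDensity: float = 0.66
    kcDensity: float = 0.33
    hepDensity: float = 0.9
    enzymesPerCellMin: int = 4
    enzymesPerCellMax: int = 8
    sampleRatio: float = 0.00115
    forwardBias: float = 0.2
    lateralBias: float = 0.6
    flowRate: int = 2
    max_successors: int = 3
    binding: BindingConfig = field(
        default_factory=lambda: BindingConfig(mode="variable")
    )
    inflammation: InflammationConfig = field(
        default_factory=lambda: InflammationConfig(
            inflammatoryThreshold=3, cytokineThreshold=2, cytokineExponent=3.0
        )
    )
    downreg: DownRegConfig = field(
        default_factory=lambda: DownRegConfig(delay=600, pReplenish=0.0001)
    )
    cytokine_type: str = "cytokine"

    def __post_init__(self) -> None:
        if self.layers < 2:
            raise ValueError("lobule needs at least 2 layers")
        for name in ("ecDensity", "kcDensity", "hepDensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.ecDensity + self.kcDensity > 1.0 + 1e-12:
            raise ValueError("ecDensity + kcDensity must not exceed 1")
        if not 0.0 <= self.sampleRatio <= 1.0:
            raise ValueError("sampleRatio must lie in [0, 1]")
        if self.forwardBias + self.lateralBias > 1.0 + 1e-12:
            raise ValueError("forwardBias + lateralBias must not exceed 1")
        if self.flowRate < 1:
            raise ValueError("flowRate must be a positive integer")

    def kernel(self) -> dict[str, float]:
        """Movement kernel for non-core spaces.

        Forward and lateral carry the two published bias weights; the
        remainder splits equally among backward, radial-in, radial-out and
        stay.  Forward/backward moves cross to the successor/predecessor
        segment with probability 1/core_length (one lattice step per
        cycle; pooled, position-free treatment within a space).
        """
        rest = max(0.0, 1.0 - self.forwardBias - self.lateralBias) / 4.0
        return {
            "stay": rest,
            "cross_fwd": self.forwardBias / self.core_length,
            "cross_bwd": rest / self.core_length,
            "radial_in": rest,
            "radial_out": rest,
            # non-crossing forward/backward + all lateral: stay in-space
            "within": (
                self.forwardBias * (1 - 1 / self.core_length)
                + self.lateralBias
                + rest * (1 - 1 / self.core_length)
            ),
        }


def apply_vd_change(
    dose: int, factor_srf: float, Vd_change: float
) -> tuple[int, float]:
    """Volume-of-distribution correction for LPS-arm runs.

    The wet-lab fold increase in a drug's volume of distribution under LPS
    is mimicked coarsely by dividing both the injected dose and the
    body-to-lobule transfer factor by ``Vd_change``.
    """
    if Vd_change <= 0:
        raise ValueError("Vd_change must be positive")
    return int(round(dose / Vd_change)), factor_srf / Vd_change


class LiverModel:
    """Pooled-count liver analog: lobule graph, cells, per-cycle dynamics."""

    def __init__(self, settings: ISLSettings, rng: RngStream) -> None:
        self.settings = settings
        self.rng = rng
        self.registry = settings.registry
        self.clock = SimulationClock(cycle_limit=10**9, seconds_per_cycle=1.0)

        self.type_names = list(self.registry.solutes)
        self.type_index = {n: i for i, n in enumerate(self.type_names)}
        self.n_types = len(self.type_names)
        self.drug_names = [
            n for n, st in self.registry.solutes.items() if st.bindable
        ]
        self.drug_index = {n: i for i, n in enumerate(self.drug_names)}
        self.n_drugs = len(self.drug_names)
        self._inflammatory_idx = [
            self.type_index[n]
            for n, st in self.registry.solutes.items()
            if st.inflammatory
        ]
        self._cyt_idx = self.type_index.get(settings.cytokine_type)

        self._build_graph()
        self._build_cells()
        self._build_state()
        # Biliary excretion applies to metabolites only: the modeled drugs
        # are essentially fully metabolized in the referent, and endotoxin /
        # cytokine are eliminated by cellular degradation (pDegrade), not
        # bile.  Non-excretable species make an in-place move instead of a
        # radial-out move from hepatocyte space.
        products = {
            p
            for st in self.registry.solutes.values()
            for p in st.metabolicProduct
        }
        self.bile_ok = np.array([n in products for n in self.type_names])
        # per-type sampleRatioFactor overrides (volume-of-distribution rule)
        self.srf_override: dict[str, float] = {}

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    def _build_graph(self) -> None:
        s = self.settings
        gen = self.rng.generator
        self.n_seg = s.layers * s.segments_per_layer
        self.layer_of = np.repeat(np.arange(s.layers), s.segments_per_layer)
        self.d_of_seg = self.layer_of / (s.layers - 1)
        self.successors: list[list[int]] = [[] for _ in range(self.n_seg)]
        self.predecessors: list[list[int]] = [[] for _ in range(self.n_seg)]
        W = s.segments_per_layer
        for layer in range(s.layers - 1):
            nxt = list(range((layer + 1) * W, (layer + 2) * W))
            for seg in range(layer * W, (layer + 1) * W):
                k = int(gen.integers(1, min(s.max_successors, W) + 1))
                chosen = gen.choice(nxt, size=k, replace=False)
                self.successors[seg] = [int(c) for c in chosen]
            # guarantee every next-layer segment is reachable
            covered = {c for seg in range(layer * W, (layer + 1) * W)
                       for c in self.successors[seg]}
            for orphan in set(nxt) - covered:
                donor = int(gen.integers(layer * W, (layer + 1) * W))
                self.successors[donor].append(orphan)
        for seg, succs in enumerate(self.successors):
            for c in succs:
                self.predecessors[c].append(seg)
        self.first_layer = list(range(W))
        self.last_layer = list(range((s.layers - 1) * W, s.layers * W))

    def _build_cells(self) -> None:
        s = self.settings
        gen = self.rng.generator
        n_pts = s.space_circumference * s.core_length
        self.n_space_points = n_pts
        seg_ec, seg_kc, seg_hep = [], [], []
        for seg in range(self.n_seg):
            u = gen.random(n_pts)
            n_ec = int(np.sum(u < s.ecDensity))
            n_kc = int(np.sum((u >= s.ecDensity) & (u < s.ecDensity + s.kcDensity)))
            seg_ec.append(n_ec)
            seg_kc.append(n_kc)
            seg_hep.append(int(np.sum(gen.random(n_pts) < s.hepDensity)))
        self.seg_of_ec = np.repeat(np.arange(self.n_seg), seg_ec)
        self.seg_of_kc = np.repeat(np.arange(self.n_seg), seg_kc)
        self.seg_of_hep = np.repeat(np.arange(self.n_seg), seg_hep)
        self.n_ec = len(self.seg_of_ec)
        self.n_kc = len(self.seg_of_kc)
        self.n_hep = len(self.seg_of_hep)
        self.ec_ids_by_seg = [
            np.flatnonzero(self.seg_of_ec == seg) for seg in range(self.n_seg)
        ]
        self.kc_ids_by_seg = [
            np.flatnonzero(self.seg_of_kc == seg) for seg in range(self.n_seg)
        ]
        self.hep_ids_by_seg = [
            np.flatnonzero(self.seg_of_hep == seg) for seg in range(self.n_seg)
        ]
        # zonated metabolism: pMetabolize interpolated at the cell's segment d
        d_hep = self.d_of_seg[self.seg_of_hep]
        self.pmet = np.zeros((self.n_hep, self.n_drugs))
        for dname, di in self.drug_index.items():
            st = self.registry.solute(dname)
            self.pmet[:, di] = [st.pmetabolize_at(d) for d in d_hep]

        # enzymes: one down-regulation pool per drug-matched enzyme type
        self.enzyme_pools: dict[str, PooledDownReg] = {}
        self.enzyme_type_drug: dict[str, int] = {}
        for et in self.registry.enzymes.values():
            if "hepatocyte" in et.expressingCellTypes and et.metabolic:
                accepted = [a for a in et.acceptedSolutes]
                if len(accepted) != 1:
                    raise NotImplementedError(
                        "pooled liver analog expects one accepted drug per "
                        "metabolic enzyme type"
                    )
                initial = gen.integers(
                    s.enzymesPerCellMin, s.enzymesPerCellMax + 1, size=self.n_hep
                )
                if not et.downRegulated:
                    raise NotImplementedError(
                        "metabolic hepatocyte enzymes are expected to be "
                        "down-regulatable"
                    )
                self.enzyme_pools[et.name] = PooledDownReg(
                    initial,
                    self.settings.downreg.premove_for(et),
                    self.settings.downreg.delay,
                    self.settings.downreg.pReplenish,
                )
                self.enzyme_type_drug[et.name] = self.drug_index[accepted[0]]
        # nonspecific binding sites on endothelial cells (binding only)
        self.ns_total = gen.integers(
            s.enzymesPerCellMin, s.enzymesPerCellMax + 1, size=self.n_ec
        ).astype(np.int64)
        self.ns_initial = self.ns_total.copy()
        self.ns_bindexp = 1.0
        for et in self.registry.enzymes.values():
            if not et.metabolic and "endothelial-cell" in et.expressingCellTypes:
                self.ns_bindexp = et.bindExponent

    def _build_state(self) -> None:
        s = self.settings
        bc = s.binding.bindCycles
        self.core = np.zeros((self.n_seg, s.core_length, self.n_types), np.int64)
        self.interface = np.zeros((self.n_seg, self.n_types), np.int64)
        self.disse = np.zeros((self.n_seg, self.n_types), np.int64)
        self.endo_x = np.zeros((self.n_seg, self.n_types), np.int64)
        self.hep_x = np.zeros((self.n_seg, self.n_types), np.int64)
        self.ec_sol = np.zeros((self.n_ec, self.n_types), np.int64)
        self.kc_sol = np.zeros((self.n_kc, self.n_types), np.int64)
        self.hep_sol = np.zeros((self.n_hep, self.n_types), np.int64)
        # bound solute/enzyme pairs by cycles-until-release ring slot
        self.hep_rb = np.zeros((self.n_hep, self.n_drugs, bc), np.int64)
        self.ns_rb = np.zeros((self.n_ec, self.n_drugs, bc), np.int64)
        self.body = np.zeros(self.n_types, np.int64)
        self.cv_stage = np.zeros(self.n_types, np.int64)
        self.bile = np.zeros(self.n_types, np.int64)
        self.degraded = np.zeros(self.n_types, np.int64)
        self.metabolized = np.zeros(self.n_types, np.int64)
        self.created = np.zeros(self.n_types, np.int64)
        self.dosed = np.zeros(self.n_types, np.int64)

    # ------------------------------------------------------------------
    # dosing / measurement / accounting
    # ------------------------------------------------------------------
    def dose_body(self, solute_type: str, amount: int) -> None:
        if amount < 0:
            raise ValueError("dose amount must be non-negative")
        t = self.type_index[solute_type]
        self.body[t] += amount
        self.dosed[t] += amount

    def measure(self, selector: str) -> int:
        """Body count of a solute type, or total enzyme count of a type."""
        if selector in self.type_index:
            return int(self.body[self.type_index[selector]])
        if selector in self.enzyme_pools:
            return int(self.enzyme_pools[selector].total.sum())
        raise KeyError(f"unknown selector {selector!r}")

    def lobule_count(self, solute_type: str) -> int:
        t = self.type_index[solute_type]
        n = (
            int(self.core[:, :, t].sum())
            + int(self.interface[:, t].sum())
            + int(self.disse[:, t].sum())
            + int(self.endo_x[:, t].sum())
            + int(self.hep_x[:, t].sum())
            + int(self.ec_sol[:, t].sum())
            + int(self.kc_sol[:, t].sum())
            + int(self.hep_sol[:, t].sum())
        )
        if solute_type in self.drug_index:
            d = self.drug_index[solute_type]
            n += int(self.hep_rb[:, d, :].sum()) + int(self.ns_rb[:, d, :].sum())
        return n

    def accounting(self, solute_type: str) -> dict[str, int]:
        """Exact partition of everything ever dosed or created of a type."""
        t = self.type_index[solute_type]
        return {
            "body": int(self.body[t]),
            "cv_stage": int(self.cv_stage[t]),
            "lobule": self.lobule_count(solute_type),
            "bile": int(self.bile[t]),
            "degraded": int(self.degraded[t]),
            "metabolized": int(self.metabolized[t]),
            "dosed": int(self.dosed[t]),
            "created": int(self.created[t]),
        }

    # ------------------------------------------------------------------
    # per-cycle dynamics
    # ------------------------------------------------------------------
    def run_cycle(self) -> None:
        now = self.clock.cycle + 1
        self._event_phase(now)
        self._body_exchange()
        self._move_solutes()
        gen = self.rng.generator
        for h in gen.permutation(5):
            if h == 0:
                self._binding(now)
            elif h == 1:
                self._metabolism()
            elif h == 2:
                self._inflammation()
            elif h == 3:
                self._downregulation(now)
            else:
                self._degradation()
        self.clock.advance()

    def run(self, cycles: int) -> None:
        for _ in range(cycles):
            self.run_cycle()

    def _event_phase(self, now: int) -> None:
        """Release bound pairs whose bindCycles elapsed; fire due removals."""
        slot = now % self.settings.binding.bindCycles
        released_hep = self.hep_rb[:, :, slot].copy()
        if released_hep.any():
            self.hep_rb[:, :, slot] = 0
            for dname, d in self.drug_index.items():
                t = self.type_index[dname]
                self.hep_sol[:, t] += released_hep[:, d]
        released_ns = self.ns_rb[:, :, slot]
        if released_ns.any():
            for dname, d in self.drug_index.items():
                t = self.type_index[dname]
                self.ec_sol[:, t] += released_ns[:, d]
            self.ns_rb[:, :, slot] = 0
        bound = self.hep_rb.sum(axis=2)
        for ename, pool in self.enzyme_pools.items():
            d = self.enzyme_type_drug[ename]
            if released_hep.any():
                freed = np.flatnonzero((released_hep[:, d] > 0) & (pool.deferred > 0))
                if freed.size:
                    pool.on_release(freed, bound[:, d])
            pool.fire_due(now, bound[:, d])

    def _body_exchange(self) -> None:
        gen = self.rng.generator
        # yesterday's CV arrivals re-enter body
        self.body += self.cv_stage
        self.cv_stage[:] = 0
        # body -> portal-vein transfer, binomial per type
        for t, name in enumerate(self.type_names):
            if self.body[t] == 0:
                continue
            srf = self.srf_override.get(
                name, self.registry.solute(name).sampleRatioFactor
            )
            if srf is None:
                continue
            p = self.settings.sampleRatio * srf
            if p > 1.0:
                raise ValueError("sampleRatio * sampleRatioFactor exceeds 1")
            xfer = int(gen.binomial(self.body[t], p))
            if xfer == 0:
                continue
            self.body[t] -= xfer
            alloc = gen.multinomial(
                xfer, np.full(len(self.first_layer), 1.0 / len(self.first_layer))
            )
            for seg, n in zip(self.first_layer, alloc):
                self.core[seg, 0, t] += n

    # -- movement ----------------------------------------------------------
    def _move_solutes(self) -> None:
        gen = self.rng.generator
        ker = self.settings.kernel()
        cats = np.array(
            [
                ker["stay"],
                ker["within"],
                ker["cross_fwd"],
                ker["cross_bwd"],
                ker["radial_in"],
                ker["radial_out"],
            ]
        )
        cats = cats / cats.sum()
        # destination accumulators
        new_interface = np.zeros_like(self.interface)
        new_disse = np.zeros_like(self.disse)
        arrive_endo = np.zeros_like(self.endo_x)   # re-scatter over endo lattice
        arrive_hep = np.zeros_like(self.hep_x)     # re-scatter over hep lattice
        new_endo_x = np.zeros_like(self.endo_x)
        new_hep_x = np.zeros_like(self.hep_x)
        core_in: list[tuple[int, int, int]] = []   # (seg, type, n) uniform position

        # core: plug flow with a radial exit chance of the kernel's
        # radial-out weight, then advance flowRate points
        if self.core.any():
            exits = gen.binomial(self.core, ker["radial_out"])
            new_interface += exits.sum(axis=1)
            rest = self.core - exits
            fr = self.settings.flowRate
            L = self.settings.core_length
            self.core[:] = 0
            self.core[:, fr:, :] = rest[:, : L - fr, :]
            overflow = rest[:, L - fr :, :].sum(axis=1)  # reached segment end
            for seg in range(self.n_seg):
                for t in np.flatnonzero(overflow[seg]):
                    self._forward_core(seg, int(t), int(overflow[seg, t]), gen)

        # one stacked kernel split covers every non-core pool (identical
        # per-pool distributions; just fewer binomial passes)
        ns = self.n_seg
        stack = np.concatenate(
            (self.interface, self.disse, self.endo_x, self.hep_x,
             self.ec_sol, self.kc_sol, self.hep_sol),
            axis=0,
        )
        if stack.any():
            stay, within, cfwd, cbwd, rin, rout = split_counts(gen, stack, cats)
            parts = {}
            offsets = [("interface", ns), ("disse", ns), ("endo_x", ns),
                       ("hep_x", ns), ("ec", self.n_ec), ("kc", self.n_kc),
                       ("hep", self.n_hep)]
            lo = 0
            for name, size in offsets:
                parts[name] = slice(lo, lo + size)
                lo += size

            # blood-cell interface (acellular): radial-in -> core, out -> endo
            sl = parts["interface"]
            new_interface += stay[sl] + within[sl]
            self._cross(cfwd[sl], new_interface, gen, cv_ok=True)
            self._cross(cbwd[sl], new_interface, gen, backward=True)
            arrive_endo += rout[sl]
            rin_if = rin[sl]
            for seg in range(ns):
                for t in np.flatnonzero(rin_if[seg]):
                    core_in.append((seg, int(t), int(rin_if[seg, t])))
            # space of Disse (acellular): radial-in -> endo, out -> hep space
            sl = parts["disse"]
            new_disse += stay[sl] + within[sl]
            self._cross(cfwd[sl], new_disse, gen)
            self._cross(cbwd[sl], new_disse, gen, backward=True)
            arrive_endo += rin[sl]
            arrive_hep += rout[sl]
            # endothelial space, extracellular
            sl = parts["endo_x"]
            new_endo_x += stay[sl]
            arrive_endo += within[sl]
            self._cross(cfwd[sl], arrive_endo, gen)
            self._cross(cbwd[sl], arrive_endo, gen, backward=True)
            new_interface += rin[sl]
            new_disse += rout[sl]
            # hepatocyte space, extracellular (radial-out -> bile, terminal;
            # species without a bile route make an in-place move instead)
            sl = parts["hep_x"]
            new_hep_x += stay[sl]
            arrive_hep += within[sl]
            self._cross(cfwd[sl], arrive_hep, gen)
            self._cross(cbwd[sl], arrive_hep, gen, backward=True)
            new_disse += rin[sl]
            self.bile += np.where(self.bile_ok, rout[sl].sum(axis=0), 0)
            new_hep_x += np.where(self.bile_ok, 0, rout[sl])
            # solutes inside cells follow the same kernel; "stay" keeps them
            # in the cell, any other move takes them out
            for name, pool, seg_of, space in (
                ("ec", self.ec_sol, self.seg_of_ec, "endo"),
                ("kc", self.kc_sol, self.seg_of_kc, "endo"),
                ("hep", self.hep_sol, self.seg_of_hep, "hep"),
            ):
                sl = parts[name]
                if pool.shape[0] == 0:
                    continue
                pool[:] = stay[sl]
                seg_within = self._by_seg(within[sl], seg_of)
                seg_cfwd = self._by_seg(cfwd[sl], seg_of)
                seg_cbwd = self._by_seg(cbwd[sl], seg_of)
                seg_rin = self._by_seg(rin[sl], seg_of)
                seg_rout = self._by_seg(rout[sl], seg_of)
                if space == "endo":
                    arrive_endo += seg_within
                    self._cross(seg_cfwd, arrive_endo, gen)
                    self._cross(seg_cbwd, arrive_endo, gen, backward=True)
                    new_interface += seg_rin
                    new_disse += seg_rout
                else:
                    arrive_hep += seg_within
                    self._cross(seg_cfwd, arrive_hep, gen)
                    self._cross(seg_cbwd, arrive_hep, gen, backward=True)
                    new_disse += seg_rin
                    self.bile += np.where(
                        self.bile_ok, seg_rout.sum(axis=0), 0
                    )
                    # blocked species stay inside the cell
                    pool += np.where(self.bile_ok, 0, rout[sl])

        # commit acellular pools
        self.interface = new_interface
        self.disse = new_disse
        # re-scatter arrivals over the cellular lattices (cells + free points)
        self._allocate(arrive_endo, new_endo_x, "endo", gen)
        self._allocate(arrive_hep, new_hep_x, "hep", gen)
        self.endo_x = new_endo_x
        self.hep_x = new_hep_x
        # interface -> core entries at a uniform core position
        for seg, t, n in core_in:
            pos = gen.multinomial(
                n, np.full(self.settings.core_length, 1.0 / self.settings.core_length)
            )
            self.core[seg, :, t] += pos

    def _forward_core(self, seg: int, t: int, n: int, gen) -> None:
        """Core overflow crosses to a successor core (or the CV)."""
        succs = self.successors[seg]
        if not succs:
            self.cv_stage[t] += n
            return
        if len(succs) == 1:
            self.core[succs[0], 0, t] += n
            return
        alloc = gen.multinomial(n, np.full(len(succs), 1.0 / len(succs)))
        for c, k in zip(succs, alloc):
            self.core[c, 0, t] += k

    def _cross(
        self,
        moved: np.ndarray,
        dest: np.ndarray,
        gen,
        backward: bool = False,
        cv_ok: bool = False,
    ) -> None:
        """Move per-segment counts to neighbor segments' same space.

        Without a neighbor the move degenerates to a within-space move
        (except the blood-adjacent interface, whose forward crossings from
        the last layer exit to the CV)."""
        if not moved.any():
            return
        for seg in range(self.n_seg):
            row = moved[seg]
            if not row.any():
                continue
            nbrs = self.predecessors[seg] if backward else self.successors[seg]
            if not nbrs:
                if cv_ok and not backward:
                    self.cv_stage += row
                else:
                    dest[seg] += row
                continue
            if len(nbrs) == 1:
                dest[nbrs[0]] += row
                continue
            for t in np.flatnonzero(row):
                alloc = gen.multinomial(
                    int(row[t]), np.full(len(nbrs), 1.0 / len(nbrs))
                )
                for nb, k in zip(nbrs, alloc):
                    dest[nb, t] += k

    def _by_seg(self, per_cell: np.ndarray, seg_of: np.ndarray) -> np.ndarray:
        out = np.zeros((self.n_seg, self.n_types), np.int64)
        np.add.at(out, seg_of, per_cell)
        return out

    def _allocate(
        self, arrivals: np.ndarray, extra_dest: np.ndarray, space: str, gen
    ) -> None:
        """Land arrivals on uniform lattice points: occupied -> inside cell."""
        if not arrivals.any():
            return
        n_pts = self.n_space_points
        for seg in range(self.n_seg):
            row = arrivals[seg]
            if not row.any():
                continue
            if space == "endo":
                cells = [(self.ec_sol, i) for i in self.ec_ids_by_seg[seg]] + [
                    (self.kc_sol, i) for i in self.kc_ids_by_seg[seg]
                ]
            else:
                cells = [(self.hep_sol, i) for i in self.hep_ids_by_seg[seg]]
            n_cells = len(cells)
            p_extra = max(n_pts - n_cells, 0) / n_pts
            pvals = np.append(np.full(n_cells, 1.0 / n_pts), p_extra)
            pvals = pvals / pvals.sum()
            for t in np.flatnonzero(row):
                alloc = gen.multinomial(int(row[t]), pvals)
                extra_dest[seg, t] += alloc[-1]
                hit = np.flatnonzero(alloc[:-1])
                for j in hit:
                    pool, i = cells[j]
                    pool[i, t] += alloc[j]

    # -- handlers ----------------------------------------------------------
    def _binding(self, now: int) -> None:
        cfg = self.settings.binding
        gen = self.rng.generator
        slot = now % cfg.bindCycles
        # hepatocytes: each drug binds only its matched enzyme type
        for ename, pool in self.enzyme_pools.items():
            d = self.enzyme_type_drug[ename]
            t = self.type_index[self.drug_names[d]]
            bound = self.hep_rb[:, d, :].sum(axis=1)
            cand = np.flatnonzero((self.hep_sol[:, t] > 0) & (pool.total - bound > 0))
            for i in cand:
                et = self.registry.enzyme(ename)
                n = sequential_bind(
                    gen,
                    int(self.hep_sol[i, t]),
                    int(pool.total[i]),
                    int(bound[i]),
                    int(pool.initial[i]),
                    cfg.pBind,
                    et.bindExponent,
                    cfg.mode,
                )
                if n:
                    self.hep_sol[i, t] -= n
                    self.hep_rb[i, d, slot] += n
        # endothelial nonspecific sites accept every drug (no metabolism)
        if self.n_ec:
            drug_ts = [self.type_index[dn] for dn in self.drug_names]
            has = np.flatnonzero(self.ec_sol[:, drug_ts].sum(axis=1) > 0)
            for i in has:
                order = gen.permutation(self.n_drugs)
                for d in order:
                    t = drug_ts[d]
                    s = int(self.ec_sol[i, t])
                    if s == 0:
                        continue
                    bound = int(self.ns_rb[i].sum())
                    n = sequential_bind(
                        gen,
                        s,
                        int(self.ns_total[i]),
                        bound,
                        int(self.ns_initial[i]),
                        cfg.pBind,
                        self.ns_bindexp,
                        cfg.mode,
                    )
                    if n:
                        self.ec_sol[i, t] -= n
                        self.ns_rb[i, d, slot] += n

    def _metabolism(self) -> None:
        """Bound drugs convert to their metabolite inside hepatocytes."""
        if not self.hep_rb.any():
            return
        gen = self.rng.generator
        m = gen.binomial(self.hep_rb, self.pmet[:, :, None])
        if not m.any():
            return
        self.hep_rb -= m
        freed = m.sum(axis=2)
        bound = self.hep_rb.sum(axis=2)
        for dname, d in self.drug_index.items():
            events = int(freed[:, d].sum())
            if events == 0:
                continue
            t = self.type_index[dname]
            self.metabolized[t] += events
            st = self.registry.solute(dname)
            if len(st.metabolicProduct) > 1:
                raise NotImplementedError(
                    "pooled runs expect at most one metabolite product"
                )
            if st.metabolicProduct:
                pt = self.type_index[st.metabolicProduct[0]]
                self.hep_sol[:, pt] += freed[:, d]
                self.created[pt] += events
        for ename, pool in self.enzyme_pools.items():
            d = self.enzyme_type_drug[ename]
            idx = np.flatnonzero((freed[:, d] > 0) & (pool.deferred > 0))
            if idx.size:
                pool.on_release(idx, bound[:, d])

    def _inflammation(self) -> None:
        if self._cyt_idx is None or self.n_kc == 0:
            return
        cfg = self.settings.inflammation
        gen = self.rng.generator
        stim = self.kc_sol[:, self._inflammatory_idx].sum(axis=1)
        ncyt = self.kc_sol[:, self._cyt_idx]
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
            self.kc_sol[produced, self._cyt_idx] += 1
            self.created[self._cyt_idx] += produced.size

    def _downregulation(self, now: int) -> None:
        if self._cyt_idx is None:
            return
        ncyt = self.hep_sol[:, self._cyt_idx]
        for pool in self.enzyme_pools.values():
            pool.step(now, ncyt, self.rng.generator)

    def _degradation(self) -> None:
        """Unbound degradable solutes inside cells are removed."""
        gen = self.rng.generator
        for t, name in enumerate(self.type_names):
            p = self.registry.solute(name).pDegrade
            if p is None or p == 0.0:
                continue
            for pool in (self.hep_sol, self.ec_sol, self.kc_sol):
                if pool.shape[0] == 0 or not pool[:, t].any():
                    continue
                deg = gen.binomial(pool[:, t], p)
                pool[:, t] -= deg
                self.degraded[t] += int(deg.sum())


def build_lobule(settings: ISLSettings, rng: RngStream) -> LiverModel:
    """Construct a liver model (graph wiring and cells drawn from ``rng``)."""
    return LiverModel(settings, rng)
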