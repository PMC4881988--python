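"""Component ontology: solute and enzyme type registries and cell agents.

Solutes are mobile objects mapping to groups of small molecules (the
bacterial endotoxin LPS, a generic proinflammatory cytokine, three drugs —
acetaminophen, antipyrine, chlorzoxazone — and their metabolites).  Enzymes
are intracellular objects mapping to the portion of cell material that can
influence metabolism within one cycle; they do not map to individual P450
molecules.  Cells are the agents: hepatocytes (metabolism, down-regulation),
endothelial cells (nonspecific binding only), and Kupffer cells (cytokine
production; they hold no enzymes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .engine import RngStream

__all__ = [
    "SoluteType",
    "EnzymeType",
    "Solute",
    "Enzyme",
    "Cell",
    "TypeRegistry",
    "create_cell",
    "resolve_expression",
    "HEPATOCYTE",
    "ENDOTHELIAL",
    "KUPFFER",
]

HEPATOCYTE = "hepatocyte"
ENDOTHELIAL = "endothelial-cell"
KUPFFER = "kupffer-cell"
CELL_TYPES = (HEPATOCYTE, ENDOTHELIAL, KUPFFER)


@dataclass(frozen=True)
class SoluteType:
    """Species-level solute parameters.

    ``pMetabolize`` is a single probability or a ``(min, max)`` pair; a
    pair encodes lobule zonation (portal-vein cells use the minimum,
    central-vein cells the maximum, linear in between).  Absent optional
    parameters mean the associated process never applies to this type:
    no ``pDegrade`` means the solute cannot be degraded, no
    ``sampleRatioFactor`` means it is never transferred from body to the
    lobule.
    """

    name: str
    bindable: bool = False
    inflammatory: bool = False
    pMetabolize: float | tuple[float, float] | None = None
    metabolicProduct: tuple[str, ...] = ()
    pDegrade: float | None = None
    sampleRatioFactor: float | None = None
    Vd_change: float | None = None
    pExitCell: float | None = None
    pExitMedia: float | None = None

    def __post_init__(self) -> None:
        for attr in ("pDegrade", "pExitCell", "pExitMedia"):
            v = getattr(self, attr)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.name}.{attr} must lie in [0, 1], got {v}")
        if self.Vd_change is not None and self.Vd_change <= 0:
            raise ValueError(f"{self.name}.Vd_change must be positive")
        pm = self.pMetabolize
        if pm is not None:
            lohi = pm if isinstance(pm, tuple) else (pm, pm)
            if not (0.0 <= lohi[0] <= lohi[1] <= 1.0):
                raise ValueError(f"{self.name}.pMetabolize out of range: {pm}")

    def pmetabolize_at(self, d: float) -> float:
        """Zonated metabolism probability at normalized PV->CV position d."""
        if self.pMetabolize is None:
            return 0.0
        if isinstance(self.pMetabolize, tuple):
            lo, hi = self.pMetabolize
            return lo + d * (hi - lo)
        return float(self.pMetabolize)


@dataclass(frozen=True)
class EnzymeType:
    """Type-level enzyme parameters (generation-2 enzyme ontology)."""

    name: str
    expressingCellTypes: tuple[str, ...]
    acceptedSolutes: tuple[str, ...]
    metabolic: bool
    downRegulated: bool
    pRemove: float | None = None
    bindExponent: float = 1.0

    def __post_init__(self) -> None:
        if self.pRemove is not None and not 0.0 <= self.pRemove <= 1.0:
            raise ValueError(f"{self.name}.pRemove must lie in [0, 1]")
        if self.bindExponent <= 0:
            raise ValueError(f"{self.name}.bindExponent must be positive")
        for ct in self.expressingCellTypes:
            if ct not in CELL_TYPES:
                raise ValueError(f"{self.name}: unknown cell type {ct!r}")


class TypeRegistry:
    """Validated lookup of solute and enzyme types.

    Enforces type closure: enzyme ``acceptedSolutes`` must name registered,
    bindable solute types, and metabolite products must be registered.
    """

    def __init__(
        self,
        solute_types: list[SoluteType],
        enzyme_types: list[EnzymeType],
        kupffer_expresses_nonspecific: bool = False,
    ) -> None:
        self.solutes: dict[str, SoluteType] = {}
        self.enzymes: dict[str, EnzymeType] = {}
        for st in solute_types:
            if st.name in self.solutes:
                raise ValueError(f"duplicate solute type {st.name!r}")
            self.solutes[st.name] = st
        for et in enzyme_types:
            if et.name in self.enzymes:
                raise ValueError(f"duplicate enzyme type {et.name!r}")
            self.enzymes[et.name] = et
        self.kupffer_expresses_nonspecific = kupffer_expresses_nonspecific
        self._validate()

    def _validate(self) -> None:
        for st in self.solutes.values():
            for prod in st.metabolicProduct:
                if prod not in self.solutes:
                    raise ValueError(
                        f"solute {st.name!r} lists unknown metabolite {prod!r}"
                    )
        for et in self.enzymes.values():
            for sn in et.acceptedSolutes:
                if sn not in self.solutes:
                    raise ValueError(
                        f"enzyme {et.name!r} accepts unknown solute {sn!r}"
                    )
                if not self.solutes[sn].bindable:
                    raise ValueError(
                        f"enzyme {et.name!r} accepts non-bindable solute {sn!r}"
                    )

    def solute(self, name: str) -> SoluteType:
        try:
            return self.solutes[name]
        except KeyError:
            raise KeyError(f"unknown solute type {name!r}") from None

    def enzyme(self, name: str) -> EnzymeType:
        try:
            return self.enzymes[name]
        except KeyError:
            raise KeyError(f"unknown enzyme type {name!r}") from None

    def enzymes_accepting(self, solute_name: str) -> list[EnzymeType]:
        return [e for e in self.enzymes.values() if solute_name in e.acceptedSolutes]


def resolve_expression(cell_type: str, registry: TypeRegistry) -> list[EnzymeType]:
    """Enzyme types a cell of ``cell_type`` expresses.

    Kupffer cells express nothing by default; the registry's
    ``kupffer_expresses_nonspecific`` switch lets them carry nonspecific
    binding sites instead.
    """
    if cell_type not in CELL_TYPES:
        raise ValueError(f"unknown cell type {cell_type!r}")
    out = []
    for et in registry.enzymes.values():
        if cell_type in et.expressingCellTypes:
            if cell_type == KUPFFER and not registry.kupffer_expresses_nonspecific:
                continue
            out.append(et)
    return out


@dataclass
class Solute:
    """One mobile solute object (agent-per-object representation)."""

    type: SoluteType
    location: object = None
    bound_to: "Enzyme | None" = None

    @property
    def bound(self) -> bool:
        return self.bound_to is not None


@dataclass
class Enzyme:
    """One enzyme instance inside a cell."""

    type: EnzymeType
    bound_solute: Solute | None = None
    marked_for_removal: bool = False

    @property
    def bound(self) -> bool:
        return self.bound_solute is not None


@dataclass
class DownRegState:
    """Per-enzyme-type down-regulation bookkeeping inside one cell.

    ``pending_removals`` holds the fire cycles of queued removals; appends
    go to the tail at ``max(now, last queued fire) + delay``, so fire
    cycles strictly increase.  ``deferred`` counts removals that fired
    while every enzyme was bound and execute on the next release.
    """

    pending_removals: list[int] = field(default_factory=list)
    deferred: int = 0

    @property
    def queue_empty(self) -> bool:
        return not self.pending_removals and self.deferred == 0


class Cell:
    """A cell agent holding enzymes, solutes, and down-regulation state."""

    def __init__(self, cell_type: str) -> None:
        if cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell type {cell_type!r}")
        self.cell_type = cell_type
        self.enzymes: dict[str, list[Enzyme]] = {}
        self.initial_enzyme_count: dict[str, int] = {}
        self.solutes: list[Solute] = []
        self.downreg: dict[str, DownRegState] = {}
        # Zonated metabolism position (liver analog); 0 for culture cells.
        self.d: float = 0.0

    def enzyme_count(self, type_name: str) -> int:
        return len(self.enzymes.get(type_name, []))

    def unbound_enzymes(self, type_name: str) -> list[Enzyme]:
        return [e for e in self.enzymes.get(type_name, []) if not e.bound]

    def solute_count(self, type_name: str, include_bound: bool = True) -> int:
        return sum(
            1
            for s in self.solutes
            if s.type.name == type_name and (include_bound or not s.bound)
        )

    def add_solute(self, solute: Solute) -> None:
        solute.location = self
        self.solutes.append(solute)

    def remove_solute(self, solute: Solute) -> None:
        self.solutes.remove(solute)
        solute.location = None


def create_cell(
    cell_type: str,
    registry: TypeRegistry,
    enzymes_per_cell_min: int,
    enzymes_per_cell_max: int,
    rng: RngStream,
    d: float = 0.0,
) -> Cell:
    """Instantiate a cell with its expressed enzyme complement.

    Each expressed enzyme type gets a count drawn uniformly from the
    integer range [min, max]; that draw is recorded as the basal level the
    down-regulation handler replenishes toward.
    """
    if enzymes_per_cell_min > enzymes_per_cell_max:
        raise ValueError("enzymesPerCellMin exceeds enzymesPerCellMax")
    if enzymes_per_cell_min < 0:
        raise ValueError("enzyme counts must be non-negative")
    cell = Cell(cell_type)
    cell.d = d
    for et in resolve_expression(cell_type, registry):
        n = int(rng.integers(enzymes_per_cell_min, enzymes_per_cell_max + 1))
        cell.enzymes[et.name] = [Enzyme(et) for _ in range(n)]
        cell.initial_enzyme_count[et.name] = n
        if et.downRegulated:
            cell.downreg[et.name] = DownRegState()
    return cell
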