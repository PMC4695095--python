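"""Core domain types for Boolean inference of signal-driven gene induction.

The central abstraction is a :class:`CellSystem`: a population of initially
equivalent cells exposed to a handful of extracellular signals.  Each signal
has a *strength ordering* over the cells (a weak order derived from, e.g.,
contact areas with the signaling source) and a *reception mask* (the cells
physically able to receive the ligand; a membrane-tethered ligand never
reaches cells that do not touch a source cell, and autocrine reception of
GPI-anchored ligands is excluded upstream).

A :class:`SensingPattern` assigns every cell a binary state per signal --
whether the cell senses that signal above threshold.  The signaling-source
rule ("Rule 1") restricts the per-signal state sets to up-closed sets of the
strength ordering: a cell with more exposure to the source can never be off
while a less-exposed cell is on.  The uniqueness rule ("Rule 2") demands
that one input tuple never maps to both expression and non-expression of the
output gene in any cell under any experimental condition; it is enforced by
the screening stage as truth-table consistency.

Bilaterally symmetric cells (e.g. the left/right ``a6.5`` blastomeres of an
ascidian embryo) are collapsed into single units upstream; the data model
never represents the two members of a pair separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

Row = Tuple[int, ...]

#: Observed-output level for cells whose expression is deliberately not
#: scored (e.g. a loosely regulated cell excluded from constraints).
UNKNOWN = None

#: Truth-table value for rows not pinned down by any observation.
UNDETERMINED = None

NO_OVERRIDE = "none"
FORCE0 = "force0"
FORCE1 = "force1"
OVERRIDE_LEVELS = (NO_OVERRIDE, FORCE0, FORCE1)


def all_rows(k: int) -> List[Row]:
    """All k-bit input tuples in binary-counting order, ``(0,...,0)`` first."""
    return [tuple(bits) for bits in product((0, 1), repeat=k)]


@dataclass
class SignalSpec:
    """One signaling pathway: its strength ordering and reception mask.

    Parameters
    ----------
    name:
        Signal identifier, e.g. ``"fgf"``.
    ordering:
        Tie-groups of cell identifiers, strongest first.  Cells inside one
        tie-group have indistinguishable exposure and are forced to share a
        binary state.  Cells in the reception mask that are absent from the
        ordering are unconstrained (free in {0, 1}); an empty ordering means
        no source-geometry constraint at all.
    reception_mask:
        Cells able to receive the signal, or ``None`` for "all cells".
        Cells outside the mask are permanently in state 0.
    tethered:
        Documentation flag for membrane-bound ligands.  The semantics live
        entirely in ``ordering`` and ``reception_mask``.
    """

    name: str
    ordering: Tuple[Tuple[str, ...], ...] = ()
    reception_mask: Optional[frozenset] = None
    tethered: bool = False

    def __post_init__(self) -> None:
        self.ordering = tuple(tuple(group) for group in self.ordering)
        if self.reception_mask is not None:
            self.reception_mask = frozenset(self.reception_mask)

    def mask_for(self, cells: Sequence[str]) -> frozenset:
        """The effective reception mask, resolving ``None`` to all cells."""
        if self.reception_mask is None:
            return frozenset(cells)
        return self.reception_mask

    def ordered_cells(self) -> List[str]:
        return [cell for group in self.ordering for cell in group]


@dataclass
class CellSystem:
    """The universe the screen runs over: cells, signals, and the output gene.

    ``cells`` are units of equivalent cells (a bilateral pair counts once).
    The order of ``signals`` is canonical: truth-table input tuples list the
    signals in this order.
    """

    cells: Tuple[str, ...]
    signals: Tuple[SignalSpec, ...]
    output_name: str = "output"

    def __post_init__(self) -> None:
        self.cells = tuple(self.cells)
        self.signals = tuple(self.signals)

    @property
    def k(self) -> int:
        return len(self.signals)

    @property
    def signal_names(self) -> Tuple[str, ...]:
        return tuple(spec.name for spec in self.signals)

    def signal(self, name: str) -> SignalSpec:
        for spec in self.signals:
            if spec.name == name:
                return spec
        raise KeyError(f"no signal named {name!r}")


@dataclass
class SensingPattern:
    """Per-cell binary signaling states, one bit per signal in canonical order."""

    states: Dict[str, Row]

    def __post_init__(self) -> None:
        self.states = {cell: tuple(bits) for cell, bits in self.states.items()}

    def key(self) -> Tuple[Tuple[str, Row], ...]:
        """Hashable identity, independent of dict insertion order."""
        return tuple(sorted(self.states.items()))

    def column(self, signal_index: int) -> Dict[str, int]:
        """The state of one signal across all cells."""
        return {cell: bits[signal_index] for cell, bits in self.states.items()}

    @classmethod
    def from_columns(
        cls, system: CellSystem, columns: Mapping[str, Mapping[str, int]]
    ) -> "SensingPattern":
        """Build a pattern from per-signal columns keyed by signal name."""
        states = {
            cell: tuple(columns[name][cell] for name in system.signal_names)
            for cell in system.cells
        }
        return cls(states)


@dataclass
class Condition:
    """One experimental condition: per-signal overrides and observed output.

    Overrides model whole-embryo perturbations: ``force0`` is a knockdown
    (morpholino), ``force1`` a gain of function (overexpression or a bath of
    recombinant protein).  ``observed`` maps cells to 1 / 0 / :data:`UNKNOWN`;
    unknown cells contribute no constraint to the screen.
    """

    name: str
    overrides: Dict[str, str] = field(default_factory=dict)
    observed: Dict[str, Optional[int]] = field(default_factory=dict)

    def override_for(self, signal_name: str) -> str:
        return self.overrides.get(signal_name, NO_OVERRIDE)


@dataclass
class PartialTruthTable:
    """A map from every k-bit input tuple to {0, 1, undetermined}."""

    k: int
    entries: Dict[Row, Optional[int]]

    @classmethod
    def empty(cls, k: int) -> "PartialTruthTable":
        return cls(k, {row: UNDETERMINED for row in all_rows(k)})

    def determined(self) -> Dict[Row, int]:
        return {r: v for r, v in self.entries.items() if v is not UNDETERMINED}

    def copy(self) -> "PartialTruthTable":
        return PartialTruthTable(self.k, dict(self.entries))


@dataclass
class BooleanFunction:
    """A total Boolean function of k signal states."""

    k: int
    entries: Dict[Row, int]

    def __call__(self, row: Row) -> int:
        return self.entries[tuple(row)]

    def completes(self, table: PartialTruthTable) -> bool:
        """True iff this function agrees with every determined table entry."""
        return all(
            self.entries[row] == value for row, value in table.determined().items()
        )

    def bits(self) -> Tuple[int, ...]:
        """Outputs in binary-counting row order; a compact identity."""
        return tuple(self.entries[row] for row in all_rows(self.k))

    @classmethod
    def from_bits(cls, k: int, bits: Sequence[int]) -> "BooleanFunction":
        rows = all_rows(k)
        if len(bits) != len(rows):
            raise ValueError(f"need {len(rows)} output bits, got {len(bits)}")
        return cls(k, dict(zip(rows, (int(b) for b in bits))))


@dataclass
class ScreenResult:
    """Outcome of a Rule-2 screen over all admissible sensing patterns."""

    surviving_patterns: List[SensingPattern]
    partial_tables: List[PartialTruthTable]
    function_counts: List[int]
    common_functions: List[BooleanFunction]
    common_conflict_rows: List[Row]
    criticality: List[Dict[str, str]]
    n_patterns_total: int = 0


def validate_system(system: CellSystem) -> List[str]:
    """Check every structural invariant of a cell system.

    Returns an empty list iff the system is well formed, otherwise one
    message per violation.  Raises :class:`TypeError` only when the input is
    structurally unreadable (wrong container shapes), naming the offending
    field.
    """
    if not isinstance(system, CellSystem):
        raise TypeError("expected a CellSystem instance")
    violations: List[str] = []
    cells = system.cells
    if not isinstance(cells, tuple) or not all(isinstance(c, str) for c in cells):
        raise TypeError("field 'cells' must be a sequence of strings")
    if len(cells) == 0:
        violations.append("system has no cells")
    if len(set(cells)) != len(cells):
        dupes = sorted({c for c in cells if cells.count(c) > 1})
        violations.append(f"duplicate cell identifiers: {', '.join(dupes)}")
    if len(system.signals) == 0:
        violations.append("system has no signals")
    names = [spec.name for spec in system.signals]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        violations.append(f"duplicate signal names: {', '.join(dupes)}")
    cell_set = set(cells)
    for spec in system.signals:
        if not isinstance(spec, SignalSpec):
            raise TypeError("field 'signals' must contain SignalSpec instances")
        mask = spec.mask_for(cells)
        stray = sorted(mask - cell_set)
        if stray:
            violations.append(
                f"signal {spec.name!r}: reception_mask names unknown cells "
                f"{', '.join(stray)}"
            )
        ordered = spec.ordered_cells()
        seen: set = set()
        for cell in ordered:
            if cell in seen:
                violations.append(
                    f"signal {spec.name!r}: cell {cell!r} appears more than once "
                    "in the ordering"
                )
            seen.add(cell)
        outside = sorted(set(ordered) - mask)
        if outside:
            violations.append(
                f"signal {spec.name!r}: ordering lists cells outside the "
                f"reception_mask: {', '.join(outside)}"
            )
        for group in spec.ordering:
            if len(group) == 0:
                violations.append(f"signal {spec.name!r}: empty tie-group")
    return violations


def _check_pattern_matches_system(pattern: SensingPattern, system: CellSystem) -> None:
    if set(pattern.states) != set(system.cells):
        raise ValueError("pattern cells do not match system cells")
    k = system.k
    for cell, bits in pattern.states.items():
        if len(bits) != k:
            raise ValueError(
                f"pattern for cell {cell!r} has {len(bits)} bits, expected {k}"
            )
        if any(b not in (0, 1) for b in bits):
            raise ValueError(f"pattern for cell {cell!r} has non-binary states")


def pattern_is_admissible(pattern: SensingPattern, system: CellSystem) -> bool:
    """Does a sensing pattern respect the signaling-source rule (Rule 1)?

    For each signal, the set of state-1 cells must be up-closed with respect
    to the strength ordering: no cell may be on while a strictly stronger
    cell is off, cells in one tie-group share one state, and cells outside
    the reception mask are 0.  Cells in the mask but absent from the ordering
    are unconstrained.
    """
    _check_pattern_matches_system(pattern, system)
    for j, spec in enumerate(system.signals):
        mask = spec.mask_for(system.cells)
        column = pattern.column(j)
        if any(column[cell] != 0 for cell in system.cells if cell not in mask):
            return False
        # Down the chain the group states must read 1...1 0...0.
        previous = 1
        for group in spec.ordering:
            values = {column[cell] for cell in group}
            if len(values) > 1:
                return False
            value = values.pop()
            if value > previous:
                return False
            previous = value
    return True
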