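"""Enumeration of sensing patterns admissible under the signaling-source rule.

For a single signal whose strength ordering is a chain of ``g`` tie-groups,
the admissible per-cell state sets are exactly the ``g + 1`` prefixes of the
chain (the strongest 0, 1, ..., g groups set to 1).  Cells in the reception
mask but not in the ordering are free, contributing a factor of 2 each; the
whole-system admissible set is the Cartesian product over signals.
"""

from __future__ import annotations

from dataclasses import replace
from itertools import product
from math import prod
from typing import Dict, Iterator, List, Sequence

from .model import CellSystem, Row, SensingPattern, SignalSpec


def iter_signal_states(
    spec: SignalSpec, cells: Sequence[str]
) -> Iterator[Dict[str, int]]:
    """Lazily yield admissible single-signal assignments, all-0 first.

    One assignment (cell -> bit) per prefix of the tie-group chain, combined
    with every assignment of the unconstrained mask cells (free cells are an
    inner binary counter, so the all-1-on-the-mask state comes last).
    """
    mask = spec.mask_for(cells)
    ordered = spec.ordered_cells()
    free = [c for c in cells if c in mask and c not in ordered]
    for depth in range(len(spec.ordering) + 1):
        on = {cell for group in spec.ordering[:depth] for cell in group}
        for free_bits in product((0, 1), repeat=len(free)):
            assignment = {cell: 0 for cell in cells}
            for cell in on:
                assignment[cell] = 1
            for cell, bit in zip(free, free_bits):
                assignment[cell] = bit
            yield assignment


def signal_states(spec: SignalSpec, cells: Sequence[str]) -> List[Dict[str, int]]:
    """All admissible single-signal state assignments, ordered all-0 to all-1.

    The materialized form of :func:`iter_signal_states`; the list has length
    ``(g + 1) * 2**f`` where ``g`` counts tie-groups and ``f`` counts free
    cells -- for a chain covering the whole mask, the familiar
    ``(number of cells) + 1``.
    """
    return list(iter_signal_states(spec, cells))


def count_signal_states(spec: SignalSpec, cells: Sequence[str]) -> int:
    """Number of admissible states for one signal, without materializing."""
    mask = spec.mask_for(cells)
    ordered = spec.ordered_cells()
    n_free = sum(1 for c in cells if c in mask and c not in ordered)
    return (len(spec.ordering) + 1) * 2**n_free


def enumerate_patterns(system: CellSystem) -> Iterator[SensingPattern]:
    """Lazily yield every Rule-1-admissible sensing pattern.

    The iteration order is lexicographic over per-signal state indices
    (first signal slowest), each signal's states ordered as in
    :func:`signal_states`.  The product is taken over lazy per-signal
    generators, so even astronomically large admissible sets can be
    streamed.
    """

    def rec(j: int, acc: List[Dict[str, int]]) -> Iterator[SensingPattern]:
        if j == len(system.signals):
            yield SensingPattern(
                {
                    cell: tuple(assignment[cell] for assignment in acc)
                    for cell in system.cells
                }
            )
            return
        for assignment in iter_signal_states(system.signals[j], system.cells):
            yield from rec(j + 1, acc + [assignment])

    return rec(0, [])


def count_patterns(system: CellSystem) -> int:
    """Number of admissible sensing patterns, computed without enumeration."""
    return prod(count_signal_states(spec, system.cells) for spec in system.signals)


def relax_orderings(system: CellSystem) -> CellSystem:
    """A copy of the system with all source-geometry constraints removed.

    Every signal keeps its reception mask but loses its ordering, so each
    mask cell becomes free; :func:`count_patterns` on the result gives the
    unconstrained total ``prod(2**|mask_i|)``.
    """
    return CellSystem(
        cells=system.cells,
        signals=tuple(replace(spec, ordering=()) for spec in system.signals),
        output_name=system.output_name,
    )
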