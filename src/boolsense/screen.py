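"""Uniqueness-rule (Rule 2) screening of sensing patterns against observations.

Given a candidate wild-type sensing pattern, every experimental condition
maps each observed cell to a constraint ``F(input tuple) = observed value``.
A candidate is rejected as soon as one input tuple receives both 0 and 1 --
the same signaling state cannot direct both expression and non-expression.
This truth-table formulation subsumes the textbook statement of the
uniqueness rule ("cells with identical signaling states cannot differ in
output") as the special case of the unperturbed condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .model import (
    UNKNOWN,
    CellSystem,
    Condition,
    PartialTruthTable,
    Row,
    ScreenResult,
    SensingPattern,
)
from .perturb import apply_condition
from .rule1 import count_patterns, enumerate_patterns
from . import functions as fspace


@dataclass
class Contradiction:
    """Evidence that a candidate sensing pattern cannot stand.

    ``row`` is the offending input tuple; ``first`` and ``second`` are the
    witnessing ``(condition name, cell, observed value)`` records that
    assign it conflicting outputs.
    """

    row: Row
    first: Tuple[str, str, int]
    second: Tuple[str, str, int]

    def describe(self, signal_names: Sequence[str]) -> str:
        args = ", ".join(
            f"X_{name}={bit}" for name, bit in zip(signal_names, self.row)
        )
        c1, cell1, v1 = self.first
        c2, cell2, v2 = self.second
        return (
            f"F({args}) would have to equal {v1} (cell {cell1} under {c1}) "
            f"and {v2} (cell {cell2} under {c2}) simultaneously"
        )


def accumulate_constraints(
    pattern: SensingPattern,
    conditions: Sequence[Condition],
    system: CellSystem,
) -> Union[PartialTruthTable, Contradiction]:
    """Collect truth-table constraints imposed by all conditions.

    Cells observed as :data:`UNKNOWN` contribute nothing.  Returns the
    accumulated :class:`PartialTruthTable`, or a :class:`Contradiction`
    naming the clashing row and its two witnesses.
    """
    table = PartialTruthTable.empty(system.k)
    witness: Dict[Row, Tuple[str, str, int]] = {}
    for condition in conditions:
        perturbed = apply_condition(pattern, condition, system)
        for cell, observed in condition.observed.items():
            if observed is UNKNOWN:
                continue
            if cell not in perturbed.states:
                raise ValueError(
                    f"condition {condition.name!r} observes unknown cell {cell!r}"
                )
            row = perturbed.states[cell]
            current = table.entries[row]
            if current is None:
                table.entries[row] = observed
                witness[row] = (condition.name, cell, observed)
            elif current != observed:
                return Contradiction(
                    row=row,
                    first=witness[row],
                    second=(condition.name, cell, observed),
                )
    return table


def screen_system(
    system: CellSystem,
    conditions: Sequence[Condition],
    *,
    max_undetermined: int = 20,
    criticality: bool = True,
) -> ScreenResult:
    """Run the full screen: Rule-1 enumeration filtered by Rule-2 consistency.

    Survivors are reported in enumeration order together with their partial
    truth tables and compatible-function counts.  The functions compatible
    with *every* survivor are the completions of the conflict-checked merge
    of all survivor tables.  Per-survivor criticality labels are aggregated
    over each survivor's own compatible functions (a signal is critical only
    if it is critical under all of them); criticality is skipped when a
    survivor's table leaves too many rows undetermined to enumerate, or when
    no compatible function produces a differential output.
    """
    if not conditions:
        raise ValueError("screen requires at least one condition")
    survivors: List[SensingPattern] = []
    tables: List[PartialTruthTable] = []
    for pattern in enumerate_patterns(system):
        outcome = accumulate_constraints(pattern, conditions, system)
        if isinstance(outcome, Contradiction):
            continue
        survivors.append(pattern)
        tables.append(outcome)
    counts = [fspace.count_completions(t) for t in tables]
    merged, conflicts = fspace.merge_tables(tables) if tables else (None, [])
    common: List = []
    if merged is not None and not conflicts:
        if len(fspace.undetermined_rows(merged)) <= max_undetermined:
            common = fspace.enumerate_completions(merged)
    labels: List[Dict[str, str]] = []
    if criticality:
        for pattern, table in zip(survivors, tables):
            if len(fspace.undetermined_rows(table)) > max_undetermined:
                labels.append({})
                continue
            compatible = fspace.enumerate_completions(table)
            labels.append(fspace.summarize_criticality(pattern, compatible, system))
    else:
        labels = [{} for _ in survivors]
    return ScreenResult(
        surviving_patterns=survivors,
        partial_tables=tables,
        function_counts=counts,
        common_functions=common,
        common_conflict_rows=conflicts,
        criticality=labels,
        n_patterns_total=count_patterns(system),
    )
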