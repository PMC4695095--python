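"""Boolean functions compatible with partial truth tables.

Each undetermined row of a partial truth table doubles the number of total
Boolean functions that complete it; observations therefore pin the function
space down to ``2**(number of undetermined rows)`` candidates.  This module
enumerates and intersects those candidates and classifies which signals'
cell-to-cell differences actually drive the output pattern.
"""

from __future__ import annotations

from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

from .model import (
    UNDETERMINED,
    BooleanFunction,
    CellSystem,
    PartialTruthTable,
    Row,
    SensingPattern,
    all_rows,
)

CRITICAL = "critical"
DISPENSABLE = "dispensable"
UNIFORM = "uniform"


class CompletionCapacityError(ValueError):
    """Raised when a table has too many undetermined rows to enumerate."""


def undetermined_rows(table: PartialTruthTable) -> List[Row]:
    """Input tuples whose output is not pinned down, in sorted order."""
    return sorted(r for r, v in table.entries.items() if v is UNDETERMINED)


def count_completions(table: PartialTruthTable) -> int:
    """Number of total Boolean functions agreeing with the determined rows."""
    return 2 ** len(undetermined_rows(table))


def enumerate_completions(
    table: PartialTruthTable, max_undetermined: int = 20
) -> List[BooleanFunction]:
    """All total functions completing a partial table, in deterministic order.

    Undetermined rows are filled by binary counting over their sorted order.
    Guarded: more than ``max_undetermined`` open rows raises
    :class:`CompletionCapacityError` (use :func:`count_completions` instead).
    """
    open_rows = undetermined_rows(table)
    if len(open_rows) > max_undetermined:
        raise CompletionCapacityError(
            f"{len(open_rows)} undetermined rows exceed the enumeration guard "
            f"({max_undetermined}); use count_completions for the count"
        )
    completions = []
    for fill in product((0, 1), repeat=len(open_rows)):
        entries = dict(table.entries)
        for row, bit in zip(open_rows, fill):
            entries[row] = bit
        completions.append(BooleanFunction(table.k, entries))
    return completions


def merge_tables(
    tables: Sequence[PartialTruthTable],
) -> Tuple[PartialTruthTable, List[Row]]:
    """Combine determined rows of several tables over the same signals.

    Returns the merged table plus the sorted list of conflicting rows (rows
    determined 0 in one table and 1 in another).  Conflicting rows are left
    undetermined in the returned table.
    """
    if not tables:
        raise ValueError("merge_tables requires at least one table")
    k = tables[0].k
    if any(t.k != k for t in tables):
        raise ValueError("tables disagree on the number of signals")
    merged = PartialTruthTable.empty(k)
    conflicts: set = set()
    for table in tables:
        for row, value in table.determined().items():
            current = merged.entries[row]
            if current is UNDETERMINED:
                merged.entries[row] = value
            elif current != value:
                conflicts.add(row)
                merged.entries[row] = UNDETERMINED
    return merged, sorted(conflicts)


def common_functions(tables: Sequence[PartialTruthTable]) -> List[BooleanFunction]:
    """Functions completing every table; empty when the tables conflict."""
    merged, conflicts = merge_tables(tables)
    if conflicts:
        return []
    return enumerate_completions(merged)


def critical_signals(
    pattern: SensingPattern,
    function: BooleanFunction,
    system: CellSystem,
    detailed: bool = False,
):
    """Classify each signal's role in patterning, for one (pattern, function).

    A signal whose state is the same in every cell is ``uniform`` -- it
    cannot carry positional information here.  For a non-uniform signal, its
    column is replaced by each constant in {0, 1} (a forced 1 still respects
    the reception mask) and the outputs recomputed:

    * every uniformization collapses the output to a constant -> ``critical``
      (the signal's differential input is required for any patterning);
    * at least one uniformization reproduces the exact unperturbed output
      partition -> ``dispensable`` (its differential input is not needed);
    * otherwise the signal is labeled ``critical`` with a ``mixed``
      annotation (patterning changes but does not vanish).

    Raises :class:`ValueError` when the unmodified pattern already yields a
    uniform output (no differential to attribute).
    """
    base = {cell: function(bits) for cell, bits in pattern.states.items()}
    if len(set(base.values())) == 1:
        raise ValueError(
            "function output is uniform under this pattern; "
            "criticality is undefined"
        )
    labels: Dict[str, str] = {}
    details: Dict[str, Dict] = {}
    for j, spec in enumerate(system.signals):
        column = pattern.column(j)
        if len(set(column.values())) == 1:
            labels[spec.name] = UNIFORM
            details[spec.name] = {"label": UNIFORM}
            continue
        mask = spec.mask_for(system.cells)
        outputs = []
        for value in (0, 1):
            forced = {
                cell: (value if (value == 0 or cell in mask) else 0)
                for cell in system.cells
            }
            out = {}
            for cell in system.cells:
                bits = list(pattern.states[cell])
                bits[j] = forced[cell]
                out[cell] = function(tuple(bits))
            outputs.append(out)
        collapses = [len(set(out.values())) == 1 for out in outputs]
        preserves = [out == base for out in outputs]
        if all(collapses):
            label, mixed = CRITICAL, False
        elif any(preserves):
            label, mixed = DISPENSABLE, False
        else:
            label, mixed = CRITICAL, True
        labels[spec.name] = label
        details[spec.name] = {
            "label": label,
            "mixed": mixed,
            "forced_outputs": outputs,
        }
    return details if detailed else labels


def summarize_criticality(
    pattern: SensingPattern,
    functions: Sequence[BooleanFunction],
    system: CellSystem,
) -> Dict[str, str]:
    """Aggregate criticality labels over a set of compatible functions.

    A signal is reported critical only when it is critical under every
    function that yields a differential output; uniform columns stay
    uniform; everything else is dispensable.  Functions whose output is
    uniform over the pattern are skipped (they cannot pattern the tissue);
    an empty result means no compatible function was informative.
    """
    per_function: List[Dict[str, str]] = []
    for function in functions:
        try:
            per_function.append(critical_signals(pattern, function, system))
        except ValueError:
            continue
    if not per_function:
        return {}
    summary: Dict[str, str] = {}
    for name in system.signal_names:
        votes = {labels[name] for labels in per_function}
        if votes == {UNIFORM}:
            summary[name] = UNIFORM
        elif votes == {CRITICAL}:
            summary[name] = CRITICAL
        else:
            summary[name] = DISPENSABLE
    return summary


# -- readable expressions for small k ---------------------------------------

def expression(function: BooleanFunction, names: Sequence[str]) -> str:
    """A minimal-ish Boolean expression for k <= 2, else the raw bit string.

    Candidates (constants, literals, and binary combinations of literals)
    are tried in order of increasing size; intended for report readability,
    not for canonical minimization.
    """
    k = function.k
    if k > 2 or len(names) != k:
        return "".join(str(b) for b in function.bits())
    rows = all_rows(k)

    def matches(f) -> bool:
        return all(function(r) == f(r) for r in rows)

    literals = []
    for i, name in enumerate(names):
        literals.append((name, lambda r, i=i: r[i]))
        literals.append((f"NOT {name}", lambda r, i=i: 1 - r[i]))
    candidates = [("0", lambda r: 0), ("1", lambda r: 1)]
    candidates += literals
    for ai, (atext, afun) in enumerate(literals):
        for btext, bfun in literals[ai + 1:]:
            candidates.append((f"{atext} AND {btext}",
                               lambda r, a=afun, b=bfun: a(r) & b(r)))
            candidates.append((f"{atext} OR {btext}",
                               lambda r, a=afun, b=bfun: a(r) | b(r)))
    if k == 2:
        candidates.append((f"{names[0]} XOR {names[1]}", lambda r: r[0] ^ r[1]))
        candidates.append((f"NOT ({names[0]} XOR {names[1]})",
                           lambda r: 1 - (r[0] ^ r[1])))
    for text, f in candidates:
        if matches(f):
            return text
    return "".join(str(b) for b in function.bits())
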