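"""Configuration, contact-area, and report I/O.

Cell systems and condition rosters are stored as YAML (JSON is a YAML
subset and is accepted transparently).  Signaling-strength orderings can be
derived from per-cell contact-area tables -- the working assumption being
that a larger area of contact with ligand-expressing cells means stronger
signaling -- with an optional distance-rank fallback for cells that do not
touch a source at all.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd
import yaml

from .model import (
    UNKNOWN,
    CellSystem,
    Condition,
    OVERRIDE_LEVELS,
    ScreenResult,
    SignalSpec,
)
from . import functions as fspace


class ConfigError(ValueError):
    """A configuration file violates the published schema."""

    def __init__(self, path, field: str, message: str):
        self.path = str(path)
        self.field = field
        super().__init__(f"{self.path}: field {field!r}: {message}")


# -- orderings from contact areas -------------------------------------------

def ordering_from_contacts(
    areas: Union[Mapping[str, float], pd.DataFrame],
    tie_tolerance: float = 0.0,
    fallback_ranks: Optional[Mapping[str, float]] = None,
) -> List[List[str]]:
    """Derive a strength ordering (tie-groups, strongest first) from areas.

    Cells are sorted by descending contact area; consecutive cells whose
    areas differ by at most ``tie_tolerance`` (relative to the larger of the
    two) merge into one tie-group.  Cells with zero area are appended after
    all contacting cells: ordered by ``fallback_ranks`` when given (smaller
    rank = stronger, ties merge), otherwise as a single final tie-group.

    The default tolerance is 0 because strict chains are what clean
    geometric data produce; the tolerance exists for noisy measurements.
    The result is invariant under rescaling all areas by a positive factor.
    """
    if isinstance(areas, pd.DataFrame):
        if not {"cell", "area"} <= set(areas.columns):
            raise ValueError("area table needs 'cell' and 'area' columns")
        if areas["cell"].duplicated().any():
            dup = sorted(areas.loc[areas["cell"].duplicated(), "cell"])
            raise ValueError(f"duplicate cells in area table: {', '.join(dup)}")
        areas = dict(zip(areas["cell"], areas["area"]))
    for cell, area in areas.items():
        if area < 0:
            raise ValueError(f"negative contact area for cell {cell!r}")
    if tie_tolerance < 0:
        raise ValueError("tie_tolerance must be non-negative")
    contacting = sorted(
        ((c, a) for c, a in areas.items() if a > 0),
        key=lambda item: (-item[1], item[0]),
    )
    groups: List[List[str]] = []
    previous_area: Optional[float] = None
    for cell, area in contacting:
        if (
            previous_area is not None
            and (previous_area - area) <= tie_tolerance * previous_area
        ):
            groups[-1].append(cell)
        else:
            groups.append([cell])
        previous_area = area
    zero_cells = [c for c, a in areas.items() if a == 0]
    if zero_cells:
        if fallback_ranks is not None:
            missing = sorted(c for c in zero_cells if c not in fallback_ranks)
            if missing:
                raise ValueError(
                    "zero-contact cells lack a fallback rank: "
                    + ", ".join(missing)
                )
            by_rank: Dict[float, List[str]] = {}
            for cell in zero_cells:
                by_rank.setdefault(fallback_ranks[cell], []).append(cell)
            for rank in sorted(by_rank):
                groups.append(sorted(by_rank[rank]))
        else:
            groups.append(sorted(zero_cells))
    return groups


def read_contact_table(
    path, signal: Optional[str] = None, drop_self: bool = False
) -> pd.DataFrame:
    """Load a headered CSV of per-cell contact areas.

    Expected columns: ``signal, cell, area`` and optionally ``source`` (the
    ligand-expressing cell a contact row refers to).  ``drop_self`` removes
    rows where ``source == cell`` before aggregation, which is how autocrine
    reception of a membrane-tethered ligand is excluded.  Rows are summed
    per (signal, cell).
    """
    frame = pd.read_csv(path)
    required = {"signal", "cell", "area"}
    if not required <= set(frame.columns):
        raise ConfigError(path, "columns", f"need columns {sorted(required)}")
    if drop_self and "source" in frame.columns:
        frame = frame[frame["source"] != frame["cell"]]
    if signal is not None:
        frame = frame[frame["signal"] == signal]
    return (
        frame.groupby(["signal", "cell"], as_index=False)["area"].sum()
    )


# -- system / condition configs ---------------------------------------------

def _load_document(path):
    text = Path(path).read_text()
    return yaml.safe_load(text)


def read_system(path) -> CellSystem:
    """Read a cell-system config (YAML or JSON)."""
    doc = _load_document(path)
    if not isinstance(doc, dict):
        raise ConfigError(path, "<root>", "expected a mapping")
    cells = doc.get("cells")
    if not isinstance(cells, list) or not all(isinstance(c, str) for c in cells):
        raise ConfigError(path, "cells", "expected a list of cell names")
    raw_signals = doc.get("signals")
    if not isinstance(raw_signals, list) or not raw_signals:
        raise ConfigError(path, "signals", "expected a non-empty list")
    specs = []
    for idx, entry in enumerate(raw_signals):
        where = f"signals[{idx}]"
        if not isinstance(entry, dict) or "name" not in entry:
            raise ConfigError(path, where, "expected a mapping with a 'name'")
        ordering = entry.get("ordering") or []
        if not isinstance(ordering, list):
            raise ConfigError(path, f"{where}.ordering", "expected a list")
        groups = []
        for group in ordering:
            if isinstance(group, str):
                group = [group]
            if not isinstance(group, list):
                raise ConfigError(
                    path, f"{where}.ordering", "tie-groups must be lists or strings"
                )
            groups.append(tuple(group))
        mask = entry.get("reception_mask")
        if mask is not None and mask != "all":
            if not isinstance(mask, list):
                raise ConfigError(
                    path, f"{where}.reception_mask", "expected 'all' or a list"
                )
            mask = frozenset(mask)
        else:
            mask = None
        specs.append(
            SignalSpec(
                name=entry["name"],
                ordering=tuple(groups),
                reception_mask=mask,
                tethered=bool(entry.get("tethered", False)),
            )
        )
    return CellSystem(
        cells=tuple(cells),
        signals=tuple(specs),
        output_name=doc.get("output", "output"),
    )


def write_system(system: CellSystem, path) -> None:
    doc = {
        "output": system.output_name,
        "cells": list(system.cells),
        "signals": [
            {
                "name": spec.name,
                "ordering": [list(group) for group in spec.ordering],
                "reception_mask": (
                    "all"
                    if spec.reception_mask is None
                    else sorted(spec.reception_mask)
                ),
                "tethered": spec.tethered,
            }
            for spec in system.signals
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _parse_observed(value, path, where):
    if value is None or value == "unknown":
        return UNKNOWN
    if value in (0, 1):
        return int(value)
    raise ConfigError(path, where, f"observed value must be 0, 1 or 'unknown', got {value!r}")


def read_conditions(path, system: Optional[CellSystem] = None) -> List[Condition]:
    """Read a condition roster (YAML/JSON list); optionally check a system."""
    doc = _load_document(path)
    if isinstance(doc, dict) and "conditions" in doc:
        doc = doc["conditions"]
    if not isinstance(doc, list):
        raise ConfigError(path, "<root>", "expected a list of conditions")
    conditions = []
    for idx, entry in enumerate(doc):
        where = f"conditions[{idx}]"
        if not isinstance(entry, dict) or "name" not in entry:
            raise ConfigError(path, where, "expected a mapping with a 'name'")
        overrides = entry.get("overrides") or {}
        for signal, level in overrides.items():
            if level not in OVERRIDE_LEVELS:
                raise ConfigError(
                    path,
                    f"{where}.overrides.{signal}",
                    f"override must be one of {OVERRIDE_LEVELS}, got {level!r}",
                )
            if system is not None and signal not in system.signal_names:
                raise ConfigError(
                    path, f"{where}.overrides", f"unknown signal {signal!r}"
                )
        observed_raw = entry.get("observed") or {}
        if not observed_raw:
            raise ConfigError(path, f"{where}.observed", "at least one cell must be observed")
        observed = {}
        for cell, value in observed_raw.items():
            if system is not None and cell not in system.cells:
                raise ConfigError(
                    path, f"{where}.observed", f"unknown cell {cell!r}"
                )
            observed[cell] = _parse_observed(value, path, f"{where}.observed.{cell}")
        conditions.append(
            Condition(name=entry["name"], overrides=dict(overrides), observed=observed)
        )
    return conditions


def write_conditions(conditions: Sequence[Condition], path) -> None:
    doc = [
        {
            "name": c.name,
            "overrides": dict(c.overrides),
            "observed": {
                cell: ("unknown" if v is UNKNOWN else int(v))
                for cell, v in c.observed.items()
            },
        }
        for c in conditions
    ]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# -- reports ----------------------------------------------------------------

def _row_key(row) -> str:
    return "".join(str(b) for b in row)


def report_dict(result: ScreenResult, system: CellSystem) -> dict:
    """A JSON-serializable summary of a screen."""
    survivors = []
    for i, (pattern, table, count) in enumerate(
        zip(result.surviving_patterns, result.partial_tables, result.function_counts)
    ):
        survivors.append(
            {
                "index": i + 1,
                "states": {
                    cell: list(pattern.states[cell]) for cell in system.cells
                },
                "truth_table": {
                    _row_key(row): value for row, value in table.determined().items()
                },
                "undetermined": [
                    _row_key(row) for row in fspace.undetermined_rows(table)
                ],
                "function_count": count,
                "criticality": result.criticality[i] if result.criticality else {},
            }
        )
    return {
        "output": system.output_name,
        "signals": list(system.signal_names),
        "cells": list(system.cells),
        "patterns_total": result.n_patterns_total,
        "survivor_count": len(result.surviving_patterns),
        "survivors": survivors,
        "function_counts": list(result.function_counts),
        "common_function_count": len(result.common_functions),
        "common_functions": [
            {_row_key(row): value for row, value in f.entries.items()}
            for f in result.common_functions
        ],
        "common_conflict_rows": [
            _row_key(row) for row in result.common_conflict_rows
        ],
    }


def render_report_text(result: ScreenResult, system: CellSystem) -> str:
    """A human-readable screen report (survivor tables and verdicts)."""
    names = system.signal_names
    lines = [
        f"Screen of {system.output_name!r}: "
        f"{len(result.surviving_patterns)} of {result.n_patterns_total} "
        "admissible sensing patterns survive",
        "",
    ]
    for i, (pattern, table, count) in enumerate(
        zip(result.surviving_patterns, result.partial_tables, result.function_counts)
    ):
        lines.append(f"sensing pattern {i + 1}")
        header = "  cell".ljust(12) + "  ".join(f"X_{n}" for n in names)
        lines.append(header)
        for cell in system.cells:
            bits = "  ".join(
                str(b).ljust(len(n) + 2) for b, n in zip(pattern.states[cell], names)
            )
            lines.append(f"  {cell}".ljust(12) + bits)
        lines.append(f"  compatible Boolean functions: {count}")
        if count == 1:
            unique = fspace.enumerate_completions(table)[0]
            lines.append(
                f"  unique function: F = {fspace.expression(unique, names)}"
                if system.k <= 2
                else "  unique function bits: "
                + "".join(str(b) for b in unique.bits())
            )
        open_rows = fspace.undetermined_rows(table)
        if open_rows:
            lines.append(
                "  undetermined rows: "
                + ", ".join("(" + ",".join(map(str, r)) + ")" for r in open_rows)
            )
        if result.criticality and result.criticality[i]:
            verdict = ", ".join(
                f"{name}: {label}" for name, label in result.criticality[i].items()
            )
            lines.append(f"  criticality: {verdict}")
        lines.append("")
    lines.append(f"functions compatible with every survivor: "
                 f"{len(result.common_functions)}")
    for f in result.common_functions:
        expr = fspace.expression(f, names)
        lines.append(f"  F = {expr}" if system.k <= 2 else f"  F bits = {expr}")
        if system.k > 2:
            ones = [r for r, v in sorted(f.entries.items()) if v == 1]
            lines.append(
                "    F=1 at: "
                + "; ".join("(" + ",".join(map(str, r)) + ")" for r in ones)
            )
    if result.common_conflict_rows:
        lines.append(
            "conflicting rows across survivors: "
            + ", ".join(
                "(" + ",".join(map(str, r)) + ")"
                for r in result.common_conflict_rows
            )
        )
    return "\n".join(lines)


def write_report(
    result: ScreenResult, system: CellSystem, path, format: str = "json"
) -> None:
    """Write a screen report to ``path`` as JSON or plain text."""
    if format == "json":
        Path(path).write_text(json.dumps(report_dict(result, system), indent=2))
    elif format == "text":
        Path(path).write_text(render_report_text(result, system) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
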