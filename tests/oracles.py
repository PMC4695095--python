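"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written directly from the definitions -- enumerate all
binary assignments, check order constraints pairwise, search all total
Boolean functions -- deliberately not reusing the package's enumeration or
screening code paths.
"""

from itertools import product

from boolsense.model import (
    UNKNOWN,
    BooleanFunction,
    CellSystem,
    SensingPattern,
    all_rows,
)


def brute_force_patterns(system: CellSystem):
    """All (2**k)**n assignments as SensingPatterns, unfiltered."""
    cells = system.cells
    k = len(system.signals)
    for bits in product((0, 1), repeat=k * len(cells)):
        yield SensingPattern(
            {
                cell: tuple(bits[i * k : (i + 1) * k])
                for i, cell in enumerate(cells)
            }
        )


def brute_admissible(pattern: SensingPattern, system: CellSystem) -> bool:
    """Source-rule check via pairwise comparisons (independent of rule1)."""
    for j, spec in enumerate(system.signals):
        mask = spec.mask_for(system.cells)
        for cell in system.cells:
            if cell not in mask and pattern.states[cell][j] != 0:
                return False
        groups = spec.ordering
        for gi in range(len(groups)):
            for gj in range(len(groups)):
                for ci in groups[gi]:
                    for cj in groups[gj]:
                        vi = pattern.states[ci][j]
                        vj = pattern.states[cj][j]
                        if gi < gj and vi < vj:  # stronger cell weaker state
                            return False
                        if gi == gj and vi != vj:  # tie-group split
                            return False
    return True


def brute_perturbed_row(pattern, condition, system, cell):
    """Input tuple of one cell under a condition, computed inline."""
    row = []
    for j, spec in enumerate(system.signals):
        level = condition.overrides.get(spec.name, "none")
        if level == "force0":
            row.append(0)
        elif level == "force1":
            row.append(1 if cell in spec.mask_for(system.cells) else 0)
        else:
            row.append(pattern.states[cell][j])
    return tuple(row)


def brute_consistent(pattern, conditions, system) -> bool:
    """Does any total Boolean function explain all observations?"""
    k = len(system.signals)
    rows = all_rows(k)
    for bits in product((0, 1), repeat=len(rows)):
        function = dict(zip(rows, bits))
        ok = True
        for condition in conditions:
            for cell, observed in condition.observed.items():
                if observed is UNKNOWN:
                    continue
                row = brute_perturbed_row(pattern, condition, system, cell)
                if function[row] != observed:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return True
    return False


def brute_survivors(system, conditions):
    """The screened set computed entirely by brute force."""
    return [
        pattern
        for pattern in brute_force_patterns(system)
        if brute_admissible(pattern, system)
        and brute_consistent(pattern, conditions, system)
    ]


def weak_orders(cells):
    """All weak orders (ordered set partitions) of a sequence of cells."""
    cells = list(cells)
    if not cells:
        yield ()
        return
    results = []

    def expand(remaining, current):
        if not remaining:
            results.append(tuple(tuple(g) for g in current))
            return
        head, rest = remaining[0], remaining[1:]
        for i in range(len(current)):
            expand(rest, current[:i] + [current[i] + [head]] + current[i + 1:])
        for i in range(len(current) + 1):
            expand(rest, current[:i] + [[head]] + current[i:])

    expand(cells, [])
    # Deduplicate: insertion into a group is order-insensitive.
    yield from sorted(set(results))
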