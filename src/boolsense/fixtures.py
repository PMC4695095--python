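"""Worked cell systems and a reproducible random-system generator.

The toy fixtures are two-cell, two-signal systems with opposing signaling
sources and a pair of conceptual loss-of-function experiments; they exercise
every stage of the pipeline at desk scale.  The embryo fixtures model the
animal hemisphere of the 32-cell ascidian embryo (eight bilateral pairs of
ectodermal cells, four signaling pathways, *Otx* as output); their strength
orderings and per-condition outcomes are shipped as data files and are
synthetic reconstructions consistent with published qualitative phenotypes
(see the comments in the data files).

:func:`random_system` draws a system together with a known ground-truth
(sensing pattern, Boolean function) pair and observations generated from it,
for soundness and recovery property tests.
"""

from __future__ import annotations

import random
from importlib import resources
from typing import Dict, List, Optional, Tuple

from .model import (
    BooleanFunction,
    CellSystem,
    Condition,
    FORCE0,
    FORCE1,
    SensingPattern,
    SignalSpec,
    all_rows,
)
from .perturb import apply_condition
from .rule1 import signal_states
from . import io as bsio

#: Cell-state order used by the classical 16-pattern numbering of the toy
#: system: cell I's state indexes the coarse block, cell II's the offset.
_TOY_STATES = ((0, 0), (0, 1), (1, 0), (1, 1))


def _data_path(name: str):
    return resources.files("boolsense.data").joinpath(name)


def fig2_pattern_number(pattern: SensingPattern) -> int:
    """The 1..16 index of a toy-system pattern.

    Reconstructed as ``4*(i - 1) + j`` where ``i`` and ``j`` are the 1-based
    positions of cell I's and cell II's ``(X_a, X_b)`` states in the order
    (0,0), (0,1), (1,0), (1,1).  This numbering reproduces all four classic
    exclusion lists: the source rule removes {3,4,7,8} (signal a) and
    {5,7,13,15} (signal b), the uniqueness rule removes {1,6,11,16}, and the
    two experiments remove {2,9,10}.
    """
    i = _TOY_STATES.index(pattern.states["I"])
    j = _TOY_STATES.index(pattern.states["II"])
    return 4 * i + j + 1


def _toy_conditions() -> List[Condition]:
    return [
        Condition(
            name="wild_type",
            overrides={},
            observed={"I": 1, "II": 0},
        ),
        Condition(
            name="experiment1_a_kd",
            overrides={"a": FORCE0},
            observed={"I": 0, "II": 0},
        ),
        Condition(
            name="experiment2_b_kd",
            overrides={"b": FORCE0},
            observed={"I": 1, "II": 1},
        ),
    ]


def fig2_system() -> Tuple[CellSystem, List[Condition]]:
    """Two cells, two opposing diffusible signals, two knockdown experiments.

    Signal ``a`` reaches cell I more strongly (its source is on cell I's
    side), signal ``b`` reaches cell II more strongly; gene ``o`` comes on
    only in cell I.  Knocking down ``a`` silences ``o`` everywhere; knocking
    down ``b`` turns ``o`` on in both cells.
    """
    system = CellSystem(
        cells=("I", "II"),
        signals=(
            SignalSpec(name="a", ordering=(("I",), ("II",))),
            SignalSpec(name="b", ordering=(("II",), ("I",))),
        ),
        output_name="o",
    )
    return system, _toy_conditions()


def s1fig_system() -> Tuple[CellSystem, List[Condition]]:
    """The toy system with ``b`` tethered to its source: cell I never receives it."""
    system = CellSystem(
        cells=("I", "II"),
        signals=(
            SignalSpec(name="a", ordering=(("I",), ("II",))),
            SignalSpec(
                name="b",
                ordering=(("II",),),
                reception_mask=frozenset({"II"}),
                tethered=True,
            ),
        ),
        output_name="o",
    )
    return system, _toy_conditions()


def s2fig_system() -> Tuple[CellSystem, List[Condition]]:
    """The toy system with tethered ``b`` also expressed by cells I and II.

    Both cells now receive ``b``; because cell II touches both the source
    and cell I while cell I only touches cell II, the strength order is
    II over I -- the same constraint as the diffusible case, and the screen
    yields the same two survivors.
    """
    system = CellSystem(
        cells=("I", "II"),
        signals=(
            SignalSpec(name="a", ordering=(("I",), ("II",))),
            SignalSpec(name="b", ordering=(("II",), ("I",)), tethered=True),
        ),
        output_name="o",
    )
    return system, _toy_conditions()


def embryo_system(
    stage: str = "mid_late",
    orderings: Optional[Dict[str, List[List[str]]]] = None,
    include_double_morphants: bool = True,
) -> Tuple[CellSystem, List[Condition]]:
    """The ascidian animal-hemisphere system with its perturbation roster.

    ``stage`` selects the ``"mid_late"`` or ``"early"`` ordering set (the
    two differ only in geometry-derived chains).  ``orderings`` overrides
    individual signals' chains, keyed by signal name, so alternative
    geometric reconstructions are config swaps rather than code changes.
    ``include_double_morphants=False`` returns the roster without the two
    discriminating double knockdowns, the state of evidence under which the
    compatible-function counts per survivor are 16, 8 and 8.
    """
    files = {
        "mid_late": "embryo_mid_late_system.yaml",
        "early": "embryo_early_system.yaml",
    }
    if stage not in files:
        raise ValueError(f"unknown stage {stage!r}; expected one of {sorted(files)}")
    with resources.as_file(_data_path(files[stage])) as path:
        system = bsio.read_system(path)
    if orderings:
        new_specs = []
        for spec in system.signals:
            if spec.name in orderings:
                spec = SignalSpec(
                    name=spec.name,
                    ordering=tuple(tuple(g) for g in orderings[spec.name]),
                    reception_mask=spec.reception_mask,
                    tethered=spec.tethered,
                )
            new_specs.append(spec)
        system = CellSystem(
            cells=system.cells, signals=tuple(new_specs),
            output_name=system.output_name,
        )
    with resources.as_file(_data_path("embryo_conditions.yaml")) as path:
        conditions = bsio.read_conditions(path, system=system)
    if include_double_morphants:
        with resources.as_file(_data_path("embryo_double_morphants.yaml")) as path:
            conditions += bsio.read_conditions(path, system=system)
    return system, conditions


def random_system(
    n_cells: int,
    k_signals: int,
    n_conditions: int,
    seed: int,
) -> Tuple[CellSystem, List[Condition], SensingPattern, BooleanFunction]:
    """A reproducible random system with known ground truth.

    Each signal gets a random weak order (random permutation with adjacent
    tie merges) and, occasionally, a reception mask excluding one cell.  The
    true sensing pattern is drawn uniformly from the admissible set, the
    true function uniformly from all total functions, and every condition's
    observations are computed by applying the function to the perturbed true
    pattern.  By construction the true pair always survives the screen.
    """
    if n_cells < 1 or k_signals < 1 or n_conditions < 1:
        raise ValueError("n_cells, k_signals and n_conditions must be positive")
    rng = random.Random(seed)
    cells = tuple(f"c{i + 1}" for i in range(n_cells))
    specs = []
    for s in range(k_signals):
        order = list(cells)
        rng.shuffle(order)
        mask = None
        if n_cells > 1 and rng.random() < 0.2:
            excluded = rng.choice(order)
            order.remove(excluded)
            mask = frozenset(c for c in cells if c != excluded)
        groups: List[Tuple[str, ...]] = []
        for cell in order:
            if groups and rng.random() < 0.3:
                groups[-1] = groups[-1] + (cell,)
            else:
                groups.append((cell,))
        specs.append(
            SignalSpec(name=f"s{s + 1}", ordering=tuple(groups), reception_mask=mask)
        )
    system = CellSystem(cells=cells, signals=tuple(specs), output_name="g")
    true_pattern = SensingPattern.from_columns(
        system,
        {
            spec.name: rng.choice(signal_states(spec, cells))
            for spec in system.signals
        },
    )
    rows = all_rows(k_signals)
    true_function = BooleanFunction(
        k_signals, {row: rng.randint(0, 1) for row in rows}
    )
    conditions = []
    for c in range(n_conditions):
        if c == 0:
            overrides: Dict[str, str] = {}
            name = "wild_type"
        else:
            chosen = rng.sample(system.signal_names, rng.randint(1, min(2, k_signals)))
            overrides = {name: rng.choice((FORCE0, FORCE1)) for name in chosen}
            name = f"perturbation_{c}"
        condition = Condition(name=name, overrides=overrides, observed={})
        perturbed = apply_condition(true_pattern, condition, system)
        condition.observed = {
            cell: true_function(perturbed.states[cell]) for cell in cells
        }
        conditions.append(condition)
    return system, conditions, true_pattern, true_function
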