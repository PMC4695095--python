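"""Transform a candidate wild-type sensing pattern under a perturbation.

A whole-embryo knockdown (``force0``) silences a signal in every cell; a
gain of function (``force1``) turns it on in every cell of the reception
mask -- a cell that cannot physically receive a tethered ligand stays off
even under overexpression, whereas a bath-applied recombinant protein is
modeled with a full mask.  Unperturbed signals keep their candidate states.
"""

from __future__ import annotations

from .model import (
    FORCE0,
    FORCE1,
    NO_OVERRIDE,
    OVERRIDE_LEVELS,
    CellSystem,
    Condition,
    SensingPattern,
    _check_pattern_matches_system,
)


def apply_condition(
    pattern: SensingPattern, condition: Condition, system: CellSystem
) -> SensingPattern:
    """The sensing pattern holding under an experimental condition.

    Forced columns are uniform on the reception mask and therefore up-closed
    by construction, so the result is admissible whenever the input is.
    Raises :class:`ValueError` if the condition overrides a signal the
    system does not have, or names an unknown override level.
    """
    _check_pattern_matches_system(pattern, system)
    names = system.signal_names
    for signal_name, level in condition.overrides.items():
        if signal_name not in names:
            raise ValueError(
                f"condition {condition.name!r} overrides unknown signal "
                f"{signal_name!r}"
            )
        if level not in OVERRIDE_LEVELS:
            raise ValueError(
                f"condition {condition.name!r}: unknown override level {level!r} "
                f"for signal {signal_name!r}"
            )
    new_states = {}
    masks = [spec.mask_for(system.cells) for spec in system.signals]
    for cell in system.cells:
        bits = list(pattern.states[cell])
        for j, spec in enumerate(system.signals):
            level = condition.override_for(spec.name)
            if level == NO_OVERRIDE:
                continue
            if level == FORCE0:
                bits[j] = 0
            elif level == FORCE1:
                bits[j] = 1 if cell in masks[j] else 0
        new_states[cell] = tuple(bits)
    return SensingPattern(new_states)
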