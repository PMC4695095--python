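"""Domain-type validation and source-rule admissibility."""

import pytest

from boolsense import fixtures as fx
from boolsense.model import (
    CellSystem,
    SensingPattern,
    SignalSpec,
    pattern_is_admissible,
    validate_system,
)

from oracles import brute_admissible, brute_force_patterns


def test_toy_fixture_is_well_formed(fig2):
    system, _ = fig2
    assert validate_system(system) == []


def test_masked_fixture_is_well_formed():
    system, _ = fx.s1fig_system()
    assert validate_system(system) == []


def test_duplicate_cell_in_ordering_is_reported():
    system = CellSystem(
        cells=("I", "II"),
        signals=(
            SignalSpec(name="a", ordering=(("I",), ("II",))),
            SignalSpec(name="b", ordering=(("II",), ("II",))),
        ),
    )
    violations = validate_system(system)
    assert len(violations) == 1
    assert "more than once" in violations[0]
    assert "'b'" in violations[0]


@pytest.mark.parametrize(
    "make_system, expected",
    [
        (lambda: CellSystem(cells=(), signals=(SignalSpec(name="a"),)), "no cells"),
        (lambda: CellSystem(cells=("I",), signals=()), "no signals"),
        (
            lambda: CellSystem(
                cells=("I",),
                signals=(SignalSpec(name="a", reception_mask=frozenset({"Z"})),),
            ),
            "unknown cells",
        ),
        (
            lambda: CellSystem(
                cells=("I", "II"),
                signals=(
                    SignalSpec(
                        name="a",
                        ordering=(("I", "II"),),
                        reception_mask=frozenset({"II"}),
                    ),
                ),
            ),
            "outside the reception_mask",
        ),
    ],
)
def test_structural_violations_are_messages_not_exceptions(make_system, expected):
    violations = validate_system(make_system())
    assert any(expected in message for message in violations)


def test_unreadable_input_raises_naming_the_field():
    with pytest.raises(TypeError, match="cells"):
        validate_system(CellSystem(cells=(1, 2), signals=(SignalSpec(name="a"),)))


def test_toy_admissibility_matches_brute_force(fig2):
    """The source rule keeps exactly the classical 9 of 16 toy patterns."""
    system, _ = fig2
    admissible_numbers = sorted(
        fx.fig2_pattern_number(p)
        for p in brute_force_patterns(system)
        if pattern_is_admissible(p, system)
    )
    assert admissible_numbers == [1, 2, 6, 9, 10, 11, 12, 14, 16]
    # and the implementation agrees with the independent pairwise check
    for pattern in brute_force_patterns(system):
        assert pattern_is_admissible(pattern, system) == brute_admissible(
            pattern, system
        )


def test_stronger_cell_cannot_be_off_while_weaker_is_on(fig2):
    system, _ = fig2
    pattern = SensingPattern({"I": (0, 0), "II": (1, 0)})
    assert not pattern_is_admissible(pattern, system)


@pytest.mark.parametrize("seed", range(5))
def test_all_zero_and_full_mask_patterns_are_admissible(seed):
    system, _, _, _ = fx.random_system(
        n_cells=4, k_signals=3, n_conditions=1, seed=seed
    )
    zero = SensingPattern({c: (0,) * system.k for c in system.cells})
    assert pattern_is_admissible(zero, system)
    masks = [spec.mask_for(system.cells) for spec in system.signals]
    saturated = SensingPattern(
        {
            c: tuple(1 if c in masks[j] else 0 for j in range(system.k))
            for c in system.cells
        }
    )
    assert pattern_is_admissible(saturated, system)


def test_pattern_system_mismatch_is_a_contract_error(fig2):
    system, _ = fig2
    with pytest.raises(ValueError):
        pattern_is_admissible(SensingPattern({"I": (0, 0)}), system)
    with pytest.raises(ValueError):
        pattern_is_admissible(
            SensingPattern({"I": (0,), "II": (0,)}), system
        )
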