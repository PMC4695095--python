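"""Uniqueness-rule screening: constraint accumulation and survivor sets."""

import pytest

from boolsense import fixtures as fx
from boolsense.model import PartialTruthTable, SensingPattern
from boolsense.screen import Contradiction, accumulate_constraints, screen_system

from oracles import brute_survivors


def test_pattern_with_identical_off_inputs_contradicts_itself(fig2):
    """A candidate whose cells share the silenced input tuple cannot explain
    differential expression once the knockdown data are added."""
    system, conditions = fig2
    pattern2 = SensingPattern({"I": (0, 0), "II": (0, 1)})  # classical no. 2
    outcome = accumulate_constraints(pattern2, conditions, system)
    assert isinstance(outcome, Contradiction)
    assert outcome.row == (0, 0)
    witnessed_values = {outcome.first[2], outcome.second[2]}
    assert witnessed_values == {0, 1}
    text = outcome.describe(system.signal_names)
    assert "F(X_a=0, X_b=0)" in text


def test_consistent_pattern_yields_a_fully_determined_table(fig2):
    system, conditions = fig2
    pattern12 = SensingPattern({"I": (1, 0), "II": (1, 1)})
    table = accumulate_constraints(pattern12, conditions, system)
    assert isinstance(table, PartialTruthTable)
    assert table.entries == {(0, 0): 0, (0, 1): 0, (1, 0): 1, (1, 1): 0}


def test_uniform_pattern_fails_on_wild_type_alone(fig2):
    system, conditions = fig2
    uniform = SensingPattern({"I": (0, 0), "II": (0, 0)})  # classical no. 1
    outcome = accumulate_constraints(uniform, conditions[:1], system)
    assert isinstance(outcome, Contradiction)
    assert outcome.row == (0, 0)


def test_unknown_observations_contribute_no_constraint(fig2):
    system, conditions = fig2
    wt = conditions[0]
    wt_unknown = type(wt)(
        name="wt", overrides={}, observed={"I": 1, "II": None}
    )
    uniform = SensingPattern({"I": (0, 0), "II": (0, 0)})
    outcome = accumulate_constraints(uniform, [wt_unknown], system)
    assert isinstance(outcome, PartialTruthTable)


def test_toy_screen_leaves_the_two_classical_survivors(fig2):
    system, conditions = fig2
    result = screen_system(system, conditions)
    numbers = sorted(fx.fig2_pattern_number(p) for p in result.surviving_patterns)
    assert numbers == [12, 14]
    assert result.n_patterns_total == 9


def test_tethered_variant_pins_a_single_pattern():
    system, conditions = fx.s1fig_system()
    result = screen_system(system, conditions)
    assert len(result.surviving_patterns) == 1
    assert result.surviving_patterns[0].states == {"I": (1, 0), "II": (1, 1)}
    assert result.function_counts == [1]


def test_self_expressed_tethered_variant_matches_the_diffusible_case():
    system, conditions = fx.s2fig_system()
    result = screen_system(system, conditions)
    numbers = sorted(fx.fig2_pattern_number(p) for p in result.surviving_patterns)
    assert numbers == [12, 14]


@pytest.mark.parametrize("seed", range(10))
def test_survivors_match_brute_force_oracle(seed):
    system, conditions, _, _ = fx.random_system(
        n_cells=3, k_signals=2, n_conditions=3, seed=seed
    )
    result = screen_system(system, conditions, criticality=False)
    assert {p.key() for p in result.surviving_patterns} == {
        p.key() for p in brute_survivors(system, conditions)
    }


@pytest.mark.parametrize("seed", range(10))
def test_adding_evidence_never_enlarges_the_survivor_set(seed):
    system, conditions, _, _ = fx.random_system(
        n_cells=4, k_signals=2, n_conditions=4, seed=seed
    )
    previous = None
    previous_tables = None
    for upto in range(1, len(conditions) + 1):
        result = screen_system(system, conditions[:upto], criticality=False)
        current = {p.key() for p in result.surviving_patterns}
        tables = {
            p.key(): t.determined()
            for p, t in zip(result.surviving_patterns, result.partial_tables)
        }
        if previous is not None:
            assert current <= previous
            for key in current:
                for row, value in previous_tables[key].items():
                    assert tables[key][row] == value  # no determined entry flips
        previous, previous_tables = current, tables


def test_screen_requires_at_least_one_condition(fig2):
    system, _ = fig2
    with pytest.raises(ValueError):
        screen_system(system, [])
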