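"""Completion counting, enumeration, intersection, and criticality."""

import random

import pytest

from boolsense import fixtures as fx
from boolsense.functions import (
    CompletionCapacityError,
    common_functions,
    count_completions,
    critical_signals,
    enumerate_completions,
    expression,
    merge_tables,
    summarize_criticality,
    undetermined_rows,
)
from boolsense.model import (
    BooleanFunction,
    PartialTruthTable,
    SensingPattern,
    all_rows,
)
from boolsense.screen import accumulate_constraints


def _table(k, determined):
    table = PartialTruthTable.empty(k)
    table.entries.update(determined)
    return table


def test_undetermined_rows_are_sorted_and_complete():
    table = _table(2, {(0, 0): 1, (1, 1): 0})
    assert undetermined_rows(table) == [(0, 1), (1, 0)]
    assert undetermined_rows(_table(1, {(0,): 0, (1,): 1})) == []
    assert undetermined_rows(PartialTruthTable.empty(2)) == all_rows(2)


@pytest.mark.parametrize("n_open, expected", [(0, 1), (3, 8), (4, 16)])
def test_completion_count_doubles_per_open_row(n_open, expected):
    table = PartialTruthTable.empty(3)
    for row in list(table.entries)[n_open:]:
        table.entries[row] = 0
    assert count_completions(table) == expected
    assert len(enumerate_completions(table)) == expected


def test_enumeration_guard_raises_capacity_error():
    table = PartialTruthTable.empty(5)  # 32 open rows
    with pytest.raises(CompletionCapacityError, match="count_completions"):
        enumerate_completions(table)


def test_empty_evidence_single_signal_table_has_four_completions():
    assert count_completions(PartialTruthTable.empty(1)) == 4
    bits = sorted(f.bits() for f in enumerate_completions(PartialTruthTable.empty(1)))
    assert bits == [(0, 0), (0, 1), (1, 0), (1, 1)]


def test_toy_survivors_each_pin_one_function_differing_at_two_rows(fig2):
    """Each surviving toy pattern admits exactly one function; the two
    functions disagree exactly where a joint perturbation would probe."""
    system, conditions = fig2
    pattern12 = SensingPattern({"I": (1, 0), "II": (1, 1)})
    pattern14 = SensingPattern({"I": (1, 1), "II": (0, 1)})
    completions = {}
    for label, pattern in (("12", pattern12), ("14", pattern14)):
        table = accumulate_constraints(pattern, conditions, system)
        functions = enumerate_completions(table)
        assert len(functions) == 1
        completions[label] = functions[0]
    assert expression(completions["12"], ["a", "b"]) == "a AND NOT b"
    assert expression(completions["14"], ["a", "b"]) == "a OR NOT b"
    disagreement = [
        row
        for row in all_rows(2)
        if completions["12"](row) != completions["14"](row)
    ]
    assert disagreement == [(0, 0), (1, 1)]


def test_common_functions_equal_intersection_of_completion_sets():
    rng = random.Random(7)
    for _ in range(25):
        tables = []
        for _ in range(rng.randint(1, 3)):
            determined = {
                row: rng.randint(0, 1)
                for row in all_rows(3)
                if rng.random() < 0.5
            }
            tables.append(_table(3, determined))
        oracle = set.intersection(
            *({f.bits() for f in enumerate_completions(t)} for t in tables)
        )
        assert {f.bits() for f in common_functions(tables)} == oracle


def test_conflicting_tables_yield_empty_result_with_flag():
    t0 = _table(1, {(0,): 0})
    t1 = _table(1, {(0,): 1})
    assert common_functions([t0, t1]) == []
    _, conflicts = merge_tables([t0, t1])
    assert conflicts == [(0,)]


def test_single_table_common_functions_are_its_own_completions():
    table = _table(2, {(0, 0): 1})
    assert {f.bits() for f in common_functions([table])} == {
        f.bits() for f in enumerate_completions(table)
    }


def test_toy_criticality_uniform_signal_vs_patterning_signal(fig2):
    system, _ = fig2
    pattern12 = SensingPattern({"I": (1, 0), "II": (1, 1)})
    function_c = BooleanFunction.from_bits(2, (0, 0, 1, 0))  # a AND NOT b
    labels = critical_signals(pattern12, function_c, system)
    assert labels == {"a": "uniform", "b": "critical"}


def test_masked_signal_whose_differential_cannot_be_removed_is_dispensable():
    system, conditions = fx.s1fig_system()
    pattern = SensingPattern({"I": (1, 0), "II": (1, 1)})
    function_c = BooleanFunction.from_bits(2, (0, 0, 1, 0))
    labels = critical_signals(pattern, function_c, system)
    # forcing b "on" leaves cell I untouched (outside the mask), so the
    # wild-type partition survives at least one uniformization
    assert labels["b"] == "dispensable"


def test_uniform_output_is_a_contract_error(fig2):
    system, _ = fig2
    pattern = SensingPattern({"I": (1, 0), "II": (1, 0)})
    constant = BooleanFunction.from_bits(2, (0, 0, 0, 0))
    with pytest.raises(ValueError, match="uniform"):
        critical_signals(pattern, constant, system)


def test_summary_requires_criticality_under_every_function(fig2):
    system, _ = fig2
    # both signals differential: uniformizing one leaves the other to pattern
    pattern10 = SensingPattern({"I": (1, 0), "II": (0, 1)})
    f_and = BooleanFunction.from_bits(2, (0, 0, 1, 0))  # a AND NOT b
    f_a = BooleanFunction.from_bits(2, (0, 0, 1, 1))  # just a
    assert critical_signals(pattern10, f_and, system)["a"] == "dispensable"
    assert critical_signals(pattern10, f_a, system)["a"] == "critical"
    summary = summarize_criticality(pattern10, [f_and, f_a], system)
    assert summary["a"] == "dispensable"  # not critical under every function
    assert summarize_criticality(pattern10, [f_a], system)["a"] == "critical"
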