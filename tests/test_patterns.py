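"""Transition taxonomy A-P, aggregation, and the chi-square test."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msapkit import (
    INCONSISTENT,
    PATTERN_ORDER,
    ContingencyTable,
    MethylationState,
    chi_square_independence,
    classify_transition,
    compare_conditions,
    consensus_transition,
    summarize_pattern_counts,
)
from msapkit.datasets import TRANSITION_COUNTS, transition_summary

from conftest import make_dataset

STATES = list(MethylationState)


def test_sixteen_pairs_partition_exactly_onto_labels():
    labels = {
        classify_transition(b, a).label
        for b, a in itertools.product(STATES, STATES)
    }
    assert labels == set(PATTERN_ORDER)


def test_classification_matches_rank_comparison_oracle():
    # independent oracle: enumerate all pairs and classify by rank alone
    for before, after in itertools.product(STATES, STATES):
        p = classify_transition(before, after)
        if after.rank == before.rank:
            expected = "no_change"
        elif after.rank < before.rank:
            expected = "demethylation"
        else:
            expected = "methylation"
        assert p.change_class == expected
        assert p.before is before and p.after is after


def test_identity_transitions_are_a_to_d_and_lane_encodings_match():
    encodings = {
        "A": ((1, 0), (1, 0)),
        "B": ((0, 1), (0, 1)),
        "C": ((1, 1), (1, 1)),
        "D": ((0, 0), (0, 0)),
        "G": ((0, 0), (1, 1)),
        "M": ((1, 1), (0, 0)),
    }
    for before, after in itertools.product(STATES, STATES):
        p = classify_transition(before, after)
        if p.label in encodings:
            assert (p.before_lanes, p.after_lanes) == encodings[p.label]
        if before is after:
            assert p.label in "ABCD"


@pytest.mark.parametrize(
    "before,after,label,change",
    [
        (MethylationState.IV, MethylationState.I, "G", "demethylation"),
        (MethylationState.I, MethylationState.IV, "M", "methylation"),
        (MethylationState.III, MethylationState.III, "B", "no_change"),
    ],
)
def test_named_transitions(before, after, label, change):
    p = classify_transition(before, after)
    assert (p.label, p.change_class) == (label, change)


def test_direction_symmetry():
    for x, y in itertools.product(STATES, STATES):
        fwd = classify_transition(x, y).change_class
        rev = classify_transition(y, x).change_class
        assert (fwd == "demethylation") == (rev == "methylation")


def test_published_pattern_counts_reproduce_class_totals():
    exa = transition_summary("Exagone")
    assert exa.n_total == 772
    assert exa.class_counts == {
        "no_change": 620,
        "demethylation": 121,
        "methylation": 31,
    }
    pct = exa.class_percentages
    assert pct["no_change"] == pytest.approx(80.3, abs=0.1)
    assert pct["demethylation"] == pytest.approx(15.7, abs=0.1)
    assert pct["methylation"] == pytest.approx(4.0, abs=0.1)

    toc = transition_summary("Toccata")
    assert toc.n_total == 783
    assert toc.class_counts == {
        "no_change": 674,
        "demethylation": 32,
        "methylation": 77,
    }
    assert toc.class_percentages["demethylation"] == pytest.approx(4.1, abs=0.1)
    assert toc.class_percentages["methylation"] == pytest.approx(9.8, abs=0.1)


def test_pattern_count_sum_mismatch_rejected():
    with pytest.raises(ValueError):
        summarize_pattern_counts({"C": 5}, total=6)


def test_all_no_change_gives_hundred_percent():
    s = summarize_pattern_counts({"C": 50}, total=50)
    assert s.class_percentages["no_change"] == 100.0
    assert s.changed_fraction_pct == 0.0


def test_compare_identical_samples_is_all_monomorphic():
    states = [0, 1, 2, 3, 2, 0]
    ds = make_dataset({"x": states, "y": states})
    s = compare_conditions(ds, "x", "y")
    cc = s.class_counts
    assert cc["demethylation"] == cc["methylation"] == 0
    assert cc["no_change"] == 6


def test_compare_constructed_pair_hits_expected_patterns():
    # hand-classified: (IV,I)->G, (I,IV)->M, (I,I)->C, (III,III)->B,
    # (IV,II)->I, (III,IV)->P
    before = [3, 0, 0, 2, 3, 2]
    after = [0, 3, 0, 2, 1, 3]
    ds = make_dataset({"b": before, "a": after})
    s = compare_conditions(ds, "b", "a")
    for label in "GMCBIP":
        assert s.pattern_counts[label] == 1, label
    assert s.n_total == 6


def test_compare_agrees_with_loop_tally(random_dataset):
    s = compare_conditions(random_dataset, "s_before", "s_after")
    tally = {c: 0 for c in ("no_change", "demethylation", "methylation")}
    b = random_dataset.states("s_before")
    a = random_dataset.states("s_after")
    for bi, ai in zip(b, a):
        tally[classify_transition(MethylationState(bi), MethylationState(ai)).change_class] += 1
    assert s.class_counts == tally


def test_consensus_unanimity_and_disagreement():
    g = classify_transition(MethylationState.IV, MethylationState.I)
    m = classify_transition(MethylationState.I, MethylationState.IV)
    c = classify_transition(MethylationState.I, MethylationState.I)
    assert consensus_transition([g, g]) is g
    assert consensus_transition([c]) is c
    assert consensus_transition([g, m]) == INCONSISTENT
    with pytest.raises(ValueError):
        consensus_transition([])


def test_chi_square_trivial_cases():
    uniform = ContingencyTable(("r1", "r2"), ("c1", "c2"), np.array([[10, 10], [10, 10]]))
    stat, dof, p = chi_square_independence(uniform)
    assert stat == pytest.approx(0.0)
    assert dof == 1
    assert p == pytest.approx(1.0)

    proportional = ContingencyTable(
        ("r1", "r2", "r3"), ("c1", "c2"), np.array([[10, 20], [20, 40], [5, 10]])
    )
    stat, dof, _ = chi_square_independence(proportional)
    assert stat == pytest.approx(0.0)
    assert dof == 2


def test_chi_square_2x2_closed_form_example():
    table = ContingencyTable(("r1", "r2"), ("c1", "c2"), np.array([[20, 10], [10, 20]]))
    stat, dof, p = chi_square_independence(table)
    # N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 60*300^2/30^4
    assert stat == pytest.approx(60 * 300**2 / 30**4, abs=1e-9)
    assert stat == pytest.approx(6.667, abs=0.001)
    assert dof == 1


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=1, max_value=200), min_size=4, max_size=4))
def test_chi_square_matches_2x2_closed_form(cells):
    a, b, c, d = cells
    table = ContingencyTable(("r1", "r2"), ("c1", "c2"), np.array([[a, b], [c, d]]))
    n = a + b + c + d
    closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # small expected cells
        stat, dof, _ = chi_square_independence(table)
    assert dof == 1
    assert stat == pytest.approx(closed, rel=1e-12, abs=1e-12)


def test_chi_square_warns_on_small_expected_and_rejects_degenerate():
    small = ContingencyTable(("r1", "r2"), ("c1", "c2"), np.array([[1, 2], [2, 1]]))
    with pytest.warns(UserWarning, match="below 5"):
        chi_square_independence(small)
    with pytest.raises(ValueError):
        ContingencyTable(("r1", "r2"), ("c1", "c2"), np.array([[0, 0], [1, 2]]))


def test_published_per_pattern_counts_sum_to_totals():
    assert sum(TRANSITION_COUNTS["Exagone"].values()) == 772
    assert sum(TRANSITION_COUNTS["Toccata"].values()) == 783
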