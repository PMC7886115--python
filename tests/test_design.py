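"""Transitional-probability calculus, XOR validation and the switch design."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from xorseq import (
    DesignSpec,
    UndefinedContextError,
    build_switch,
    enumerate_transitions,
    first_order_tp,
    nonadjacent_tp,
    second_order_tp,
    switch_tp_report,
    tp_table,
    transition_stats,
    validate_xor,
)

SINGLE = DesignSpec.from_strings(["ABC"], [1.0])


class TestFirstOrderTP:
    @pytest.mark.parametrize(
        "frm, to, positions, expected",
        [
            ("A", "B", (1, 2), 0.40 / 0.65),
            ("A", "E", (1, 2), 0.25 / 0.65),
            ("D", "B", (1, 2), 0.25 / 0.35),
            ("D", "E", (1, 2), 0.10 / 0.35),
            ("B", "C", (2, 3), 0.40 / 0.65),
            ("E", "F", (2, 3), 0.25 / 0.35),
            ("B", "F", (2, 3), 0.25 / 0.65),
            ("E", "C", (2, 3), 0.10 / 0.35),
        ],
    )
    def test_unbalanced_xor_values(self, xor, frm, to, positions, expected):
        """All eight positional TPs of the canonical design, two-decimal golden."""
        value = first_order_tp(xor, frm, to, positions)
        assert value == pytest.approx(expected)
        assert round(value, 2) == round(expected, 2)

    def test_menu_mixture(self, menus):
        """A dessert follows a dish four times out of five; a dish always follows a salad."""
        assert first_order_tp(menus, "Dish", "Dessert", "any") == pytest.approx(0.80)
        assert first_order_tp(menus, "Salad", "Dish", "any") == pytest.approx(1.0)

    def test_twenty_customers(self, customers):
        """p(Dish|NoSalad) = 5/7 in the 8/5/5/2 customer sample."""
        assert first_order_tp(customers, "NoSalad", "Dish", (1, 2)) == pytest.approx(5 / 7)

    def test_balanced_xor_all_half(self, profiles):
        values = {
            first_order_tp(profiles, a, b, pos)
            for pos, a, b in enumerate_transitions(profiles)
        }
        assert values == {0.5}

    def test_single_triplet_deterministic(self):
        assert first_order_tp(SINGLE, "A", "B", (1, 2)) == 1.0

    def test_undefined_context_raises(self, xor):
        with pytest.raises(UndefinedContextError):
            first_order_tp(xor, "C", "A", (1, 2))  # C never at position 1
        with pytest.raises(UndefinedContextError):
            first_order_tp(xor, "Z", "A", "any")


class TestSecondOrderTP:
    def test_xor_all_one(self, xor):
        for s, _ in xor.items():
            assert second_order_tp(xor, *s) == pytest.approx(1.0)

    def test_menu_half(self, menus):
        """Half of the Salad-Dish menus continue with a dessert."""
        assert second_order_tp(menus, "Salad", "Dish", "Dessert") == pytest.approx(0.5)

    def test_single_triplet(self):
        assert second_order_tp(SINGLE, "A", "B", "C") == 1.0

    def test_undefined_pair_raises(self, xor):
        with pytest.raises(UndefinedContextError):
            second_order_tp(xor, "A", "F", "C")


class TestNonadjacentTP:
    @pytest.mark.parametrize(
        "first, third, expected",
        [("A", "C", 0.40 / 0.65), ("D", "F", 0.25 / 0.35)],
    )
    def test_values(self, xor, first, third, expected):
        assert nonadjacent_tp(xor, first, third) == pytest.approx(expected)

    def test_single_triplet(self):
        assert nonadjacent_tp(SINGLE, "A", "C") == 1.0

    def test_undefined(self, xor):
        with pytest.raises(UndefinedContextError):
            nonadjacent_tp(xor, "B", "C")


class TestXorValidation:
    def test_canonical_design_is_xor(self, xor):
        assert validate_xor(xor).is_xor

    def test_switched_design_is_xor(self, switched):
        assert validate_xor(switched).is_xor

    def test_deterministic_pairs_fail(self):
        """{ABC, DEF}: the second item alone predicts the third."""
        report = validate_xor(DesignSpec.from_strings(["ABC", "DEF"], [0.7, 0.3]))
        assert not report.is_xor
        assert any("p(C|B)" in v for v in report.violations)

    def test_non_triplet_sequences_fail(self, menus):
        assert not validate_xor(menus).is_xor


class TestBuildSwitch:
    def test_canonical_switch(self, xor, switched):
        """ABC/AEF/DBF/DEC become ABF/AEC/DBC/DEF with inherited frequencies."""
        result = build_switch(xor)
        assert result.sequences == switched.sequences
        assert result.frequencies == xor.frequencies

    def test_pair_inventory_preserved(self, xor):
        result = build_switch(xor)
        assert enumerate_transitions(result) == enumerate_transitions(xor)
        assert len(enumerate_transitions(result)) == 8

    def test_no_shared_triplet(self, xor):
        assert not set(build_switch(xor).sequences) & set(xor.sequences)

    def test_involution_on_triplet_set(self, xor):
        assert set(build_switch(build_switch(xor)).sequences) == set(xor.sequences)

    def test_requires_valid_xor(self):
        with pytest.raises(ValueError):
            build_switch(DesignSpec.from_strings(["ABC", "DEF"], [0.5, 0.5]))

    def test_switch_changes_position23_tp_values(self, xor):
        """Pair inventory is preserved but 2->3 TP values move with inherited frequencies."""
        report = switch_tp_report(xor)
        assert not report[report.positions == "1-2"].changed.any()
        assert report[report.positions == "2-3"].changed.all()


class TestEnumerateTransitions:
    def test_counts(self, xor):
        assert len(enumerate_transitions(xor)) == 8
        assert len(enumerate_transitions(SINGLE)) == 2

    def test_contents(self, xor):
        expected = {
            ((1, 2), "A", "B"), ((1, 2), "A", "E"), ((1, 2), "D", "B"),
            ((1, 2), "D", "E"), ((2, 3), "B", "C"), ((2, 3), "B", "F"),
            ((2, 3), "E", "C"), ((2, 3), "E", "F"),
        }
        assert set(enumerate_transitions(xor)) == expected


class TestDesignSpecInvariants:
    def test_rejects_bad_frequencies(self):
        with pytest.raises(ValueError):
            DesignSpec.from_strings(["ABC", "DEF"], [0.5, 0.4])

    def test_rejects_repeated_items(self):
        with pytest.raises(ValueError):
            DesignSpec.from_strings(["ABA"], [1.0])

    def test_rejects_duplicate_sequences(self):
        with pytest.raises(ValueError):
            DesignSpec.from_strings(["ABC", "ABC"], [0.5, 0.5])

    def test_roundtrip_dict(self, xor):
        assert DesignSpec.from_dict(xor.to_dict()) == xor


class TestFrequencyTPDissociation:
    def test_highest_tp_is_not_most_frequent_pair(self, xor):
        """D->B carries the highest 1->2 TP while A->B is the most frequent pair."""
        stats = transition_stats(xor)
        first12 = {k: v for k, v in stats.first_order.items() if k[0] == (1, 2)}
        assert max(first12, key=first12.get) == ((1, 2), "D", "B")
        freq12 = {k: v for k, v in stats.pair_frequency.items() if k[0] == (1, 2)}
        assert max(freq12, key=freq12.get) == ((1, 2), "A", "B")
        assert first12[((1, 2), "D", "B")] > first12[((1, 2), "A", "B")]
        assert freq12[((1, 2), "A", "B")] > freq12[((1, 2), "D", "B")]

    def test_tp_table_matches_printed_rounding(self, xor):
        table = tp_table(xor).set_index("sequence")
        assert list(table.loc[["ABC", "AEF", "DBF", "DEC"], "tp_1_2"]) == [0.62, 0.38, 0.71, 0.29]
        assert list(table.loc[["ABC", "AEF", "DBF", "DEC"], "tp_2_3"]) == [0.62, 0.71, 0.38, 0.29]
        assert (table.second_order_tp == 1.0).all()


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

ITEMS = "ABCDEF"


@st.composite
def integer_count_designs(draw):
    """Random small designs with integer counts (rational frequencies)."""
    triplets = [
        "".join(p)
        for p in __import__("itertools").permutations(ITEMS, 3)
    ]
    chosen = draw(
        st.lists(st.sampled_from(triplets), min_size=1, max_size=5, unique=True)
    )
    counts = draw(
        st.lists(
            st.integers(min_value=1, max_value=9),
            min_size=len(chosen), max_size=len(chosen),
        )
    )
    return DesignSpec.from_counts(chosen, counts), chosen, counts


@given(integer_count_designs())
def test_tp_matches_bruteforce_counting(data):
    """Closed-form TPs equal transition proportions counted on the materialised multiset."""
    design, chosen, counts = data
    pool = [seq for seq, c in zip(chosen, counts) for _ in range(c)]
    for pos in ((1, 2), (2, 3)):
        a, b = pos[0] - 1, pos[1] - 1
        for frm in ITEMS:
            ctx = [s for s in pool if s[a] == frm]
            if not ctx:
                continue
            for to in ITEMS:
                hits = sum(1 for s in ctx if s[b] == to)
                assert first_order_tp(design, frm, to, pos) == pytest.approx(
                    hits / len(ctx)
                )
    for frm in ITEMS:
        ctx = [s for s in pool if s[0] == frm]
        if not ctx:
            continue
        for to in ITEMS:
            hits = sum(1 for s in ctx if s[2] == to)
            assert nonadjacent_tp(design, frm, to) == pytest.approx(hits / len(ctx))


@given(integer_count_designs())
def test_tp_normalisation(data):
    """TPs over observed successors sum to 1 for every conditioning context."""
    design, _, _ = data
    stats = transition_stats(design)
    for pos in ((1, 2), (2, 3)):
        contexts = {a for (p, a, _b) in stats.first_order if p == pos}
        for a in contexts:
            total = sum(
                v for (p, frm, _to), v in stats.first_order.items()
                if p == pos and frm == a
            )
            assert math.isclose(total, 1.0, abs_tol=1e-9)
    prefixes = {(a, b) for (a, b, _c) in stats.second_order}
    for a, b in prefixes:
        total = sum(
            v for (x, y, _z), v in stats.second_order.items() if (x, y) == (a, b)
        )
        assert math.isclose(total, 1.0, abs_tol=1e-9)
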