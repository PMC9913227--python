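"""Tandem duplication-random loss: application, search, and oracle equality."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitorearr.gene_order import GeneOrder, canonical_vertebrate_order, extract_gene_order
from mitorearr.tdrl import (
    TDRLError,
    TDRLEvent,
    apply_tdrl,
    brute_force_tdrl,
    find_minimal_tdrl,
    minimal_subset,
)


def toy(text):
    return GeneOrder.from_string(text)


class TestApply:
    def test_all_first_retention_is_identity(self, canonical):
        block = canonical.anchored()[10:15]
        ev = TDRLEvent(block_start=10, block=block, retention=("first",) * 5)
        assert apply_tdrl(canonical, ev) == canonical

    def test_hand_worked_toy_duplication(self):
        order = toy("a b c")
        ev = TDRLEvent(
            block_start=1, block=(("b", 1), ("c", 1)), retention=("second", "first")
        )
        assert apply_tdrl(order, ev) == toy("a c b")

    def test_snake_eel_event_reproduces_observed_order(
        self, canonical, duplication_event, evermanni
    ):
        result = apply_tdrl(canonical, duplication_event)
        assert result == extract_gene_order(evermanni)
        assert duplication_event.n_losses == 5

    def test_gene_kept_in_both_copies_is_rejected(self):
        with pytest.raises(TDRLError, match="both"):
            TDRLEvent(block_start=0, block=(("ND1", 1),), retention=("both",))


class TestMinimalSearch:
    def test_recovers_published_rearrangement_pathway(
        self, canonical, evermanni, duplication_event
    ):
        observed = extract_gene_order(evermanni)
        search = find_minimal_tdrl(canonical, observed)
        assert not search.identical and search.events
        assert all(len(ev.block) == 6 and ev.n_losses == 5 for ev in search.events)
        assert any(
            ev.block == duplication_event.block
            and ev.retention == duplication_event.retention
            for ev in search.events
        )

    def test_identical_orders_return_no_event_marker(self, canonical):
        search = find_minimal_tdrl(canonical, canonical)
        assert search.identical and len(search) == 0

    def test_strand_inversion_aborts_with_diagnostic(self):
        with pytest.raises(TDRLError, match="invert"):
            find_minimal_tdrl(toy("a b c"), toy("a -b c"))

    def test_unreachable_three_element_reversal(self):
        source, target = toy("a b c d e"), toy("a d c b e")
        assert len(find_minimal_tdrl(source, target)) == 0
        assert brute_force_tdrl(source, target, max_block=5) == []

    def test_soundness_of_every_reported_event(self, canonical, erabo):
        observed = extract_gene_order(erabo)
        search = find_minimal_tdrl(canonical, observed)
        assert search.events
        for ev in search.events:
            assert apply_tdrl(canonical, ev) == observed


LABELS = ["a", "b", "c", "d", "e", "f", "g", "CR"]


@st.composite
def random_instance(draw):
    n = draw(st.integers(min_value=3, max_value=8))
    labels = draw(st.permutations(LABELS[:n]))
    signs = [draw(st.sampled_from([1, -1])) if lab != "CR" else 1 for lab in labels]
    source = GeneOrder(elements=tuple(zip(labels, signs)))
    rng = random.Random(draw(st.integers(min_value=0, max_value=10_000)))
    if draw(st.booleans()):
        # reachable target: apply a random single event
        bs, L = rng.randrange(n), rng.randint(1, n)
        block = (source.anchored()[bs:] + source.anchored()[:bs])[:L]
        retention = tuple(
            "both" if lab == "CR" and rng.random() < 0.4 else rng.choice(["first", "second"])
            for lab, _ in block
        )
        target = apply_tdrl(source, TDRLEvent(block_start=bs, block=block, retention=retention))
    else:
        # arbitrary same-content permutation (may be unreachable)
        perm = list(source.elements)
        rng.shuffle(perm)
        target = GeneOrder(elements=tuple(perm))
    return source, target


class TestOracleEquality:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(random_instance())
    def test_search_matches_bruteforce_minimal_subset(self, instance):
        source, target = instance
        search = find_minimal_tdrl(source, target)
        brute = brute_force_tdrl(source, target, max_block=len(source.elements))
        if search.identical:
            # monotonicity: the search never reports a lossy event for equality
            assert len(search) == 0
            return
        expected = minimal_subset(brute)
        key = lambda ev: (ev.block_start, ev.block, ev.retention)  # noqa: E731
        assert {key(ev) for ev in search.events} == {key(ev) for ev in expected}
        for ev in search.events:
            assert apply_tdrl(source, ev) == target

    def test_bruteforce_on_paper_instance_agrees(self, canonical, evermanni):
        observed = extract_gene_order(evermanni)
        brute = minimal_subset(brute_force_tdrl(canonical, observed, max_block=8))
        search = find_minimal_tdrl(canonical, observed)
        key = lambda ev: (ev.block_start, ev.block, ev.retention)  # noqa: E731
        assert {key(ev) for ev in search.events} == {key(ev) for ev in brute}

    def test_budget_guard(self, canonical):
        with pytest.raises(TDRLError, match="budget"):
            brute_force_tdrl(canonical, canonical, max_block=38, budget=1000)
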