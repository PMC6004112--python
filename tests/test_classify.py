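"""Bayes-Factor arithmetic and the three-way assignment rule."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hsta import ln_bayes_factor, classify, filter_hits_by_best_order, assign_all
from hsta.classify import GOOD, AMBIGUOUS, UNCLASSIFIED
from hsta.profile_hmm import HitScore


def _hits(scores_evalues, query="q"):
    return [
        HitScore(query_id=query, profile_name=f"p{i}", bit_score=s, evalue=e)
        for i, (s, e) in enumerate(scores_evalues)
    ]


# ---------------------------------------------------------------------------
# ln(BF)


def test_ln_bf_worked_example():
    # 10 - ln(e^5 + e^3) computed by hand
    assert ln_bayes_factor([10, 5, 3]) == pytest.approx(4.873071988957028, abs=1e-12)


def test_ln_bf_equal_competitors_is_zero():
    assert ln_bayes_factor([7, 7]) == pytest.approx(0.0)


def test_ln_bf_single_hit_is_infinite():
    assert ln_bayes_factor([42]) == math.inf


def test_ln_bf_rejects_unsorted():
    with pytest.raises(ValueError, match="descending"):
        ln_bayes_factor([3, 10])
    with pytest.raises(ValueError, match="at least one"):
        ln_bayes_factor([])


def test_ln_bf_nats_scale():
    # in nats the scores are multiplied by ln 2 before the log-sum-exp
    ln2 = math.log(2.0)
    expected = 10 * ln2 - math.log(math.exp(5 * ln2) + math.exp(3 * ln2))
    assert ln_bayes_factor([10, 5, 3], scale="nats") == pytest.approx(expected)


def test_ln_bf_matches_naive_two_pass_extended_precision():
    """Overflow-safe log-sum-exp agrees with explicit exp/sum/ln at extended
    precision for scores up to 500."""
    from decimal import Decimal, getcontext

    getcontext().prec = 400
    for scores in ([500.0, 499.5, 100.0], [300.0, 1.0], [50.0, 49.0, 48.0, -20.0]):
        naive = float(
            Decimal(scores[0])
            - Decimal(sum((Decimal(s).exp() for s in scores[1:]), Decimal(0)).ln())
        )
        assert ln_bayes_factor(scores) == pytest.approx(naive, abs=1e-9)


@given(
    st.lists(st.floats(min_value=-100, max_value=100), min_size=2, max_size=8),
    st.floats(min_value=0.01, max_value=10.0),
)
@settings(deadline=None, max_examples=100)
def test_ln_bf_monotone_in_competitors(scores, bump):
    """Raising any competitor score never increases ln(BF)."""
    scores = sorted(scores, reverse=True)
    base = ln_bayes_factor(scores)
    idx = len(scores) - 1  # bump the weakest competitor, keeps sortedness
    bumped = sorted(scores[:idx] + [min(scores[idx] + bump, scores[0])], reverse=True)
    assert ln_bayes_factor(bumped) <= base + 1e-9


# ---------------------------------------------------------------------------
# three-way rule


def test_bf_result_summary():
    from hsta.classify import bf_result

    res = bf_result(_hits([(10.0, 1e-8), (5.0, 1e-4), (3.0, 1e-3)]))
    assert res.best_profile == "p0" and res.n_hits == 3
    assert res.ln_bf == pytest.approx(4.873071988957028)
    lone = bf_result(_hits([(9.0, 1e-5)]))
    assert lone.n_hits == 1 and lone.ln_bf == math.inf


def test_insignificant_best_hit_is_unclassified():
    a = classify(_hits([(10.0, 0.5), (5.0, 0.7)]), evalue_threshold=0.01)
    assert a.category == UNCLASSIFIED and a.taxon is None


def test_clear_winner_is_good():
    a = classify(_hits([(10.0, 1e-8), (5.0, 1e-4), (3.0, 1e-3)]), evalue_threshold=10.0)
    assert a.category == GOOD
    assert a.taxon == "p0"
    assert a.ln_bf == pytest.approx(4.873071988957028)


def test_tied_competitors_are_ambiguous():
    a = classify(_hits([(7.0, 1e-6), (7.0, 1e-6)]), evalue_threshold=10.0)
    assert a.category == AMBIGUOUS and a.ln_bf == pytest.approx(0.0)


def test_single_significant_hit_is_good():
    # insignificant competitors are excluded from the Bayes Factor sum
    a = classify(_hits([(10.0, 1e-8), (9.9, 50.0)]), evalue_threshold=10.0)
    assert a.category == GOOD and a.ln_bf == math.inf


def test_empty_hit_list_unclassified(caplog):
    with caplog.at_level("WARNING"):
        a = classify([])
    assert a.category == UNCLASSIFIED


def test_classify_rejects_unsorted_hits():
    with pytest.raises(ValueError, match="sorted"):
        classify(_hits([(5.0, 1e-3), (10.0, 1e-8)]))


@given(
    st.lists(
        st.tuples(
            st.floats(min_value=-50, max_value=200),
            st.floats(min_value=1e-12, max_value=100.0),
        ),
        min_size=1,
        max_size=6,
    ),
    st.floats(min_value=0.5, max_value=20.0),
)
@settings(deadline=None, max_examples=150)
def test_categories_partition_and_threshold_monotonicity(raw, bf_threshold):
    """Every query lands in exactly one category, and raising the BF
    threshold can only shrink the Good set."""
    hits = _hits(sorted(raw, key=lambda t: -t[0]))
    a_low = classify(hits, bf_threshold=bf_threshold)
    a_high = classify(hits, bf_threshold=bf_threshold + 5.0)
    for a in (a_low, a_high):
        assert a.category in (GOOD, AMBIGUOUS, UNCLASSIFIED)
    if a_high.category == GOOD:
        assert a_low.category == GOOD


# ---------------------------------------------------------------------------
# reference hit filtering


def _hit_table(rows):
    return pd.DataFrame(
        rows, columns=["query_id", "subject_id", "subject_order_label", "bit_score", "rank_position"]
    )


def test_filter_keeps_best_hit_order():
    rows = [("q1", f"s{i}", "Coleoptera" if i < 6 else "Diptera", 100 - i, i + 1) for i in range(10)]
    out = filter_hits_by_best_order(_hit_table(rows))
    assert len(out) == 6
    assert set(out["subject_order_label"]) == {"Coleoptera"}


def test_filter_identity_when_uniform():
    rows = [("q1", f"s{i}", "Coleoptera", 100 - i, i + 1) for i in range(10)]
    out = filter_hits_by_best_order(_hit_table(rows))
    assert len(out) == 10


def test_filter_drops_query_with_unlabeled_best(caplog):
    rows = [("q1", "s0", None, 100, 1), ("q1", "s1", "Diptera", 90, 2)]
    with caplog.at_level("WARNING"):
        out = filter_hits_by_best_order(_hit_table(rows))
    assert out.empty
    assert "dropped" in caplog.text


def test_filter_requires_best_row():
    rows = [("q1", "s1", "Diptera", 90, 2)]
    with pytest.raises(ValueError, match="rank_position-1"):
        filter_hits_by_best_order(_hit_table(rows))


# ---------------------------------------------------------------------------
# end-to-end assignment


def test_clean_reads_all_good_and_correct(small_refs, small_spec, order_profiles):
    """Error-free reads from known taxa are all Good with the right label."""
    from hsta.synthetic import ErrorModel, sample_reads
    import dataclasses

    clean_spec = dataclasses.replace(
        small_spec,
        error_model=ErrorModel(base_sub_rate=0.0, gc_sub_slope=0.0, homopolymer_indel_rate=0.0),
    )
    reads, truth = sample_reads(small_refs, clean_spec, 100, seed=17)
    assignments, abundance = assign_all(reads, order_profiles, rank="order")
    assert len(assignments) == 100
    truth_by_id = {t["read_id"]: t["order_label"] for t in truth}
    for a in assignments:
        assert a.category == GOOD
        assert a.taxon == truth_by_id[a.query_id]
    assert abundance["count"].sum() == 100


def test_assign_all_empty_queries(order_profiles):
    assignments, abundance = assign_all([], order_profiles)
    assert assignments == [] and abundance.empty


def test_divergent_taxon_mostly_not_good(small_spec, order_profiles):
    """Reads from a taxon far outside the profile set should rarely be Good."""
    import dataclasses
    from hsta.synthetic import CommunitySpec, TaxonSpec, evolve_references, sample_reads

    alien_spec = dataclasses.replace(
        small_spec,
        taxa=(TaxonSpec("OrdX", n_species=2, biomass_g=1.0),),
        order_divergence=0.45,  # far from every profiled order
        seed=99,
    )
    alien_refs = evolve_references(alien_spec)
    reads, _ = sample_reads(alien_refs, alien_spec, 40, seed=101)
    assignments, _ = assign_all(reads, order_profiles, rank="order")
    not_good = sum(a.category != GOOD for a in assignments)
    assert not_good / len(assignments) >= 0.8


def test_single_profile_collection_never_ambiguous(small_refs, small_spec, order_profiles):
    """With one profile, every significant query is Good (n=1, infinite BF)."""
    from hsta.synthetic import sample_reads

    reads, _ = sample_reads(small_refs, small_spec, 30, seed=23)
    assignments, _ = assign_all(reads, order_profiles[:1], rank="order")
    assert all(a.category in (GOOD, UNCLASSIFIED) for a in assignments)
    assert all(a.ln_bf == math.inf for a in assignments if a.category == GOOD)
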