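"""Profile construction and forward-scoring semantics.

The load-bearing check is oracle equivalence: the vectorized forward
recursion must agree to 1e-9 bits with an exhaustive enumeration of every
local alignment path on small profiles.
"""

from __future__ import annotations

import numpy as np
import pytest

from hsta import (
    TaxonRecord,
    build_profile,
    calibrate_evalue,
    evalue,
    forward_bits,
    viterbi_bits,
    align_to_profile,
    load_profiles,
    save_profiles,
    scan,
)
from hsta.profile_hmm import ProfileHMM

from conftest import brute_force_bits


# ---------------------------------------------------------------------------
# building


def test_degenerate_consensus_profile():
    p = build_profile(["ACGT"] * 4, "toy", pseudocount=0.0)
    assert p.M == 4
    for k, base_idx in enumerate([0, 1, 2, 3]):
        assert p.match_emissions[k, base_idx] == pytest.approx(1.0)


def test_occupancy_threshold_is_strict():
    # column 2 is gapped in exactly half the rows: not a match column
    p = build_profile(["AC", "A-"], "toy")
    assert p.M == 1


def test_laplace_pseudocount_emissions():
    p = build_profile(["AAA", "AAC", "AAG"], "toy", pseudocount=1.0)
    assert p.match_emissions[2, 0] == pytest.approx(2.0 / 7.0)  # (1+1)/(3+4)


@pytest.mark.parametrize(
    "rows,err",
    [([ "ACGT"], "at least 2"), (["--", "--"], "no match columns")],
)
def test_build_rejects_degenerate_alignments(rows, err):
    with pytest.raises(ValueError, match=err):
        build_profile(rows, "bad")


def test_transition_distributions_normalized(order_profiles):
    for p in order_profiles:
        for name, totals in p.state_distributions().items():
            assert np.allclose(totals, 1.0, atol=1e-9), name


# ---------------------------------------------------------------------------
# forward scoring vs. the enumeration oracle


def _toy_profiles():
    out = [
        build_profile(["ACGT", "ACGT", "AGGT"], "m3a", pseudocount=0.5),
        build_profile(["AC-", "ACG", "A-G", "ACG"], "gappy", pseudocount=1.0),
        build_profile(["AAT", "AAT", "CAT", "AA-"], "m3b", pseudocount=0.25),
        build_profile(["AC", "AC", "GC"], "m2", pseudocount=1.0),
        build_profile(["A", "A", "C"], "m1", pseudocount=1.0),
    ]
    # a hand-set 2-state profile, not produced by build_profile
    hand = ProfileHMM(
        name="hand",
        rank="order",
        M=2,
        match_emissions=np.array([[0.7, 0.1, 0.1, 0.1], [0.1, 0.1, 0.1, 0.7]]),
        insert_emissions=np.array([[0.25, 0.25, 0.25, 0.25]]),
        t_mm=np.array([0.7]),
        t_mi=np.array([0.3]),
        t_md=np.array([0.0]),
        t_im=np.array([0.6]),
        t_ii=np.array([0.4]),
        t_dm=np.array([1.0]),
        t_dd=np.array([0.0]),
        background=np.full(4, 0.25),
    )
    out.append(hand)
    return out


@pytest.mark.parametrize("profile", _toy_profiles(), ids=lambda p: p.name)
@pytest.mark.parametrize("query", ["A", "AC", "ACG", "ACGT", "TTT", "ANG", "CAT"])
def test_forward_matches_exhaustive_enumeration(profile, query):
    """Full path-sum enumeration and the DP agree to 1e-9 bits."""
    if profile.M > 3 and len(query) > 4:
        pytest.skip("oracle only exhaustive for small cases")
    expected = brute_force_bits(profile, query)
    assert forward_bits(profile, query) == pytest.approx(expected, abs=1e-9)


def test_consensus_outscores_reverse_complement(order_profiles):
    comp = str.maketrans("ACGT", "TGCA")
    for p in order_profiles:
        cons = p.consensus()
        rc = cons.translate(comp)[::-1]
        assert forward_bits(p, cons) > forward_bits(p, rc)


def test_background_flanks_stable_viterbi_score(order_profiles):
    """Local-alignment contract: the best-path score barely moves when
    independent background flanks are concatenated to a query."""
    rng = np.random.default_rng(3)
    for p in order_profiles:
        core = p.consensus()[100:350]
        plain = viterbi_bits(p, core)
        deltas = []
        for _ in range(7):
            flank_l = "".join(rng.choice(list("ACGT"), size=25))
            flank_r = "".join(rng.choice(list("ACGT"), size=25))
            deltas.append(abs(viterbi_bits(p, flank_l + core + flank_r) - plain))
        # a lucky flank can genuinely extend the best alignment a little,
        # so the contract is distributional: the typical shift is tiny
        assert np.median(deltas) < 1.0


def test_background_flanks_inflate_forward_only_logarithmically(order_profiles):
    """The path-sum (forward) score gains at most ~log(flank length) bits
    from background flanks: each flank-absorbing extension step has unit
    expected odds, so the added mass per side is bounded by a short
    geometric series, never by the flank's length itself."""
    rng = np.random.default_rng(3)
    p = order_profiles[0]
    core = p.consensus()[100:350]
    plain = forward_bits(p, core)
    for n in (10, 25, 50):
        flank_l = "".join(rng.choice(list("ACGT"), size=n))
        flank_r = "".join(rng.choice(list("ACGT"), size=n))
        delta = forward_bits(p, flank_l + core + flank_r) - plain
        assert -1.0 < delta < 2.0 * np.log2(n + 1) + 2.0


def test_background_flanks_leave_score_margins_nearly_unchanged(order_profiles):
    """The decision statistic is a score *difference* between profiles:
    flank inflation is largely common mode, so the best-vs-competitor
    margin moves by a small fraction of its value and never flips."""
    rng = np.random.default_rng(3)
    best, second = order_profiles[0], order_profiles[1]
    core = best.consensus()[100:350]
    flank_l = "".join(rng.choice(list("ACGT"), size=25))
    flank_r = "".join(rng.choice(list("ACGT"), size=25))
    margin_plain = forward_bits(best, core) - forward_bits(second, core)
    flanked = flank_l + core + flank_r
    margin_flanked = forward_bits(best, flanked) - forward_bits(second, flanked)
    assert margin_plain > 0 and margin_flanked > 0
    assert abs(margin_flanked - margin_plain) < 0.05 * margin_plain


def test_empty_sequence_rejected(order_profiles):
    with pytest.raises(ValueError):
        forward_bits(order_profiles[0], "")


# ---------------------------------------------------------------------------
# calibration and E-values


@pytest.fixture(scope="module")
def calibrated_toy():
    p = build_profile(
        ["ACGTACGTACGTACGTACGTGGCA"] * 3 + ["ACGTACGTACGAACGTACGTGGCA"], "cal"
    )
    p.calibration = calibrate_evalue(p, n_shuffles=100, seed=7)
    return p


def test_evalue_at_gumbel_location(calibrated_toy):
    c = calibrated_toy.calibration
    assert evalue(c, c.gumbel_mu, n_targets=1) == pytest.approx(1 - np.exp(-1), abs=1e-9)


def test_evalue_monotone_decreasing(calibrated_toy):
    c = calibrated_toy.calibration
    # below mu - a few scale units the survival probability saturates at 1
    # in double precision, so probe the informative range upward of mu
    grid = np.linspace(c.gumbel_mu, c.gumbel_mu + 20, 40)
    vals = [evalue(c, s, n_targets=3) for s in grid]
    assert all(a > b for a, b in zip(vals, vals[1:]))


def test_calibration_deterministic(calibrated_toy):
    again = calibrate_evalue(calibrated_toy, n_shuffles=100, seed=7)
    assert again.gumbel_mu == calibrated_toy.calibration.gumbel_mu
    assert again.gumbel_lambda == calibrated_toy.calibration.gumbel_lambda


def test_calibration_requires_enough_shuffles(calibrated_toy):
    with pytest.raises(ValueError, match="100"):
        calibrate_evalue(calibrated_toy, n_shuffles=50, seed=1)


# ---------------------------------------------------------------------------
# scanning


def test_scan_single_profile(calibrated_toy):
    hits = scan(TaxonRecord("q", "ACGTACGT"), [calibrated_toy])
    assert len(hits) == 1 and hits[0].profile_name == "cal"


def test_scan_tie_breaks_by_name(calibrated_toy):
    import copy

    twin = copy.deepcopy(calibrated_toy)
    twin.name = "aaa_twin"
    hits = scan(TaxonRecord("q", "ACGTACGT"), [calibrated_toy, twin])
    assert hits[0].bit_score == hits[1].bit_score
    assert [h.profile_name for h in hits] == ["aaa_twin", "cal"]


def test_scan_recovers_source_profile(order_profiles, small_refs, small_spec):
    """Reads drawn from a taxon's references rank that taxon's profile first."""
    from hsta import sample_reads

    reads, truth = sample_reads(small_refs, small_spec, 60, seed=21)
    correct = 0
    for read, row in zip(reads, truth):
        hits = scan(read, order_profiles)
        correct += hits[0].profile_name == row["order_label"]
    assert correct / len(reads) >= 0.95


def test_scan_requires_calibration(small_refs):
    p = build_profile([r.seq for r in small_refs[:3]], "uncal")
    with pytest.raises(ValueError, match="not calibrated"):
        scan(TaxonRecord("q", "ACGT"), [p])


# ---------------------------------------------------------------------------
# persistence and alignment placement


def test_profile_json_roundtrip(tmp_path, calibrated_toy, order_profiles):
    path = tmp_path / "profiles.jsonl"
    save_profiles([calibrated_toy, order_profiles[0]], path)
    back = load_profiles(path)
    assert [p.name for p in back] == [calibrated_toy.name, order_profiles[0].name]
    assert np.allclose(back[0].match_emissions, calibrated_toy.match_emissions)
    assert back[0].calibration.gumbel_mu == calibrated_toy.calibration.gumbel_mu
    q = TaxonRecord("q", "ACGTACGTACGTACGT")
    assert forward_bits(back[0], q.seq) == forward_bits(calibrated_toy, q.seq)


def test_viterbi_places_clean_fragment(order_profiles):
    """An error-free consensus fragment aligns back to its own columns."""
    p = order_profiles[0]
    cons = p.consensus()
    frag = cons[50:200]
    placed = align_to_profile(p, frag)
    assert len(placed) == p.M
    matched = [(i, c) for i, c in enumerate(placed) if c != "-"]
    # the fragment should land contiguously at its true offset
    positions = [i for i, _ in matched]
    assert positions == list(range(50, 200))
    assert "".join(c for _, c in matched) == frag
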