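import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connmap import (
    ConnectionResult,
    GeneSignature,
    ProbeUniverse,
    QueryConfig,
    ReferenceSet,
    connection_score,
    estimate_fdr,
    estimate_pvalue,
    query_database,
    rank_results,
    score_from_ranks,
    scores_from_ranks,
    set_score,
)
from connmap.datasets import cross_platform_stable_hits
from connmap.scoring import ScoringError, results_to_frame

from conftest import exhaustive_pvalue, make_profile, random_database


class TestConnectionScore:
    def test_perfect_match_scores_one(self, five_probe_profile):
        sig = GeneSignature(("A", "B"), (1, -1))
        assert connection_score(sig, five_probe_profile) == 1.0

    def test_hand_evaluated_partial_match(self, five_probe_profile):
        # c = 5 - 4 = 1; c_max = 5 + 4 = 9
        sig = GeneSignature(("A", "B"), (1, 1))
        assert connection_score(sig, five_probe_profile) == pytest.approx(1 / 9)

    def test_antisymmetry_under_sign_flip(self, five_probe_profile):
        sig = GeneSignature(("A", "C", "E"), (1, -1, 1))
        assert connection_score(sig.flipped(), five_probe_profile) == pytest.approx(
            -connection_score(sig, five_probe_profile)
        )

    def test_unknown_probe_named_in_error(self, five_probe_profile):
        sig = GeneSignature(("A", "ZZZ"), (1, 1))
        with pytest.raises(ScoringError, match="ZZZ"):
            connection_score(sig, five_probe_profile)

    @settings(derandomize=True, max_examples=60)
    @given(data=st.data())
    def test_score_bounded_and_extremal_only_at_top_ranks(self, data):
        N = data.draw(st.integers(4, 12), label="N")
        m = data.draw(st.integers(1, 3), label="m")
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000), label="seed"))
        uni = ProbeUniverse(tuple(f"g{i}" for i in range(N)))
        profile = make_profile(
            uni, rng.choice((-1, 1), size=N) * (rng.permutation(N) + 1)
        )
        probes = tuple(rng.choice(N, size=m, replace=False))
        sig = GeneSignature(
            tuple(uni.probe_ids[i] for i in probes),
            tuple(int(s) for s in rng.choice((-1, 1), size=m)),
        )
        c = connection_score(sig, profile)
        assert -1.0 <= c <= 1.0
        if abs(c) == 1.0:
            mags = np.abs(profile.ranks_for(sig.probe_ids))
            assert sorted(mags) == list(range(N - m + 1, N + 1))


class TestSetScore:
    def test_mean_of_replicate_scores(self):
        uni = ProbeUniverse(("A", "B", "C"))
        p1 = make_profile(uni, [3, -2, 1], "r1", "d")
        p2 = make_profile(uni, [-3, 2, -1], "r2", "d")
        sig = GeneSignature(("A",), (1,))
        refset = ReferenceSet("d", (p1, p2))
        assert set_score(sig, refset) == pytest.approx(0.0)
        expected = np.mean([connection_score(sig, p1), connection_score(sig, p2)])
        assert set_score(sig, refset) == expected

    def test_singleton_set_reduces_to_profile_score(self, five_probe_profile):
        sig = GeneSignature(("A", "D"), (1, -1))
        refset = ReferenceSet("drugX", (five_probe_profile,))
        assert set_score(sig, refset) == connection_score(sig, five_probe_profile)

    def test_duplicating_a_profile_leaves_set_score_unchanged(self, five_probe_profile):
        sig = GeneSignature(("A", "B", "C"), (1, -1, 1))
        once = ReferenceSet("drugX", (five_probe_profile,))
        twice = ReferenceSet("drugX", (five_probe_profile, five_probe_profile))
        assert set_score(sig, twice) == pytest.approx(set_score(sig, once))

    def test_probe_file_order_is_immaterial(self):
        rng = np.random.default_rng(4)
        N = 30
        ids = tuple(f"g{i}" for i in range(N))
        ranks = rng.choice((-1, 1), size=N) * (rng.permutation(N) + 1)
        perm = rng.permutation(N)
        uni_a = ProbeUniverse(ids)
        uni_b = ProbeUniverse(tuple(ids[i] for i in perm))
        prof_a = make_profile(uni_a, ranks)
        prof_b = make_profile(uni_b, ranks[perm])
        sig = GeneSignature(("g3", "g7", "g11"), (1, -1, 1))
        assert connection_score(sig, prof_a) == pytest.approx(
            connection_score(sig, prof_b)
        )


class TestScoresFromRanks:
    def test_replicate_matrix_matches_full_profiles(self, five_probe_profile):
        sig = GeneSignature(("A", "B"), (1, -1))
        refset = ReferenceSet("drugX", (five_probe_profile, five_probe_profile))
        mat = np.stack(
            [p.ranks_for(sig.probe_ids) for p in refset.profiles], axis=1
        )
        mean_score, per = scores_from_ranks(sig.signs, mat, N=5)
        assert mean_score == pytest.approx(set_score(sig, refset))
        assert per == pytest.approx([1.0, 1.0])

    def test_platform_scale_excerpt(self):
        """Setscore from a 6-replicate signed-rank excerpt over the
        HG-U133A-sized universe (N = 22,283), checked against exact
        integer arithmetic. Synthetic stand-in values."""
        N = 22_283
        signs = [1] * 10
        rng = np.random.default_rng(99)
        mat = rng.choice((-1, 1), size=(10, 6)) * rng.integers(
            1, N + 1, size=(10, 6)
        )
        c_max = sum(N - i for i in range(10))
        expected = sum(
            sum(int(mat[i, k]) for i in range(10)) / c_max for k in range(6)
        ) / 6
        mean_score, per = scores_from_ranks(signs, mat, N)
        assert mean_score == pytest.approx(expected, abs=1e-12)
        assert len(per) == 6

    def test_score_from_ranks_antisymmetry(self):
        signs = [1, -1, 1]
        ranks = [120, -80, 5]
        a = score_from_ranks(signs, ranks, 200)
        b = score_from_ranks([-s for s in signs], ranks, 200)
        assert b == pytest.approx(-a)


class TestEstimatePvalue:
    def test_matches_exhaustive_enumeration(self, four_probe_set):
        """Sampled null p-value agrees with full enumeration over all
        C(4,2) = 6 probe pairs: the (A, C) signature is beaten by no
        other configuration (p = 1/6); (A, B) by all (p = 1)."""
        cfg = QueryConfig(n_random=100_000, seed=42)
        sig_ac = GeneSignature(("A", "C"), (1, 1))
        exact = exhaustive_pvalue(sig_ac, four_probe_set)
        assert exact == pytest.approx(1 / 6)
        sampled = estimate_pvalue(sig_ac, four_probe_set, cfg)
        se = math.sqrt(float(exact) * (1 - float(exact)) / cfg.n_random)
        assert abs(sampled - float(exact)) <= 3 * se + 2 / cfg.n_random

        sig_ab = GeneSignature(("A", "B"), (1, 1))
        assert exhaustive_pvalue(sig_ab, four_probe_set) == 1
        assert estimate_pvalue(sig_ab, four_probe_set, cfg) == pytest.approx(
            1.0, abs=1e-4
        )

    def test_same_seed_same_pvalue(self, four_probe_set):
        cfg = QueryConfig(n_random=5_000, seed=7)
        sig = GeneSignature(("A", "D"), (1, -1))
        assert estimate_pvalue(sig, four_probe_set, cfg) == estimate_pvalue(
            sig, four_probe_set, cfg
        )

    def test_degenerate_null_rejected(self, four_probe_set):
        sig = GeneSignature(("A", "B", "C", "D"), (1, 1, 1, 1))
        with pytest.raises(ScoringError, match="degenerate"):
            estimate_pvalue(sig, four_probe_set, QueryConfig(n_random=100, seed=0))

    def test_pvalue_unchanged_by_sign_flip(self, four_probe_set):
        cfg = QueryConfig(n_random=20_000, seed=3)
        sig = GeneSignature(("A", "C"), (1, -1))
        p_fwd = estimate_pvalue(sig, four_probe_set, cfg)
        p_rev = estimate_pvalue(sig.flipped(), four_probe_set, cfg)
        assert p_fwd == pytest.approx(p_rev, abs=5e-3)


class TestQueryDatabase:
    def test_planted_compound_dominates_nulls(self):
        from connmap import SyntheticConfig, gen_reference_db

        cfg = SyntheticConfig(N=400, D=21, K_range=(3, 3), seed=5,
                              planted=(("cmpd0000", 1.0, 1),))
        db, truth = gen_reference_db(cfg)
        qc = QueryConfig(n_random=2_000, seed=5)
        results = query_database(truth.signature, db, qc)
        planted = next(r for r in results if r.compound == "cmpd0000")
        assert planted.sig == 1
        assert planted.setscore == pytest.approx(1.0)
        assert all(
            abs(r.setscore) < abs(planted.setscore)
            for r in results
            if r.compound != "cmpd0000"
        )

    def test_one_result_per_set_with_threshold_flag(self):
        db = random_database(N=60, D=10, K=2, seed=1)
        qc = QueryConfig(n_random=1_000, seed=1)
        sig = GeneSignature(("pr0", "pr5", "pr9"), (1, -1, 1))
        results = query_database(sig, db, qc)
        assert [r.compound for r in results] == db.compounds()
        for r in results:
            assert r.sig == int(r.pvalue <= qc.alpha_family / db.D)
            assert -1 <= r.setscore <= 1

    def test_insufficient_n_random_rejected(self):
        db = random_database(N=60, D=10, K=1, seed=2)
        sig = GeneSignature(("pr1", "pr2"), (1, 1))
        with pytest.raises(ScoringError, match="n_random"):
            query_database(sig, db, QueryConfig(n_random=50, seed=0))


class TestEstimateFdr:
    def test_reciprocal_of_hit_count(self):
        cfg = QueryConfig(n_random=10_000, seed=0)
        assert estimate_fdr(271, cfg) == pytest.approx(1 / 271)
        assert estimate_fdr(154, cfg) == pytest.approx(1 / 154)
        assert estimate_fdr(271, cfg) <= cfg.fdr_target
        assert estimate_fdr(154, cfg) <= cfg.fdr_target

    def test_zero_hits_gives_sentinel(self):
        assert estimate_fdr(0, QueryConfig(seed=0)) == math.inf

    def test_monotone_decreasing_in_hits(self):
        cfg = QueryConfig(seed=0)
        fdrs = [estimate_fdr(n, cfg) for n in range(1, 20)]
        assert fdrs == sorted(fdrs, reverse=True)


def _result(compound, setsize, setscore, sig=1, per=1.0):
    return ConnectionResult(
        compound=compound,
        setsize=setsize,
        query_name="q",
        query_length=10,
        setscore=setscore,
        pvalue=0.0001,
        sig=sig,
        perturbation_stability=per,
    )


class TestRankResults:
    def test_published_stable_hits_order(self):
        """On the published cross-platform table of fully stable hits, the
        ranking rule (setsize desc, then |setscore| desc) puts cotinine
        (K=6) first, then morantel (K=5), then tobramycin and trioxysalen
        (K=4, |setscore| 0.671 > 0.658)."""
        df = cross_platform_stable_hits()
        results = [
            _result(row.refsetname, row.setsize, row.setscore_rnaseq)
            for row in df.itertuples(index=False)
        ]
        ranked = rank_results(results)
        assert [r.compound for r in ranked[:4]] == [
            "cotinine",
            "morantel",
            "tobramycin",
            "trioxysalen",
        ]

    def test_only_significant_kept_and_stability_required(self):
        results = [
            _result("a", 2, 0.5),
            _result("b", 2, 0.9, sig=0),
            _result("c", 2, 0.7, per=None),
        ]
        assert [r.compound for r in rank_results(results[:2])] == ["a"]
        with pytest.raises(ScoringError, match="stability"):
            rank_results(results)

    def test_all_equal_keys_alphabetical(self):
        results = [_result(c, 3, 0.4) for c in ("zeta", "alpha", "mid")]
        ranked = rank_results(results)
        assert [r.compound for r in ranked] == ["alpha", "mid", "zeta"]

    def test_single_result_is_itself(self):
        results = [_result("only", 1, -0.3)]
        assert rank_results(results) == results

    def test_stability_ranks_before_setsize(self):
        results = [_result("big", 10, 0.9, per=0.5), _result("small", 2, 0.2, per=1.0)]
        assert [r.compound for r in rank_results(results)] == ["small", "big"]


def test_results_frame_has_conventional_columns():
    df = results_to_frame([_result("a", 2, 0.5)])
    assert list(df.columns) == [
        "refsetname",
        "setsize",
        "queryName",
        "queryLength",
        "setscore",
        "pvalue",
        "sig",
        "Per",
    ]
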