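import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_corr
from coexhub import (
    DifferentialExpressionRecord,
    GeneSetLibrary,
    auroc,
    deg_filter,
    mean_pcc,
    overlap_significance,
    prioritize_perturbations,
    rank_genes_for_set,
    score_library,
)
from coexhub.association import parse_signature_label


class TestMeanPcc:
    def test_arithmetic_mean_over_present_members(self):
        c = make_corr({("Q", "a"): 0.5, ("Q", "b"): 0.3})
        assert mean_pcc(c, "Q", {"a", "b"}) == (pytest.approx(0.4), 2)

    def test_query_excluded_from_its_own_set(self):
        c = make_corr({("Q", "a"): 0.6})
        assert mean_pcc(c, "Q", {"Q", "a"}) == (pytest.approx(0.6), 1)

    def test_absent_members_silently_dropped_and_counted(self):
        c = make_corr({("Q", "a"): 0.2})
        assert mean_pcc(c, "Q", {"a", "missing_gene"}) == (pytest.approx(0.2), 1)

    def test_empty_effective_set_rejected(self):
        c = make_corr({("Q", "a"): 0.2})
        with pytest.raises(ValueError, match="empty effective set"):
            mean_pcc(c, "Q", {"Q", "missing"})


class TestScoreLibrary:
    def worked_example(self):
        # Background mean PCCs with the term are {0.1, 0.2, 0.3}; the query
        # holds the 0.3 -> mu=0.2, sigma=0.1 (ddof=1), z=1.
        c = make_corr({("A", "t"): 0.1, ("B", "t"): 0.2, ("Q", "t"): 0.3})
        lib = GeneSetLibrary({"T": ["t"]})
        return score_library(c, "Q", lib, {"A", "B", "Q"})

    def test_z_and_right_tail_match_hand_computation(self):
        (s,) = self.worked_example()
        assert s.z == pytest.approx(1.0)
        assert s.p_right == pytest.approx(0.158655, abs=1e-6)
        assert s.mean_pcc == pytest.approx(0.3)

    def test_tails_sum_to_one(self, corpus):
        scores = score_library(
            corpus["corr"],
            corpus["truth"].lncrna_queries()[0],
            corpus["library"],
            set(corpus["corr"].gene_ids),
        )
        for s in scores:
            assert s.p_right + s.p_left == pytest.approx(1.0, abs=1e-12)

    def test_query_at_null_mean_gives_half_half(self):
        c = make_corr({("A", "t"): 0.1, ("B", "t"): 0.3, ("Q", "t"): 0.2})
        (s,) = score_library(c, "Q", GeneSetLibrary({"T": ["t"]}), {"A", "B", "Q"})
        assert s.z == pytest.approx(0.0)
        assert s.p_right == pytest.approx(0.5) and s.p_left == pytest.approx(0.5)

    def test_degenerate_zero_sd_term_flagged(self):
        c = make_corr({("A", "t"): 0.2, ("Q", "t"): 0.2})
        (s,) = score_library(c, "Q", GeneSetLibrary({"T": ["t"]}), {"A", "Q"})
        assert s.degenerate and s.p_right == 0.5 and s.p_left == 0.5

    def test_planted_module_outranks_background_terms(self, corpus):
        truth = corpus["truth"]
        q = truth.lncrna_queries()[0]
        scores = score_library(corpus["corr"], q, corpus["library"], set(corpus["corr"].gene_ids))
        scores.sort(key=lambda s: (s.p_right, s.term))
        assert scores[0].term == f"module_{truth.module_of[q]}"
        planted_z = scores[0].z
        background_z = [s.z for s in scores if s.term.startswith("background_")]
        assert planted_z > max(abs(z) for z in background_z)


class TestRankGenesForSet:
    def test_descending_mean_pcc_with_lexicographic_ties(self):
        c = make_corr({("X", "t"): 0.4, ("Y", "t"): 0.1, ("B", "t"): 0.2, ("A", "t"): 0.2})
        ranked = rank_genes_for_set(c, {"X", "Y", "A", "B"}, {"t"})
        assert [g for g, _ in ranked] == ["X", "A", "B", "Y"]

    def test_candidate_inside_target_set_still_ranked(self):
        c = make_corr({("X", "t"): 0.4, ("t", "t2"): 0.9, ("X", "t2"): 0.1})
        ranked = rank_genes_for_set(c, {"X", "t"}, {"t", "t2"})
        assert {g for g, _ in ranked} == {"X", "t"}

    def test_empty_candidates_rejected(self):
        c = make_corr({("X", "t"): 0.4})
        with pytest.raises(ValueError):
            rank_genes_for_set(c, set(), {"t"})


class TestPerturbations:
    def test_direction_suffix_parsing(self):
        assert parse_signature_label("drugA 10uM up") == ("drugA 10uM", "up")
        assert parse_signature_label("KO_TP53-down") == ("KO_TP53", "down")
        with pytest.raises(ValueError, match="direction"):
            parse_signature_label("no_direction_here")

    def test_inverted_gmt_round_trips_against_rankings(self, corpus):
        corr = corpus["corr"]
        genes = corr.gene_ids
        rng = np.random.default_rng(3)
        sigs = {}
        for i in range(25):
            for d in ("up", "down"):
                sigs[f"sig{i:02d} {d}"] = sorted(rng.choice(genes, size=15, replace=False))
        lib = GeneSetLibrary(sigs)
        queries = sorted(rng.choice(genes, size=30, replace=False))
        top_k = 10
        per_query, inverted = prioritize_perturbations(corr, lib, queries, top_k=top_k)

        # Recompute each signature's top-k ranking independently.
        expected_pairs = set()
        for label, members in sigs.items():
            base, direction = parse_signature_label(label)
            ranked = rank_genes_for_set(corr, queries, members)[:top_k]
            for q, _ in ranked:
                expected_pairs.add((q, base, direction))
        got_pairs = {
            (q, row["signature"], row["direction"])
            for q, rows in per_query.items()
            for row in rows
        }
        assert got_pairs == expected_pairs
        gmt_pairs = {
            (q, *member.rsplit("|", 1)) for q, members in inverted.terms.items() for member in members
        }
        assert gmt_pairs == expected_pairs

    def test_query_outside_every_top_k_absent_from_inversion(self):
        c = make_corr({("A", "t"): 0.9, ("B", "t"): 0.5, ("Z", "t"): 0.1})
        lib = GeneSetLibrary({"sig up": ["t"]})
        per_query, inverted = prioritize_perturbations(c, lib, {"A", "B", "Z"}, top_k=2)
        assert "Z" not in per_query and "Z" not in inverted.terms

    def test_p_value_ordering_is_non_decreasing(self, corpus):
        corr = corpus["corr"]
        rng = np.random.default_rng(4)
        genes = corr.gene_ids
        sigs = GeneSetLibrary(
            {f"s{i} up": sorted(rng.choice(genes, size=12, replace=False)) for i in range(8)}
        )
        queries = sorted(rng.choice(genes, size=25, replace=False))
        per_query, _ = prioritize_perturbations(corr, sigs, queries, top_k=25, sort_by="p_right")
        for rows in per_query.values():
            ps = [r["p_right"] for r in rows]
            assert ps == sorted(ps)

    def test_unlabeled_signature_rejected(self):
        c = make_corr({("A", "t"): 0.9})
        with pytest.raises(ValueError, match="direction"):
            prioritize_perturbations(c, GeneSetLibrary({"nodirection": ["t"]}), {"A"})


class TestDegFilter:
    RECORDS = [
        DifferentialExpressionRecord("g_fc_fail", 0.4, 0.01, 2.0),
        DifferentialExpressionRecord("g_fdr_fail", 1.0, 0.20, 2.0),
        DifferentialExpressionRecord("g_z_fail", 1.0, 0.01, 1.0),
        DifferentialExpressionRecord("g_up", 0.8, 0.01, 2.0),
        DifferentialExpressionRecord("g_down", -1.2, 0.04, -1.7),
    ]

    def test_thresholds_applied_jointly(self):
        up, down = deg_filter(self.RECORDS)
        assert up == ["g_up"]
        assert down == ["g_down"]

    def test_truncation_to_top_n_by_abs_fold_change(self):
        records = [
            DifferentialExpressionRecord(f"g{i:03d}", 0.6 + 0.001 * i, 0.01, 2.0)
            for i in range(300)
        ]
        up, down = deg_filter(records, top_n=200)
        assert len(up) == 200 and not down
        assert up[0] == "g299"  # largest |log2FC| first

    def test_tie_break_prefers_smaller_fdr_then_name(self):
        records = [
            DifferentialExpressionRecord("b", 1.0, 0.02, 2.0),
            DifferentialExpressionRecord("a", 1.0, 0.02, 2.0),
            DifferentialExpressionRecord("c", 1.0, 0.01, 2.0),
        ]
        up, _ = deg_filter(records, top_n=2)
        assert up == ["c", "a"]


def hypergeom_right_tail(N, nA, nB, k):
    """Enumerated right tail P(overlap >= k) (independent oracle)."""
    total = 0
    for i in range(k, min(nA, nB) + 1):
        total += math.comb(nA, i) * math.comb(N - nA, nB - i)
    return total / math.comb(N, nB)


class TestOverlapSignificance:
    def test_complete_overlap_small_universe(self):
        universe = {f"g{i}" for i in range(20)}
        a = {f"g{i}" for i in range(5)}
        k, p, _ = overlap_significance(a, a, universe)
        assert k == 5
        assert p == pytest.approx(1 / 15504, rel=1e-9)

    def test_degenerate_full_table(self):
        u = {"a", "b", "c"}
        k, p, _ = overlap_significance(u, u, u)
        assert k == 3 and p == pytest.approx(1.0)

    @pytest.mark.parametrize("N,nA,nB,k", [
        (10, 3, 4, 2), (25, 10, 5, 0), (60, 20, 15, 7), (100, 40, 30, 12), (100, 2, 2, 1),
    ])
    def test_matches_hypergeometric_enumeration(self, N, nA, nB, k):
        universe = {f"g{i}" for i in range(N)}
        a = {f"g{i}" for i in range(nA)}
        b = {f"g{i}" for i in range(nA - k, nA - k + nB)}
        assert len(a & b) == k
        _, p, _ = overlap_significance(a, b, universe)
        assert p == pytest.approx(hypergeom_right_tail(N, nA, nB, k), rel=1e-9)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_significance(set(), set(), set())


def pair_counting_auroc(scores, positives):
    """Explicit all-pairs Mann-Whitney count (independent oracle)."""
    pos = [s for item, s in scores if item in positives]
    neg = [s for item, s in scores if item not in positives]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        scores = [("p1", 0.9), ("p2", 0.8), ("n1", 0.2), ("n2", 0.1)]
        assert auroc(scores, {"p1", "p2"}) == 1.0

    def test_interleaved_scores_give_half(self):
        scores = [("p1", 0.8), ("p2", 0.2), ("n1", 0.6), ("n2", 0.4)]
        assert auroc(scores, {"p1", "p2"}) == 0.5

    def test_all_ties_give_half(self):
        scores = [(f"x{i}", 1.0) for i in range(6)]
        assert auroc(scores, {"x0", "x1"}) == 0.5

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 5), min_size=2, max_size=60),
        st.data(),
    )
    def test_matches_all_pairs_counting(self, raw_scores, data):
        items = [(f"i{j}", float(s)) for j, s in enumerate(raw_scores)]
        n_pos = data.draw(st.integers(1, len(items) - 1))
        positives = {f"i{j}" for j in range(n_pos)}
        assert auroc(items, positives) == pytest.approx(
            pair_counting_auroc(items, positives), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([("a", 1.0), ("b", 0.5)], {"a", "b"})
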