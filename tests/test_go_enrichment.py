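"""Enrichment statistics vs exact enumeration; annotation propagation; pair similarity."""

import math
from fractions import Fraction

import pytest
from scipy.stats import fisher_exact

from bidipromoter.go_enrichment import (
    adjust_bh,
    adjust_yekutieli,
    enrich_gene_sets,
    enrich_terms,
    hypergeometric_p,
    pair_shared_terms,
    propagate_annotations,
)
from bidipromoter.io_formats import GeneAnnotationSet


def exact_upper_tail(k: int, n: int, K: int, N: int) -> Fraction:
    """Oracle: exact P(X >= k) as a rational number from the pmf."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for j in range(k, min(n, K) + 1):
        acc += Fraction(math.comb(K, j) * math.comb(N - K, n - j), total)
    return acc


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------

class TestPropagation:
    def test_chain_closure(self, diamond_ontology):
        ann = GeneAnnotationSet({"g": {"T:B"}})
        closed = propagate_annotations(ann, diamond_ontology)
        assert closed["g"] == {"T:B", "T:A"}

    def test_idempotent(self, diamond_ontology):
        ann = GeneAnnotationSet({"g": {"T:D"}})
        once = propagate_annotations(ann, diamond_ontology)
        assert propagate_annotations(once, diamond_ontology) == once

    def test_diamond_counts_shared_ancestor_once(self, diamond_ontology):
        ann = GeneAnnotationSet({"g": {"T:D"}})
        closed = propagate_annotations(ann, diamond_ontology)
        # reachability oracle: D -> {B, C} -> A
        assert closed["g"] == {"T:D", "T:B", "T:C", "T:A"}
        assert len(closed["g"]) == 4

    def test_unknown_term_rejected(self, diamond_ontology):
        with pytest.raises(ValueError, match="T:X"):
            propagate_annotations(GeneAnnotationSet({"g": {"T:X"}}), diamond_ontology)


# ---------------------------------------------------------------------------
# hypergeometric test
# ---------------------------------------------------------------------------

class TestHypergeometric:
    def test_saturated_draw(self):
        # all 5 study genes carry the term out of 5 carriers in 10:
        # C(5,5)C(5,0)/C(10,5) = 1/252
        assert hypergeometric_p(5, 5, 5, 10) == pytest.approx(1 / 252, rel=1e-12)

    def test_k_zero_is_one(self):
        assert hypergeometric_p(0, 3, 4, 8) == 1.0

    def test_two_of_three(self):
        expected = float(exact_upper_tail(2, 3, 4, 8))
        assert hypergeometric_p(2, 3, 4, 8) == pytest.approx(expected, rel=1e-12)

    def test_matches_enumeration_for_all_small_margins(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(n, K) + 1):
                        expected = float(exact_upper_tail(k, n, K, N))
                        assert hypergeometric_p(k, n, K, N) == pytest.approx(
                            expected, rel=1e-10, abs=1e-300
                        ), (k, n, K, N)

    def test_invalid_margins_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_p(3, 2, 4, 8)
        with pytest.raises(ValueError):
            hypergeometric_p(1, 2, 9, 8)


# ---------------------------------------------------------------------------
# multiple-testing adjustments
# ---------------------------------------------------------------------------

def by_oracle(pvalues):
    """Hand evaluation of the BY formula: min over j >= rank of
    m * c(m) * p_(j) / j, capped at 1."""
    m = len(pvalues)
    c_m = sum(1 / i for i in range(1, m + 1))
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [None] * m
    running = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * c_m * pvalues[i] / rank)
        adjusted[i] = min(running, 1.0)
    return adjusted


class TestAdjustments:
    def test_single_p_is_identity(self):
        assert adjust_yekutieli([0.03]) == [pytest.approx(0.03)]

    def test_two_values_hand_case(self):
        # m=2, c(2)=1.5: candidates 0.01*2*1.5/1 = 0.03 and 0.04*2*1.5/2 = 0.06
        assert adjust_yekutieli([0.01, 0.04]) == [
            pytest.approx(0.03),
            pytest.approx(0.06),
        ]

    def test_all_ones_stay_one(self):
        assert adjust_yekutieli([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    @pytest.mark.parametrize(
        "pvalues",
        [
            [0.5, 0.01, 0.04],
            [0.001, 0.2, 0.2, 0.9],
            [0.11, 0.11, 0.11],
            [0.03, 0.5, 0.0001, 1.0, 0.2, 0.07],
        ],
    )
    def test_matches_hand_formula_and_dominates_bh(self, pvalues):
        adjusted = adjust_yekutieli(pvalues)
        assert adjusted == pytest.approx(by_oracle(pvalues))
        bh = adjust_bh(pvalues)
        for raw, a_by, a_bh in zip(pvalues, adjusted, bh):
            assert a_by >= a_bh >= raw - 1e-15
        # monotone along the sorted raw order
        order = sorted(range(len(pvalues)), key=lambda i: pvalues[i])
        sorted_adj = [adjusted[i] for i in order]
        assert sorted_adj == sorted(sorted_adj)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_yekutieli([0.1, 1.5])
        with pytest.raises(ValueError):
            adjust_bh([-0.1])


# ---------------------------------------------------------------------------
# term enrichment
# ---------------------------------------------------------------------------

class TestEnrichTerms:
    def test_planted_term_matches_enumeration(self, diamond_ontology):
        population = [f"g{i}" for i in range(8)]
        study = population[:3]
        # T:D planted in 2/3 study vs 4/8 population (direct, leaf term)
        ann = GeneAnnotationSet(
            {g: {"T:D"} for g in ["g0", "g1", "g3", "g4"]}
            | {g: {"T:M"} for g in ["g2", "g5", "g6", "g7"]}
        )
        records = enrich_terms(study, population, ann, diamond_ontology)
        by_term = {r.term_id: r for r in records}
        assert by_term["T:D"].k == 2 and by_term["T:D"].K == 4
        assert by_term["T:D"].p_raw == pytest.approx(
            float(exact_upper_tail(2, 3, 4, 8)), rel=1e-12
        )
        # propagated ancestors of T:D have identical margins here
        assert by_term["T:A"].k == 2 and by_term["T:A"].K == 4

    def test_study_equals_population_saturates(self, diamond_ontology):
        genes = ["g0", "g1"]
        ann = GeneAnnotationSet({"g0": {"T:D"}, "g1": {"T:B"}})
        records = enrich_terms(genes, genes, ann, diamond_ontology)
        assert all(r.k == r.K for r in records)

    def test_term_without_study_gene_absent(self, diamond_ontology):
        ann = GeneAnnotationSet({"g0": {"T:B"}, "g1": {"T:M"}})
        records = enrich_terms(["g0"], ["g0", "g1"], ann, diamond_ontology)
        assert "T:M" not in {r.term_id for r in records}

    def test_study_outside_population_rejected(self, diamond_ontology):
        ann = GeneAnnotationSet({"gX": {"T:B"}})
        with pytest.raises(ValueError, match="gX"):
            enrich_terms(["gX"], ["g0"], ann, diamond_ontology)

    def test_adjusted_at_least_raw_and_sorted(self, diamond_ontology):
        population = [f"g{i}" for i in range(10)]
        ann = GeneAnnotationSet(
            {g: ({"T:D"} if i < 4 else {"T:C"}) for i, g in enumerate(population)}
        )
        records = enrich_terms(population[:4], population, ann, diamond_ontology)
        assert all(r.p_adjusted >= r.p_raw for r in records)
        assert [r.p_adjusted for r in records] == sorted(
            r.p_adjusted for r in records
        )


# ---------------------------------------------------------------------------
# pair similarity
# ---------------------------------------------------------------------------

class TestPairSharedTerms:
    def test_intersection_and_histogram(self, diamond_ontology):
        ann = GeneAnnotationSet(
            {"p1": {"T:B", "T:C"}, "m1": {"T:C", "T:D"}, "p2": {"T:B"}, "m2": {"T:D"}}
        )
        records, summary = pair_shared_terms(
            [("P1", "p1", "m1"), ("P2", "p2", "m2")], ann, diamond_ontology
        )
        assert records[0].shared_terms == {"T:C"}
        assert records[1].shared_count == 0
        assert summary["fraction_sharing"] == 0.5
        assert summary["histogram"] == {0: 1, 1: 1}
        assert summary["n_sharing_by_namespace"]["biological_process"] == 1

    def test_namespace_partition(self, diamond_ontology):
        ann = GeneAnnotationSet({"p": {"T:B", "T:M"}, "m": {"T:B", "T:M"}})
        records, _ = pair_shared_terms([("P", "p", "m")], ann, diamond_ontology)
        (record,) = records
        union = set()
        for ns_terms in record.by_namespace.values():
            assert union.isdisjoint(ns_terms)
            union |= ns_terms
        assert union == record.shared_terms

    def test_symmetric_under_member_swap(self, diamond_ontology):
        ann = GeneAnnotationSet({"a": {"T:B"}, "b": {"T:B", "T:C"}})
        _, fwd = pair_shared_terms([("P", "a", "b")], ann, diamond_ontology)
        _, rev = pair_shared_terms([("P", "b", "a")], ann, diamond_ontology)
        assert fwd["fraction_sharing"] == rev["fraction_sharing"]

    def test_unannotated_member_counts_as_empty(self, diamond_ontology):
        ann = GeneAnnotationSet({"a": {"T:B"}})
        records, summary = pair_shared_terms([("P", "a", "zz")], ann, diamond_ontology)
        assert records[0].shared_count == 0
        assert not records[0].minus_annotated
        assert summary["fraction_sharing"] == 0.0

    def test_propagated_mode_excludes_shallow_terms(self, diamond_ontology):
        # members share only via the root once propagated; depth filter drops it
        ann = GeneAnnotationSet({"a": {"T:B"}, "b": {"T:C"}})
        records, _ = pair_shared_terms(
            [("P", "a", "b")], ann, diamond_ontology, propagated=True
        )
        assert records[0].shared_count == 0


# ---------------------------------------------------------------------------
# gene-set (GMT) enrichment
# ---------------------------------------------------------------------------

class TestGeneSets:
    def test_identical_to_hypergeometric_on_margins(self):
        population = [f"g{i}" for i in range(10)]
        study = population[:5]
        collections = {"setA": ("all-of-study", frozenset(population[:5]))}
        (record,) = enrich_gene_sets(study, population, collections)
        assert record.p_raw == pytest.approx(1 / 252, rel=1e-12)
        # independent route: scipy one-sided Fisher on the same 2x2 table
        _, fisher_p = fisher_exact([[5, 0], [0, 5]], alternative="greater")
        assert record.p_raw == pytest.approx(fisher_p, rel=1e-9)

    def test_disjoint_set_p_one(self):
        population = [f"g{i}" for i in range(10)]
        collections = {"setB": ("", frozenset(population[5:]))}
        (record,) = enrich_gene_sets(population[:5], population, collections)
        assert record.p_raw == 1.0

    def test_empty_set_skipped(self):
        population = ["g0", "g1"]
        collections = {"ghost": ("", frozenset({"zz"}))}
        assert enrich_gene_sets(["g0"], population, collections) == []
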