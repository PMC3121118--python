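"""Clustering and pair/uni classification, checked against brute-force oracles."""

import pytest
from hypothesis import given, settings, strategies as st

from bidipromoter.io_formats import TranscriptRecord
from bidipromoter.pair_classification import (
    classify_bidirectional,
    classify_unidirectional,
    collapse_clusters,
    deduplicate_pairs,
    filter_evidence,
    tss_of,
)

from conftest import make_cluster


# ---------------------------------------------------------------------------
# TSS definition
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "strand, start, end, expected",
    [("+", 1000, 5000, 1000), ("-", 200, 800, 800), ("+", 7, 8, 7)],
)
def test_tss_is_five_prime_end(strand, start, end, expected):
    record = TranscriptRecord("NM_1", "g", "chr1", strand, start, end)
    assert tss_of(record) == expected
    assert tss_of(make_cluster("chr1", strand, start, end)) == expected


# ---------------------------------------------------------------------------
# collapse
# ---------------------------------------------------------------------------

def _tx(acc, chrom, strand, start, end, symbol="g"):
    return TranscriptRecord(acc, symbol, chrom, strand, start, end)


class TestCollapse:
    def test_overlap_merge(self):
        clusters = collapse_clusters(
            [_tx("NM_1", "chr1", "+", 100, 500), _tx("NM_2", "chr1", "+", 400, 900)]
        )
        assert len(clusters) == 1
        assert (clusters[0].start, clusters[0].end, clusters[0].tss) == (100, 900, 100)

    def test_strands_never_merge(self):
        clusters = collapse_clusters(
            [_tx("NM_1", "chr1", "+", 100, 500), _tx("NM_2", "chr1", "-", 100, 500)]
        )
        assert len(clusters) == 2

    def test_abutting_merge_derived_from_interval_union(self):
        clusters = collapse_clusters(
            [
                _tx("NM_1", "chr1", "+", 0, 10),
                _tx("NM_2", "chr1", "+", 10, 20),
                _tx("NM_3", "chr1", "+", 30, 40),
            ]
        )
        assert [(c.start, c.end) for c in clusters] == [(0, 20), (30, 40)]

    def test_symbol_from_five_prime_member_with_accession_tiebreak(self):
        clusters = collapse_clusters(
            [
                _tx("NM_9", "chr1", "-", 100, 500, "late"),
                _tx("NM_2", "chr1", "-", 200, 500, "tieA"),
                _tx("NM_1", "chr1", "-", 300, 500, "tieB"),
            ]
        )
        (cluster,) = clusters
        assert cluster.tss == 500
        # both NM_1 and NM_2 end at the cluster TSS; NM_1 wins lexicographically
        assert cluster.gene_symbol == "tieB"

    def test_best_evidence_class_among_members(self):
        (cluster,) = collapse_clusters(
            [_tx("XR_1", "chr1", "+", 0, 50), _tx("NR_1", "chr1", "+", 10, 60)]
        )
        assert cluster.evidence_class == "curated-noncoding"

    @given(
        st.lists(
            st.tuples(st.integers(0, 300), st.integers(1, 60)),
            min_size=1,
            max_size=20,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_interval_union_oracle(self, spans):
        records = [
            _tx(f"NM_{i}", "chr1", "+", start, start + length)
            for i, (start, length) in enumerate(spans)
        ]
        clusters = collapse_clusters(records)
        # oracle: sweep over sorted intervals, merging on overlap/abutment
        merged = []
        for start, end in sorted((s, s + l) for s, l in spans):
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        assert [(c.start, c.end) for c in clusters] == [tuple(m) for m in merged]
        # every transcript is accounted for exactly once
        assert sum(len(c.members) for c in clusters) == len(records)


# ---------------------------------------------------------------------------
# evidence filter
# ---------------------------------------------------------------------------

class TestFilterEvidence:
    @pytest.fixture
    def mixed(self):
        return [
            make_cluster("chr1", "+", 0, 10, "nm", "curated-mRNA"),
            make_cluster("chr1", "+", 20, 30, "nr", "curated-noncoding"),
            make_cluster("chr1", "+", 40, 50, "xr", "predicted"),
            make_cluster("chr1", "+", 60, 70, "oth", "other"),
        ]

    def test_modes(self, mixed):
        assert [c.gene_symbol for c in filter_evidence(mixed, "curated-mRNA")] == ["nm"]
        assert [c.gene_symbol for c in filter_evidence(mixed, "curated")] == ["nm", "nr"]
        # predictions are always excluded, even under "all"
        assert [c.gene_symbol for c in filter_evidence(mixed, "all")] == [
            "nm",
            "nr",
            "oth",
        ]

    def test_unknown_mode_and_empty_input(self, mixed):
        with pytest.raises(ValueError, match="mode"):
            filter_evidence(mixed, "everything")
        assert filter_evidence([], "curated") == []


# ---------------------------------------------------------------------------
# bidirectional pairs
# ---------------------------------------------------------------------------

def _divergent(minus_tss, plus_tss, chrom="chr1"):
    return [
        make_cluster(chrom, "-", minus_tss - 4000, minus_tss, "m"),
        make_cluster(chrom, "+", plus_tss, plus_tss + 4000, "p"),
    ]


class TestClassifyBidirectional:
    def test_divergent_within_distance(self):
        (pair,) = classify_bidirectional(_divergent(10_000, 10_500))
        assert pair.tss_distance == 500
        assert pair.intergenic == (10_000, 10_500)

    def test_distance_bound_is_strict(self):
        assert classify_bidirectional(_divergent(10_000, 10_999))[0].tss_distance == 999
        assert classify_bidirectional(_divergent(10_000, 11_000)) == []

    def test_convergent_not_paired(self):
        clusters = [
            make_cluster("chr1", "+", 10_000, 14_000, "p"),  # tss 10 000
            make_cluster("chr1", "-", 6_000, 10_500, "m"),  # tss 10 500 > plus tss
        ]
        assert classify_bidirectional(clusters) == []

    def test_intervening_tss_blocks_adjacency(self):
        clusters = _divergent(10_000, 10_900) + [
            make_cluster("chr1", "+", 10_400, 10_450, "mid")
        ]
        pairs = classify_bidirectional(clusters)
        assert [(p.minus_gene.tss, p.plus_gene.tss) for p in pairs] == [(10_000, 10_400)]

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["chr1", "chr2"]),
                st.sampled_from(["+", "-"]),
                st.integers(0, 100),  # TSS slot; scaled to keep TSSs distinct
            ),
            min_size=2,
            max_size=50,
            unique_by=lambda t: (t[0], t[2]),
        )
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_quadratic_oracle(self, specs):
        clusters = []
        for i, (chrom, strand, slot) in enumerate(specs):
            tss = slot * 37  # distinct per chromosome by construction
            if strand == "+":
                clusters.append(make_cluster(chrom, "+", tss, tss + 5, f"g{i}"))
            else:
                clusters.append(make_cluster(chrom, "-", max(tss - 5, 0), tss, f"g{i}"))
        pairs = classify_bidirectional(clusters, max_distance=1000)
        found = {(p.chromosome, p.minus_gene.tss, p.plus_gene.tss) for p in pairs}

        expected = set()
        for a in clusters:
            for b in clusters:
                if (
                    a.strand == "-"
                    and b.strand == "+"
                    and a.chromosome == b.chromosome
                    and 0 <= b.tss - a.tss < 1000
                    and not any(
                        c.chromosome == a.chromosome and a.tss < c.tss < b.tss
                        for c in clusters
                    )
                ):
                    expected.add((a.chromosome, a.tss, b.tss))
        assert found == expected


# ---------------------------------------------------------------------------
# unidirectional genes
# ---------------------------------------------------------------------------

class TestClassifyUnidirectional:
    def test_isolated_gene(self):
        clusters = [
            make_cluster("chr1", "+", 100_000, 104_000, "iso"),
            make_cluster("chr1", "-", 150_000, 154_000, "far"),
        ]
        assert {c.gene_symbol for c in classify_unidirectional(clusters)} == {
            "iso",
            "far",
        }

    def test_opposite_tss_within_10kb_blocks(self):
        clusters = [
            make_cluster("chr1", "+", 100_000, 104_000, "g"),  # tss 100 000
            make_cluster("chr1", "-", 87_000, 91_000, "opp"),  # tss 91 000: 9 kb up
        ]
        uni = {c.gene_symbol for c in classify_unidirectional(clusters)}
        assert "g" not in uni

    def test_same_strand_beyond_1kb_allowed(self):
        clusters = [
            make_cluster("chr1", "+", 100_000, 104_000, "g"),
            make_cluster("chr1", "+", 98_500, 99_000, "up"),  # tss 1 500 bp upstream
        ]
        uni = {c.gene_symbol for c in classify_unidirectional(clusters)}
        assert "g" in uni

    @pytest.mark.parametrize(
        "upstream_d, expect_uni", [(1000, False), (1001, True)]
    )
    def test_same_strand_1kb_boundary(self, upstream_d, expect_uni):
        clusters = [
            make_cluster("chr1", "+", 100_000, 104_000, "g"),
            make_cluster("chr1", "+", 100_000 - upstream_d, 100_000 - upstream_d + 10, "up"),
        ]
        uni = {c.gene_symbol for c in classify_unidirectional(clusters)}
        assert ("g" in uni) is expect_uni

    @pytest.mark.parametrize(
        "upstream_d, expect_uni", [(10_000, False), (10_001, True)]
    )
    def test_opposite_strand_10kb_boundary(self, upstream_d, expect_uni):
        tss = 100_000
        clusters = [
            make_cluster("chr1", "+", tss, tss + 4_000, "g"),
            make_cluster("chr1", "-", tss - upstream_d - 100, tss - upstream_d, "opp"),
        ]
        uni = {c.gene_symbol for c in classify_unidirectional(clusters)}
        assert ("g" in uni) is expect_uni

    def test_downstream_neighbours_irrelevant(self):
        clusters = [
            make_cluster("chr1", "+", 100_000, 104_000, "g"),
            make_cluster("chr1", "-", 104_500, 108_000, "down"),  # tss 108 000 downstream
        ]
        uni = {c.gene_symbol for c in classify_unidirectional(clusters)}
        assert "g" in uni

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["+", "-"]),
                st.integers(0, 60),
            ),
            min_size=2,
            max_size=40,
            unique_by=lambda t: t[1],
        )
    )
    @settings(max_examples=150, deadline=None)
    def test_pair_members_never_unidirectional(self, specs):
        clusters = []
        for i, (strand, slot) in enumerate(specs):
            tss = slot * 613  # mixture of near and far neighbours
            if strand == "+":
                clusters.append(make_cluster("chr1", "+", tss, tss + 10, f"g{i}"))
            else:
                clusters.append(make_cluster("chr1", "-", max(tss - 10, 0), tss, f"g{i}"))
        pairs = classify_bidirectional(clusters)
        uni = classify_unidirectional(clusters)
        paired = {
            c.cluster_id for p in pairs for c in (p.plus_gene, p.minus_gene)
        }
        assert paired.isdisjoint({c.cluster_id for c in uni})


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

class TestDeduplicate:
    def test_identical_intergenic_collapses_to_smallest_symbols(self):
        pairs = classify_bidirectional(
            [
                make_cluster("chr1", "-", 6_000, 10_000, "mB"),
                make_cluster("chr1", "+", 10_500, 14_000, "pB"),
            ]
        ) + classify_bidirectional(
            [
                make_cluster("chr1", "-", 6_100, 10_000, "mA"),
                make_cluster("chr1", "+", 10_500, 14_100, "pA"),
            ]
        )
        assert len(pairs) == 2
        kept = deduplicate_pairs(pairs)
        assert len(kept) == 1
        assert kept[0].plus_gene.gene_symbol == "pA"

    def test_distinct_intergenic_both_kept(self):
        pairs = classify_bidirectional(
            [
                make_cluster("chr1", "-", 6_000, 10_000, "m1"),
                make_cluster("chr1", "+", 10_500, 14_000, "p1"),
                make_cluster("chr1", "-", 46_000, 50_000, "m2"),
                make_cluster("chr1", "+", 50_501, 54_000, "p2"),
            ]
        )
        assert len(deduplicate_pairs(pairs)) == 2

    def test_empty(self):
        assert deduplicate_pairs([]) == []


def test_pipeline_determinism_same_table_same_pairs(tmp_path):
    from bidipromoter.io_formats import read_gene_table, write_gene_table

    records = [
        TranscriptRecord("NM_1", "m", "chr1", "-", 6_000, 10_000),
        TranscriptRecord("NM_2", "p", "chr1", "+", 10_400, 14_000),
        TranscriptRecord("NM_3", "u", "chr2", "+", 50_000, 55_000),
    ]
    path = tmp_path / "g.tsv"
    write_gene_table(records, path)

    def run():
        clusters = collapse_clusters(read_gene_table(path))
        pairs = deduplicate_pairs(classify_bidirectional(clusters))
        return [(p.pair_id, p.chromosome, p.intergenic) for p in pairs]

    assert run() == run() == [("BP00001", "chr1", (10_000, 10_400))]
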