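"""Classify head-to-head gene pairs and uni-directional genes.

Builds a small transcript table in memory, collapses it into strand-specific
clusters, and applies the divergent-pair (< 1 kb TSS distance) and
uni-directional (10 kb opposite-strand / 1 kb same-strand isolation) rules.
"""

from bidipromoter import (
    TranscriptRecord,
    classify_bidirectional,
    classify_unidirectional,
    collapse_clusters,
    deduplicate_pairs,
    filter_evidence,
)

transcripts = [
    # a divergent pair: TSSs at 100 000 (minus) and 100 400 (plus)
    TranscriptRecord("NM_001", "MRPS12", "chr1", "-", 96_000, 100_000),
    TranscriptRecord("NM_002", "SARS2", "chr1", "+", 100_400, 104_000),
    # an isolated gene 60 kb away
    TranscriptRecord("NM_003", "LONELY", "chr1", "+", 160_000, 165_000),
    # a predicted model that the evidence filter removes
    TranscriptRecord("XM_004", "GUESS", "chr1", "+", 300_000, 305_000),
]

clusters = filter_evidence(collapse_clusters(transcripts), mode="curated-mRNA")
pairs = deduplicate_pairs(classify_bidirectional(clusters))
uni = classify_unidirectional(clusters)

for pair in pairs:
    print(
        f"pair {pair.minus_gene.gene_symbol} <-> {pair.plus_gene.gene_symbol}: "
        f"TSS distance {pair.tss_distance} bp, "
        f"intergenic promoter {pair.chromosome}:{pair.intergenic[0]}-{pair.intergenic[1]}"
    )
print("uni-directional genes:", [c.gene_symbol for c in uni])
# The 400 bp between the two facing TSSs is the putative bidirectional
# promoter; LONELY qualifies as uni-directional because nothing transcribes
# within 10 kb upstream of its TSS.
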