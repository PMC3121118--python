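"""Transcript clustering and bidirectional / uni-directional classification.

Transcripts are collapsed into strand-specific non-overlapping clusters, each
with a single representative TSS (the 5'-most among members). A bidirectional
(head-to-head, divergent) gene pair is two adjacent clusters on opposite
strands whose TSSs face each other less than ``max_distance`` bp apart
(default 1 kb); the intervening interval is the putative bidirectional
promoter. A cluster is uni-directional when no opposite-strand TSS lies
within 10 kb upstream of its TSS and no same-strand TSS lies within 1 kb
upstream, so that its full 1 kb of 5' flanking DNA is an unshared promoter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import EVIDENCE_RANK, TranscriptRecord

logger = logging.getLogger(__name__)

EVIDENCE_MODES = ("all", "curated", "curated-mRNA")


@dataclass(frozen=True)
class GeneCluster:
    """A strand-specific non-overlapping transcript cluster."""

    cluster_id: str
    gene_symbol: str
    chromosome: str
    strand: str
    start: int  # span, 0-based half-open
    end: int
    tss: int
    members: tuple[str, ...]
    evidence_class: str

    def __post_init__(self) -> None:
        expected = self.start if self.strand == "+" else self.end
        if self.tss != expected:
            raise ValueError(
                f"cluster {self.cluster_id}: TSS {self.tss} is not the 5'-most "
                f"position of span [{self.start}, {self.end}) on {self.strand}"
            )


@dataclass(frozen=True)
class GenePair:
    """Two divergent adjacent clusters with their TSS distance."""

    pair_id: str
    plus_gene: GeneCluster
    minus_gene: GeneCluster

    def __post_init__(self) -> None:
        if self.plus_gene.strand != "+" or self.minus_gene.strand != "-":
            raise ValueError(f"pair {self.pair_id}: strands must be (+, -)")
        if self.plus_gene.chromosome != self.minus_gene.chromosome:
            raise ValueError(f"pair {self.pair_id}: clusters on different chromosomes")
        if self.minus_gene.tss > self.plus_gene.tss:
            raise ValueError(
                f"pair {self.pair_id}: not divergent "
                f"(minus TSS {self.minus_gene.tss} > plus TSS {self.plus_gene.tss})"
            )

    @property
    def chromosome(self) -> str:
        return self.plus_gene.chromosome

    @property
    def tss_distance(self) -> int:
        return self.plus_gene.tss - self.minus_gene.tss

    @property
    def intergenic(self) -> tuple[int, int]:
        """The interval [minus TSS, plus TSS): the putative promoter."""
        return (self.minus_gene.tss, self.plus_gene.tss)


def tss_of(record) -> int:
    """5'-most coordinate of a transcript or cluster span.

    Under the half-open convention this is the span start on '+' and the
    span end (one past the last base) on '-'.
    """
    strand = record.strand
    if strand == "+":
        return record.tx_start if isinstance(record, TranscriptRecord) else record.start
    if strand == "-":
        return record.tx_end if isinstance(record, TranscriptRecord) else record.end
    raise ValueError(f"invalid strand {strand!r}")


def collapse_clusters(records: Sequence[TranscriptRecord]) -> list[GeneCluster]:
    """Merge overlapping or abutting transcripts per (chromosome, strand).

    Merging is transitive; the cluster span is the union hull, its TSS the
    5'-most member TSS, and its gene symbol comes from the member whose TSS
    equals the cluster TSS (ties broken by lexicographic accession). The
    evidence class is the best among members. Output is sorted by
    (chromosome, span start).
    """
    by_group: dict[tuple[str, str], list[TranscriptRecord]] = {}
    for record in records:
        by_group.setdefault((record.chromosome, record.strand), []).append(record)

    clusters: list[GeneCluster] = []
    for (chrom, strand), group in by_group.items():
        group = sorted(group, key=lambda r: (r.tx_start, r.tx_end, r.accession))
        current: list[TranscriptRecord] = []
        current_end = -1
        for record in group:
            if current and record.tx_start > current_end:
                clusters.append(_build_cluster(chrom, strand, current))
                current = []
            current.append(record)
            current_end = max(current_end, record.tx_end)
        if current:
            clusters.append(_build_cluster(chrom, strand, current))

    clusters.sort(key=lambda c: (c.chromosome, c.start, c.strand))
    return clusters


def _build_cluster(chrom: str, strand: str, members: list[TranscriptRecord]) -> GeneCluster:
    start = min(r.tx_start for r in members)
    end = max(r.tx_end for r in members)
    tss = start if strand == "+" else end
    at_tss = sorted(
        (r for r in members if tss_of(r) == tss), key=lambda r: r.accession
    )
    symbol = at_tss[0].gene_symbol
    evidence = min((r.evidence_class for r in members), key=EVIDENCE_RANK.__getitem__)
    return GeneCluster(
        cluster_id=f"{chrom}:{start}-{end}:{strand}",
        gene_symbol=symbol,
        chromosome=chrom,
        strand=strand,
        start=start,
        end=end,
        tss=tss,
        members=tuple(sorted(r.accession for r in members)),
        evidence_class=evidence,
    )


def filter_evidence(
    clusters: Iterable[GeneCluster], mode: str = "curated-mRNA"
) -> list[GeneCluster]:
    """Filter clusters by evidence class.

    ``all`` keeps everything except predicted (XM/XR models are always
    excluded, lacking conclusive transcription evidence); ``curated`` keeps
    curated mRNA plus curated non-coding (NM + NR); ``curated-mRNA`` keeps
    conclusive mRNAs only (NM), the paper-style analysis set.
    """
    if mode not in EVIDENCE_MODES:
        raise ValueError(f"unknown evidence mode {mode!r}; pick one of {EVIDENCE_MODES}")
    if mode == "all":
        keep = {"curated-mRNA", "curated-noncoding", "other"}
    elif mode == "curated":
        keep = {"curated-mRNA", "curated-noncoding"}
    else:
        keep = {"curated-mRNA"}
    return [c for c in clusters if c.evidence_class in keep]


def classify_bidirectional(
    clusters: Sequence[GeneCluster], max_distance: int = 1000
) -> list[GenePair]:
    """Find divergent head-to-head pairs with TSS distance in [0, max_distance).

    Clusters are ranked by (chromosome, TSS); a pair is emitted for every two
    TSS-adjacent clusters (no third TSS strictly between) on opposite strands
    with the minus-strand TSS at or upstream of the plus-strand TSS. The
    ``< max_distance`` bound is strict.
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be positive")
    ranked = sorted(clusters, key=lambda c: (c.chromosome, c.tss, c.strand, c.start))
    pairs: list[GenePair] = []
    for left, right in zip(ranked, ranked[1:]):
        if left.chromosome != right.chromosome:
            continue
        if left.strand == right.strand:
            continue
        minus, plus = (left, right) if left.strand == "-" else (right, left)
        if minus.tss > plus.tss:
            continue  # convergent: 5' ends face away from each other
        distance = plus.tss - minus.tss
        if distance < max_distance:
            pairs.append(
                GenePair(
                    pair_id=f"BP{len(pairs) + 1:05d}",
                    plus_gene=plus,
                    minus_gene=minus,
                )
            )
    return pairs


def classify_unidirectional(
    clusters: Sequence[GeneCluster],
    opposite_window: int = 10_000,
    same_window: int = 1_000,
) -> list[GeneCluster]:
    """Return clusters with an unshared upstream promoter.

    A cluster is uni-directional iff (a) no opposite-strand TSS lies within
    ``opposite_window`` bp upstream of its TSS (distance 0 <= d <= window;
    upstream means lower coordinates on '+', higher on '-') and (b) no
    same-strand TSS lies within ``same_window`` bp upstream (0 < d <= window).
    A coincident opposite-strand TSS (d = 0, a distance-0 head-to-head pair)
    counts as within the window, keeping the pair and uni-directional sets
    disjoint at gene level.
    """
    by_chrom: dict[str, list[GeneCluster]] = {}
    for cluster in clusters:
        by_chrom.setdefault(cluster.chromosome, []).append(cluster)

    result: list[GeneCluster] = []
    for cluster in clusters:
        neighbours = by_chrom[cluster.chromosome]
        if _is_unidirectional(cluster, neighbours, opposite_window, same_window):
            result.append(cluster)
    result.sort(key=lambda c: (c.chromosome, c.start, c.strand))
    return result


def _is_unidirectional(
    cluster: GeneCluster,
    neighbours: Sequence[GeneCluster],
    opposite_window: int,
    same_window: int,
) -> bool:
    tss = cluster.tss
    for other in neighbours:
        if other is cluster:
            continue
        # upstream distance from this cluster's TSS to the other TSS
        d = tss - other.tss if cluster.strand == "+" else other.tss - tss
        if d < 0:
            continue  # downstream
        if other.strand != cluster.strand:
            if d <= opposite_window:
                return False
        else:
            if 0 < d <= same_window:
                return False
    return True


def deduplicate_pairs(pairs: Sequence[GenePair]) -> list[GenePair]:
    """Drop redundant pairs sharing the same intergenic sequence.

    Among pairs with identical (chromosome, intergenic interval), the one
    with lexicographically smallest (plus symbol, minus symbol) is kept;
    order is otherwise preserved.
    """
    best: dict[tuple[str, int, int], GenePair] = {}
    for pair in pairs:
        key = (pair.chromosome, *pair.intergenic)
        incumbent = best.get(key)
        if incumbent is None or (
            (pair.plus_gene.gene_symbol, pair.minus_gene.gene_symbol)
            < (incumbent.plus_gene.gene_symbol, incumbent.minus_gene.gene_symbol)
        ):
            best[key] = pair
    kept = set(map(id, best.values()))
    return [p for p in pairs if id(p) in kept]
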