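"""Promoter interval derivation and sequence fetching.

The bidirectional promoter of a head-to-head pair is the entire intergenic
interval between the two TSSs; when shorter than the minimum CpG-island
length it can be extended symmetrically to that length. The uni-directional
promoter is the fixed 1 kb immediately upstream of an isolated gene's TSS.
Sequences are always taken from the forward genome strand: GC% and CpG
observed/expected are strand-symmetric, and motif scanning covers both
strands itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .io_formats import GenomeSequence
from .pair_classification import GeneCluster, GenePair

logger = logging.getLogger(__name__)


class DegenerateRegionError(ValueError):
    """A pair with TSS distance 0 has an empty intergenic interval."""


@dataclass(frozen=True)
class PromoterRegion:
    """A promoter interval, optionally carrying its fetched sequence."""

    region_id: str
    source: str  # pair id or cluster id
    chromosome: str
    start: int  # 0-based half-open
    end: int
    kind: str  # "bidirectional" | "unidirectional"
    extended: bool = False
    truncated: bool = False
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError(
                f"region {self.region_id}: interval [{self.start}, {self.end}) "
                f"must have length >= 1"
            )
        if self.kind not in ("bidirectional", "unidirectional"):
            raise ValueError(f"region {self.region_id}: unknown kind {self.kind!r}")
        if self.sequence is not None and len(self.sequence) != len(self):
            raise ValueError(
                f"region {self.region_id}: sequence length {len(self.sequence)} "
                f"!= interval length {len(self)}"
            )

    def __len__(self) -> int:
        return self.end - self.start


def bidirectional_promoter(pair: GenePair) -> PromoterRegion:
    """The intergenic interval [minus TSS, plus TSS) of a divergent pair."""
    if pair.tss_distance == 0:
        raise DegenerateRegionError(
            f"pair {pair.pair_id} has TSS distance 0: empty intergenic region"
        )
    start, end = pair.intergenic
    return PromoterRegion(
        region_id=pair.pair_id,
        source=pair.pair_id,
        chromosome=pair.chromosome,
        start=start,
        end=end,
        kind="bidirectional",
    )


def extend_symmetric(
    region: PromoterRegion, chromosome_length: int, min_length: int = 1000
) -> PromoterRegion:
    """Pad a short bidirectional promoter on both sides to ``min_length``.

    Odd deficits put the extra base on the left. Padding never crosses
    chromosome bounds: a clamped side's shortfall shifts to the other side
    when possible; a chromosome shorter than ``min_length`` yields the whole
    chromosome with a warning. Idempotent on regions already long enough.
    """
    if region.kind != "bidirectional":
        raise ValueError("extend_symmetric applies to bidirectional promoters only")
    length = len(region)
    if length >= min_length:
        return region
    if chromosome_length < min_length:
        logger.warning(
            "chromosome of length %d shorter than min promoter length %d; "
            "region %s extends over the whole chromosome",
            chromosome_length,
            min_length,
            region.region_id,
        )
        return replace(region, start=0, end=chromosome_length, extended=True)
    deficit = min_length - length
    left = (deficit + 1) // 2
    right = deficit // 2
    start = region.start - left
    end = region.end + right
    if start < 0:
        end += -start
        start = 0
    if end > chromosome_length:
        start -= end - chromosome_length
        end = chromosome_length
        start = max(start, 0)
    return replace(region, start=start, end=end, extended=True)


def unidirectional_promoter(
    gene: GeneCluster, chromosome_length: int, length: int = 1000
) -> PromoterRegion:
    """The fixed ``length`` bp upstream of a uni-directional gene's TSS.

    '+' strand: [TSS - length, TSS); '-' strand: [TSS, TSS + length).
    Truncation at a chromosome end is flagged.
    """
    if gene.strand == "+":
        start, end = gene.tss - length, gene.tss
    else:
        start, end = gene.tss, gene.tss + length
    truncated = False
    if start < 0:
        start, truncated = 0, True
    if end > chromosome_length:
        end, truncated = chromosome_length, True
    if end - start < 1:
        raise ValueError(
            f"gene {gene.cluster_id}: upstream promoter falls entirely "
            f"outside the chromosome"
        )
    return PromoterRegion(
        region_id=f"UP_{gene.cluster_id}",
        source=gene.cluster_id,
        chromosome=gene.chromosome,
        start=start,
        end=end,
        kind="unidirectional",
        truncated=truncated,
    )


def fetch_sequences(
    regions: Iterable[PromoterRegion], genome: GenomeSequence
) -> list[PromoterRegion]:
    """Attach forward-strand genome sequence to each region.

    Intervals must already lie within chromosome bounds (clamping is the
    responsibility of the extraction step); violations raise.
    """
    fetched = []
    for region in regions:
        seq = genome.fetch(region.chromosome, region.start, region.end)
        fetched.append(replace(region, sequence=seq))
    return fetched
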