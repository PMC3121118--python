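"""PWM scanning of promoters and 2-fold motif enrichment classification.

Count matrices are converted to log-odds scores against a background base
distribution with a pseudocount split by background. Every offset of a
promoter is scored on both strands; offsets scoring at or above a threshold
(a fraction of the min-max score range, default 0.8) are hits. Hit counts
are normalised to hits per kilobase of total promoter sequence in each
class, and each motif's bidirectional/uni-directional rate ratio is
classified at a 2-fold threshold: fold >= 2 over-represented, fold <= 0.5
under-represented, otherwise shared.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import BASES, PositionWeightMatrix
from .promoter_extraction import PromoterRegion

logger = logging.getLogger(__name__)

UNIFORM_BACKGROUND = {b: 0.25 for b in BASES}

_CODE_TABLE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE_TABLE[ord(_b)] = _i
    _CODE_TABLE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class LogOddsMatrix:
    """Log2-odds scores of a PWM against a background distribution."""

    motif_id: str
    name: str
    scores: np.ndarray = field(repr=False)  # shape (4, width)
    max_score: float = 0.0
    min_score: float = 0.0

    @property
    def width(self) -> int:
        return self.scores.shape[1]


@dataclass(frozen=True)
class MotifHit:
    """A scoring window; offset is 0-based on the forward region sequence."""

    motif_id: str
    region_id: str
    strand: str  # relative to the stored promoter sequence
    offset: int
    score: float


@dataclass(frozen=True)
class FoldResult:
    fold: float  # may be inf; nan marks the both-zero case
    category: str  # over-represented | shared | under-represented
    both_zero: bool = False


@dataclass(frozen=True)
class MotifEnrichmentRecord:
    motif_id: str
    name: str
    bidir_rate: float  # hits per kb
    uni_rate: float
    fold: float
    category: str
    both_zero: bool = False
    too_wide: bool = False


def pwm_to_log_odds(
    pwm: PositionWeightMatrix,
    background: Mapping[str, float] | None = None,
    pseudocount: float = 0.8,
) -> LogOddsMatrix:
    """Convert counts to log2-odds with a background-split pseudocount.

    score(b, j) = log2((count(b,j) + pc*bg(b)) / (colsum(j) + pc) / bg(b)).
    """
    background = dict(background or UNIFORM_BACKGROUND)
    bg = np.array([background[b] for b in BASES], dtype=float)
    if np.any(bg <= 0) or not math.isclose(bg.sum(), 1.0, rel_tol=1e-6):
        raise ValueError("background frequencies must be positive and sum to 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    counts = pwm.counts
    colsums = counts.sum(axis=0)
    if pseudocount == 0 and np.any(colsums == 0):
        raise ValueError(
            f"motif {pwm.motif_id}: zero column sum requires a positive pseudocount"
        )
    probs = (counts + pseudocount * bg[:, None]) / (colsums + pseudocount)[None, :]
    scores = np.log2(probs / bg[:, None])
    return LogOddsMatrix(
        motif_id=pwm.motif_id,
        name=pwm.name,
        scores=scores,
        max_score=float(scores.max(axis=0).sum()),
        min_score=float(scores.min(axis=0).sum()),
    )


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to codes A=0 C=1 G=2 T=3; N (or anything else) = -1."""
    return _CODE_TABLE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _strand_scores(codes: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Window score at every offset; windows touching N score -inf.

    Accumulates column by column so each window's score is the same
    left-to-right IEEE sum a naive per-offset scorer produces.
    """
    width = scores.shape[1]
    n_offsets = len(codes) - width + 1
    if n_offsets <= 0:
        return np.empty(0)
    total = np.zeros(n_offsets)
    valid = np.ones(n_offsets, dtype=bool)
    for j in range(width):
        column = codes[j : j + n_offsets]
        valid &= column >= 0
        total += scores[np.where(column >= 0, column, 0), j]
    return np.where(valid, total, -np.inf)


def scan_region(
    sequence: str,
    matrix: LogOddsMatrix,
    threshold_fraction: float = 0.8,
    region_id: str = "",
) -> list[MotifHit]:
    """All hits of a motif on both strands of a region sequence.

    The absolute threshold is min + threshold_fraction * (max - min); windows
    scoring >= it are hits. Reverse-complement hits are reported with strand
    '-' and their offset mapped back to forward coordinates. Hits are sorted
    by offset then strand.
    """
    if not (0 < threshold_fraction <= 1):
        raise ValueError("threshold_fraction must be in (0, 1]")
    width = matrix.width
    length = len(sequence)
    if length < width:
        return []
    threshold = matrix.min_score + threshold_fraction * (
        matrix.max_score - matrix.min_score
    )
    codes = encode_sequence(sequence)
    rc_codes = np.where(codes[::-1] >= 0, 3 - codes[::-1], -1)

    hits: list[MotifHit] = []
    forward = _strand_scores(codes, matrix.scores)
    for offset in np.nonzero(forward >= threshold)[0]:
        hits.append(
            MotifHit(matrix.motif_id, region_id, "+", int(offset), float(forward[offset]))
        )
    reverse = _strand_scores(rc_codes, matrix.scores)
    for rc_offset in np.nonzero(reverse >= threshold)[0]:
        offset = length - int(rc_offset) - width
        hits.append(
            MotifHit(matrix.motif_id, region_id, "-", offset, float(reverse[rc_offset]))
        )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def normalized_count(hits: Sequence[MotifHit], regions: Sequence[PromoterRegion]) -> float:
    """Total hits per kilobase of total region sequence."""
    if not regions:
        raise ValueError("normalized_count over an empty region set")
    total_bp = sum(len(r) for r in regions)
    if total_bp == 0:
        raise ValueError("normalized_count over zero total sequence length")
    return len(hits) / (total_bp / 1000)


def classify_fold(bidir_rate: float, uni_rate: float, threshold: float = 2.0) -> FoldResult:
    """Over/shared/under classification of a bidir/uni rate ratio.

    Boundaries are inclusive: fold exactly ``threshold`` is over-represented
    and exactly ``1/threshold`` under-represented. A motif absent from both
    classes is reported as shared with the both_zero flag rather than dropped.
    """
    if bidir_rate < 0 or uni_rate < 0:
        raise ValueError("rates must be non-negative")
    if threshold <= 1:
        raise ValueError("fold threshold must exceed 1")
    if bidir_rate == 0 and uni_rate == 0:
        return FoldResult(fold=math.nan, category="shared", both_zero=True)
    if uni_rate == 0:
        return FoldResult(fold=math.inf, category="over-represented")
    fold = bidir_rate / uni_rate
    if fold >= threshold:
        category = "over-represented"
    elif fold <= 1 / threshold:
        category = "under-represented"
    else:
        category = "shared"
    return FoldResult(fold=fold, category=category)


def enrichment_table(
    bidir_regions: Sequence[PromoterRegion],
    uni_regions: Sequence[PromoterRegion],
    pwms: Sequence[PositionWeightMatrix],
    threshold_fraction: float = 0.8,
    fold_threshold: float = 2.0,
    background: Mapping[str, float] | None = None,
    pseudocount: float = 0.8,
) -> list[MotifEnrichmentRecord]:
    """Per-motif normalised hit rates in both promoter classes and the
    fold category, sorted by fold descending (ties by motif id)."""
    if not bidir_regions or not uni_regions:
        raise ValueError("both promoter sets must be non-empty")
    for region in list(bidir_regions) + list(uni_regions):
        if region.sequence is None:
            raise ValueError(f"region {region.region_id} has no fetched sequence")

    records: list[MotifEnrichmentRecord] = []
    for pwm in pwms:
        matrix = pwm_to_log_odds(pwm, background=background, pseudocount=pseudocount)
        too_wide = all(len(r) < pwm.width for r in bidir_regions) and all(
            len(r) < pwm.width for r in uni_regions
        )
        if too_wide:
            logger.warning(
                "motif %s (width %d) is wider than every promoter", pwm.motif_id, pwm.width
            )
        rates = []
        for regions in (bidir_regions, uni_regions):
            hits: list[MotifHit] = []
            for region in regions:
                hits.extend(
                    scan_region(
                        region.sequence, matrix, threshold_fraction, region.region_id
                    )
                )
            rates.append(normalized_count(hits, regions))
        result = classify_fold(rates[0], rates[1], fold_threshold)
        records.append(
            MotifEnrichmentRecord(
                motif_id=pwm.motif_id,
                name=pwm.name,
                bidir_rate=rates[0],
                uni_rate=rates[1],
                fold=result.fold,
                category=result.category,
                both_zero=result.both_zero,
                too_wide=too_wide,
            )
        )

    def sort_key(r: MotifEnrichmentRecord):
        # inf folds first, NaN (both-zero) last
        fold = -1.0 if math.isnan(r.fold) else r.fold
        return (-fold, r.motif_id)

    records.sort(key=sort_key)
    return records


def overlap_over_represented(
    records_a: Iterable[MotifEnrichmentRecord],
    records_b: Iterable[MotifEnrichmentRecord],
) -> set[str]:
    """Motif names over-represented in both collections (case-insensitive)."""
    over_a = {r.name.lower() for r in records_a if r.category == "over-represented"}
    over_b = {r.name.lower() for r in records_b if r.category == "over-represented"}
    return over_a & over_b
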