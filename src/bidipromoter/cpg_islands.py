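"""CpG island detection and promoter-class composition comparison.

Two named criteria sets are provided: the traditional Gardiner-Garden
thresholds (GC >= 50%, CpG Obs/Exp >= 0.60 over >= 500 bp) and a strict
variant (GC >= 55%). CpG Obs/Exp follows the Gardiner-Garden definition
(#CpG x L) / (#C x #G) with L the number of unambiguous bases. N bases are
excluded from all base counts and break CpG dinucleotides.

The island finder marks every window of length >= min_length satisfying
both thresholds, merges overlapping or abutting marked windows into
candidate regions, verifies each merged candidate as a whole (trimming
1 bp at a time from whichever end most improves the failing statistic
until it qualifies or drops below min_length), and reports the maximal
disjoint qualifying regions left to right.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CpGCriteria:
    name: str
    min_gc: float
    min_obs_exp: float
    min_length: int

    def __post_init__(self) -> None:
        if not (0 < self.min_gc <= 1):
            raise ValueError("min_gc must be in (0, 1]")
        if self.min_obs_exp <= 0:
            raise ValueError("min_obs_exp must be positive")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


GARDINER_GARDEN = CpGCriteria("gardiner_garden", 0.50, 0.60, 500)
STRICT = CpGCriteria("strict", 0.55, 0.60, 500)
CRITERIA_PRESETS = {c.name: c for c in (GARDINER_GARDEN, STRICT)}


@dataclass(frozen=True)
class CpGIsland:
    """A qualifying sub-interval of a promoter (local 0-based half-open)."""

    region_id: str
    start: int
    end: int
    gc: float
    obs_exp: float
    criteria: str

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def chromosome(self) -> str:  # for BED output of local coordinates
        return self.region_id


@dataclass(frozen=True)
class CpGSummary:
    """Per-promoter-class CpG island statistics."""

    n_promoters: int
    n_with_island: int
    fraction_with_island: float | None
    islands_per_kb: float | None
    islands_per_promoter: float | None
    mean_gc: float | None


def gc_content(seq: str) -> float:
    """(#C + #G) / (#A + #C + #G + #T); N excluded from both counts."""
    if not seq:
        raise ValueError("gc_content of empty sequence")
    seq = seq.upper()
    gc = seq.count("C") + seq.count("G")
    valid = len(seq) - seq.count("N")
    if valid == 0:
        logger.warning("all-N sequence; GC content reported as 0")
        return 0.0
    return gc / valid


def cpg_obs_exp(seq: str) -> float:
    """Gardiner-Garden CpG observed/expected: (#CpG x L) / (#C x #G).

    L excludes N bases; overlapping "CG" occurrences are counted on the
    forward sequence (an N between C and G breaks the dinucleotide). When
    #C or #G is zero the expected count is zero and the ratio is defined
    as 0 rather than a division error.
    """
    if not seq:
        raise ValueError("cpg_obs_exp of empty sequence")
    seq = seq.upper()
    n_c = seq.count("C")
    n_g = seq.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    n_cg = seq.count("CG")
    length = len(seq) - seq.count("N")
    return n_cg * length / (n_c * n_g)


def _prefix_counts(seq: str) -> dict[str, np.ndarray]:
    """Cumulative counts used by the sliding-window search (exact integers)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_n = arr == ord("N")
    is_cg = np.zeros(len(arr), dtype=bool)
    if len(arr) > 1:
        is_cg[:-1] = is_c[:-1] & is_g[1:]

    def prefix(mask: np.ndarray) -> np.ndarray:
        out = np.zeros(len(arr) + 1, dtype=np.int64)
        np.cumsum(mask, out=out[1:])
        return out

    return {"C": prefix(is_c), "G": prefix(is_g), "N": prefix(is_n), "CG": prefix(is_cg)}


def _window_stats(p: Mapping[str, np.ndarray], start: int, end: int) -> tuple[float, float]:
    """(gc, obs_exp) of [start, end), identical to the direct computation."""
    n_c = int(p["C"][end] - p["C"][start])
    n_g = int(p["G"][end] - p["G"][start])
    valid = (end - start) - int(p["N"][end] - p["N"][start])
    # CG pairs fully inside the window start at positions [start, end - 1)
    n_cg = int(p["CG"][end - 1] - p["CG"][start]) if end - start > 1 else 0
    gc = (n_c + n_g) / valid if valid > 0 else 0.0
    oe = n_cg * valid / (n_c * n_g) if n_c > 0 and n_g > 0 else 0.0
    return gc, oe


def find_cpg_islands(
    seq: str, criteria: CpGCriteria, region_id: str = ""
) -> list[CpGIsland]:
    """Locate maximal disjoint CpG islands in a sequence under one criteria set."""
    length = len(seq)
    min_len = criteria.min_length
    if length < min_len:
        return []
    p = _prefix_counts(seq)

    # Step 1: union of all qualifying windows of length >= min_length.
    # For each start, qualifying ends are found vectorised; the union over
    # ends of [s, e) is [s, max qualifying e).
    c, g, n, cg = p["C"], p["G"], p["N"], p["CG"]
    covered: list[tuple[int, int]] = []
    for s in range(0, length - min_len + 1):
        ends = np.arange(s + min_len, length + 1)
        n_c = c[ends] - c[s]
        n_g = g[ends] - g[s]
        valid = (ends - s) - (n[ends] - n[s])
        n_cg = cg[ends - 1] - cg[s]
        with np.errstate(divide="ignore", invalid="ignore"):
            gc_ok = np.where(valid > 0, (n_c + n_g) / np.maximum(valid, 1), 0.0)
            oe_ok = np.where(
                (n_c > 0) & (n_g > 0),
                n_cg * valid / np.maximum(n_c * n_g, 1),
                0.0,
            )
        ok = (gc_ok >= criteria.min_gc) & (oe_ok >= criteria.min_obs_exp)
        if ok.any():
            covered.append((s, int(ends[np.nonzero(ok)[0][-1]])))

    # Step 2: merge overlapping or abutting marked intervals.
    merged: list[list[int]] = []
    for s, e in covered:  # starts are increasing
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    # Step 3: verify each merged candidate as a whole; trim if needed.
    islands: list[CpGIsland] = []
    for a, b in merged:
        result = _verify_and_trim(p, a, b, criteria)
        if result is not None:
            a2, b2 = result
            gc, oe = _window_stats(p, a2, b2)
            islands.append(
                CpGIsland(
                    region_id=region_id,
                    start=a2,
                    end=b2,
                    gc=gc,
                    obs_exp=oe,
                    criteria=criteria.name,
                )
            )
    return islands


def _verify_and_trim(
    p: Mapping[str, np.ndarray], a: int, b: int, criteria: CpGCriteria
) -> tuple[int, int] | None:
    """Trim 1 bp at a time from the end that most improves the failing
    statistic until the region qualifies or drops below min_length."""
    while b - a >= criteria.min_length:
        gc, oe = _window_stats(p, a, b)
        if gc >= criteria.min_gc and oe >= criteria.min_obs_exp:
            return a, b
        # the failing statistic drives the trim choice; GC takes precedence
        stat_index = 0 if gc < criteria.min_gc else 1
        left_stats = _window_stats(p, a + 1, b)
        right_stats = _window_stats(p, a, b - 1)
        if left_stats[stat_index] >= right_stats[stat_index]:
            a += 1  # ties trim the left end (fixed for determinism)
        else:
            b -= 1
    return None


def summarize_class(
    regions_with_islands: Sequence[tuple[object, Sequence[CpGIsland]]],
) -> CpGSummary:
    """Summary statistics over one promoter class.

    Each item pairs a promoter region (with a fetched sequence) with the
    islands found in it. Fractions over an empty class are reported as None
    rather than 0.
    """
    n = len(regions_with_islands)
    if n == 0:
        return CpGSummary(0, 0, None, None, None, None)
    n_with = sum(1 for _, islands in regions_with_islands if islands)
    total_islands = sum(len(islands) for _, islands in regions_with_islands)
    total_bp = sum(len(region.sequence) for region, _ in regions_with_islands)
    mean_gc = float(
        np.mean([gc_content(region.sequence) for region, _ in regions_with_islands])
    )
    return CpGSummary(
        n_promoters=n,
        n_with_island=n_with,
        fraction_with_island=n_with / n,
        islands_per_kb=total_islands / (total_bp / 1000) if total_bp else None,
        islands_per_promoter=total_islands / n,
        mean_gc=mean_gc,
    )


def summarize_by_class(
    bidirectional: Sequence[tuple[object, Sequence[CpGIsland]]],
    unidirectional: Sequence[tuple[object, Sequence[CpGIsland]]],
) -> dict:
    """Per-class summaries plus between-class differences (bidir - uni)."""
    bidir = summarize_class(bidirectional)
    uni = summarize_class(unidirectional)

    def diff(x: float | None, y: float | None) -> float | None:
        return None if x is None or y is None else x - y

    return {
        "bidirectional": bidir,
        "unidirectional": uni,
        "differences": {
            "fraction_with_island": diff(
                bidir.fraction_with_island, uni.fraction_with_island
            ),
            "islands_per_kb": diff(bidir.islands_per_kb, uni.islands_per_kb),
            "islands_per_promoter": diff(
                bidir.islands_per_promoter, uni.islands_per_promoter
            ),
            "mean_gc": diff(bidir.mean_gc, uni.mean_gc),
        },
    }


def islands_by_region(
    regions: Iterable, criteria: CpGCriteria
) -> list[tuple[object, list[CpGIsland]]]:
    """Run the island finder over fetched promoter regions."""
    out = []
    for region in regions:
        if region.sequence is None:
            raise ValueError(f"region {region.region_id} has no fetched sequence")
        out.append(
            (region, find_cpg_islands(region.sequence, criteria, region.region_id))
        )
    return out
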