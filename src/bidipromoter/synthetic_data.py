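"""Seeded synthetic genomes, gene tables, ontologies and PWM collections.

The generator emulates the statistical structure the pipeline is built to
detect, with every planted feature recorded in a ground-truth manifest:

* genes laid out in divergent (head-to-head) pairs and isolated
  uni-directional placements, spaced so the planted classes are exactly
  recoverable by the classification rules;
* promoter sequences drawn from a first-order (dinucleotide) Markov sampler
  whose GC fraction and CpG observed/expected ratio are controlled
  independently — bidirectional promoters CpG-island-like (GC 0.60,
  Obs/Exp 0.9), uni-directional promoters CpG-poor (GC 0.45, Obs/Exp 0.3)
  against a neutral background (GC 0.40, Obs/Exp 0.5);
* motif consensus strings planted at class-dependent Poisson rates into the
  (extension-adjusted) promoter intervals, overwriting background bases so
  manifest coordinates are exact;
* a three-namespace ontology whose paired genes share a direct term with a
  controlled probability p_share.

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    BASES,
    GeneAnnotationSet,
    GenomeSequence,
    OntologyGraph,
    OntologyTerm,
    PositionWeightMatrix,
    TranscriptRecord,
    NAMESPACES,
    write_annotations,
    write_fasta,
    write_gene_table,
    write_obo,
    write_pwm_jaspar,
    write_pwm_transfac,
)

_DEFAULT_RATES_BIDIR = {"SYNM_A": 7.5, "SYNM_B": 5.0, "SYNM_C": 1.5}
_DEFAULT_RATES_UNI = {"SYNM_A": 1.5, "SYNM_B": 5.0, "SYNM_C": 7.5}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the standard conditions.

    Motif rates are expected insertions per kilobase of promoter sequence
    per class; SYNM_A is enriched 5x in bidirectional promoters, SYNM_B is
    planted at equal rates, SYNM_C mirrors SYNM_A (5x in uni-directional).
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 500_000
    n_genes: int = 60
    fraction_bidirectional: float = 0.5
    tss_gap_range: tuple[int, int] = (100, 900)
    gene_body_range: tuple[int, int] = (2_000, 4_000)
    min_gene_spacing: int = 12_000
    background_gc: float = 0.40
    background_obs_exp: float = 0.50
    bidir_gc: float = 0.60
    bidir_obs_exp: float = 0.90
    uni_gc: float = 0.45
    uni_obs_exp: float = 0.30
    promoter_length: int = 1_000
    motif_width: int = 10
    motif_rates_bidir: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_RATES_BIDIR)
    )
    motif_rates_uni: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_RATES_UNI)
    )
    ontology_terms_per_namespace: int = 40
    ontology_depth: int = 4
    n_ontology_pairs: int = 400
    p_share: float = 0.5
    terms_per_gene: tuple[int, int] = (2, 4)

    def __post_init__(self) -> None:
        for name in ("fraction_bidirectional", "p_share"):
            value = getattr(self, name)
            if not (0 <= value <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        lo, hi = self.tss_gap_range
        if not (0 < lo <= hi < 1000):
            raise ValueError(
                "tss_gap_range must lie within (0, 1000) so planted pairs "
                "satisfy the bidirectional classification rule"
            )
        if self.min_gene_spacing <= 10_000:
            raise ValueError(
                "min_gene_spacing must exceed 10 kb so planted uni-directional "
                "genes satisfy the opposite-strand isolation rule"
            )
        if not (6 <= self.motif_width <= 15):
            raise ValueError("motif_width must be in [6, 15]")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


# ---------------------------------------------------------------------------
# Dinucleotide-controlled sequence sampling
# ---------------------------------------------------------------------------

def markov_parameters(gc: float, obs_exp: float) -> tuple[np.ndarray, np.ndarray]:
    """Stationary base frequencies and transition matrix realising the targets.

    The marginal distribution is pinned exactly at (A, C, G, T) =
    ((1-gc)/2, gc/2, gc/2, (1-gc)/2) and the C→G transition is scaled so
    that P(CpG) = obs_exp * pi_C * pi_G, which makes the expected
    Gardiner-Garden Obs/Exp ratio equal obs_exp. A plain i.i.d. sampler
    cannot decouple the two quantities.
    """
    if not (0 < gc < 1):
        raise ValueError("gc must be in (0, 1)")
    if obs_exp <= 0:
        raise ValueError("obs_exp must be positive")
    pi = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    i_c, i_g = BASES.index("C"), BASES.index("G")
    s = obs_exp * pi[i_g]  # P(G | C)
    if s >= 1:
        raise ValueError(f"obs_exp {obs_exp} infeasible at gc {gc}")
    row_c = pi * (1 - s) / (1 - pi[i_g])
    row_c[i_g] = s
    # identical row q for the three non-C states, chosen so pi is stationary
    q = (pi - pi[i_c] * row_c) / (1 - pi[i_c])
    if np.any(q < 0) or np.any(row_c < 0):
        raise ValueError(f"(gc={gc}, obs_exp={obs_exp}) is outside the feasible region")
    rows = np.tile(q, (4, 1))
    rows[i_c] = row_c
    return pi, rows


def sample_markov_codes(
    rng: np.random.Generator, length: int, gc: float, obs_exp: float
) -> np.ndarray:
    """Sample base codes (A=0..T=3) from the first-order chain."""
    pi, rows = markov_parameters(gc, obs_exp)
    cum0 = tuple(np.cumsum(pi))
    cums = [tuple(np.cumsum(row)) for row in rows]
    u = rng.random(length)
    out = np.empty(length, dtype=np.int8)
    state = _pick(cum0, u[0])
    out[0] = state
    for i in range(1, length):
        state = _pick(cums[state], u[i])
        out[i] = state
    return out


def _pick(cum: tuple, x: float) -> int:
    if x < cum[0]:
        return 0
    if x < cum[1]:
        return 1
    if x < cum[2]:
        return 2
    return 3


def codes_to_seq(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# PWM collection
# ---------------------------------------------------------------------------

def generate_pwms(config: SimulationConfig) -> list[PositionWeightMatrix]:
    """Information-rich matrices whose consensus strings the genome plants.

    Consensus strings are GC-balanced shuffles so chance-hit rates are
    comparable between the GC-rich and GC-poor promoter classes; the
    consensus base carries 17 of 20 counts per column.
    """
    rng = _rng(config, 0)
    motif_ids = sorted(set(config.motif_rates_bidir) | set(config.motif_rates_uni))
    width = config.motif_width
    consensuses: list[str] = []
    while len(consensuses) < len(motif_ids):
        pool = list("ACGT" * (width // 4 + 1))[:width]
        consensus = "".join(np.array(pool)[rng.permutation(width)])
        if consensus not in consensuses:
            consensuses.append(consensus)
    pwms = []
    for motif_id, consensus in zip(motif_ids, consensuses):
        counts = np.ones((4, width))
        for j, base in enumerate(consensus):
            counts[BASES.index(base), j] = 17
        pwms.append(
            PositionWeightMatrix(motif_id=motif_id, name=motif_id.lower(), counts=counts)
        )
    return pwms


# ---------------------------------------------------------------------------
# Genome and gene table
# ---------------------------------------------------------------------------

def generate_genome(
    config: SimulationConfig,
    pwms: Sequence[PositionWeightMatrix] | None = None,
) -> tuple[GenomeSequence, list[TranscriptRecord], dict]:
    """Genome FASTA + transcript table + ground-truth manifest.

    Gene units (head-to-head pairs and isolated uni-directional genes) are
    placed left to right with at least ``min_gene_spacing`` bp between
    units, distributed round-robin over chromosomes. Promoter-class motif
    insertions go into the symmetrically-extended bidirectional promoter
    interval (length ``promoter_length``) and the fixed upstream
    uni-directional promoter, so planted per-kb rates match what a scan of
    those intervals observes.
    """
    if pwms is None:
        pwms = generate_pwms(config)
    consensus = {p.motif_id: p.consensus() for p in pwms}
    rng = _rng(config, 1)

    n_pairs = round(config.n_genes * config.fraction_bidirectional / 2)
    n_uni = config.n_genes - 2 * n_pairs
    units = [("pair", i) for i in range(n_pairs)] + [("uni", i) for i in range(n_uni)]

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    cursors = {name: 5_000 for name in chrom_names}
    layouts: dict[str, list] = {name: [] for name in chrom_names}
    for index, unit in enumerate(units):
        layouts[chrom_names[index % len(chrom_names)]].append(unit)

    records: list[TranscriptRecord] = []
    manifest: dict = {
        "seed": config.seed,
        "pairs": [],
        "unidirectional": [],
        "motif_insertions": [],
    }
    accession_counter = 100_001
    bidir_promoters: list[tuple[str, int, int]] = []
    uni_promoters: list[tuple[str, int, int]] = []
    compositions: list[tuple[str, int, int, float, float]] = []

    for chrom in chrom_names:
        for kind, index in layouts[chrom]:
            cursor = cursors[chrom]
            if kind == "pair":
                minus_body = int(rng.integers(*config.gene_body_range, endpoint=True))
                plus_body = int(rng.integers(*config.gene_body_range, endpoint=True))
                gap = int(rng.integers(*config.tss_gap_range, endpoint=True))
                minus_start = cursor
                minus_tss = minus_start + minus_body
                plus_tss = minus_tss + gap
                plus_end = plus_tss + plus_body
                minus_symbol = f"BD{index:03d}M"
                plus_symbol = f"BD{index:03d}P"
                records.append(
                    TranscriptRecord(
                        accession=f"NM_{accession_counter}",
                        gene_symbol=minus_symbol,
                        chromosome=chrom,
                        strand="-",
                        tx_start=minus_start,
                        tx_end=minus_tss,
                    )
                )
                records.append(
                    TranscriptRecord(
                        accession=f"NM_{accession_counter + 1}",
                        gene_symbol=plus_symbol,
                        chromosome=chrom,
                        strand="+",
                        tx_start=plus_tss,
                        tx_end=plus_end,
                    )
                )
                accession_counter += 2
                # motif planting targets the symmetrically extended interval
                deficit = max(config.promoter_length - gap, 0)
                ext_start = minus_tss - (deficit + 1) // 2
                ext_end = plus_tss + deficit // 2
                manifest["pairs"].append(
                    {
                        "chromosome": chrom,
                        "plus_symbol": plus_symbol,
                        "minus_symbol": minus_symbol,
                        "minus_tss": minus_tss,
                        "plus_tss": plus_tss,
                        "gap": gap,
                        "intergenic": [minus_tss, plus_tss],
                        "extended_promoter": [ext_start, ext_end],
                    }
                )
                compositions.append(
                    (chrom, minus_tss, plus_tss, config.bidir_gc, config.bidir_obs_exp)
                )
                bidir_promoters.append((chrom, ext_start, ext_end))
                end_of_unit = plus_end
            else:
                body = int(rng.integers(*config.gene_body_range, endpoint=True))
                strand = "+" if rng.random() < 0.5 else "-"
                symbol = f"UN{index:03d}"
                if strand == "+":
                    tx_start = cursor + config.promoter_length
                    tx_end = tx_start + body
                    tss = tx_start
                    promoter = (tss - config.promoter_length, tss)
                    end_of_unit = tx_end
                else:
                    tx_start = cursor
                    tx_end = cursor + body
                    tss = tx_end
                    promoter = (tss, tss + config.promoter_length)
                    end_of_unit = promoter[1]
                records.append(
                    TranscriptRecord(
                        accession=f"NM_{accession_counter}",
                        gene_symbol=symbol,
                        chromosome=chrom,
                        strand=strand,
                        tx_start=tx_start,
                        tx_end=tx_end,
                    )
                )
                accession_counter += 1
                manifest["unidirectional"].append(
                    {
                        "chromosome": chrom,
                        "symbol": symbol,
                        "strand": strand,
                        "tss": tss,
                        "promoter": list(promoter),
                    }
                )
                compositions.append(
                    (chrom, promoter[0], promoter[1], config.uni_gc, config.uni_obs_exp)
                )
                uni_promoters.append((chrom, promoter[0], promoter[1]))
            if end_of_unit > config.chromosome_length - 1_000:
                raise ValueError(
                    f"layout infeasible: chromosome length {config.chromosome_length} "
                    f"cannot hold the requested genes with "
                    f">= {config.min_gene_spacing} bp spacing (overflow on {chrom})"
                )
            spacing = config.min_gene_spacing + int(rng.integers(0, 2_000))
            cursors[chrom] = end_of_unit + spacing

    # background sequence, then promoter-composition overwrites
    chromosomes: dict[str, np.ndarray] = {}
    for chrom in chrom_names:
        chromosomes[chrom] = sample_markov_codes(
            rng, config.chromosome_length, config.background_gc, config.background_obs_exp
        )
    for chrom, start, end, gc, obs_exp in compositions:
        chromosomes[chrom][start:end] = sample_markov_codes(rng, end - start, gc, obs_exp)

    # motif insertions overwrite bases (no indels): manifest offsets are exact
    for class_rates, promoters, kind in (
        (config.motif_rates_bidir, bidir_promoters, "bidirectional"),
        (config.motif_rates_uni, uni_promoters, "unidirectional"),
    ):
        for chrom, start, end in promoters:
            used: list[tuple[int, int]] = []
            for motif_id in sorted(class_rates):
                rate = class_rates[motif_id]
                width = len(consensus[motif_id])
                n_insert = rng.poisson(rate * (end - start) / 1000)
                for _ in range(n_insert):
                    for _attempt in range(50):
                        offset = int(rng.integers(0, end - start - width + 1))
                        if all(
                            offset + width <= a or offset >= b for a, b in used
                        ):
                            break
                    else:
                        continue  # region saturated; skip this insertion
                    used.append((offset, offset + width))
                    strand = "+" if rng.random() < 0.5 else "-"
                    planted = (
                        consensus[motif_id]
                        if strand == "+"
                        else reverse_complement(consensus[motif_id])
                    )
                    codes = np.array([BASES.index(b) for b in planted], dtype=np.int8)
                    chromosomes[chrom][start + offset : start + offset + width] = codes
                    manifest["motif_insertions"].append(
                        {
                            "motif_id": motif_id,
                            "chromosome": chrom,
                            "kind": kind,
                            "region": [start, end],
                            "offset": start + offset,
                            "strand": strand,
                        }
                    )

    genome = GenomeSequence(
        {chrom: codes_to_seq(codes) for chrom, codes in chromosomes.items()}
    )
    records.sort(key=lambda r: (r.chromosome, r.tx_start, r.accession))
    return genome, records, manifest


# ---------------------------------------------------------------------------
# Ontology and annotations
# ---------------------------------------------------------------------------

def generate_ontology(
    config: SimulationConfig,
    pairs: Sequence[tuple[str, str, str]] | None = None,
    extra_genes: Sequence[str] = (),
) -> tuple[OntologyGraph, GeneAnnotationSet, dict]:
    """Three-namespace DAG + annotations with controlled within-pair sharing.

    ``pairs`` is a list of (pair_id, plus_symbol, minus_symbol); when omitted
    a standalone fixture of ``n_ontology_pairs`` synthetic pairs is created.
    Each pair shares at least one direct term with probability ``p_share``
    (independent Bernoulli), and is guaranteed fully disjoint otherwise.
    """
    if config.ontology_terms_per_namespace < 3:
        raise ValueError("need at least 3 terms per namespace")
    rng = _rng(config, 2)
    if pairs is None:
        pairs = [
            (f"SP{i:05d}", f"SGP{i:05d}", f"SGM{i:05d}")
            for i in range(config.n_ontology_pairs)
        ]

    terms: list[OntologyTerm] = []
    edges: list[tuple[str, str]] = []
    deep_pool: list[str] = []  # depth >= 2: specific enough to be informative
    counter = 1
    for namespace in NAMESPACES:
        n_terms = config.ontology_terms_per_namespace
        depth = max(config.ontology_depth, 2)
        per_level = max((n_terms - 1) // depth, 1)
        levels: list[list[str]] = []
        remaining = n_terms
        for level in range(depth + 1):
            size = 1 if level == 0 else min(per_level, remaining)
            if size <= 0:
                break
            level_ids = []
            for _ in range(size):
                term_id = f"ST:{counter:07d}"
                counter += 1
                terms.append(
                    OntologyTerm(term_id, f"synthetic term {counter - 1}", namespace)
                )
                level_ids.append(term_id)
                if level >= 2:
                    deep_pool.append(term_id)
            remaining -= size
            if level > 0:
                for term_id in level_ids:
                    n_parents = 1 + int(rng.random() < 0.3 and len(levels[-1]) > 1)
                    parent_ids = rng.choice(
                        len(levels[-1]), size=n_parents, replace=False
                    )
                    for p in parent_ids:
                        edges.append((term_id, levels[-1][int(p)]))
            levels.append(level_ids)
    ontology = OntologyGraph(terms, edges)

    pool = np.array(deep_pool)
    lo, hi = config.terms_per_gene
    annotations: dict[str, set[str]] = {}
    manifest = {"seed": config.seed, "pairs": []}

    def draw(k: int, exclude: set[str] = frozenset()) -> set[str]:
        available = [t for t in pool if t not in exclude]
        idx = rng.choice(len(available), size=min(k, len(available)), replace=False)
        return {available[int(i)] for i in idx}

    for pair_id, plus_symbol, minus_symbol in pairs:
        shares = bool(rng.random() < config.p_share)
        k_plus = int(rng.integers(lo, hi, endpoint=True))
        k_minus = int(rng.integers(lo, hi, endpoint=True))
        plus_terms = draw(k_plus)
        if shares:
            shared = {str(pool[int(rng.integers(0, len(pool)))])}
            plus_terms |= shared
            minus_terms = draw(k_minus) | shared
        else:
            minus_terms = draw(k_minus, exclude=plus_terms)
        annotations[plus_symbol] = plus_terms
        annotations[minus_symbol] = minus_terms
        manifest["pairs"].append(
            {
                "pair_id": pair_id,
                "plus_symbol": plus_symbol,
                "minus_symbol": minus_symbol,
                "shares": shares,
                "shared_terms": sorted(plus_terms & minus_terms),
            }
        )
    for gene in extra_genes:
        annotations[gene] = draw(int(rng.integers(lo, hi, endpoint=True)))
    return ontology, GeneAnnotationSet(annotations), manifest


# ---------------------------------------------------------------------------
# Bundle orchestration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    config: SimulationConfig
    genome: GenomeSequence
    transcripts: list[TranscriptRecord]
    pwms: list[PositionWeightMatrix]
    ontology: OntologyGraph
    annotations: GeneAnnotationSet
    manifest: dict


def generate_bundle(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SyntheticBundle:
    """Generate every input the pipeline needs; optionally write them to disk.

    The ontology annotates the genome's own planted pairs and uni genes
    (not the standalone ``n_ontology_pairs`` fixture), so the bundle is
    end-to-end consistent.
    """
    pwms = generate_pwms(config)
    genome, transcripts, genome_manifest = generate_genome(config, pwms)
    pairs = [
        (f"BP{i + 1:05d}", entry["plus_symbol"], entry["minus_symbol"])
        for i, entry in enumerate(genome_manifest["pairs"])
    ]
    extra = [entry["symbol"] for entry in genome_manifest["unidirectional"]]
    ontology, annotations, ontology_manifest = generate_ontology(
        config, pairs=pairs, extra_genes=extra
    )
    manifest = {
        "config": dataclasses.asdict(config),
        "genome": genome_manifest,
        "ontology": ontology_manifest,
    }
    bundle = SyntheticBundle(
        config=config,
        genome=genome,
        transcripts=transcripts,
        pwms=pwms,
        ontology=ontology,
        annotations=annotations,
        manifest=manifest,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, out_dir / "genome.fa")
        write_gene_table(transcripts, out_dir / "genes.tsv")
        write_obo(ontology, out_dir / "ontology.obo")
        write_annotations(annotations, out_dir / "annotations.tsv")
        write_pwm_jaspar(pwms, out_dir / "motifs.jaspar")
        write_pwm_transfac(pwms, out_dir / "motifs.transfac")
        with open(out_dir / "truth.json", "w") as handle:
            json.dump(_jsonify(manifest), handle, indent=1, sort_keys=True)
    return bundle


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
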