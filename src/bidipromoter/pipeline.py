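"""End-to-end pipeline orchestration and summary reporting.

Stages run in order: classify → promoters → cpg → functional (GO term
enrichment, within-pair similarity, optional GMT gene-set enrichment) →
tfbs. Each stage writes plain-TSV/BED/FASTA artifacts into the output
directory; a stage can be resumed from disk with ``from_stage`` because
each stage's inputs are exactly the previous stages' files. A run log
records the parameter set and a content digest of every input, so reports
are traceable to exact inputs; no timestamps are written, keeping reruns
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import cpg_islands as cpg
from . import go_enrichment as go
from . import tfbs_enrichment as tfbs
from .io_formats import (
    read_annotations,
    read_fasta,
    read_gene_table,
    read_gmt,
    read_obo,
    read_pwm_jaspar,
    read_pwm_transfac,
    write_bed,
)
from .pair_classification import (
    GeneCluster,
    GenePair,
    classify_bidirectional,
    classify_unidirectional,
    collapse_clusters,
    deduplicate_pairs,
    filter_evidence,
    EVIDENCE_MODES,
)
from .promoter_extraction import (
    DegenerateRegionError,
    PromoterRegion,
    bidirectional_promoter,
    extend_symmetric,
    fetch_sequences,
    unidirectional_promoter,
)

logger = logging.getLogger(__name__)

STAGES = ("classify", "promoters", "cpg", "functional", "tfbs")


class PipelineValidationError(ValueError):
    """The configuration references missing inputs or invalid parameters."""


class StageError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    genes: str | Path = ""
    genome: str | Path = ""
    obo: str | Path | None = None
    annotations: str | Path | None = None
    jaspar: str | Path | None = None
    transfac: str | Path | None = None
    gmt: str | Path | None = None
    out_dir: str | Path = "bidipromoter_out"
    mode: str = "curated-mRNA"
    max_distance: int = 1000
    min_promoter_length: int = 1000
    pure_ig: bool = False
    threshold_fraction: float = 0.8
    fold_threshold: float = 2.0
    adjust: str = "by"
    log_level: str = "INFO"
    _input_paths: tuple[str, ...] = field(
        default=("genes", "genome", "obo", "annotations", "jaspar", "transfac", "gmt"),
        repr=False,
    )

    def validate(self) -> None:
        for name in ("genes", "genome"):
            value = getattr(self, name)
            if not value:
                raise PipelineValidationError(f"required input {name!r} not set")
        for name in self._input_paths:
            value = getattr(self, name)
            if value and not Path(value).exists():
                raise PipelineValidationError(f"input {name!r} missing: {value}")
        if self.mode not in EVIDENCE_MODES:
            raise PipelineValidationError(f"unknown evidence mode {self.mode!r}")
        if self.max_distance <= 0 or self.min_promoter_length <= 0:
            raise PipelineValidationError("distances must be positive")
        if not (0 < self.threshold_fraction <= 1):
            raise PipelineValidationError("threshold_fraction must be in (0, 1]")


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, from_stage: str = "classify") -> dict:
    """Run the pipeline, returning a report bundle of summary tables.

    ``from_stage`` resumes from a later stage by reading the earlier stages'
    on-disk artifacts from ``out_dir``.
    """
    config.validate()
    if from_stage not in STAGES:
        raise PipelineValidationError(f"unknown stage {from_stage!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    start = STAGES.index(from_stage)

    settings = {
        k: (str(v) if isinstance(v, Path) else v)
        for k, v in asdict(config).items()
        if not k.startswith("_")
    }
    digests = {
        name: _digest(getattr(config, name))
        for name in config._input_paths
        if getattr(config, name)
    }
    (out / "run_log.txt").write_text(
        "parameters:\n"
        + json.dumps(settings, indent=1, sort_keys=True)
        + "\ninput_sha256_prefixes:\n"
        + json.dumps(digests, indent=1, sort_keys=True)
        + "\n"
    )

    report: dict = {}
    try:
        if start <= STAGES.index("classify"):
            _stage_classify(config, out, report)
        if start <= STAGES.index("promoters"):
            _stage_promoters(config, out, report)
        if start <= STAGES.index("cpg"):
            _stage_cpg(config, out, report)
        if start <= STAGES.index("functional"):
            _stage_functional(config, out, report)
        if start <= STAGES.index("tfbs"):
            _stage_tfbs(config, out, report)
    except (PipelineValidationError, StageError):
        raise
    except Exception as exc:
        stage = report.get("_current_stage", "unknown")
        raise StageError(f"stage {stage!r} failed: {exc}") from exc
    report.pop("_current_stage", None)

    summary = {
        "n_pairs": report.get("n_pairs"),
        "n_unidirectional": report.get("n_unidirectional"),
        "cpg": report.get("cpg_summary_plain"),
        "pair_similarity": report.get("pairsim_summary"),
        "tfbs_categories": report.get("tfbs_categories"),
    }
    with open(out / "summary.json", "w") as handle:
        json.dump(summary, handle, indent=1, sort_keys=True)
    return report


# ---------------------------------------------------------------------------
# Stage implementations (each reads predecessors' artifacts from disk)
# ---------------------------------------------------------------------------

def _stage_classify(config: PipelineConfig, out: Path, report: dict) -> None:
    report["_current_stage"] = "classify"
    records = read_gene_table(config.genes)
    clusters = collapse_clusters(records)

    # per-chromosome pair counts under each evidence mode (the shape of the
    # classic distribution-by-chromosome table)
    count_rows = []
    chromosomes = sorted({c.chromosome for c in clusters})
    per_mode_pairs = {}
    for mode in EVIDENCE_MODES:
        selected = filter_evidence(clusters, mode)
        per_mode_pairs[mode] = deduplicate_pairs(
            classify_bidirectional(selected, config.max_distance)
        )
    for chrom in chromosomes:
        row = {"chromosome": chrom}
        for mode in EVIDENCE_MODES:
            row[mode] = sum(1 for p in per_mode_pairs[mode] if p.chromosome == chrom)
        count_rows.append(row)
    counts = pd.DataFrame(count_rows)
    counts.to_csv(out / "pair_counts_by_chromosome.tsv", sep="\t", index=False)

    selected = filter_evidence(clusters, config.mode)
    pairs = per_mode_pairs[config.mode]
    uni = classify_unidirectional(selected)

    pd.DataFrame(
        [
            {
                "pair_id": p.pair_id,
                "chrom": p.chromosome,
                "minus_symbol": p.minus_gene.gene_symbol,
                "minus_tss": p.minus_gene.tss,
                "plus_symbol": p.plus_gene.gene_symbol,
                "plus_tss": p.plus_gene.tss,
                "distance": p.tss_distance,
            }
            for p in pairs
        ]
    ).to_csv(out / "pairs.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "chrom": c.chromosome,
                "strand": c.strand,
                "symbol": c.gene_symbol,
                "tss": c.tss,
                "start": c.start,
                "end": c.end,
            }
            for c in uni
        ]
    ).to_csv(out / "unidirectional.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"symbol": c.gene_symbol} for c in selected]
    ).to_csv(out / "population.tsv", sep="\t", index=False)

    report["pairs"] = pairs
    report["unidirectional"] = uni
    report["n_pairs"] = len(pairs)
    report["n_unidirectional"] = len(uni)
    report["pair_counts"] = counts


def _load_pairs(out: Path) -> list[GenePair]:
    table = pd.read_csv(out / "pairs.tsv", sep="\t")
    pairs = []
    for row in table.itertuples():
        minus = GeneCluster(
            cluster_id=f"{row.chrom}:{row.minus_tss}:-",
            gene_symbol=row.minus_symbol,
            chromosome=row.chrom,
            strand="-",
            start=row.minus_tss - 1,
            end=row.minus_tss,
            tss=row.minus_tss,
            members=(),
            evidence_class="curated-mRNA",
        )
        plus = GeneCluster(
            cluster_id=f"{row.chrom}:{row.plus_tss}:+",
            gene_symbol=row.plus_symbol,
            chromosome=row.chrom,
            strand="+",
            start=row.plus_tss,
            end=row.plus_tss + 1,
            tss=row.plus_tss,
            members=(),
            evidence_class="curated-mRNA",
        )
        pairs.append(GenePair(pair_id=row.pair_id, plus_gene=plus, minus_gene=minus))
    return pairs


def _load_unidirectional(out: Path) -> list[GeneCluster]:
    table = pd.read_csv(out / "unidirectional.tsv", sep="\t")
    return [
        GeneCluster(
            cluster_id=row.cluster_id,
            gene_symbol=row.symbol,
            chromosome=row.chrom,
            strand=row.strand,
            start=row.start,
            end=row.end,
            tss=row.tss,
            members=(),
            evidence_class="curated-mRNA",
        )
        for row in table.itertuples()
    ]


def _stage_promoters(config: PipelineConfig, out: Path, report: dict) -> None:
    report["_current_stage"] = "promoters"
    pairs = report.get("pairs") or _load_pairs(out)
    uni = report.get("unidirectional") or _load_unidirectional(out)
    genome = read_fasta(config.genome)
    lengths = genome.lengths

    bidir_regions: list[PromoterRegion] = []
    for pair in pairs:
        try:
            region = bidirectional_promoter(pair)
        except DegenerateRegionError:
            logger.warning("pair %s skipped: TSS distance 0", pair.pair_id)
            continue
        if not config.pure_ig:
            region = extend_symmetric(
                region, lengths[region.chromosome], config.min_promoter_length
            )
        bidir_regions.append(region)
    uni_regions = [
        unidirectional_promoter(gene, lengths[gene.chromosome], config.min_promoter_length)
        for gene in uni
    ]
    bidir_regions = fetch_sequences(bidir_regions, genome)
    uni_regions = fetch_sequences(uni_regions, genome)

    write_bed(bidir_regions + uni_regions, out / "promoters.bed")
    _write_promoter_fasta(bidir_regions, out / "promoters_bidir.fa")
    _write_promoter_fasta(uni_regions, out / "promoters_uni.fa")
    pd.DataFrame(
        [
            {
                "region_id": r.region_id,
                "source": r.source,
                "chrom": r.chromosome,
                "start": r.start,
                "end": r.end,
                "kind": r.kind,
                "extended": r.extended,
                "truncated": r.truncated,
            }
            for r in bidir_regions + uni_regions
        ]
    ).to_csv(out / "promoters.tsv", sep="\t", index=False)
    report["bidir_regions"] = bidir_regions
    report["uni_regions"] = uni_regions


def _write_promoter_fasta(regions: Sequence[PromoterRegion], path: Path) -> None:
    with open(path, "w") as handle:
        for region in regions:
            handle.write(f">{region.region_id}\n")
            for i in range(0, len(region.sequence), 60):
                handle.write(region.sequence[i : i + 60] + "\n")


def _load_promoters(out: Path) -> tuple[list[PromoterRegion], list[PromoterRegion]]:
    table = pd.read_csv(out / "promoters.tsv", sep="\t")
    meta = {row.region_id: row for row in table.itertuples()}
    loaded: dict[str, list[PromoterRegion]] = {"bidirectional": [], "unidirectional": []}
    for kind, name in (("bidirectional", "promoters_bidir.fa"), ("unidirectional", "promoters_uni.fa")):
        genome_like = read_fasta(out / name)
        for region_id in genome_like.chromosomes:
            row = meta[region_id]
            loaded[kind].append(
                PromoterRegion(
                    region_id=region_id,
                    source=row.source,
                    chromosome=row.chrom,
                    start=row.start,
                    end=row.end,
                    kind=kind,
                    extended=bool(row.extended),
                    truncated=bool(row.truncated),
                    sequence=genome_like[region_id],
                )
            )
    return loaded["bidirectional"], loaded["unidirectional"]


def _stage_cpg(config: PipelineConfig, out: Path, report: dict) -> None:
    report["_current_stage"] = "cpg"
    if "bidir_regions" in report:
        bidir_regions, uni_regions = report["bidir_regions"], report["uni_regions"]
    else:
        bidir_regions, uni_regions = _load_promoters(out)

    rows = []
    plain: dict = {}
    for criteria in (cpg.GARDINER_GARDEN, cpg.STRICT):
        bidir_islands = cpg.islands_by_region(bidir_regions, criteria)
        uni_islands = cpg.islands_by_region(uni_regions, criteria)
        summary = cpg.summarize_by_class(bidir_islands, uni_islands)
        report[f"cpg_{criteria.name}"] = summary
        plain[criteria.name] = {
            cls: asdict(summary[cls]) for cls in ("bidirectional", "unidirectional")
        }
        all_islands = [i for _, islands in bidir_islands + uni_islands for i in islands]
        write_bed(all_islands, out / f"cpg_islands_{criteria.name}.bed")
        for cls in ("bidirectional", "unidirectional"):
            entry = summary[cls]
            rows.append({"criteria": criteria.name, "class": cls, **asdict(entry)})
    pd.DataFrame(rows).to_csv(out / "cpg_summary.tsv", sep="\t", index=False)
    report["cpg_summary_plain"] = plain


def _stage_functional(config: PipelineConfig, out: Path, report: dict) -> None:
    report["_current_stage"] = "functional"
    if config.obo is None or config.annotations is None:
        logger.info("no ontology/annotations supplied; functional stage skipped")
        return
    pairs = report.get("pairs") or _load_pairs(out)
    ontology = read_obo(config.obo)
    annotations = read_annotations(config.annotations, ontology)
    population = set(pd.read_csv(out / "population.tsv", sep="\t")["symbol"])
    study = {p.plus_gene.gene_symbol for p in pairs} | {
        p.minus_gene.gene_symbol for p in pairs
    }
    study &= population

    records = go.enrich_terms(
        study, population, annotations, ontology, adjust=config.adjust
    )
    pd.DataFrame([asdict(r) for r in records]).to_csv(
        out / "go_enrichment.tsv", sep="\t", index=False
    )

    sim_records, sim_summary = go.pair_shared_terms(pairs, annotations, ontology)
    pd.DataFrame(
        [
            {
                "pair_id": r.pair_id,
                "plus_symbol": r.plus_symbol,
                "minus_symbol": r.minus_symbol,
                "shared_count": r.shared_count,
                "shared_terms": ",".join(sorted(r.shared_terms)),
            }
            for r in sim_records
        ]
    ).to_csv(out / "pair_similarity.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"shared_count": k, "n_pairs": v}
            for k, v in sim_summary["histogram"].items()
        ]
    ).to_csv(out / "shared_histogram.tsv", sep="\t", index=False)
    report["go_records"] = records
    report["pairsim_summary"] = sim_summary

    if config.gmt:
        collections = read_gmt(config.gmt)
        gsea = go.enrich_gene_sets(study, population, collections)
        pd.DataFrame([asdict(r) for r in gsea]).to_csv(
            out / "gene_set_enrichment.tsv", sep="\t", index=False
        )
        report["gene_set_records"] = gsea


def _stage_tfbs(config: PipelineConfig, out: Path, report: dict) -> None:
    report["_current_stage"] = "tfbs"
    if config.jaspar is None and config.transfac is None:
        logger.info("no PWM collections supplied; tfbs stage skipped")
        return
    if "bidir_regions" in report:
        bidir_regions, uni_regions = report["bidir_regions"], report["uni_regions"]
    else:
        bidir_regions, uni_regions = _load_promoters(out)

    tables = {}
    for label, path, reader in (
        ("jaspar", config.jaspar, read_pwm_jaspar),
        ("transfac", config.transfac, read_pwm_transfac),
    ):
        if path is None:
            continue
        pwms = reader(path)
        records = tfbs.enrichment_table(
            bidir_regions,
            uni_regions,
            pwms,
            threshold_fraction=config.threshold_fraction,
            fold_threshold=config.fold_threshold,
        )
        tables[label] = records
        pd.DataFrame(
            [
                {
                    "motif_id": r.motif_id,
                    "name": r.name,
                    "source_db": label,
                    "bidir_rate": r.bidir_rate,
                    "uni_rate": r.uni_rate,
                    "fold": r.fold,
                    "category": r.category,
                }
                for r in records
            ]
        ).to_csv(out / f"tfbs_enrichment_{label}.tsv", sep="\t", index=False)

    if len(tables) == 2:
        overlap = tfbs.overlap_over_represented(tables["jaspar"], tables["transfac"])
        pd.DataFrame({"motif_name": sorted(overlap)}).to_csv(
            out / "tfbs_overlap.tsv", sep="\t", index=False
        )
        report["tfbs_overlap"] = overlap
    report["tfbs_tables"] = tables
    report["tfbs_categories"] = {
        label: {
            category: sum(1 for r in records if r.category == category)
            for category in ("over-represented", "shared", "under-represented")
        }
        for label, records in tables.items()
    }
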