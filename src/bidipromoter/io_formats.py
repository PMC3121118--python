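"""Readers and writers for the external formats the pipeline touches.

Every downstream module consumes only the domain types defined here:
transcript tables (UCSC refGene-style TSV), genome FASTA, OBO ontologies,
gene→term annotation TSV, JASPAR/TRANSFAC position weight matrices, BED6
and GMT gene-set collections.

All genomic coordinates are 0-based half-open throughout the package; the
refGene and BED conventions match this natively, so coordinates pass through
readers and writers unchanged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np
import obonet
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
VALID_SEQ_CHARS = frozenset("ACGTN")
NAMESPACES = ("biological_process", "molecular_function", "cellular_component")

#: RefSeq accession prefix → evidence class. NM = curated mRNA, NR = curated
#: non-coding, XM/XR = computational predictions without conclusive mRNA support.
EVIDENCE_BY_PREFIX = {
    "NM": "curated-mRNA",
    "NR": "curated-noncoding",
    "XM": "predicted",
    "XR": "predicted",
}
#: Ranking used when a cluster mixes members of several classes (best first).
EVIDENCE_RANK = {
    "curated-mRNA": 0,
    "curated-noncoding": 1,
    "predicted": 2,
    "other": 3,
}


class FormatError(ValueError):
    """A file did not conform to the expected dialect."""


class GeneTableFormatError(FormatError):
    pass


class FastaFormatError(FormatError):
    pass


class OntologyFormatError(FormatError):
    pass


class AnnotationFormatError(FormatError):
    pass


class PWMFormatError(FormatError):
    pass


def evidence_class_of(accession: str) -> str:
    """Evidence class implied by a RefSeq-style accession prefix.

    Unknown prefixes map to ``"other"`` so synthetic or non-RefSeq fixtures
    are retained rather than rejected.
    """
    prefix = accession.split("_", 1)[0]
    cls = EVIDENCE_BY_PREFIX.get(prefix)
    if cls is None:
        return "other"
    return cls


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript row of a refGene-style table (0-based half-open span)."""

    accession: str
    gene_symbol: str
    chromosome: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GeneTableFormatError(
                f"strand must be '+' or '-', got {self.strand!r} "
                f"for {self.accession}"
            )
        if self.tx_start < 0:
            raise GeneTableFormatError(
                f"negative tx_start {self.tx_start} for {self.accession}"
            )
        if self.tx_start >= self.tx_end:
            raise GeneTableFormatError(
                f"tx_start must be < tx_end, got [{self.tx_start}, {self.tx_end}) "
                f"for {self.accession}"
            )

    @property
    def evidence_class(self) -> str:
        return evidence_class_of(self.accession)


class GenomeSequence:
    """Uppercase per-chromosome DNA over the alphabet {A, C, G, T, N}.

    Out-of-bounds lookups raise; any clamping to chromosome ends is an
    explicit operation performed by the caller (promoter extraction).
    """

    def __init__(self, sequences: Mapping[str, str]):
        clean: dict[str, str] = {}
        for name, seq in sequences.items():
            if not seq:
                raise FastaFormatError(f"empty sequence for chromosome {name!r}")
            seq = seq.upper()
            bad = set(seq) - VALID_SEQ_CHARS
            if bad:
                raise FastaFormatError(
                    f"chromosome {name!r} contains invalid characters: "
                    f"{sorted(bad)}"
                )
            if name in clean:
                raise FastaFormatError(f"duplicate chromosome name {name!r}")
            clean[name] = seq
        self._sequences = clean

    @property
    def chromosomes(self) -> list[str]:
        return list(self._sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._sequences.items()}

    def __contains__(self, name: str) -> bool:
        return name in self._sequences

    def __getitem__(self, name: str) -> str:
        try:
            return self._sequences[name]
        except KeyError:
            raise KeyError(f"chromosome {name!r} not present in genome") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeSequence):
            return NotImplemented
        return self._sequences == other._sequences

    def fetch(self, chromosome: str, start: int, end: int) -> str:
        """Forward-strand substring [start, end); rejects out-of-bounds access."""
        seq = self[chromosome]
        if not (0 <= start < end <= len(seq)):
            raise ValueError(
                f"interval [{start}, {end}) outside chromosome "
                f"{chromosome!r} of length {len(seq)}"
            )
        return seq[start:end]


# ---------------------------------------------------------------------------
# refGene-style transcript tables
# ---------------------------------------------------------------------------

GENE_TABLE_COLUMNS = (
    "accession",
    "gene_symbol",
    "chromosome",
    "strand",
    "tx_start",
    "tx_end",
)


def read_gene_table(path: str | Path) -> list[TranscriptRecord]:
    """Read a tab-separated transcript table into TranscriptRecords.

    Columns: accession, gene_symbol, chromosome, strand, tx_start, tx_end,
    with coordinates 0-based half-open (the UCSC convention). A header line
    is detected by a non-numeric coordinate field and skipped. Rows are
    returned in file order.
    """
    path = Path(path)
    records: list[TranscriptRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise GeneTableFormatError(
                    f"{path}:{lineno}: expected 6 tab-separated columns, "
                    f"got {len(fields)}"
                )
            acc, symbol, chrom, strand, start_s, end_s = fields[:6]
            if lineno == 1 and not (_is_int(start_s) and _is_int(end_s)):
                continue  # header line
            if not (_is_int(start_s) and _is_int(end_s)):
                raise GeneTableFormatError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{start_s!r}, {end_s!r}"
                )
            try:
                record = TranscriptRecord(
                    accession=acc,
                    gene_symbol=symbol,
                    chromosome=chrom,
                    strand=strand,
                    tx_start=int(start_s),
                    tx_end=int(end_s),
                )
            except GeneTableFormatError as exc:
                raise GeneTableFormatError(f"{path}:{lineno}: {exc}") from None
            if record.evidence_class == "other":
                logger.warning(
                    "%s:%d: accession %r has no recognised RefSeq prefix; "
                    "evidence class set to 'other'",
                    path,
                    lineno,
                    acc,
                )
            records.append(record)
    return records


def write_gene_table(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for r in records:
            handle.write(
                f"{r.accession}\t{r.gene_symbol}\t{r.chromosome}\t{r.strand}"
                f"\t{r.tx_start}\t{r.tx_end}\n"
            )


def _is_int(text: str) -> bool:
    try:
        int(text)
    except ValueError:
        return False
    return True


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a (multi-)FASTA file, case-folding to uppercase.

    Records are keyed by the first whitespace-delimited token of each header.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in sequences:
            raise FastaFormatError(f"{path}: duplicate chromosome name {name!r}")
        sequences[name] = str(record.seq)
    if not sequences:
        raise FastaFormatError(f"{path}: no FASTA records found")
    try:
        return GenomeSequence(sequences)
    except FastaFormatError as exc:
        raise FastaFormatError(f"{path}: {exc}") from None


def write_fasta(genome: GenomeSequence, path: str | Path, line_width: int = 60) -> None:
    records = [
        SeqRecord(Seq(genome[name]), id=name, description="")
        for name in genome.chromosomes
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=line_width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Ontology (OBO 1.2) and gene annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OntologyTerm:
    term_id: str
    name: str
    namespace: str


class OntologyGraph:
    """An acyclic is_a hierarchy over named, namespaced terms."""

    def __init__(
        self,
        terms: Iterable[OntologyTerm],
        edges: Iterable[tuple[str, str]],
    ):
        self.terms: dict[str, OntologyTerm] = {}
        for term in terms:
            if term.namespace not in NAMESPACES:
                raise OntologyFormatError(
                    f"term {term.term_id} has unknown namespace {term.namespace!r}"
                )
            self.terms[term.term_id] = term
        self.parents: dict[str, frozenset[str]] = {t: frozenset() for t in self.terms}
        by_child: dict[str, set[str]] = {}
        graph = nx.DiGraph()
        graph.add_nodes_from(self.terms)
        for child, parent in edges:
            for endpoint in (child, parent):
                if endpoint not in self.terms:
                    raise OntologyFormatError(
                        f"is_a edge {child} -> {parent} references "
                        f"undeclared term {endpoint}"
                    )
            by_child.setdefault(child, set()).add(parent)
            graph.add_edge(child, parent)
        try:
            cycle = nx.find_cycle(graph)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            pretty = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[0][0]}"
            raise OntologyFormatError(f"is_a relation is cyclic: {pretty}")
        for child, parents in by_child.items():
            self.parents[child] = frozenset(parents)
        self._ancestor_cache: dict[str, frozenset[str]] = {}
        self._depth_cache: dict[str, int] = {}

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def namespace_of(self, term_id: str) -> str:
        return self.terms[term_id].namespace

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All is_a ancestors of a term (the term itself excluded)."""
        cached = self._ancestor_cache.get(term_id)
        if cached is not None:
            return cached
        result: set[str] = set()
        stack = list(self.parents[term_id])
        while stack:
            node = stack.pop()
            if node not in result:
                result.add(node)
                stack.extend(self.parents[node])
        frozen = frozenset(result)
        self._ancestor_cache[term_id] = frozen
        return frozen

    def depth(self, term_id: str) -> int:
        """Shortest is_a distance to a root (a term with no parents)."""
        cached = self._depth_cache.get(term_id)
        if cached is not None:
            return cached
        parents = self.parents[term_id]
        depth = 0 if not parents else 1 + min(self.depth(p) for p in parents)
        self._depth_cache[term_id] = depth
        return depth


def read_obo(path: str | Path) -> OntologyGraph:
    """Read an OBO 1.2 file; only [Term] stanzas with id/name/namespace/is_a
    are interpreted and obsolete terms are skipped."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        graph = obonet.read_obo(str(path))
    terms: list[OntologyTerm] = []
    edges: list[tuple[str, str]] = []
    for node, data in graph.nodes(data=True):
        if "name" not in data:
            # obonet materialises is_a targets that have no stanza of their own
            raise OntologyFormatError(
                f"{path}: is_a reference to undeclared term {node}"
            )
        terms.append(
            OntologyTerm(
                term_id=node,
                name=data["name"],
                namespace=data.get("namespace", "biological_process"),
            )
        )
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            edges.append((child, parent))
    try:
        return OntologyGraph(terms, edges)
    except OntologyFormatError as exc:
        raise OntologyFormatError(f"{path}: {exc}") from None


def write_obo(ontology: OntologyGraph, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("format-version: 1.2\nontology: synthetic\n")
        for term_id in sorted(ontology.terms):
            term = ontology.terms[term_id]
            handle.write("\n[Term]\n")
            handle.write(f"id: {term.term_id}\n")
            handle.write(f"name: {term.name}\n")
            handle.write(f"namespace: {term.namespace}\n")
            for parent in sorted(ontology.parents[term_id]):
                handle.write(f"is_a: {parent}\n")


class GeneAnnotationSet:
    """Direct gene → term-id annotations (a mapping to frozensets)."""

    def __init__(self, data: Mapping[str, Iterable[str]]):
        self._data: dict[str, frozenset[str]] = {
            gene: frozenset(terms) for gene, terms in data.items()
        }

    def __getitem__(self, gene: str) -> frozenset[str]:
        return self._data[gene]

    def get(self, gene: str, default: frozenset[str] = frozenset()) -> frozenset[str]:
        return self._data.get(gene, default)

    def __contains__(self, gene: str) -> bool:
        return gene in self._data

    def __iter__(self) -> Iterator[str]:
        return iter(self._data)

    def __len__(self) -> int:
        return len(self._data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneAnnotationSet):
            return NotImplemented
        return self._data == other._data

    def items(self):
        return self._data.items()

    def genes(self) -> set[str]:
        return set(self._data)

    def validate_against(self, ontology: OntologyGraph) -> None:
        for gene, terms in self._data.items():
            for term in terms:
                if term not in ontology:
                    raise AnnotationFormatError(
                        f"gene {gene!r} annotated to term {term} "
                        f"absent from the ontology"
                    )


def read_annotations(
    path: str | Path, ontology: OntologyGraph | None = None
) -> GeneAnnotationSet:
    """Read a two-column TSV of (gene_symbol, term_id); duplicates collapse.

    Extra columns are ignored with a warning. When an ontology is supplied,
    every term id must exist in it.
    """
    data: dict[str, set[str]] = {}
    extra_warned = False
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise AnnotationFormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            if len(fields) > 2 and not extra_warned:
                logger.warning(
                    "%s:%d: extra columns beyond (gene, term) ignored", path, lineno
                )
                extra_warned = True
            gene, term = fields[0], fields[1]
            data.setdefault(gene, set()).add(term)
    annotations = GeneAnnotationSet(data)
    if ontology is not None:
        annotations.validate_against(ontology)
    return annotations


def write_annotations(annotations: GeneAnnotationSet, path: str | Path) -> None:
    with open(path, "w") as handle:
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                handle.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# Position weight matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PositionWeightMatrix:
    """Per-base, per-position counts of a motif (rows A, C, G, T)."""

    motif_id: str
    name: str
    counts: np.ndarray = field(repr=False)  # shape (4, width)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise PWMFormatError(
                f"motif {self.motif_id}: counts must be 4 x L with L >= 1, "
                f"got shape {counts.shape}"
            )
        if not np.all(np.isfinite(counts)) or np.any(counts < 0):
            raise PWMFormatError(
                f"motif {self.motif_id}: counts must be finite and non-negative"
            )
        if np.any(counts.sum(axis=0) <= 0):
            raise PWMFormatError(
                f"motif {self.motif_id}: every position needs at least one "
                f"strictly positive count"
            )
        object.__setattr__(self, "counts", counts)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PositionWeightMatrix):
            return NotImplemented
        return (
            self.motif_id == other.motif_id
            and self.name == other.name
            and self.counts.shape == other.counts.shape
            and np.allclose(self.counts, other.counts)
        )


def _from_bio_motif(motif, motif_id: str, name: str) -> PositionWeightMatrix:
    counts = np.array([list(motif.counts[b]) for b in BASES], dtype=float)
    return PositionWeightMatrix(motif_id=motif_id, name=name, counts=counts)


def read_pwm_jaspar(path: str | Path) -> list[PositionWeightMatrix]:
    """Read JASPAR-dialect matrices (``>ID name`` headers, bracketed rows)."""
    try:
        with open(path) as handle:
            parsed = bio_motifs.parse(handle, "jaspar")
            result = [
                _from_bio_motif(m, m.matrix_id or m.name, m.name or m.matrix_id)
                for m in parsed
            ]
    except PWMFormatError:
        raise
    except Exception as exc:  # Biopython raises bare Exception subclasses
        raise PWMFormatError(f"{path}: malformed JASPAR matrix file: {exc}") from exc
    return result


def read_pwm_transfac(path: str | Path) -> list[PositionWeightMatrix]:
    """Read TRANSFAC-dialect matrices (ID/P0 blocks terminated by ``//``).

    Both dialects yield identical PositionWeightMatrix semantics.
    """
    try:
        with open(path) as handle:
            parsed = bio_motifs.parse(handle, "transfac", strict=False)
            result = []
            for m in parsed:
                motif_id = m.get("ID") or m.get("AC") or ""
                name = m.get("NA") or motif_id
                result.append(_from_bio_motif(m, motif_id, name))
    except PWMFormatError:
        raise
    except Exception as exc:
        raise PWMFormatError(f"{path}: malformed TRANSFAC matrix file: {exc}") from exc
    return result


def _format_count(x: float) -> str:
    return f"{int(x)}" if float(x).is_integer() else f"{x:g}"


def write_pwm_jaspar(pwms: Iterable[PositionWeightMatrix], path: str | Path) -> None:
    with open(path, "w") as handle:
        for pwm in pwms:
            handle.write(f">{pwm.motif_id} {pwm.name}\n")
            for i, base in enumerate(BASES):
                row = " ".join(f"{_format_count(x):>6}" for x in pwm.counts[i])
                handle.write(f"{base} [ {row} ]\n")


def write_pwm_transfac(pwms: Iterable[PositionWeightMatrix], path: str | Path) -> None:
    with open(path, "w") as handle:
        for pwm in pwms:
            handle.write(f"ID {pwm.motif_id}\n")
            handle.write(f"NA {pwm.name}\n")
            handle.write("P0      A      C      G      T\n")
            consensus = pwm.consensus()
            for j in range(pwm.width):
                row = "  ".join(
                    f"{_format_count(pwm.counts[i, j]):>5}" for i in range(4)
                )
                handle.write(f"{j + 1:02d}  {row}  {consensus[j]}\n")
            handle.write("XX\n//\n")


# ---------------------------------------------------------------------------
# BED6 and GMT
# ---------------------------------------------------------------------------

def write_bed(regions: Iterable, path: str | Path) -> None:
    """Write intervals as BED6 (chrom, start, end, name, score, strand).

    Accepts any objects with chromosome/start/end attributes; an optional
    ``region_id`` (or ``name``) and ``strand`` are used when present.
    Internal coordinates are already 0-based half-open, matching BED.
    """
    with open(path, "w") as handle:
        for region in regions:
            name = getattr(region, "region_id", None) or getattr(
                region, "name", "."
            )
            strand = getattr(region, "strand", ".")
            handle.write(
                f"{region.chromosome}\t{region.start}\t{region.end}"
                f"\t{name}\t0\t{strand}\n"
            )


def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a GMT gene-set collection: name, description, member genes.

    Duplicate genes within a line are collapsed (set semantics).
    """
    collections: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT lines need name, description "
                    f"and at least one gene"
                )
            name, description = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            collections[name] = (description, genes)
    return collections


def write_gmt(
    collections: Mapping[str, tuple[str, Iterable[str]]], path: str | Path
) -> None:
    with open(path, "w") as handle:
        for name, (description, genes) in collections.items():
            handle.write("\t".join([name, description, *sorted(genes)]) + "\n")
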