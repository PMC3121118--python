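"""Functional enrichment and within-pair functional similarity.

Term enrichment of the bidirectional gene set against a population uses the
upper-tail hypergeometric test on propagated (true-path) annotations, with
Benjamini-Yekutieli adjustment applied within each ontology namespace.
Generic gene-set (pathway) enrichment over GMT collections uses the
one-sided Fisher's exact test (identical to the hypergeometric tail on the
2x2 margins) with Benjamini-Hochberg FDR.

Within-pair similarity intersects the two members' DIRECT term sets: under
propagation every annotated pair would trivially share namespace roots,
collapsing the shared-term distribution. An exploratory propagated mode
excludes root and depth-1 terms instead.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneAnnotationSet, OntologyGraph, NAMESPACES

logger = logging.getLogger(__name__)

ADJUST_METHODS = ("by", "bh", "none")


@dataclass(frozen=True)
class EnrichmentRecord:
    """One term's (or gene set's) enrichment statistics."""

    term_id: str
    name: str
    namespace: str  # ontology namespace or GMT collection name
    k: int  # study genes carrying the term
    n: int  # study size
    K: int  # population genes carrying the term
    N: int  # population size
    p_raw: float
    p_adjusted: float
    test: str

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K) and self.n <= self.N and self.K <= self.N):
            raise ValueError(
                f"{self.term_id}: inconsistent margins "
                f"k={self.k} n={self.n} K={self.K} N={self.N}"
            )


@dataclass(frozen=True)
class PairSimilarityRecord:
    """Shared direct GO terms between the two members of a gene pair."""

    pair_id: str
    plus_symbol: str
    minus_symbol: str
    shared_terms: frozenset[str]
    by_namespace: Mapping[str, frozenset[str]]
    plus_annotated: bool
    minus_annotated: bool

    @property
    def shared_count(self) -> int:
        return len(self.shared_terms)


def propagate_annotations(
    annotations: GeneAnnotationSet, ontology: OntologyGraph
) -> GeneAnnotationSet:
    """Close each gene's term set under is_a ancestors (true-path rule)."""
    closed: dict[str, set[str]] = {}
    for gene, terms in annotations.items():
        expanded: set[str] = set()
        for term in terms:
            if term not in ontology:
                raise ValueError(f"gene {gene!r} annotated to unknown term {term}")
            expanded.add(term)
            expanded.update(ontology.ancestors(term))
        closed[gene] = expanded
    return GeneAnnotationSet(closed)


def hypergeometric_p(k: int, n: int, K: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N population genes of which K carry the term; n drawn (the study set);
    k observed carriers among them.
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"invalid hypergeometric margins k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def _check_pvalues(pvalues: Sequence[float]) -> None:
    for p in pvalues:
        if not (0 <= p <= 1):
            raise ValueError(f"p-value {p} outside [0, 1]")


def adjust_yekutieli(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Yekutieli FDR adjustment (valid under arbitrary dependence).

    BH scaled by the harmonic sum c(m) = sum_{i<=m} 1/i, enforced monotone
    and capped at 1; input order is preserved.
    """
    _check_pvalues(pvalues)
    if len(pvalues) == 0:
        return []
    return list(multipletests(pvalues, method="fdr_by")[1])


def adjust_bh(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg FDR adjustment; input order preserved."""
    _check_pvalues(pvalues)
    if len(pvalues) == 0:
        return []
    return list(multipletests(pvalues, method="fdr_bh")[1])


def _adjust(pvalues: Sequence[float], method: str) -> list[float]:
    if method == "by":
        return adjust_yekutieli(pvalues)
    if method == "bh":
        return adjust_bh(pvalues)
    if method == "none":
        return list(pvalues)
    raise ValueError(f"unknown adjustment method {method!r}; pick one of {ADJUST_METHODS}")


def enrich_terms(
    study_genes: Iterable[str],
    population_genes: Iterable[str],
    annotations: GeneAnnotationSet,
    ontology: OntologyGraph,
    adjust: str = "by",
    propagate: bool = True,
) -> list[EnrichmentRecord]:
    """Hypergeometric enrichment of every term annotated to a study gene.

    Adjustment is applied within each namespace separately (the convention of
    GO enrichment tools); records are sorted by adjusted p then term id.
    """
    study = set(study_genes)
    population = set(population_genes)
    missing = sorted(study - population)
    if missing:
        raise ValueError(f"study genes absent from population: {missing}")
    if propagate:
        annotations = propagate_annotations(annotations, ontology)

    term_study: dict[str, int] = Counter()
    term_pop: dict[str, int] = Counter()
    for gene in population:
        for term in annotations.get(gene):
            term_pop[term] += 1
            if gene in study:
                term_study[term] += 1

    n, N = len(study), len(population)
    drafts: list[tuple[str, int, int, float]] = []
    for term, k in term_study.items():
        K = term_pop[term]
        drafts.append((term, k, K, hypergeometric_p(k, n, K, N)))

    # adjust within each namespace separately
    adjusted: dict[str, float] = {}
    for namespace in NAMESPACES:
        group = [d for d in drafts if ontology.namespace_of(d[0]) == namespace]
        values = _adjust([d[3] for d in group], adjust)
        for (term, *_), p_adj in zip(group, values):
            adjusted[term] = p_adj

    records = [
        EnrichmentRecord(
            term_id=term,
            name=ontology.terms[term].name,
            namespace=ontology.namespace_of(term),
            k=k,
            n=n,
            K=K,
            N=N,
            p_raw=p,
            p_adjusted=min(max(adjusted[term], p), 1.0),
            test="hypergeometric",
        )
        for term, k, K, p in drafts
    ]
    records.sort(key=lambda r: (r.p_adjusted, r.term_id))
    return records


def pair_shared_terms(
    pairs: Sequence,
    annotations: GeneAnnotationSet,
    ontology: OntologyGraph,
    propagated: bool = False,
    min_depth_when_propagated: int = 2,
) -> tuple[list[PairSimilarityRecord], dict]:
    """Within-pair shared-term records plus the shared-count distribution.

    ``pairs`` may be GenePair objects or (pair_id, plus_symbol, minus_symbol)
    triples. Annotations are taken as DIRECT by default; with
    ``propagated=True`` the ancestor closure is used but terms shallower than
    ``min_depth_when_propagated`` are excluded (roots are shared trivially).
    Unannotated members are flagged and contribute empty sets.
    """
    if propagated:
        annotations = propagate_annotations(annotations, ontology)

    records: list[PairSimilarityRecord] = []
    for pair in pairs:
        if hasattr(pair, "plus_gene"):
            pair_id = pair.pair_id
            plus_symbol = pair.plus_gene.gene_symbol
            minus_symbol = pair.minus_gene.gene_symbol
        else:
            pair_id, plus_symbol, minus_symbol = pair
        plus_terms = annotations.get(plus_symbol)
        minus_terms = annotations.get(minus_symbol)
        plus_annotated = plus_symbol in annotations
        minus_annotated = minus_symbol in annotations
        if not (plus_annotated and minus_annotated):
            logger.warning(
                "pair %s: unannotated member(s); shared set taken as empty",
                pair_id,
            )
        shared = plus_terms & minus_terms
        if propagated:
            shared = frozenset(
                t for t in shared if ontology.depth(t) >= min_depth_when_propagated
            )
        by_namespace = {
            ns: frozenset(t for t in shared if ontology.namespace_of(t) == ns)
            for ns in NAMESPACES
        }
        records.append(
            PairSimilarityRecord(
                pair_id=pair_id,
                plus_symbol=plus_symbol,
                minus_symbol=minus_symbol,
                shared_terms=frozenset(shared),
                by_namespace=by_namespace,
                plus_annotated=plus_annotated,
                minus_annotated=minus_annotated,
            )
        )

    histogram = Counter(r.shared_count for r in records)
    n_pairs = len(records)
    n_sharing = sum(1 for r in records if r.shared_count >= 1)
    summary = {
        "n_pairs": n_pairs,
        "n_sharing": n_sharing,
        "fraction_sharing": n_sharing / n_pairs if n_pairs else None,
        "histogram": dict(sorted(histogram.items())),
        "n_sharing_by_namespace": {
            ns: sum(1 for r in records if r.by_namespace[ns]) for ns in NAMESPACES
        },
    }
    return records, summary


def enrich_gene_sets(
    study_genes: Iterable[str],
    population_genes: Iterable[str],
    collections: Mapping[str, tuple[str, frozenset[str]]],
    adjust: str = "bh",
) -> list[EnrichmentRecord]:
    """One-sided Fisher's exact (upper-tail hypergeometric) test per gene set.

    Set members outside the population are ignored; empty (post-restriction)
    sets are skipped with a warning. FDR is applied across all sets in the
    collection.
    """
    study = set(study_genes)
    population = set(population_genes)
    missing = sorted(study - population)
    if missing:
        raise ValueError(f"study genes absent from population: {missing}")
    n, N = len(study), len(population)

    drafts = []
    for name, (description, genes) in collections.items():
        members = genes & population
        if not members:
            logger.warning("gene set %r has no members in the population; skipped", name)
            continue
        k = len(members & study)
        K = len(members)
        drafts.append((name, description, k, K, hypergeometric_p(k, n, K, N)))

    values = _adjust([d[4] for d in drafts], adjust)
    records = [
        EnrichmentRecord(
            term_id=name,
            name=description or name,
            namespace="gene_set",
            k=k,
            n=n,
            K=K,
            N=N,
            p_raw=p,
            p_adjusted=min(max(p_adj, p), 1.0),
            test="fisher_one_sided",
        )
        for (name, description, k, K, p), p_adj in zip(drafts, values)
    ]
    records.sort(key=lambda r: (r.p_adjusted, r.term_id))
    return records
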