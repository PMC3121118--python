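import pytest

from bidipromoter.io_formats import (
    GeneAnnotationSet,
    OntologyGraph,
    OntologyTerm,
)
from bidipromoter.pair_classification import GeneCluster
from bidipromoter.synthetic_data import SimulationConfig, generate_bundle


def make_cluster(
    chrom: str,
    strand: str,
    start: int,
    end: int,
    symbol: str = "G",
    evidence: str = "curated-mRNA",
) -> GeneCluster:
    return GeneCluster(
        cluster_id=f"{chrom}:{start}-{end}:{strand}",
        gene_symbol=symbol,
        chromosome=chrom,
        strand=strand,
        start=start,
        end=end,
        tss=start if strand == "+" else end,
        members=(),
        evidence_class=evidence,
    )


@pytest.fixture(scope="session")
def diamond_ontology() -> OntologyGraph:
    """A is the root; B and C are children of A; D inherits from both."""
    terms = [
        OntologyTerm("T:A", "root", "biological_process"),
        OntologyTerm("T:B", "left", "biological_process"),
        OntologyTerm("T:C", "right", "biological_process"),
        OntologyTerm("T:D", "leaf", "biological_process"),
        OntologyTerm("T:M", "mf root", "molecular_function"),
    ]
    edges = [("T:B", "T:A"), ("T:C", "T:A"), ("T:D", "T:B"), ("T:D", "T:C")]
    return OntologyGraph(terms, edges)


@pytest.fixture(scope="session")
def default_bundle():
    """One default-scale synthetic study, shared across tests (read-only)."""
    return generate_bundle(SimulationConfig(seed=1))


@pytest.fixture
def annotations_factory():
    def make(mapping) -> GeneAnnotationSet:
        return GeneAnnotationSet(mapping)

    return make
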