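import pytest

from fusionbench.annotation import (
    AnnotationSet,
    Exon,
    Gene,
    GenomeSeq,
    Transcript,
    load_annotation,
)
from fusionbench.fixtures import FixtureSpec, generate_fixture

FIXTURE_SPEC = FixtureSpec(
    n_chroms=2,
    chrom_length=100_000,
    n_genes=20,
    n_noncoding=2,
    n_paralog_pairs=3,
    n_similar_pairs=2,
    seed=11,
)


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    return generate_fixture(FIXTURE_SPEC, tmp_path_factory.mktemp("fixture"))


@pytest.fixture(scope="session")
def ann(fixture_paths):
    return load_annotation(
        fixture_paths["gtf"],
        fixture_paths["fasta"],
        fixture_paths["paralogs"],
        fixture_paths["similarity"],
        fixture_paths["annots"],
    )


def make_gene(gene_id, symbol, chrom, strand, exons, biotype="protein_coding", tx_id=None):
    """Hand-built single-transcript gene for unit tests."""
    tx = Transcript(tx_id or f"{gene_id}.t1", [Exon(s, e) for s, e in exons])
    return Gene(gene_id, symbol, chrom, strand, biotype, [tx])


def make_annotation(genomes: dict[str, str], genes: list[Gene]) -> AnnotationSet:
    """Minimal in-memory annotation bundle for unit tests."""
    genome = {c: GenomeSeq(c, s) for c, s in genomes.items()}
    gene_map = {g.gene_id: g for g in genes}
    symbol_index: dict[str, list[str]] = {}
    for g in genes:
        symbol_index.setdefault(g.symbol, []).append(g.gene_id)
    return AnnotationSet(genome=genome, genes=gene_map, symbol_index=symbol_index)
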