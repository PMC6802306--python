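"""Genome, gene-model, and auxiliary pair-table loading and queries.

This module owns the in-memory annotation bundle every other component
queries: chromosome sequences, gene/transcript/exon models parsed from GTF,
a paralog pair list, a gene-pair sequence-similarity table (tabular output
of an external all-vs-all nucleotide aligner), and a fusion-annotation
("red herring") label table.

All internal coordinates are 0-based, half-open.  GTF input (1-based,
inclusive) is converted on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

#: Fixed vocabulary for fusion-annotation labels.
ANNOT_LABELS = frozenset({"NORMAL", "MITOCHONDRIAL", "HLA", "IG_SEGMENT"})


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation inputs."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class GenomeSeq:
    """One chromosome: name plus uppercase DNA sequence."""

    chrom_name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise AnnotationError(f"chromosome {self.chrom_name!r} has empty sequence")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence on [start, end); out-of-bounds lookups are errors."""
        if start < 0 or end > len(self.sequence) or start > end:
            raise AnnotationError(
                f"coordinates [{start}, {end}) outside chromosome "
                f"{self.chrom_name!r} of length {len(self.sequence)}"
            )
        return self.sequence[start:end]


@dataclass(frozen=True, order=True)
class Exon:
    """Genomic exon interval, 0-based half-open."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise AnnotationError(f"exon start {self.start} must be < end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Transcript:
    transcript_id: str
    exons: list[Exon]

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"transcript {self.transcript_id!r}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class Gene:
    gene_id: str
    symbol: str
    chrom: str
    strand: str
    biotype: str
    transcripts: list[Transcript]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise AnnotationError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_id!r} has no transcripts")

    @property
    def span(self) -> tuple[int, int]:
        """Union span of all transcripts, half-open."""
        starts = [e.start for t in self.transcripts for e in t.exons]
        ends = [e.end for t in self.transcripts for e in t.exons]
        return min(starts), max(ends)

    def exons_in_transcription_order(self, transcript: Transcript) -> list[Exon]:
        return transcript.exons if self.strand == "+" else list(reversed(transcript.exons))


@dataclass
class ParalogDB:
    """Unordered symbol pairs flagged as likely paralogs."""

    pairs: set[frozenset] = field(default_factory=set)

    def add(self, sym_x: str, sym_y: str) -> None:
        if sym_x == sym_y:
            return  # no self-pairs
        self.pairs.add(frozenset((sym_x, sym_y)))

    def are_paralogs(self, sym_x: str, sym_y: str) -> bool:
        if sym_x == sym_y:
            return False
        return frozenset((sym_x, sym_y)) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


# A stored aligned region: ((chrom, start, end), (chrom, start, end))
AlignedRegionPair = tuple[tuple[str, int, int], tuple[str, int, int]]


@dataclass
class SimilarityDB:
    """Aligned genomic sub-regions between gene pairs.

    Keys are gene-id pairs in sorted order; each entry keeps the region on
    the first gene of the key paired with the region on the second.
    """

    entries: dict[tuple[str, str], list[AlignedRegionPair]] = field(default_factory=dict)

    def add(
        self,
        gene_x: str,
        gene_y: str,
        region_x: tuple[str, int, int],
        region_y: tuple[str, int, int],
    ) -> None:
        if gene_x <= gene_y:
            key, pair = (gene_x, gene_y), (region_x, region_y)
        else:
            key, pair = (gene_y, gene_x), (region_y, region_x)
        self.entries.setdefault(key, []).append(pair)

    def regions_for(self, gene_x: str, gene_y: str) -> list[AlignedRegionPair]:
        """Aligned regions with the first element on gene_x's side."""
        if gene_x <= gene_y:
            return self.entries.get((gene_x, gene_y), [])
        return [(b, a) for a, b in self.entries.get((gene_y, gene_x), [])]


@dataclass
class FusionAnnotDB:
    """Red-herring labels: per unordered symbol pair and per gene symbol."""

    pair_labels: dict[frozenset, set] = field(default_factory=dict)
    gene_labels: dict[str, set] = field(default_factory=dict)

    def add_pair(self, sym_x: str, sym_y: str, labels: Iterable[str]) -> None:
        labels = set(labels)
        self._check(labels)
        self.pair_labels.setdefault(frozenset((sym_x, sym_y)), set()).update(labels)

    def add_gene(self, sym: str, labels: Iterable[str]) -> None:
        labels = set(labels)
        self._check(labels)
        self.gene_labels.setdefault(sym, set()).update(labels)

    @staticmethod
    def _check(labels: set) -> None:
        bad = labels - ANNOT_LABELS
        if bad:
            raise AnnotationError(f"unknown fusion-annotation labels: {sorted(bad)}")

    def labels_for_pair(self, sym_x: str, sym_y: str) -> set:
        return set(self.pair_labels.get(frozenset((sym_x, sym_y)), set()))

    def labels_for_gene(self, sym: str) -> set:
        return set(self.gene_labels.get(sym, set()))


@dataclass
class AnnotationSet:
    """The full annotation bundle queried by all other modules."""

    genome: dict[str, GenomeSeq]
    genes: dict[str, Gene]
    symbol_index: dict[str, list[str]]
    paralogs: ParalogDB = field(default_factory=ParalogDB)
    similarity: SimilarityDB = field(default_factory=SimilarityDB)
    fusion_annots: FusionAnnotDB = field(default_factory=FusionAnnotDB)

    def gene(self, gene_id: str) -> Gene:
        try:
            return self.genes[gene_id]
        except KeyError:
            raise AnnotationError(f"unknown gene id {gene_id!r}") from None

    def genes_for_symbol(self, symbol: str) -> list[Gene]:
        return [self.genes[g] for g in self.symbol_index.get(symbol, [])]

    def symbol_of(self, gene_id: str) -> str:
        return self.gene(gene_id).symbol

    def protein_coding_genes(self) -> list[Gene]:
        return [g for g in self.genes.values() if g.biotype == "protein_coding"]

    def symbols_overlap(self, sym_x: str, sym_y: str) -> bool:
        """True if any gene with symbol sym_x genomically overlaps any with sym_y."""
        return any(
            genes_overlap(gx, gy)
            for gx in self.genes_for_symbol(sym_x)
            for gy in self.genes_for_symbol(sym_y)
        )


def _intervals_intersect(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def genes_overlap(gene_x: Gene, gene_y: Gene) -> bool:
    """Same chromosome and union gene spans intersect; strand is ignored."""
    return gene_x.chrom == gene_y.chrom and _intervals_intersect(gene_x.span, gene_y.span)


def are_paralogs(sym_x: str, sym_y: str, db: ParalogDB) -> bool:
    return db.are_paralogs(sym_x, sym_y)


def spliced_sequence(gene: Gene, transcript: Transcript, genome: GenomeSeq) -> str:
    """Transcript sequence: exon substrings concatenated in genomic order,
    reverse-complemented as one unit for minus-strand genes."""
    parts = [genome.fetch(e.start, e.end) for e in transcript.exons]
    seq = "".join(parts)
    return reverse_complement(seq) if gene.strand == "-" else seq


def similar_region_overlap(
    gene_x: Gene,
    gene_y: Gene,
    interval_x: tuple[int, int],
    interval_y: tuple[int, int],
    db: SimilarityDB,
) -> bool:
    """True iff the two read intervals both fall inside one stored aligned
    region pair between the two genes (same pairing, matching sides)."""
    for region_x, region_y in db.regions_for(gene_x.gene_id, gene_y.gene_id):
        chrom_x, sx, ex = region_x
        chrom_y, sy, ey = region_y
        if chrom_x != gene_x.chrom or chrom_y != gene_y.chrom:
            continue
        if _intervals_intersect(interval_x, (sx, ex)) and _intervals_intersect(
            interval_y, (sy, ey)
        ):
            return True
    return False


# ---------------------------------------------------------------------------
# Loading


def _read_fasta(fasta_path: Path) -> dict[str, GenomeSeq]:
    genome: dict[str, GenomeSeq] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        genome[rec.id] = GenomeSeq(rec.id, str(rec.seq))
    if not genome:
        raise AnnotationError(f"no FASTA records in {fasta_path}")
    return genome


def _parse_gtf(
    gtf_path: Path, genome: dict[str, GenomeSeq], biotype_keys: tuple[str, ...]
) -> tuple[dict[str, Gene], dict[str, list[str]]]:
    """Build gene models from GTF exon features.

    Only ``exon`` features are consulted; ``gene``/``transcript`` rows are
    tolerated but gene metadata is taken from the exon attributes, which
    both GENCODE-style and minimal GTFs carry.
    """
    # gene_id -> metadata and transcript_id -> exon list
    meta: dict[str, dict] = {}
    tx_exons: dict[str, list[Exon]] = {}
    tx_gene: dict[str, str] = {}
    gene_order: list[str] = []

    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise AnnotationError(
                    f"{gtf_path}:{lineno}: malformed GTF line (expected 9 tab-separated fields)"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted parse errors
                raise AnnotationError(f"{gtf_path}:{lineno}: cannot parse GTF line: {exc}") from exc
            if feat.featuretype != "exon":
                continue
            attrs = feat.attributes
            try:
                gene_id = attrs["gene_id"][0]
                tx_id = attrs["transcript_id"][0]
            except KeyError as exc:
                raise AnnotationError(
                    f"{gtf_path}:{lineno}: exon lacks gene_id/transcript_id attribute"
                ) from exc
            if feat.seqid not in genome:
                raise AnnotationError(
                    f"{gtf_path}:{lineno}: chromosome {feat.seqid!r} absent from FASTA"
                )
            symbol = attrs.get("gene_name", [gene_id])[0]
            biotype = "unknown"
            for key in biotype_keys:
                if key in attrs:
                    biotype = attrs[key][0]
                    break
            if gene_id not in meta:
                meta[gene_id] = {
                    "symbol": symbol,
                    "chrom": feat.seqid,
                    "strand": feat.strand,
                    "biotype": biotype,
                }
                gene_order.append(gene_id)
            elif meta[gene_id]["chrom"] != feat.seqid:
                raise AnnotationError(
                    f"{gtf_path}:{lineno}: gene {gene_id!r} spans multiple chromosomes"
                )
            # GTF is 1-based inclusive; convert to 0-based half-open.
            exon = Exon(feat.start - 1, feat.end)
            chrom_len = len(genome[feat.seqid])
            if exon.end > chrom_len:
                raise AnnotationError(
                    f"{gtf_path}:{lineno}: exon [{exon.start},{exon.end}) exceeds "
                    f"chromosome {feat.seqid!r} length {chrom_len}"
                )
            tx_exons.setdefault(tx_id, []).append(exon)
            tx_gene[tx_id] = gene_id

    genes: dict[str, Gene] = {}
    gene_tx: dict[str, list[Transcript]] = {g: [] for g in gene_order}
    for tx_id, exons in tx_exons.items():
        gene_tx[tx_gene[tx_id]].append(Transcript(tx_id, exons))
    for gene_id in gene_order:
        m = meta[gene_id]
        genes[gene_id] = Gene(
            gene_id, m["symbol"], m["chrom"], m["strand"], m["biotype"], gene_tx[gene_id]
        )
    symbol_index: dict[str, list[str]] = {}
    for gene_id, gene in genes.items():
        symbol_index.setdefault(gene.symbol, []).append(gene_id)
    return genes, symbol_index


def _parse_region(token: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (0-based half-open)."""
    try:
        chrom, rng = token.rsplit(":", 1)
        start, end = rng.split("-")
        return chrom, int(start), int(end)
    except ValueError as exc:
        raise AnnotationError(f"cannot parse genomic region {token!r}") from exc


def _data_lines(path: Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def load_paralogs(path: Path) -> ParalogDB:
    db = ParalogDB()
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise AnnotationError(f"{path}:{lineno}: paralog row needs 2 columns")
        db.add(fields[0], fields[1])
    return db


def load_similarity(path: Path) -> SimilarityDB:
    db = SimilarityDB()
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise AnnotationError(f"{path}:{lineno}: similarity row needs 4 columns")
        db.add(fields[0], fields[1], _parse_region(fields[2]), _parse_region(fields[3]))
    return db


def load_fusion_annots(path: Path) -> FusionAnnotDB:
    db = FusionAnnotDB()
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise AnnotationError(f"{path}:{lineno}: annotation row needs 2 columns")
        name, labels = fields[0], [x for x in fields[1].split(",") if x]
        if "--" in name:
            sym_x, sym_y = name.split("--", 1)
            db.add_pair(sym_x, sym_y, labels)
        else:
            db.add_gene(name, labels)
    return db


def load_annotation(
    gtf_path,
    fasta_path,
    paralog_path=None,
    similarity_path=None,
    annot_path=None,
    biotype_keys: tuple[str, ...] = ("gene_biotype", "gene_type"),
) -> AnnotationSet:
    """Load the annotation bundle; see module docstring for conventions.

    ``biotype_keys`` lists the GTF attribute keys (in priority order) that
    carry the gene biotype, accommodating GTF dialect differences.
    """
    genome = _read_fasta(Path(fasta_path))
    genes, symbol_index = _parse_gtf(Path(gtf_path), genome, biotype_keys)
    ann = AnnotationSet(genome=genome, genes=genes, symbol_index=symbol_index)
    if paralog_path is not None:
        ann.paralogs = load_paralogs(Path(paralog_path))
    if similarity_path is not None:
        ann.similarity = load_similarity(Path(similarity_path))
    if annot_path is not None:
        ann.fusion_annots = load_fusion_annots(Path(annot_path))
    # validate similarity intervals lie within the referenced gene spans
    for (ga, gb), pairs in ann.similarity.entries.items():
        for (ca, sa, ea), (cb, sb, eb) in pairs:
            for gid, (c, s, e) in ((ga, (ca, sa, ea)), (gb, (cb, sb, eb))):
                if gid in ann.genes:
                    gene = ann.genes[gid]
                    lo, hi = gene.span
                    if c != gene.chrom or s < lo or e > hi:
                        logger.warning(
                            "similarity region %s:%d-%d outside span of gene %s", c, s, e, gid
                        )
    logger.info(
        "loaded %d chromosomes, %d genes, %d paralog pairs, %d similarity pairs",
        len(genome),
        len(genes),
        len(ann.paralogs),
        len(ann.similarity.entries),
    )
    return ann
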