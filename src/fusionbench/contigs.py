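"""Breakpoint validation for de novo assembled chimeric contigs.

A candidate chimeric contig is split around its putative breakpoint with
fixed overhangs; each piece's alignment is extended base-by-base into the
overhang against the reference genome (an ungapped exact-match extension
standing in for a spliced realigner).  Contigs whose alignments extend too
far past the junction are eliminated as likely assembly artifacts between
sequence-similar genes.  Survivors additionally need reference-spliced
breakpoints, minimum read support, and sufficient breakpoint sequence
complexity (Shannon entropy) when only junction-overlapping reads support
them.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

from .annotation import AnnotationSet, GenomeSeq, reverse_complement
from .chimeric import FilterConfig, FusionCandidate, SampleContext, compute_ffpm

logger = logging.getLogger(__name__)

DEFAULT_OVERHANG = 25
MAX_OVERHANG_EXTENSION = 12  # "beyond 12 bases" eliminates, so 12 still passes
MIN_BREAKPOINT_ENTROPY = 1.5
ENTROPY_WINDOW = 12


class ContigError(ValueError):
    pass


@dataclass
class ChimericContig:
    contig_id: str
    sequence: str
    breakpoint_index: int  # 0-based offset of the first base of the 3' segment
    geneA_id: str
    geneB_id: str
    splice_ref: bool
    locusA: tuple[str, int, int]
    locusB: tuple[str, int, int]

    def __post_init__(self) -> None:
        if not 0 < self.breakpoint_index < len(self.sequence):
            raise ContigError(
                f"contig {self.contig_id!r}: breakpoint {self.breakpoint_index} "
                f"outside (0, {len(self.sequence)})"
            )


@dataclass
class OverhangSplit:
    left_piece: str
    right_piece: str
    left_native_len: int
    right_native_len: int


@dataclass
class ContigReadSupport:
    junction_frags: int = 0
    spanning_frags: int = 0

    def __post_init__(self) -> None:
        if self.junction_frags < 0 or self.spanning_frags < 0:
            raise ContigError("support counts must be non-negative")


def split_with_overhangs(contig: ChimericContig, overhang: int = DEFAULT_OVERHANG) -> OverhangSplit:
    """Split at the breakpoint with ``overhang`` extra bases on each piece,
    truncated at the contig ends."""
    bp, n = contig.breakpoint_index, len(contig.sequence)
    left_end = min(bp + overhang, n)
    right_start = max(bp - overhang, 0)
    return OverhangSplit(
        left_piece=contig.sequence[:left_end],
        right_piece=contig.sequence[right_start:],
        left_native_len=bp,
        right_native_len=n - bp,
    )


def measure_overhang_extension(
    piece: str,
    native_len: int,
    locus: tuple[str, int, int],
    genome: GenomeSeq,
    side: str = "left",
    strand: str = "+",
) -> int:
    """Bases of the overhang that continue to match the genome when the
    native alignment is extended base-by-base (ungapped, exact match).

    For the left piece the native segment aligns ending at ``locus`` end
    and the overhang extends rightward past it; for the right piece the
    native segment aligns starting at ``locus`` start and the overhang
    extends leftward before it.  Minus-strand loci compare against the
    reverse complement.
    """
    chrom, lo, hi = locus
    if chrom != genome.chrom_name:
        raise ContigError(f"locus chromosome {chrom!r} does not match genome {genome.chrom_name!r}")
    if not 0 <= lo <= hi <= len(genome):
        raise ContigError(f"locus {locus} outside genome bounds")
    if side == "left":
        overhang = piece[native_len:]
    elif side == "right":
        overhang = piece[: len(piece) - native_len][::-1]  # junction-outward order
    else:
        raise ContigError(f"side must be 'left' or 'right', got {side!r}")
    if not overhang:
        return 0

    if strand == "+":
        if side == "left":
            genomic = genome.fetch(hi, min(hi + len(overhang), len(genome)))
        else:
            genomic = genome.fetch(max(lo - len(overhang), 0), lo)[::-1]
    else:
        # native alignment on the minus strand: extension continues on the
        # opposite genomic side, read as reverse complement
        if side == "left":
            genomic = reverse_complement(genome.fetch(max(lo - len(overhang), 0), lo))
        else:
            genomic = reverse_complement(genome.fetch(hi, min(hi + len(overhang), len(genome))))[::-1]

    ext = 0
    for a, b in zip(overhang, genomic):
        if a != b:
            break
        ext += 1
    return ext


def fuzzy_overhang_filter(
    ext_a: int, ext_b: int, max_ext: int = MAX_OVERHANG_EXTENSION
) -> bool:
    """Keep unless either alignment extends *beyond* ``max_ext`` bases into
    the overhang (strict reading: an extension of exactly 12 passes)."""
    return ext_a <= max_ext and ext_b <= max_ext


def shannon_entropy(window: str) -> float:
    """Base-2 Shannon entropy of mononucleotide frequencies."""
    counts = Counter(window)
    n = len(window)
    return -sum((c / n) * math.log2(c / n) for c in counts.values()) + 0.0


def breakpoint_entropy(
    contig: ChimericContig, window: int = ENTROPY_WINDOW
) -> tuple[float, float]:
    """Entropy of the windows immediately left and right of the breakpoint."""
    bp, n = contig.breakpoint_index, len(contig.sequence)
    if bp < window or n - bp < window:
        raise ContigError(
            f"contig {contig.contig_id!r} too short for a {window}-base window on both sides"
        )
    left = contig.sequence[bp - window : bp]
    right = contig.sequence[bp : bp + window]
    return shannon_entropy(left), shannon_entropy(right)


def count_read_support(
    contig: ChimericContig,
    alignments: list[tuple[str, str, int, int, str]],
    min_anchor: int = 1,
) -> ContigReadSupport:
    """Classify read-to-contig alignments into junction and spanning
    fragments.

    ``alignments`` rows are (read_id, contig_id, start, end, mate_id);
    a fragment is a junction fragment if any of its reads covers the
    breakpoint with at least ``min_anchor`` bases on each side, and a
    spanning fragment if its mates lie entirely on opposite sides.
    """
    bp = contig.breakpoint_index
    frags: dict[frozenset, list[tuple[int, int]]] = {}
    for read_id, contig_id, start, end, mate_id in alignments:
        if contig_id != contig.contig_id:
            continue
        frags.setdefault(frozenset((read_id, mate_id)), []).append((start, end))
    junction = spanning = 0
    for intervals in frags.values():
        crosses = any(s <= bp - min_anchor and e >= bp + min_anchor for s, e in intervals)
        if crosses:
            junction += 1
            continue
        left = any(e <= bp for s, e in intervals)
        right = any(s >= bp for s, e in intervals)
        if left and right and len(intervals) >= 2:
            spanning += 1
    return ContigReadSupport(junction_frags=junction, spanning_frags=spanning)


def support_and_validate(
    contig: ChimericContig,
    support: ContigReadSupport,
    ext_a: int,
    ext_b: int,
    max_ext: int = MAX_OVERHANG_EXTENSION,
    min_entropy: float = MIN_BREAKPOINT_ENTROPY,
    entropy_window: int = ENTROPY_WINDOW,
) -> bool:
    """Full validation: reference-spliced breakpoint, fuzzy overhang pass,
    >=2 supporting fragments, and breakpoint complexity when support is
    junction-only."""
    if not contig.splice_ref:
        logger.debug("contig %s rejected: breakpoint not at reference splice sites", contig.contig_id)
        return False
    if not fuzzy_overhang_filter(ext_a, ext_b, max_ext):
        logger.debug("contig %s rejected: overhang extension (%d, %d)", contig.contig_id, ext_a, ext_b)
        return False
    if support.junction_frags + support.spanning_frags < 2:
        logger.debug("contig %s rejected: insufficient read support", contig.contig_id)
        return False
    if support.spanning_frags < 1:
        ent_l, ent_r = breakpoint_entropy(contig, entropy_window)
        if ent_l < min_entropy or ent_r < min_entropy:
            logger.debug(
                "contig %s rejected: breakpoint entropy (%.3f, %.3f)", contig.contig_id, ent_l, ent_r
            )
            return False
    return True


def contig_to_candidate(
    contig: ChimericContig,
    support: ContigReadSupport,
    ann: AnnotationSet,
    ctx: SampleContext,
) -> FusionCandidate:
    """Shared prediction-record form, so validated contigs can pass through
    the same advanced filters as read-mapping candidates."""
    return FusionCandidate(
        geneA_id=contig.geneA_id,
        geneB_id=contig.geneB_id,
        breakpointA=contig.locusA[2],
        breakpointB=contig.locusB[1],
        junction_reads=support.junction_frags,
        spanning_frags=support.spanning_frags,
        splice_ref=contig.splice_ref,
        max_anchor_A=0,
        max_anchor_B=0,
        ffpm=compute_ffpm(support.junction_frags + support.spanning_frags, ctx.total_fragments),
        symA=ann.symbol_of(contig.geneA_id),
        symB=ann.symbol_of(contig.geneB_id),
    )


def validate_contigs(
    contigs: list[ChimericContig],
    supports: dict[str, ContigReadSupport],
    extensions: dict[str, tuple[int, int]],
    ann: AnnotationSet,
    ctx: SampleContext,
    config: FilterConfig | None = None,
    max_ext: int = MAX_OVERHANG_EXTENSION,
    min_entropy: float = MIN_BREAKPOINT_ENTROPY,
) -> list[FusionCandidate]:
    """Validate each contig, then run survivors through the advanced
    (paralog / promiscuity / red-herring) filters shared with the
    read-mapping cascade."""
    from .chimeric import paralog_filter, promiscuity_filter, red_herring_filter

    cands = []
    for contig in contigs:
        support = supports.get(contig.contig_id, ContigReadSupport())
        ext_a, ext_b = extensions.get(contig.contig_id, (0, 0))
        if support_and_validate(contig, support, ext_a, ext_b, max_ext, min_entropy):
            cands.append(contig_to_candidate(contig, support, ann, ctx))
    cands = paralog_filter(cands, ann)
    cands = promiscuity_filter(cands, config)
    cands = red_herring_filter(cands, ann)
    return sorted(cands, key=lambda c: (-c.evidence, c.fusion_name))


# ---------------------------------------------------------------------------
# Tabular I/O


def read_breakpoints_tsv(path, contig_seqs: dict[str, str]) -> list[ChimericContig]:
    """Breakpoint table: contig_id, breakpoint_index, geneA, geneB,
    splice_ref, locusA (chrom:start-end), locusB."""
    from .annotation import _parse_region

    contigs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("contig_id\t"):
                continue
            f = line.split("\t")
            if len(f) < 7:
                raise ContigError(f"{path}:{lineno}: expected 7 columns")
            if f[0] not in contig_seqs:
                raise ContigError(f"{path}:{lineno}: contig {f[0]!r} absent from FASTA")
            contigs.append(
                ChimericContig(
                    contig_id=f[0],
                    sequence=contig_seqs[f[0]],
                    breakpoint_index=int(f[1]),
                    geneA_id=f[2],
                    geneB_id=f[3],
                    splice_ref=bool(int(f[4])),
                    locusA=_parse_region(f[5]),
                    locusB=_parse_region(f[6]),
                )
            )
    return contigs


def read_alignments_tsv(path) -> list[tuple[str, str, int, int, str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("read_id\t"):
                continue
            f = line.split("\t")
            rows.append((f[0], f[1], int(f[2]), int(f[3]), f[4]))
    return rows


def read_extensions_tsv(path) -> dict[str, tuple[int, int]]:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("contig_id\t"):
                continue
            f = line.split("\t")
            out[f[0]] = (int(f[1]), int(f[2]))
    return out
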