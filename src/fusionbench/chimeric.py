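"""Chimeric-read evidence aggregation and the fusion filtering cascade.

Chimeric alignment records (split reads and spanning read pairs) are turned
into per-gene-pair fusion candidates, which then pass through a fixed
cascade: sequence-similarity exclusion, duplicate removal, sense-sense
aggregation, a basic evidence filter, and four "advanced" filters
(paralogs, promiscuous partners, red-herring annotations, and a
depth-normalized expression threshold in fusion fragments per million,
FFPM).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .annotation import AnnotationSet, Gene, similar_region_overlap

logger = logging.getLogger(__name__)

SPLIT = "SPLIT"
SPANNING = "SPANNING"

#: Advanced-filter defaults (all configurable via FilterConfig).
MIN_FFPM = 0.1
PROMISCUITY_FACTOR = 20
PROMISCUITY_MAX_PARTNERS = 10
MIN_ANCHOR = 25
MIN_SPLIT_NONREF = 3


class FilterError(ValueError):
    pass


@dataclass(frozen=True)
class ChimericEvent:
    read_id: str
    kind: str  # SPLIT or SPANNING
    geneA_id: str  # 5' side in transcript sense
    geneB_id: str
    breakpointA: int
    breakpointB: int
    intervalA: tuple[int, int]
    intervalB: tuple[int, int]
    anchorA_len: int = 0
    anchorB_len: int = 0
    splice_ref: bool = False
    sense_sense: bool = True

    def __post_init__(self) -> None:
        if self.kind == SPLIT and (self.anchorA_len <= 0 or self.anchorB_len <= 0):
            raise FilterError("SPLIT events require positive anchor lengths")
        if self.kind == SPANNING and (self.anchorA_len or self.anchorB_len):
            raise FilterError("SPANNING events must have zero anchor lengths")


@dataclass
class FusionCandidate:
    geneA_id: str
    geneB_id: str
    breakpointA: int
    breakpointB: int
    junction_reads: int
    spanning_frags: int
    splice_ref: bool
    max_anchor_A: int
    max_anchor_B: int
    ffpm: float = 0.0
    symA: str = ""
    symB: str = ""

    @property
    def evidence(self) -> int:
        return self.junction_reads + self.spanning_frags

    @property
    def fusion_name(self) -> str:
        return f"{self.symA or self.geneA_id}--{self.symB or self.geneB_id}"


@dataclass
class SampleContext:
    total_fragments: int

    def __post_init__(self) -> None:
        if self.total_fragments <= 0:
            raise FilterError("total_fragments must be positive")


@dataclass
class FilterConfig:
    min_ffpm: float = MIN_FFPM
    promiscuity_factor: int = PROMISCUITY_FACTOR
    promiscuity_max_partners: int = PROMISCUITY_MAX_PARTNERS
    min_anchor: int = MIN_ANCHOR
    min_split_nonref: int = MIN_SPLIT_NONREF


# ---------------------------------------------------------------------------
# Stage 1: alignment-level exclusion and deduplication


def exclude_similar_alignments(
    events: list[ChimericEvent], ann: AnnotationSet
) -> list[ChimericEvent]:
    """Drop events whose two aligned intervals fall inside a stored
    aligned-region pair between the two genes (likely mismapping between
    sequence-similar genes)."""
    kept = []
    for ev in events:
        gene_a = ann.gene(ev.geneA_id)
        gene_b = ann.gene(ev.geneB_id)
        if similar_region_overlap(gene_a, gene_b, ev.intervalA, ev.intervalB, ann.similarity):
            logger.debug("similar-region exclusion: %s %s--%s", ev.read_id, ev.geneA_id, ev.geneB_id)
            continue
        kept.append(ev)
    return kept


def _dup_key(ev: ChimericEvent):
    # read id deliberately excluded: identical placements are PCR/optical
    # duplicates regardless of read name
    return (ev.kind, ev.geneA_id, ev.geneB_id, ev.intervalA, ev.intervalB,
            ev.breakpointA, ev.breakpointB)


def dedup_events(events: list[ChimericEvent]) -> list[ChimericEvent]:
    seen = set()
    kept = []
    for ev in events:
        key = _dup_key(ev)
        if key in seen:
            continue
        seen.add(key)
        kept.append(ev)
    return kept


# ---------------------------------------------------------------------------
# Stage 2: candidate aggregation


def compute_ffpm(supporting_fragments: int, total_fragments: int) -> float:
    """Fusion fragments per million total RNA-seq fragments."""
    if total_fragments <= 0:
        raise FilterError("total_fragments must be positive")
    return supporting_fragments * 1e6 / total_fragments


def _span_supports(ev: ChimericEvent, cand: FusionCandidate, ann: AnnotationSet) -> bool:
    """A spanning pair supports a breakpoint whose junction lies downstream
    (transcript sense) of the geneA mate and upstream of the geneB mate."""
    gene_a = ann.gene(ev.geneA_id)
    gene_b = ann.gene(ev.geneB_id)
    if gene_a.strand == "+":
        ok_a = cand.breakpointA >= ev.intervalA[0]
    else:
        ok_a = cand.breakpointA <= ev.intervalA[1]
    if gene_b.strand == "+":
        ok_b = cand.breakpointB <= ev.intervalB[1]
    else:
        ok_b = cand.breakpointB >= ev.intervalB[0]
    return ok_a and ok_b


def aggregate_candidates(
    events: list[ChimericEvent], ann: AnnotationSet, ctx: SampleContext
) -> list[FusionCandidate]:
    """Group sense-sense events into per-breakpoint fusion candidates.

    SPLIT events define breakpoint groups; each SPANNING fragment is counted
    once, toward the qualifying breakpoint of its gene pair with the most
    split support (ties resolved toward the 5'-most breakpoint).  Spanning
    fragments of a pair with no split-defined breakpoint form a single
    nominal candidate so downstream stages see every pair.
    """
    sense = [ev for ev in events if ev.sense_sense]
    for ev in events:
        if not ev.sense_sense:
            logger.debug("antisense evidence dropped: %s", ev.read_id)

    groups: dict[tuple, FusionCandidate] = {}
    for ev in sense:
        if ev.kind != SPLIT:
            continue
        key = (ev.geneA_id, ev.geneB_id, ev.breakpointA, ev.breakpointB)
        cand = groups.get(key)
        if cand is None:
            cand = FusionCandidate(
                geneA_id=ev.geneA_id,
                geneB_id=ev.geneB_id,
                breakpointA=ev.breakpointA,
                breakpointB=ev.breakpointB,
                junction_reads=0,
                spanning_frags=0,
                splice_ref=ev.splice_ref,
                max_anchor_A=0,
                max_anchor_B=0,
                symA=ann.symbol_of(ev.geneA_id),
                symB=ann.symbol_of(ev.geneB_id),
            )
            groups[key] = cand
        cand.junction_reads += 1
        cand.splice_ref = cand.splice_ref or ev.splice_ref
        cand.max_anchor_A = max(cand.max_anchor_A, ev.anchorA_len)
        cand.max_anchor_B = max(cand.max_anchor_B, ev.anchorB_len)

    by_pair: dict[tuple, list[FusionCandidate]] = {}
    for cand in groups.values():
        by_pair.setdefault((cand.geneA_id, cand.geneB_id), []).append(cand)

    orphan_spans: dict[tuple, list[ChimericEvent]] = {}
    for ev in sense:
        if ev.kind != SPANNING:
            continue
        pair = (ev.geneA_id, ev.geneB_id)
        qualifying = [c for c in by_pair.get(pair, []) if _span_supports(ev, c, ann)]
        if qualifying:
            strand_a = ann.gene(ev.geneA_id).strand
            # most split support, then 5'-most junction in transcript sense
            qualifying.sort(
                key=lambda c: (
                    -c.junction_reads,
                    c.breakpointA if strand_a == "+" else -c.breakpointA,
                )
            )
            qualifying[0].spanning_frags += 1
        else:
            orphan_spans.setdefault(pair, []).append(ev)

    candidates = list(groups.values())
    for (ga, gb), evs in orphan_spans.items():
        ev0 = evs[0]
        candidates.append(
            FusionCandidate(
                geneA_id=ga,
                geneB_id=gb,
                breakpointA=ev0.intervalA[1],
                breakpointB=ev0.intervalB[0],
                junction_reads=0,
                spanning_frags=len(evs),
                splice_ref=False,
                max_anchor_A=0,
                max_anchor_B=0,
                symA=ann.symbol_of(ga),
                symB=ann.symbol_of(gb),
            )
        )
    for cand in candidates:
        cand.ffpm = compute_ffpm(cand.evidence, ctx.total_fragments)
    return candidates


# ---------------------------------------------------------------------------
# Stage 3: basic and advanced filters


def basic_filter(cand: FusionCandidate, config: FilterConfig | None = None) -> bool:
    """Minimum-evidence rules: >=2 supporting fragments with >=1 split read;
    non-reference breakpoints need >=3 split reads; split-only support
    needs >=25-base anchors on both sides of the junction."""
    cfg = config or FilterConfig()
    if cand.junction_reads + cand.spanning_frags < 2:
        return False
    if cand.junction_reads < 1:
        return False
    if not cand.splice_ref and cand.junction_reads < cfg.min_split_nonref:
        return False
    if cand.spanning_frags < 1 and not (
        cand.max_anchor_A >= cfg.min_anchor and cand.max_anchor_B >= cfg.min_anchor
    ):
        return False
    return True


def apply_basic_filter(
    cands: list[FusionCandidate], config: FilterConfig | None = None
) -> list[FusionCandidate]:
    kept = []
    for c in cands:
        if basic_filter(c, config):
            kept.append(c)
        else:
            logger.debug("basic filter removed %s", c.fusion_name)
    return kept


def paralog_filter(cands: list[FusionCandidate], ann: AnnotationSet) -> list[FusionCandidate]:
    """Remove mutual-paralog pairs; among candidates sharing one partner
    whose other partners are paralogs of each other, keep only the
    evidence-dominant candidate (strict dominance; ties keep both)."""
    kept = [
        c for c in cands if not ann.paralogs.are_paralogs(c.symA, c.symB)
    ]
    for c in cands:
        if ann.paralogs.are_paralogs(c.symA, c.symB):
            logger.debug("paralog filter removed mutual-paralog pair %s", c.fusion_name)

    doomed: set[int] = set()
    for i, ci in enumerate(kept):
        for j, cj in enumerate(kept):
            if i == j:
                continue
            # shared 5' partner, 3' partners paralogous
            if ci.geneA_id == cj.geneA_id and ann.paralogs.are_paralogs(ci.symB, cj.symB):
                if ci.evidence > cj.evidence:
                    doomed.add(j)
            # shared 3' partner, 5' partners paralogous
            if ci.geneB_id == cj.geneB_id and ann.paralogs.are_paralogs(ci.symA, cj.symA):
                if ci.evidence > cj.evidence:
                    doomed.add(j)
    for j in sorted(doomed):
        logger.debug("paralog filter removed dominated candidate %s", kept[j].fusion_name)
    return [c for j, c in enumerate(kept) if j not in doomed]


def promiscuity_filter(
    cands: list[FusionCandidate], config: FilterConfig | None = None
) -> list[FusionCandidate]:
    """Per gene: drop alternatives with at most 1/20 of the dominant
    partner's evidence, then drop every candidate of any gene that still
    has ten or more fusion partners."""
    cfg = config or FilterConfig()

    def genes_of(c: FusionCandidate):
        return (c.geneA_id, c.geneB_id)

    best: dict[str, int] = {}
    for c in cands:
        for g in genes_of(c):
            best[g] = max(best.get(g, 0), c.evidence)
    kept = []
    for c in cands:
        dominated = any(
            best[g] >= cfg.promiscuity_factor * c.evidence and best[g] > c.evidence
            for g in genes_of(c)
        )
        if dominated:
            logger.debug("promiscuity filter removed dominated %s", c.fusion_name)
        else:
            kept.append(c)

    partners: dict[str, set] = {}
    for c in kept:
        partners.setdefault(c.geneA_id, set()).add(c.geneB_id)
        partners.setdefault(c.geneB_id, set()).add(c.geneA_id)
    promiscuous = {g for g, p in partners.items() if len(p) >= cfg.promiscuity_max_partners}
    final = []
    for c in kept:
        if c.geneA_id in promiscuous or c.geneB_id in promiscuous:
            logger.debug("promiscuity filter removed %s (promiscuous partner)", c.fusion_name)
        else:
            final.append(c)
    return final


def red_herring_filter(
    cands: list[FusionCandidate], ann: AnnotationSet
) -> list[FusionCandidate]:
    """Drop pairs seen in normal samples, pairs with a mitochondrial or HLA
    partner, and pairs where both genes are immunoglobulin segments."""
    db = ann.fusion_annots
    kept = []
    for c in cands:
        pair_labels = db.labels_for_pair(c.symA, c.symB)
        labels_a = db.labels_for_gene(c.symA)
        labels_b = db.labels_for_gene(c.symB)
        if "NORMAL" in pair_labels:
            logger.debug("red-herring filter removed %s (NORMAL)", c.fusion_name)
            continue
        if {"MITOCHONDRIAL", "HLA"} & (labels_a | labels_b):
            logger.debug("red-herring filter removed %s (MITO/HLA partner)", c.fusion_name)
            continue
        if "IG_SEGMENT" in labels_a and "IG_SEGMENT" in labels_b:
            logger.debug("red-herring filter removed %s (both IG segments)", c.fusion_name)
            continue
        kept.append(c)
    return kept


def expression_filter(
    cands: list[FusionCandidate], ctx: SampleContext, config: FilterConfig | None = None
) -> list[FusionCandidate]:
    """Keep candidates with FFPM at or above the threshold (boundary
    inclusive: the rule discards candidates with *less* support)."""
    cfg = config or FilterConfig()
    kept = []
    for c in cands:
        if c.ffpm >= cfg.min_ffpm:
            kept.append(c)
        else:
            logger.debug("expression filter removed %s (ffpm=%.4g)", c.fusion_name, c.ffpm)
    return kept


def run_filter_pipeline(
    events: list[ChimericEvent],
    ann: AnnotationSet,
    ctx: SampleContext,
    config: FilterConfig | None = None,
) -> list[FusionCandidate]:
    """Full cascade; survivors sorted by descending evidence, then name."""
    cfg = config or FilterConfig()
    events = exclude_similar_alignments(events, ann)
    events = dedup_events(events)
    cands = aggregate_candidates(events, ann, ctx)
    cands = apply_basic_filter(cands, cfg)
    cands = paralog_filter(cands, ann)
    cands = promiscuity_filter(cands, cfg)
    cands = red_herring_filter(cands, ann)
    cands = expression_filter(cands, ctx, cfg)
    return sorted(cands, key=lambda c: (-c.evidence, c.fusion_name))


# ---------------------------------------------------------------------------
# Input dialects

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def _cigar_ref_span_and_anchor(cigar: str) -> tuple[int, int]:
    """Reference bases consumed and aligned (M/=/X) bases of a CIGAR."""
    ref = aligned = 0
    for n, op in _CIGAR_RE.findall(cigar):
        n = int(n)
        if op in "MDN=X":
            ref += n
        if op in "M=X":
            aligned += n
    return ref, aligned


def _gene_at(ann: AnnotationSet, chrom: str, interval: tuple[int, int]) -> Gene | None:
    """Gene whose exons overlap the interval most (coordinate overlap)."""
    best, best_overlap = None, 0
    for gene in ann.genes.values():
        if gene.chrom != chrom:
            continue
        lo, hi = gene.span
        if interval[0] >= hi or interval[1] <= lo:
            continue
        overlap = 0
        for tx in gene.transcripts:
            for e in tx.exons:
                overlap = max(
                    overlap, min(interval[1], e.end) - max(interval[0], e.start)
                )
        if overlap > best_overlap:
            best, best_overlap = gene, overlap
    return best


def _splice_boundaries(gene: Gene, side: str) -> set:
    """Annotated exon boundaries at which a breakpoint is reference-spliced.

    side 'donor': transcription-sense 3' exon edges; 'acceptor': 5' edges.
    """
    out = set()
    for tx in gene.transcripts:
        for e in tx.exons:
            if side == "donor":
                out.add(e.end if gene.strand == "+" else e.start)
            else:
                out.add(e.start if gene.strand == "+" else e.end)
    return out


def parse_star_junctions(path, ann: AnnotationSet) -> list[ChimericEvent]:
    """Parse a STAR ``Chimeric.out.junction``-style TSV.

    Columns: chrA, posA (1-based; donor-side intron base), strandA, chrB,
    posB, strandB, junction_type (-1 for spanning pairs), repeat_left,
    repeat_right, read_name, startA (1-based), cigarA, startB, cigarB.
    Segments are assigned to genes by exon-coordinate overlap; records whose
    segments cannot be assigned to two distinct genes are dropped with a
    logged reason.
    """
    events = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 14:
                raise FilterError(f"{path}:{lineno}: expected >=14 columns")
            (chr_a, pos_a, strand_a, chr_b, pos_b, strand_b, jtype, _rl, _rr,
             read_id, start_a, cigar_a, start_b, cigar_b) = fields[:14]
            jtype = int(jtype)
            span_a, anchor_a = _cigar_ref_span_and_anchor(cigar_a)
            span_b, anchor_b = _cigar_ref_span_and_anchor(cigar_b)
            interval_a = (int(start_a) - 1, int(start_a) - 1 + span_a)
            interval_b = (int(start_b) - 1, int(start_b) - 1 + span_b)
            gene_a = _gene_at(ann, chr_a, interval_a)
            gene_b = _gene_at(ann, chr_b, interval_b)
            if gene_a is None or gene_b is None or gene_a.gene_id == gene_b.gene_id:
                logger.debug("%s:%d: segments not assignable to two genes", path, lineno)
                continue
            if jtype < 0:
                kind = SPANNING
                bp_a = interval_a[1] if gene_a.strand == "+" else interval_a[0]
                bp_b = interval_b[0] if gene_b.strand == "+" else interval_b[1]
                anchor_a = anchor_b = 0
                splice_ref = False
            else:
                kind = SPLIT
                # STAR reports the first intronic base after the donor
                # segment and the last intronic base before the acceptor
                bp_a = int(pos_a) - 1 if strand_a == "+" else int(pos_a)
                bp_b = int(pos_b) if strand_b == "+" else int(pos_b) - 1
                splice_ref = bp_a in _splice_boundaries(gene_a, "donor") and bp_b in _splice_boundaries(gene_b, "acceptor")
            sense = strand_a == gene_a.strand and strand_b == gene_b.strand
            events.append(
                ChimericEvent(
                    read_id=read_id,
                    kind=kind,
                    geneA_id=gene_a.gene_id,
                    geneB_id=gene_b.gene_id,
                    breakpointA=bp_a,
                    breakpointB=bp_b,
                    intervalA=interval_a,
                    intervalB=interval_b,
                    anchorA_len=anchor_a if kind == SPLIT else 0,
                    anchorB_len=anchor_b if kind == SPLIT else 0,
                    splice_ref=splice_ref,
                    sense_sense=sense,
                )
            )
    return events


EVENT_TSV_HEADER = (
    "read_id\tkind\tgeneA\tgeneB\tbreakpointA\tbreakpointB\t"
    "startA\tendA\tstartB\tendB\tanchorA\tanchorB\tsplice_ref\tsense_sense"
)


def write_events_tsv(events: list[ChimericEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write(EVENT_TSV_HEADER + "\n")
        for ev in events:
            fh.write(
                f"{ev.read_id}\t{ev.kind}\t{ev.geneA_id}\t{ev.geneB_id}\t"
                f"{ev.breakpointA}\t{ev.breakpointB}\t"
                f"{ev.intervalA[0]}\t{ev.intervalA[1]}\t"
                f"{ev.intervalB[0]}\t{ev.intervalB[1]}\t"
                f"{ev.anchorA_len}\t{ev.anchorB_len}\t"
                f"{int(ev.splice_ref)}\t{int(ev.sense_sense)}\n"
            )


def parse_events_tsv(path) -> list[ChimericEvent]:
    """Parse the internal pre-annotated event dialect (see EVENT_TSV_HEADER)."""
    events = []
    with open(path) as fh:
        header = fh.readline()
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 14:
                raise FilterError(f"{path}:{lineno}: expected 14 columns")
            events.append(
                ChimericEvent(
                    read_id=f[0],
                    kind=f[1],
                    geneA_id=f[2],
                    geneB_id=f[3],
                    breakpointA=int(f[4]),
                    breakpointB=int(f[5]),
                    intervalA=(int(f[6]), int(f[7])),
                    intervalB=(int(f[8]), int(f[9])),
                    anchorA_len=int(f[10]),
                    anchorB_len=int(f[11]),
                    splice_ref=bool(int(f[12])),
                    sense_sense=bool(int(f[13])),
                )
            )
    return events


PREDICTION_TSV_HEADER = (
    "sample\tmethod\tfusion\tjunction_reads\tspanning_frags\tffpm\tbreakpointA\tbreakpointB"
)


def write_predictions_tsv(
    cands: list[FusionCandidate], path, sample: str = "sample", method: str = "fusionbench"
) -> None:
    with open(path, "w") as fh:
        fh.write(PREDICTION_TSV_HEADER + "\n")
        for c in cands:
            fh.write(
                f"{sample}\t{method}\t{c.fusion_name}\t{c.junction_reads}\t"
                f"{c.spanning_frags}\t{c.ffpm:.6f}\t{c.breakpointA}\t{c.breakpointB}\n"
            )
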