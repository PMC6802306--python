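"""Fusion-transcript simulation and paired-end read generation.

Simulated fusions join the spliced prefix of a randomly chosen donor gene
to the spliced suffix of an acceptor gene, with the breakpoint placed
between exons that carry canonical GT..AG splice dinucleotides and each
partner contributing at least 100 transcribed bases.  Fusion expression is
drawn uniformly on the log2(TPM) scale over a 1-15 dynamic range;
background transcripts draw from a log-normal stand-in for an empirical
expression profile, and the joint profile is renormalized to sum to one
million TPM.

Reads follow a deliberately simple paired-end model: fragment lengths are
normal (truncated to [read_length, transcript length]), placement is
uniform, mates are FR-oriented with random strand of origin, and
sequencing errors are uniform substitutions.  Placement records are kept
so downstream evidence counts can be recomputed exactly.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import AnnotationSet, Gene, Transcript, reverse_complement, spliced_sequence

logger = logging.getLogger(__name__)

MIN_PARTNER_CONTRIBUTION = 100  # bases each gene must contribute to a fusion


class SimulationError(ValueError):
    pass


class CapacityError(SimulationError):
    """Not enough eligible genes to build the requested number of fusions."""


class ConstructionError(SimulationError):
    """No admissible breakpoint pair for a given gene pair."""


@dataclass
class FusionDesign:
    geneA: str
    geneB: str
    donor_exon_index: int  # transcription-order index within donor transcript
    acceptor_exon_index: int
    sequence: str
    breakpoint_offset: int  # length of the donor-derived prefix
    fusion_name: str
    donor_transcript: str = ""
    acceptor_transcript: str = ""
    genomic_breakpointA: int = -1
    genomic_breakpointB: int = -1

    def __post_init__(self) -> None:
        if self.breakpoint_offset < MIN_PARTNER_CONTRIBUTION:
            raise SimulationError("donor prefix shorter than 100 bases")
        if len(self.sequence) - self.breakpoint_offset < MIN_PARTNER_CONTRIBUTION:
            raise SimulationError("acceptor suffix shorter than 100 bases")


@dataclass
class ExpressionProfile:
    tpm: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.tpm.values())
        if self.tpm and abs(total - 1e6) > 1e-9 * 1e6:
            raise SimulationError(f"TPM values sum to {total}, expected 1e6")


@dataclass
class ReadSimConfig:
    read_length: int = 101
    n_fragments: int = 100_000
    fragment_mean: float = 300.0
    fragment_sd: float = 50.0
    error_rate: float = 0.0
    seed: int = 0
    quality_char: str = "I"

    def __post_init__(self) -> None:
        if self.fragment_mean < self.read_length:
            raise SimulationError("fragment_mean must be >= read_length")


@dataclass
class Placement:
    """One simulated fragment: source transcript/fusion, coordinates, flip."""

    frag_id: str
    source_id: str
    start: int
    length: int
    flipped: bool  # mate 1 sequenced from the reverse strand


@dataclass
class SimulatedSample:
    designs: list[FusionDesign]
    profile: ExpressionProfile
    reads1: list[tuple[str, str]]  # (read id, sequence)
    reads2: list[tuple[str, str]]
    truth: list[tuple[str, float, int]]  # (fusion_name, TPM, breakpoint_offset)
    placements: list[Placement] = field(default_factory=list)
    config: ReadSimConfig | None = None


# ---------------------------------------------------------------------------
# Breakpoint admissibility


def _donor_consensus(gene: Gene, exon, genome) -> bool:
    """GT immediately 3' of the donor exon in transcription sense."""
    try:
        if gene.strand == "+":
            return genome.fetch(exon.end, exon.end + 2) == "GT"
        return genome.fetch(exon.start - 2, exon.start) == "AC"
    except Exception:
        return False


def _acceptor_consensus(gene: Gene, exon, genome) -> bool:
    """AG immediately 5' of the acceptor exon in transcription sense."""
    try:
        if gene.strand == "+":
            return genome.fetch(exon.start - 2, exon.start) == "AG"
        return genome.fetch(exon.end, exon.end + 2) == "CT"
    except Exception:
        return False


def _gene_admits_breakpoint(gene: Gene, ann: AnnotationSet) -> bool:
    """True if some transcript admits both a donor- and an acceptor-side
    breakpoint, so the gene can take either role in a pair."""
    genome = ann.genome[gene.chrom]
    for tx in gene.transcripts:
        exons = gene.exons_in_transcription_order(tx)
        cum = np.cumsum([len(e) for e in exons])
        total = int(cum[-1])
        donor_ok = any(
            cum[i] >= MIN_PARTNER_CONTRIBUTION and _donor_consensus(gene, exons[i], genome)
            for i in range(len(exons) - 1)
        )
        acceptor_ok = any(
            total - cum[j - 1] >= MIN_PARTNER_CONTRIBUTION
            and _acceptor_consensus(gene, exons[j], genome)
            for j in range(1, len(exons))
        )
        if donor_ok and acceptor_ok:
            return True
    return False


def select_fusion_pairs(
    ann: AnnotationSet, k: int, rng_seed: int
) -> list[tuple[str, str]]:
    """Pick k disjoint pairs of protein-coding genes, each pair usable as
    a fusion (every gene participates in at most one pair)."""
    if k == 0:
        return []
    rng = np.random.default_rng(rng_seed)
    eligible = sorted(
        (g.gene_id for g in ann.protein_coding_genes() if _gene_admits_breakpoint(g, ann))
    )
    if len(eligible) < 2 * k:
        raise CapacityError(
            f"need {2 * k} eligible protein-coding genes for {k} fusions, "
            f"only {len(eligible)} available"
        )
    order = rng.permutation(len(eligible))
    chosen = [eligible[i] for i in order[: 2 * k]]
    return [(chosen[2 * i], chosen[2 * i + 1]) for i in range(k)]


def construct_fusion(
    geneA: Gene, geneB: Gene, ann: AnnotationSet, rng_seed: int
) -> FusionDesign:
    """Fuse a random donor exon of geneA to a random acceptor exon of geneB.

    One transcript per gene is chosen uniformly; candidate breakpoint exons
    are tried in random order until the >=100-base contribution and GT/AG
    consensus constraints pass.
    """
    rng = np.random.default_rng(rng_seed)
    txA: Transcript = geneA.transcripts[int(rng.integers(len(geneA.transcripts)))]
    txB: Transcript = geneB.transcripts[int(rng.integers(len(geneB.transcripts)))]
    genomeA = ann.genome[geneA.chrom]
    genomeB = ann.genome[geneB.chrom]
    seqA = spliced_sequence(geneA, txA, genomeA)
    seqB = spliced_sequence(geneB, txB, genomeB)
    exonsA = geneA.exons_in_transcription_order(txA)
    exonsB = geneB.exons_in_transcription_order(txB)
    cumA = np.cumsum([len(e) for e in exonsA])
    cumB = np.cumsum([len(e) for e in exonsB])

    donor_candidates = [
        i
        for i in range(len(exonsA) - 1)
        if cumA[i] >= MIN_PARTNER_CONTRIBUTION and _donor_consensus(geneA, exonsA[i], genomeA)
    ]
    acceptor_candidates = [
        j
        for j in range(1, len(exonsB))
        if len(seqB) - (cumB[j - 1]) >= MIN_PARTNER_CONTRIBUTION
        and _acceptor_consensus(geneB, exonsB[j], genomeB)
    ]
    if not donor_candidates or not acceptor_candidates:
        raise ConstructionError(
            f"no admissible breakpoint for {geneA.gene_id}--{geneB.gene_id} "
            f"(donor candidates: {len(donor_candidates)}, "
            f"acceptor candidates: {len(acceptor_candidates)})"
        )
    i = donor_candidates[int(rng.integers(len(donor_candidates)))]
    j = acceptor_candidates[int(rng.integers(len(acceptor_candidates)))]
    prefix = seqA[: int(cumA[i])]
    suffix = seqB[int(cumB[j - 1]) :]
    donor_exon = exonsA[i]
    acceptor_exon = exonsB[j]
    return FusionDesign(
        geneA=geneA.gene_id,
        geneB=geneB.gene_id,
        donor_exon_index=i,
        acceptor_exon_index=j,
        sequence=prefix + suffix,
        breakpoint_offset=len(prefix),
        fusion_name=f"{geneA.symbol}--{geneB.symbol}",
        donor_transcript=txA.transcript_id,
        acceptor_transcript=txB.transcript_id,
        genomic_breakpointA=donor_exon.end if geneA.strand == "+" else donor_exon.start,
        genomic_breakpointB=acceptor_exon.start if geneB.strand == "+" else acceptor_exon.end,
    )


def build_designs(
    ann: AnnotationSet, k: int, rng_seed: int
) -> list[FusionDesign]:
    """Select k gene pairs and construct one fusion per pair."""
    pairs = select_fusion_pairs(ann, k, rng_seed)
    designs = []
    for idx, (ga, gb) in enumerate(pairs):
        designs.append(construct_fusion(ann.gene(ga), ann.gene(gb), ann, rng_seed + 1 + idx))
    return designs


# ---------------------------------------------------------------------------
# Expression

FUSION_LOG2_RANGE = (1.0, 15.0)


def draw_fusion_log2_tpm(rng: np.random.Generator, n: int, log2_range=FUSION_LOG2_RANGE):
    """Fusion expression: log2(TPM) uniform over the configured dynamic range."""
    return rng.uniform(log2_range[0], log2_range[1], size=n)


def assign_expression(
    ann: AnnotationSet,
    designs: list[FusionDesign],
    rng_seed: int,
    background_log2_mean: float = 2.0,
    background_log2_sd: float = 2.0,
    fusion_log2_range=FUSION_LOG2_RANGE,
) -> ExpressionProfile:
    """Draw raw TPMs for fusions and background transcripts, then
    renormalize jointly to one million."""
    rng = np.random.default_rng(rng_seed)
    ids: list[str] = []
    raw: list[float] = []
    fusion_log2 = draw_fusion_log2_tpm(rng, len(designs), fusion_log2_range)
    for design, l2 in zip(designs, fusion_log2):
        ids.append(design.fusion_name)
        raw.append(float(2.0**l2))
    for gene_id in sorted(ann.genes):
        for tx in ann.genes[gene_id].transcripts:
            ids.append(tx.transcript_id)
            raw.append(float(2.0 ** rng.normal(background_log2_mean, background_log2_sd)))
    raw_arr = np.asarray(raw, dtype=float)
    if raw_arr.size:
        raw_arr = raw_arr / raw_arr.sum() * 1e6
    return ExpressionProfile(dict(zip(ids, raw_arr.tolist())))


# ---------------------------------------------------------------------------
# Read simulation

_BASE_TO_IDX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_IDX[_b] = _i
_IDX_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def _apply_errors(reads: list[str], error_rate: float, rng: np.random.Generator) -> list[str]:
    """Uniform per-base substitutions; N bases are left untouched."""
    if error_rate <= 0 or not reads:
        return reads
    rl = len(reads[0])
    arr = np.frombuffer("".join(reads).encode(), dtype=np.uint8).reshape(len(reads), rl).copy()
    mask = rng.random(arr.shape) < error_rate
    idx = _BASE_TO_IDX[arr]
    mask &= idx != 255
    shift = rng.integers(1, 4, size=int(mask.sum()))
    idx[mask] = (idx[mask] + shift) % 4
    arr[mask] = _IDX_TO_BASE[idx[mask]]
    flat = arr.tobytes().decode()
    return [flat[i * rl : (i + 1) * rl] for i in range(len(reads))]


def transcript_sequences(ann: AnnotationSet) -> dict[str, str]:
    seqs = {}
    for gene in ann.genes.values():
        genome = ann.genome[gene.chrom]
        for tx in gene.transcripts:
            seqs[tx.transcript_id] = spliced_sequence(gene, tx, genome)
    return seqs


def effective_length(length: int, fragment_mean: float) -> int:
    return max(1, int(length - fragment_mean + 1))


def simulate_reads(
    ann: AnnotationSet,
    designs: list[FusionDesign],
    profile: ExpressionProfile,
    cfg: ReadSimConfig,
) -> SimulatedSample:
    """Draw paired-end fragments proportionally to TPM x effective length."""
    rng = np.random.default_rng(cfg.seed)
    # sequencing errors use their own stream so fragment placement is
    # invariant to the error model settings
    err_rng = np.random.default_rng((cfg.seed, 1))
    seqs = transcript_sequences(ann)
    for d in designs:
        seqs[d.fusion_name] = d.sequence
    seen = set()
    for d in designs:
        for gid in (d.geneA, d.geneB):
            if gid in seen:
                raise SimulationError(f"gene {gid} participates in more than one fusion")
            seen.add(gid)

    ids = sorted(profile.tpm)
    weights = np.zeros(len(ids))
    for i, tid in enumerate(ids):
        if tid not in seqs:
            raise SimulationError(f"profile id {tid!r} has no sequence")
        length = len(seqs[tid])
        if length < cfg.read_length:
            logger.warning(
                "transcript %s (length %d) shorter than read length %d: excluded",
                tid,
                length,
                cfg.read_length,
            )
            continue
        weights[i] = profile.tpm[tid] * effective_length(length, cfg.fragment_mean)

    reads1: list[tuple[str, str]] = []
    reads2: list[tuple[str, str]] = []
    placements: list[Placement] = []
    if cfg.n_fragments > 0 and weights.sum() > 0:
        counts = rng.multinomial(cfg.n_fragments, weights / weights.sum())
        frag_no = 0
        for tid, count in zip(ids, counts):
            if count == 0:
                continue
            seq = seqs[tid]
            L = len(seq)
            lengths = np.clip(
                np.rint(rng.normal(cfg.fragment_mean, cfg.fragment_sd, size=count)),
                cfg.read_length,
                L,
            ).astype(int)
            starts = np.floor(rng.random(count) * (L - lengths + 1)).astype(int)
            flips = rng.random(count) < 0.5
            raw1, raw2 = [], []
            for s, flen, flip in zip(starts, lengths, flips):
                frag = seq[s : s + flen]
                fwd = frag[: cfg.read_length]
                rev = reverse_complement(frag[-cfg.read_length :])
                raw1.append(rev if flip else fwd)
                raw2.append(fwd if flip else rev)
                placements.append(
                    Placement(f"frag{frag_no}", tid, int(s), int(flen), bool(flip))
                )
                frag_no += 1
            raw1 = _apply_errors(raw1, cfg.error_rate, err_rng)
            raw2 = _apply_errors(raw2, cfg.error_rate, err_rng)
            base = frag_no - count
            for k in range(count):
                reads1.append((f"frag{base + k}/1", raw1[k]))
                reads2.append((f"frag{base + k}/2", raw2[k]))

    truth = []
    for d in designs:
        truth.append((d.fusion_name, float(profile.tpm.get(d.fusion_name, 0.0)), d.breakpoint_offset))
    return SimulatedSample(
        designs=designs,
        profile=profile,
        reads1=reads1,
        reads2=reads2,
        truth=truth,
        placements=placements,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Output


def write_fastq(reads: list[tuple[str, str]], path, quality_char: str = "I") -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_fusion_fasta(designs: list[FusionDesign], path) -> None:
    with open(path, "w") as fh:
        for d in designs:
            fh.write(f">{d.fusion_name} breakpoint={d.breakpoint_offset}\n{d.sequence}\n")


def write_truth_set(sample: SimulatedSample, path, sample_id: str = "sample") -> None:
    with open(path, "w") as fh:
        fh.write("sample\tfusion_name\ttpm\tbreakpoint_offset\n")
        for name, tpm, offset in sample.truth:
            fh.write(f"{sample_id}\t{name}\t{tpm:.6f}\t{offset}\n")


def read_truth_set(path) -> list[tuple[str, str, float, int]]:
    rows = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            sample_id, name, tpm, offset = line.rstrip("\n").split("\t")
            rows.append((sample_id, name, float(tpm), int(offset)))
    return rows


def write_provenance(path, cfg: ReadSimConfig, extra: dict | None = None) -> None:
    payload = {
        "read_length": cfg.read_length,
        "n_fragments": cfg.n_fragments,
        "fragment_mean": cfg.fragment_mean,
        "fragment_sd": cfg.fragment_sd,
        "error_rate": cfg.error_rate,
        "seed": cfg.seed,
    }
    payload.update(extra or {})
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
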