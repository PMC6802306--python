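"""End-to-end orchestration: simulate, derive perfect chimeric evidence,
filter, and benchmark.

The "perfect caller" converts the simulator's fragment placement record
into idealized chimeric events (every fusion-crossing fragment becomes a
split or spanning record with exact anchors), which exercises the filter
cascade and benchmark without a read aligner.  An independent
placement-record bookkeeper predicts, by direct arithmetic on the same
record, which designs the cascade must recover — the two routes share only
the placement record, so their agreement is an end-to-end consistency
check.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .annotation import AnnotationSet, load_annotation
from .benchmark import (
    Mode,
    PredictionRecord,
    PRCurve,
    ScoringConfig,
    TruthSet,
    build_crowd_truth,
    score_predictions,
    threshold_sweep,
)
from .chimeric import (
    SPANNING,
    SPLIT,
    ChimericEvent,
    FilterConfig,
    FusionCandidate,
    SampleContext,
    run_filter_pipeline,
)
from .fixtures import FixtureSpec, generate_fixture
from .simulate import (
    FusionDesign,
    ReadSimConfig,
    SimulatedSample,
    assign_expression,
    build_designs,
    simulate_reads,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Perfect-caller event derivation


def _fragment_evidence(placement, design: FusionDesign, read_length: int):
    """Classify one fragment against the fusion breakpoint.

    Returns (kind, prefix_interval, suffix_interval, anchorA, anchorB) in
    transcript coordinates, or None when the fragment yields no chimeric
    evidence.  Mate order is positional (leftmost read first); the FR flip
    does not change the geometry.
    """
    bp = design.breakpoint_offset
    s, flen = placement.start, placement.length
    r1 = (s, s + read_length)
    r2 = (s + flen - read_length, s + flen)
    for read in (r1, r2):
        if read[0] < bp < read[1]:
            return (SPLIT, (read[0], bp), (bp, read[1]), bp - read[0], read[1] - bp)
    if r1[1] <= bp and r2[0] >= bp:
        return (SPANNING, r1, r2, 0, 0)
    return None


def _to_genomic_prefix(design: FusionDesign, gene, interval):
    """Map a prefix-side transcript interval onto the genome near the donor
    breakpoint (linear approximation ignoring intron structure)."""
    bp, g = design.breakpoint_offset, design.genomic_breakpointA
    d0, d1 = bp - interval[0], bp - interval[1]
    if gene.strand == "+":
        return (g - d0, g - d1)
    return (g + d1, g + d0)


def _to_genomic_suffix(design: FusionDesign, gene, interval):
    bp, g = design.breakpoint_offset, design.genomic_breakpointB
    e0, e1 = interval[0] - bp, interval[1] - bp
    if gene.strand == "+":
        return (g + e0, g + e1)
    return (g - e1, g - e0)


def perfect_caller_events(sample: SimulatedSample, ann: AnnotationSet) -> list[ChimericEvent]:
    """Idealized chimeric events for every fusion-crossing fragment."""
    designs = {d.fusion_name: d for d in sample.designs}
    read_length = sample.config.read_length
    events = []
    for placement in sample.placements:
        design = designs.get(placement.source_id)
        if design is None:
            continue
        ev = _fragment_evidence(placement, design, read_length)
        if ev is None:
            continue
        kind, prefix_iv, suffix_iv, anchor_a, anchor_b = ev
        gene_a = ann.gene(design.geneA)
        gene_b = ann.gene(design.geneB)
        events.append(
            ChimericEvent(
                read_id=placement.frag_id,
                kind=kind,
                geneA_id=design.geneA,
                geneB_id=design.geneB,
                breakpointA=design.genomic_breakpointA,
                breakpointB=design.genomic_breakpointB,
                intervalA=_to_genomic_prefix(design, gene_a, prefix_iv),
                intervalB=_to_genomic_suffix(design, gene_b, suffix_iv),
                anchorA_len=anchor_a,
                anchorB_len=anchor_b,
                splice_ref=True,
                sense_sense=True,
            )
        )
    return events


def crossing_fragment_counts(sample: SimulatedSample) -> dict[str, int]:
    """Fusion-crossing fragments (split or spanning) per design, counting
    distinct placements once (duplicate placements collapse, exactly as
    alignment-level deduplication treats them)."""
    designs = {d.fusion_name: d for d in sample.designs}
    read_length = sample.config.read_length
    seen: dict[str, set] = {d: set() for d in designs}
    for placement in sample.placements:
        design = designs.get(placement.source_id)
        if design is None:
            continue
        ev = _fragment_evidence(placement, design, read_length)
        if ev is not None:
            seen[placement.source_id].add((ev[0], placement.start, placement.length))
    return {name: len(s) for name, s in seen.items()}


def expected_recoverable(
    sample: SimulatedSample,
    ctx: SampleContext,
    config: FilterConfig | None = None,
) -> set[str]:
    """Designs the filter cascade must recover, predicted by direct
    arithmetic on the placement record: dedup placements, count split and
    spanning fragments and maximal anchors, then apply the support and
    expression rules (all breakpoints are reference-spliced by
    construction, and no similarity regions or annotations apply)."""
    cfg = config or FilterConfig()
    designs = {d.fusion_name: d for d in sample.designs}
    read_length = sample.config.read_length
    stats: dict[str, dict] = {
        name: {"split": 0, "span": 0, "maxA": 0, "maxB": 0} for name in designs
    }
    seen = set()
    for placement in sample.placements:
        design = designs.get(placement.source_id)
        if design is None:
            continue
        ev = _fragment_evidence(placement, design, read_length)
        if ev is None:
            continue
        key = (placement.source_id, ev[0], placement.start, placement.length)
        if key in seen:
            continue
        seen.add(key)
        st = stats[placement.source_id]
        if ev[0] == SPLIT:
            st["split"] += 1
            st["maxA"] = max(st["maxA"], ev[3])
            st["maxB"] = max(st["maxB"], ev[4])
        else:
            st["span"] += 1
    recoverable = set()
    for name, st in stats.items():
        total = st["split"] + st["span"]
        if total < 2 or st["split"] < 1:
            continue
        if st["span"] < 1 and not (st["maxA"] >= cfg.min_anchor and st["maxB"] >= cfg.min_anchor):
            continue
        if total / ctx.total_fragments * 1e6 < cfg.min_ffpm:
            continue
        recoverable.add(name)
    return recoverable


# ---------------------------------------------------------------------------
# Decoys and synthetic methods


def inject_decoys(
    sample_id: str, n: int, rng: np.random.Generator, method: str = "decoy_method"
) -> list[PredictionRecord]:
    """Unique fusion calls no other method makes — crowd-scheme FP bait."""
    preds = []
    for i in range(n):
        evidence = int(rng.integers(2, 20))
        preds.append(
            PredictionRecord(
                sample=sample_id,
                method=method,
                fusion=(f"DECOY{i:03d}A", f"DECOY{i:03d}B"),
                junction_reads=evidence,
            )
        )
    return preds


def candidates_to_predictions(
    cands: list[FusionCandidate], sample_id: str, method: str
) -> list[PredictionRecord]:
    return [
        PredictionRecord(
            sample=sample_id,
            method=method,
            fusion=(c.symA, c.symB),
            junction_reads=c.junction_reads,
            spanning_frags=c.spanning_frags,
        )
        for c in cands
    ]


# ---------------------------------------------------------------------------
# End-to-end run


@dataclass
class EndToEndConfig:
    seed: int = 0
    n_fusions: int = 10
    n_fragments: int = 50_000
    read_length: int = 50
    fragment_mean: float = 250.0
    fragment_sd: float = 40.0
    error_rate: float = 0.0
    n_decoys: int = 5
    crowd_n: int = 3
    min_evidence: int = 2
    fixture: FixtureSpec | None = None
    sample_id: str = "sim_sample"


def run_end_to_end(config: EndToEndConfig, work_dir) -> dict:
    """Simulate, filter, and benchmark; return a JSON-ready report."""
    work_dir = Path(work_dir)
    spec = config.fixture or FixtureSpec(
        n_chroms=2,
        chrom_length=120_000,
        n_genes=max(24, 2 * config.n_fusions + 4),
        seed=config.seed,
    )
    paths = generate_fixture(spec, work_dir / "fixture")
    ann = load_annotation(
        paths["gtf"], paths["fasta"], paths["paralogs"], paths["similarity"], paths["annots"]
    )

    designs = build_designs(ann, config.n_fusions, config.seed + 101)
    profile = assign_expression(ann, designs, config.seed + 202)
    sim_cfg = ReadSimConfig(
        read_length=config.read_length,
        n_fragments=config.n_fragments,
        fragment_mean=config.fragment_mean,
        fragment_sd=config.fragment_sd,
        error_rate=config.error_rate,
        seed=config.seed + 303,
    )
    sample = simulate_reads(ann, designs, profile, sim_cfg)

    events = perfect_caller_events(sample, ann)
    ctx = SampleContext(total_fragments=max(config.n_fragments, 1))
    cands = run_filter_pipeline(events, ann, ctx)

    pipeline_preds = candidates_to_predictions(cands, config.sample_id, "pipeline")
    recoverable = expected_recoverable(sample, ctx)
    crossing = crossing_fragment_counts(sample)

    scoring = ScoringConfig(mode=Mode.LENIENT)
    report: dict = {
        "n_designs": len(designs),
        "n_events": len(events),
        "n_candidates": len(cands),
        "n_recoverable_designs": len(recoverable),
        "crossing_fragment_counts": crossing,
    }

    if designs:
        truth_recoverable = TruthSet(
            positives={(config.sample_id, tuple(name.split("--", 1))) for name in recoverable}
        )
        counts = score_predictions(
            pipeline_preds, truth_recoverable, ann, scoring, min_evidence=config.min_evidence
        )
        truth_all = TruthSet(
            positives={(config.sample_id, (d.fusion_name.split("--")[0],
                                           d.fusion_name.split("--")[1])) for d in designs}
        )
        counts_all = score_predictions(
            pipeline_preds, truth_all, ann, scoring, min_evidence=config.min_evidence
        )
        curve = threshold_sweep(pipeline_preds, truth_all, ann, scoring)
        report.update(
            {
                "recall_at_min_evidence": counts.recall,
                "precision_at_min_evidence": counts_all.precision,
                "confusion_vs_recoverable": asdict(counts),
                "auc_vs_all_designs": curve.auc,
                "peak_f1_vs_all_designs": curve.peak_f1,
            }
        )
    else:
        report.update(
            {
                "recall_at_min_evidence": None,
                "precision_at_min_evidence": None,
                "auc_vs_all_designs": None,
                "auc_undefined": True,
            }
        )

    # crowd scheme: two agreeing synthetic callers plus a decoy-only caller
    rng = np.random.default_rng(config.seed + 404)
    agreeing = []
    for method in ("caller2", "caller3"):
        for p in pipeline_preds:
            agreeing.append(
                PredictionRecord(
                    sample=p.sample,
                    method=method,
                    fusion=p.fusion,
                    junction_reads=p.junction_reads,
                    spanning_frags=p.spanning_frags,
                )
            )
    decoys = inject_decoys(config.sample_id, config.n_decoys, rng)
    all_preds = pipeline_preds + agreeing + decoys
    if len({p.method for p in all_preds}) >= 2 and all_preds:
        crowd = build_crowd_truth(all_preds, config.crowd_n, ann=ann, cfg=scoring)
        decoy_keys = {(p.sample, p.fusion) for p in decoys}
        report["decoys_in_crowd_fp"] = sum(1 for k in decoy_keys if k in crowd.negatives)
        report["n_decoys"] = len(decoy_keys)
        report["crowd_positives"] = len(crowd.positives)
    report_path = work_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, default=float) + "\n")
    return report
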