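"""Scoring fusion predictions against explicit or wisdom-of-crowds truth.

Predictions are (sample, method, ordered gene-symbol pair, evidence)
records.  Strict scoring matches the exact ordered symbol pair; lenient
scoring additionally accepts reversed partner order and, on either side, a
gene that genomically overlaps or is a likely paralog of the true partner.
Confusion counts are swept over integer minimum-evidence thresholds to
produce a precision-recall curve whose trapezoidal area (PR-AUC) summarizes
accuracy; per-truth-set AUCs feed method leaderboards.

Wisdom-of-crowds truth sets label fusions called by at least n methods as
positives, uniquely called fusions as negatives, and intermediate
agreement as uncertain (unscored).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .annotation import AnnotationSet

logger = logging.getLogger(__name__)

Pair = tuple[str, str]
Key = tuple[str, Pair]  # (sample, ordered symbol pair)


class BenchmarkError(ValueError):
    pass


class Mode(str, Enum):
    STRICT = "STRICT"
    LENIENT = "LENIENT"


@dataclass(frozen=True)
class PredictionRecord:
    sample: str
    method: str
    fusion: Pair
    junction_reads: int
    spanning_frags: int = 0

    @property
    def evidence(self) -> int:
        return self.junction_reads + self.spanning_frags

    @property
    def key(self) -> Key:
        return (self.sample, self.fusion)


@dataclass
class TruthSet:
    positives: set = field(default_factory=set)
    negatives: set = field(default_factory=set)
    uncertain: set = field(default_factory=set)

    def validate(self) -> None:
        if (self.positives & self.negatives or self.positives & self.uncertain
                or self.negatives & self.uncertain):
            raise BenchmarkError("truth sets must be pairwise disjoint")


@dataclass
class ScoringConfig:
    mode: Mode = Mode.LENIENT
    allow_paralog_proxy: bool = True
    ignore_uncertain: bool = True


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0

    @property
    def recall(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else 0.0

    @property
    def precision(self) -> float:
        return self.TP / (self.TP + self.FP) if self.TP + self.FP else 0.0

    @property
    def f1(self) -> float:
        r, p = self.recall, self.precision
        return 2 * r * p / (r + p) if r + p else 0.0


@dataclass
class PRPoint:
    threshold: int
    recall: float
    precision: float
    f1: float


@dataclass
class PRCurve:
    points: list[PRPoint]
    auc: float | None = None

    @property
    def peak_f1(self) -> float:
        return max((p.f1 for p in self.points), default=0.0)


@dataclass
class Leaderboard:
    ranks: pd.DataFrame  # method x truth-set-n rank table
    median_rank: pd.Series
    order: list[str]  # methods by ascending median rank


# ---------------------------------------------------------------------------
# Matching


def _sym_equiv(sym_x: str, sym_t: str, ann: AnnotationSet, cfg: ScoringConfig) -> bool:
    """Is predicted symbol an acceptable proxy for the true partner?"""
    if sym_x == sym_t:
        return True
    if cfg.mode != Mode.LENIENT:
        return False
    if ann.symbols_overlap(sym_x, sym_t):
        return True
    if cfg.allow_paralog_proxy and ann.paralogs.are_paralogs(sym_x, sym_t):
        return True
    return False


def pairs_equivalent(pred: Pair, truth: Pair, ann: AnnotationSet, cfg: ScoringConfig) -> bool:
    if pred == truth:
        return True
    if cfg.mode != Mode.LENIENT:
        return False
    orientations = (pred, (pred[1], pred[0]))
    return any(
        _sym_equiv(p[0], truth[0], ann, cfg) and _sym_equiv(p[1], truth[1], ann, cfg)
        for p in orientations
    )


def match_prediction(
    pred_pair: Pair, truth_pairs, ann: AnnotationSet, cfg: ScoringConfig
) -> Pair | None:
    """First matching truth pair (exact match preferred over proxies)."""
    for t in truth_pairs:
        if pred_pair == t:
            return t
    if cfg.mode == Mode.LENIENT:
        for t in truth_pairs:
            if pairs_equivalent(pred_pair, t, ann, cfg):
                return t
    return None


def score_predictions(
    preds: list[PredictionRecord],
    truth: TruthSet,
    ann: AnnotationSet,
    cfg: ScoringConfig,
    min_evidence: int = 0,
) -> ConfusionCounts:
    """Confusion counts for one method's predictions at a minimum-evidence
    threshold.

    Each truth positive is credited at most once; predictions that proxy-
    match an already-credited positive are ignored (neither TP nor FP).
    Predictions matching uncertain entries are ignored under
    ``ignore_uncertain``, otherwise scored as FP.
    """
    truth.validate()
    surviving = [p for p in preds if p.evidence >= min_evidence]
    by_sample: dict[str, list[PredictionRecord]] = {}
    for p in surviving:
        by_sample.setdefault(p.sample, []).append(p)

    pos_by_sample: dict[str, list[Pair]] = {}
    for sample, pair in truth.positives:
        pos_by_sample.setdefault(sample, []).append(pair)
    unc_by_sample: dict[str, list[Pair]] = {}
    for sample, pair in truth.uncertain:
        unc_by_sample.setdefault(sample, []).append(pair)

    claimed: set = set()
    counts = ConfusionCounts()
    for sample, sample_preds in by_sample.items():
        positives = pos_by_sample.get(sample, [])
        uncertain = unc_by_sample.get(sample, [])
        deferred: list[PredictionRecord] = []
        # pass 1: exact matches claim truth entries first
        for p in sample_preds:
            if p.fusion in positives:
                if (sample, p.fusion) not in claimed:
                    claimed.add((sample, p.fusion))
                    counts.TP += 1
                # duplicate exact calls of a claimed positive: ignored
            else:
                deferred.append(p)
        # pass 2: proxy matches against unclaimed positives
        for p in deferred:
            matched = match_prediction(p.fusion, positives, ann, cfg)
            if matched is not None:
                if (sample, matched) not in claimed:
                    claimed.add((sample, matched))
                    counts.TP += 1
                # proxy match to a claimed positive: ignored
                continue
            unc = match_prediction(p.fusion, uncertain, ann, cfg)
            if unc is not None:
                if not cfg.ignore_uncertain:
                    counts.FP += 1
                continue
            counts.FP += 1
    counts.FN = len(truth.positives) - len(claimed)
    return counts


# ---------------------------------------------------------------------------
# Threshold sweep, AUC


def threshold_sweep(
    preds: list[PredictionRecord],
    truth: TruthSet,
    ann: AnnotationSet,
    cfg: ScoringConfig,
) -> PRCurve:
    """Score at every integer threshold from the minimum to the maximum
    observed evidence; attach the trapezoidal PR-AUC."""
    if not preds:
        return PRCurve(points=[], auc=None)
    evidences = [p.evidence for p in preds]
    points = []
    for threshold in range(min(evidences), max(evidences) + 1):
        c = score_predictions(preds, truth, ann, cfg, min_evidence=threshold)
        points.append(PRPoint(threshold, c.recall, c.precision, c.f1))
    curve = PRCurve(points=points)
    curve.auc = pr_auc(curve)
    return curve


def pr_auc(curve: PRCurve) -> float:
    """Trapezoidal area under the (recall, precision) points, anchored at
    (recall 0, precision of the highest-threshold point); no extrapolation
    beyond the maximum achieved recall."""
    if not curve.points:
        raise BenchmarkError("cannot integrate an empty curve")
    anchor_precision = curve.points[-1].precision  # highest threshold
    pts = sorted(((p.recall, p.precision) for p in curve.points))
    recalls = [0.0] + [r for r, _ in pts]
    precisions = [anchor_precision] + [p for _, p in pts]
    return float(np.trapezoid(precisions, recalls))


# ---------------------------------------------------------------------------
# Wisdom-of-crowds truth sets


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y):
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[max(rx, ry)] = min(rx, ry)


def _unordered(pair: Pair) -> Pair:
    return tuple(sorted(pair))


def build_crowd_truth(
    all_preds: list[PredictionRecord],
    n: int,
    vote_exclusions: set | None = None,
    ann: AnnotationSet | None = None,
    cfg: ScoringConfig | None = None,
) -> TruthSet:
    """Label fusions by method agreement.

    Votes are counted per lenient equivalence class (reverse order plus
    overlap/paralog proxies, merged by union-find over the union of calls)
    over the counted methods only; excluded methods' calls are still
    scorable but cast no votes.  Classes with >= n votes are positives,
    single-vote classes are negatives (crowd FPs), and classes with 2..n-1
    votes are uncertain.  Each class is represented by its
    lexicographically smallest member pair.
    """
    if n < 1:
        raise BenchmarkError("n must be >= 1")
    vote_exclusions = vote_exclusions or set()
    cfg = cfg or ScoringConfig()
    counted_methods = {p.method for p in all_preds} - vote_exclusions
    if len(counted_methods) < 2:
        raise BenchmarkError("crowd truth needs at least 2 counted methods")
    if not 3 <= n <= len(counted_methods):
        logger.warning(
            "crowd n=%d outside the usual 3..%d range", n, len(counted_methods)
        )

    truth = TruthSet()
    samples = {p.sample for p in all_preds}
    for sample in sorted(samples):
        sample_preds = [p for p in all_preds if p.sample == sample]
        pairs = sorted({p.fusion for p in sample_preds})
        uf = _UnionFind(pairs)
        if ann is not None and cfg.mode == Mode.LENIENT:
            for i, a in enumerate(pairs):
                for b in pairs[i + 1 :]:
                    if pairs_equivalent(a, b, ann, cfg) or pairs_equivalent(b, a, ann, cfg):
                        uf.union(a, b)
        else:
            # reverse-order equivalence always applies
            seen: dict[Pair, Pair] = {}
            for a in pairs:
                u = _unordered(a)
                if u in seen:
                    uf.union(seen[u], a)
                else:
                    seen[u] = a
        classes: dict[Pair, list[Pair]] = {}
        for a in pairs:
            classes.setdefault(uf.find(a), []).append(a)
        for root, members in classes.items():
            voters = {
                p.method
                for p in sample_preds
                if p.fusion in members and p.method in counted_methods
            }
            rep = (sample, min(members))
            if len(voters) >= n:
                truth.positives.add(rep)
            elif len(voters) <= 1:
                truth.negatives.add(rep)
            else:
                truth.uncertain.add(rep)
    truth.validate()
    return truth


def method_correlation(all_preds: list[PredictionRecord]) -> pd.DataFrame:
    """Pearson correlation of binary call indicators over the union of
    (sample, unordered fusion) keys.  Methods with zero calls yield NaN."""
    methods = sorted({p.method for p in all_preds})
    if len(methods) < 2:
        raise BenchmarkError("correlation needs at least 2 methods")
    def key(p: PredictionRecord) -> str:
        a, b = _unordered(p.fusion)
        return f"{p.sample}|{a}--{b}"

    keys = sorted({key(p) for p in all_preds})
    mat = pd.DataFrame(0.0, index=pd.Index(keys), columns=methods)
    for p in all_preds:
        mat.loc[key(p), p.method] = 1.0
    return mat.corr(method="pearson")


def rank_leaderboard(auc_table: pd.DataFrame) -> Leaderboard:
    """Rank methods per truth set by descending AUC (tied ranks averaged);
    order methods by their median rank across truth sets."""
    ranks = auc_table.rank(ascending=False, axis=0, method="average")
    median = ranks.median(axis=1)
    order = list(median.sort_values(kind="stable").index)
    return Leaderboard(ranks=ranks, median_rank=median, order=order)


# ---------------------------------------------------------------------------
# Tabular I/O


def read_predictions_tsv(path) -> list[PredictionRecord]:
    """Shared prediction format:
    sample, method, fusion (symA--symB), junction_reads, spanning_frags[, ...]."""
    preds = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("sample\t"):
                continue
            f = line.split("\t")
            if len(f) < 5:
                raise BenchmarkError(f"{path}:{lineno}: expected >=5 columns")
            if "--" not in f[2]:
                raise BenchmarkError(f"{path}:{lineno}: fusion must be symA--symB")
            sym_a, sym_b = f[2].split("--", 1)
            preds.append(
                PredictionRecord(
                    sample=f[0],
                    method=f[1],
                    fusion=(sym_a, sym_b),
                    junction_reads=int(f[3]),
                    spanning_frags=int(f[4]),
                )
            )
    return preds


def read_truth_tsv(path) -> TruthSet:
    """Explicit truth: sample <TAB> symA--symB per line (positives only)."""
    truth = TruthSet()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("sample\t"):
                continue
            f = line.split("\t")
            sym_a, sym_b = f[1].split("--", 1)
            truth.positives.add((f[0], (sym_a, sym_b)))
    return truth


def auc_table(
    all_preds: list[PredictionRecord],
    ann: AnnotationSet,
    cfg: ScoringConfig,
    n_range: range,
    vote_exclusions: set | None = None,
) -> pd.DataFrame:
    """AUC per method per crowd truth-set n."""
    methods = sorted({p.method for p in all_preds})
    table = pd.DataFrame(index=methods, columns=list(n_range), dtype=float)
    for n in n_range:
        truth = build_crowd_truth(all_preds, n, vote_exclusions, ann, cfg)
        for method in methods:
            preds = [p for p in all_preds if p.method == method]
            curve = threshold_sweep(preds, truth, ann, cfg)
            table.loc[method, n] = curve.auc if curve.auc is not None else np.nan
    return table


def plot_pr_curves(curves: dict[str, PRCurve], path) -> None:
    """Optional PR-curve plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        rs = [p.recall for p in curve.points]
        ps = [p.precision for p in curve.points]
        auc = f" (AUC={curve.auc:.3f})" if curve.auc is not None else ""
        ax.plot(rs, ps, marker="o", label=label + auc)
    ax.set_xlabel("Recall")
    ax.set_ylabel("Precision")
    ax.set_xlim(0, 1.02)
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
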