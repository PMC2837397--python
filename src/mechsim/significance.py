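"""Dataset/background construction and classification statistics.

Functional-analog pairs (same EC sub-subclass, no shared structural
superfamily) are the positive class; pairs from a background of entries
sharing neither sub-subclass nor superfamily are the negative class.
Confusion matrices are evaluated at every observed score ("score >= cutoff"
counts as positive), yielding precision/recall/F-measure/MCC, F-optimal and
empirical 5%-significance cutoffs, enrichment factors, and ROC curves with
trapezium-rule AUC.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from mechsim.reaction_model import ReactionEntry

import logging

logger = logging.getLogger(__name__)


class DegenerateBackgroundError(ValueError):
    """No background score satisfies the significance condition."""


@dataclass(frozen=True)
class ThresholdMetrics:
    """Confusion counts and derived statistics at one cutoff."""

    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    f_measure: float
    mcc: float
    tpr: float
    fpr: float
    enrichment: float
    #: True when a derived ratio was 0/0 and reported as 0.
    degenerate: bool = False


@dataclass(frozen=True)
class RocResult:
    """Ordered (FPR, TPR) points plus trapezium-rule AUC."""

    points: tuple[tuple[float, float], ...]
    auc: float


def repetitions_needed(p: float, f: float) -> int:
    """Repetitions of random selection needed to find the best solution.

    ``p`` is the probability corresponding to the confidence level of having
    found the best solution and ``f`` the fraction of selections that
    produce it; the approximation is ceil(-ln(p)/f).
    """
    if not (0 < p < 1):
        raise ValueError(f"p must be in (0, 1), got {p}")
    if not (0 < f <= 1):
        raise ValueError(f"f must be in (0, 1], got {f}")
    return math.ceil(-math.log(p) / f)


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def metrics_at(
    dataset_scores: Sequence[float],
    background_scores: Sequence[float],
    cutoff: float,
) -> ThresholdMetrics:
    """Confusion matrix and derived statistics at one cutoff.

    Dataset pairs are the positive class: scores >= cutoff are true
    positives, below are false negatives.  Background pairs scoring >=
    cutoff are false positives, below are true negatives.  Ratios that come
    out 0/0 are reported as 0 with the ``degenerate`` flag set.
    """
    ds = np.asarray(dataset_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    if ds.size == 0 or bg.size == 0:
        raise ValueError("dataset and background score collections must be non-empty")
    tp = int((ds >= cutoff).sum())
    fn = int(ds.size - tp)
    fp = int((bg >= cutoff).sum())
    tn = int(bg.size - fp)
    degenerate = False
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, degenerate = 0.0, True
    recall = tp / (tp + fn)
    if precision + recall > 0:
        f_measure = 2 * precision * recall / (precision + recall)
    else:
        f_measure, degenerate = 0.0, True
    tpr = recall
    fpr = fp / (fp + tn)
    if fpr > 0:
        enrichment = tpr / fpr
    else:
        enrichment, degenerate = (0.0, True) if tpr == 0 else (math.inf, degenerate)
    return ThresholdMetrics(
        cutoff=float(cutoff),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        precision=precision,
        recall=recall,
        f_measure=f_measure,
        mcc=mcc(tp, fp, tn, fn),
        tpr=tpr,
        fpr=fpr,
        enrichment=enrichment,
        degenerate=degenerate,
    )


def candidate_cutoffs(
    dataset_scores: Iterable[float], background_scores: Iterable[float]
) -> list[float]:
    """Sorted union of observed scores: the natural cutoff grid, since
    Tanimoto scores are rationals with small denominators."""
    return sorted(set(dataset_scores) | set(background_scores))


def optimal_f_cutoff(
    dataset_scores: Sequence[float], background_scores: Sequence[float]
) -> tuple[float, ThresholdMetrics]:
    """Cutoff over the observed-score grid that maximizes the F-measure.

    Ties are broken toward the lowest cutoff (maximal recall at equal F).
    """
    best: tuple[float, ThresholdMetrics] | None = None
    for cut in candidate_cutoffs(dataset_scores, background_scores):
        m = metrics_at(dataset_scores, background_scores, cut)
        if best is None or m.f_measure > best[1].f_measure + 1e-12:
            best = (cut, m)
    assert best is not None
    return best


def significance_cutoff(background_scores: Sequence[float], alpha: float = 0.05) -> float:
    """Smallest observed score with fewer than ``alpha`` of background at or above.

    A score s is significant at level alpha when less than alpha of the
    background pairs score equal or higher than s.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    bg = np.asarray(background_scores, dtype=float)
    if bg.size == 0:
        raise ValueError("background scores must be non-empty")
    for s in np.unique(bg):  # ascending
        if (bg >= s).sum() / bg.size < alpha:
            return float(s)
    raise DegenerateBackgroundError(
        f"no background score has fewer than {alpha:.0%} of pairs at or above it"
    )


def label_pairs(
    dataset_scores: Sequence[float],
    f_optimal: float,
    significance: float,
) -> list[str]:
    """Two-tier similarity labels for dataset pairs.

    ``highly_similar`` at or above the F-optimal cutoff, ``distantly_similar``
    between the 5%-significance cutoff and the F-optimal cutoff, otherwise
    ``non_similar``.
    """
    labels = []
    for s in dataset_scores:
        if s >= f_optimal:
            labels.append("highly_similar")
        elif s >= significance:
            labels.append("distantly_similar")
        else:
            labels.append("non_similar")
    return labels


def roc(dataset_scores: Sequence[float], background_scores: Sequence[float]) -> RocResult:
    """ROC curve over all candidate cutoffs, AUC by the trapezium rule.

    Points run from (0, 0) (cutoff above every score) to (1, 1) (cutoff
    below every score), sweeping the observed scores in descending order.
    """
    ds = np.asarray(dataset_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    if ds.size == 0 or bg.size == 0:
        raise ValueError("dataset and background score collections must be non-empty")
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    for cut in sorted(set(ds) | set(bg), reverse=True):
        tpr = float((ds >= cut).sum() / ds.size)
        fpr = float((bg >= cut).sum() / bg.size)
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    auc = float(np.trapezoid(ys, xs))
    return RocResult(points=tuple(points), auc=auc)


# ---------------------------------------------------------------------------
# Dataset and background assembly by repeated random selection.
# ---------------------------------------------------------------------------


def _share_superfamily(a: ReactionEntry, b: ReactionEntry) -> bool:
    return bool(a.superfamilies & b.superfamilies)


def _collapse_homologs(entries: list[ReactionEntry], rng: np.random.Generator) -> list[ReactionEntry]:
    """Iterative random selection keeping pairwise non-homologous entries."""
    pool = list(entries)
    survivors: list[ReactionEntry] = []
    while pool:
        pick = pool.pop(int(rng.integers(len(pool))))
        survivors.append(pick)
        pool = [e for e in pool if not _share_superfamily(pick, e)]
    return survivors


def analog_pairs(
    entries: Iterable[ReactionEntry], seed: int | np.random.Generator
) -> set[tuple[str, str]]:
    """Functional-analog pairs: same sub-subclass, homologs collapsed.

    Within each EC sub-subclass group of two or more entries, entries
    sharing any structural superfamily are reduced to one random
    representative; all within-group unordered pairs of survivors are
    returned as sorted id tuples.  Entries without superfamily assignments
    are excluded with a warning.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    groups: dict[str, list[ReactionEntry]] = defaultdict(list)
    for e in entries:
        if not e.superfamilies:
            logger.warning("%s: no superfamily assignment, excluded from analog pairing", e.id)
            continue
        groups[e.sub_subclass].append(e)
    pairs: set[tuple[str, str]] = set()
    for key in sorted(groups):
        members = groups[key]
        if len(members) < 2:
            continue
        survivors = _collapse_homologs(members, rng)
        for a, b in itertools.combinations(sorted(survivors, key=lambda e: e.id), 2):
            pairs.add((a.id, b.id))
    return pairs


def build_background(
    entries: Iterable[ReactionEntry], seed: int | np.random.Generator
) -> list[ReactionEntry]:
    """Background entries pairwise unrelated by function and structure.

    Entries are picked uniformly at random; each pick removes all remaining
    entries in the same EC sub-subclass (functional analogs) or sharing any
    structural superfamily (homologs).  The result supports all C(k, 2)
    null pairs.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pool = sorted(entries, key=lambda e: e.id)
    survivors: list[ReactionEntry] = []
    while pool:
        pick = pool.pop(int(rng.integers(len(pool))))
        survivors.append(pick)
        pool = [
            e
            for e in pool
            if e.sub_subclass != pick.sub_subclass and not _share_superfamily(pick, e)
        ]
    return sorted(survivors, key=lambda e: e.id)


def min_domain_combinations(
    entries: Iterable[ReactionEntry],
    repetitions: int = 500,
    seed: int | np.random.Generator = 0,
) -> dict[str, int]:
    """Minimum non-homologous survivor count per sub-subclass.

    The random non-homologous selection is repeated ``repetitions`` times
    per sub-subclass and the minimum survivor count across repetitions is
    reported.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    groups: dict[str, list[ReactionEntry]] = defaultdict(list)
    for e in entries:
        groups[e.sub_subclass].append(e)
    out: dict[str, int] = {}
    for key in sorted(groups):
        members = groups[key]
        best = len(members)
        for _ in range(repetitions):
            best = min(best, len(_collapse_homologs(members, rng)))
            if best == 1:
                break
        out[key] = best
    return out
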