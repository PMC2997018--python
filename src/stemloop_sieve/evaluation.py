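"""Ranking evaluation against annotations: labels, undersampled ROC curves,
optimal cutoffs, overlap reduction and mature-sequence checks.

Candidate sets are hugely imbalanced (tens of known precursors against
hundreds of thousands of other stem-loops), so ROC statistics are computed
over many negative subsets, each drawn at the size of the positive set, and
averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .background import ScoredCandidate
from .io import AnnotationRecord, GenomicInterval


def _interval(obj) -> GenomicInterval:
    cand = getattr(obj, "candidate", obj)
    return cand.interval if hasattr(cand, "interval") else cand


@dataclass
class LabelledSet:
    """Candidates partitioned by overlap with known precursors."""

    positives: list
    negatives: list


def label_candidates(
    candidates: list,
    annotations: list[AnnotationRecord] | list[GenomicInterval],
    stranded: bool = True,
) -> LabelledSet:
    """Positive iff the candidate shares >= 1 nt with any known precursor on
    the same contig (and strand, by default)."""
    known = [
        a.precursor if isinstance(a, AnnotationRecord) else a for a in annotations
    ]
    positives, negatives = [], []
    for cand in candidates:
        iv = _interval(cand)
        if any(iv.overlaps(k, stranded=stranded) for k in known):
            positives.append(cand)
        else:
            negatives.append(cand)
    return LabelledSet(positives, negatives)


def best_match_with_mature(
    candidates: list,
    annotation: AnnotationRecord,
    tolerance: int = 2,
) -> tuple[object, bool]:
    """The overlapping candidate with the greatest overlap with the
    annotated precursor (ties: higher cscore when present, then 5'-most),
    and whether the mature sequence lies within one of its stem arms.

    Each mature endpoint may fall outside the arm by at most `tolerance`
    nucleotides (missed dangling ends in the annotation).
    """
    overlapping = [
        c for c in candidates
        if _interval(c).overlaps(annotation.precursor)
    ]
    if not overlapping:
        raise ValueError(
            f"no candidate overlaps precursor {annotation.name or annotation.precursor}"
        )

    def sort_key(c):
        iv = _interval(c)
        return (
            -iv.overlap_length(annotation.precursor),
            -getattr(c, "cscore", 0.0),
            iv.start,
        )

    best = min(overlapping, key=sort_key)
    cand = getattr(best, "candidate", best)
    arms = [
        GenomicInterval(cand.interval.contig, cand.interval.start,
                        cand.loop.start, cand.interval.strand)
        if cand.loop.start > cand.interval.start else None,
        GenomicInterval(cand.interval.contig, cand.loop.end,
                        cand.interval.end, cand.interval.strand)
        if cand.interval.end > cand.loop.end else None,
    ]
    mature_in_arm = any(
        arm is not None and arm.contains(mat, slack=tolerance)
        for mat in annotation.matures
        for arm in arms
    )
    return best, mature_in_arm


def undersample_negatives(
    negatives: list,
    sample_size: int,
    n_samples: int = 1000,
    seed: int = 0,
) -> list[list]:
    """Draw `n_samples` negative subsets of `sample_size`, each without
    replacement within itself (independent across samples)."""
    if len(negatives) < sample_size:
        raise ValueError(
            f"need at least {sample_size} negatives, have {len(negatives)}"
        )
    rng = np.random.default_rng(seed)
    return [
        [negatives[i] for i in rng.choice(len(negatives), sample_size, replace=False)]
        for _ in range(n_samples)
    ]


@dataclass
class RocCurve:
    """ROC points sorted by FPR, trapezoid AUC and the Youden-style optimal
    cutoff (threshold maximising TPR - FPR; ties resolved toward the lowest
    threshold, favouring sensitivity)."""

    points: list[tuple[float, float]]
    auc: float
    optimal_cutoff: float


def roc(pos_scores, neg_scores) -> RocCurve:
    """ROC over the observed score thresholds (score >= threshold is called
    positive).  Tied scores are swept together, making the trapezoid AUC
    equal to the Mann-Whitney statistic with ties counted 1/2."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    points = [(0.0, 0.0)]
    best = (-np.inf, np.inf)  # (tpr - fpr, threshold)
    for t in thresholds:
        tpr = float(np.mean(pos >= t))
        fpr = float(np.mean(neg >= t))
        points.append((fpr, tpr))
        delta = tpr - fpr
        if delta > best[0] or (delta == best[0] and t < best[1]):
            best = (delta, float(t))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    auc = float(np.trapezoid(ys, xs))
    return RocCurve(points, auc, best[1])


def optimal_cutoff(curve: RocCurve) -> float:
    """The score threshold of a curve maximising TPR - FPR."""
    return curve.optimal_cutoff


@dataclass
class AveragedRoc:
    mean_auc: float
    mean_cutoff: float
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    aucs: np.ndarray
    cutoffs: np.ndarray


def average_roc(curves: list[RocCurve], grid_points: int = 101) -> AveragedRoc:
    """Arithmetic mean of per-sample AUCs and cutoffs, plus the vertically
    averaged curve (mean TPR on a fixed FPR grid)."""
    if not curves:
        raise ValueError("need at least one curve")
    grid = np.linspace(0.0, 1.0, grid_points)
    tprs = np.empty((len(curves), grid_points))
    for k, curve in enumerate(curves):
        fpr = np.array([p[0] for p in curve.points])
        tpr = np.array([p[1] for p in curve.points])
        # step curve: TPR attained at the largest observed FPR <= grid value
        idx = np.searchsorted(fpr, grid, side="right") - 1
        tprs[k] = tpr[np.maximum(idx, 0)]
    aucs = np.array([c.auc for c in curves])
    cutoffs = np.array([c.optimal_cutoff for c in curves])
    return AveragedRoc(
        float(aucs.mean()), float(cutoffs.mean()), grid, tprs.mean(axis=0),
        aucs, cutoffs,
    )


def reduce_by_overlap(
    scored: list[ScoredCandidate],
    cutoff: float = 0.0,
    stranded: bool = True,
) -> list[ScoredCandidate]:
    """Drop candidates scoring below `cutoff`, then eliminate every candidate
    overlapped by a surviving candidate with strictly higher cscore.

    Processing in descending cscore order (ties: longer, then 5'-most first)
    makes the rule deterministic: a candidate is removed iff a *kept*
    strictly-higher-scoring candidate overlaps it.
    """
    alive = [c for c in scored if c.cscore >= cutoff]
    order = sorted(
        alive,
        key=lambda c: (-c.cscore, -len(_interval(c)), _interval(c).start,
                       _interval(c).contig, _interval(c).strand),
    )
    kept: list[ScoredCandidate] = []
    for cand in order:
        iv = _interval(cand)
        if any(
            k.cscore > cand.cscore and _interval(k).overlaps(iv, stranded=stranded)
            for k in kept
        ):
            continue
        kept.append(cand)
    kept.sort(key=lambda c: (_interval(c).contig, _interval(c).start,
                             _interval(c).end, _interval(c).strand))
    return kept
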