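"""Labelling, undersampled ROC statistics and overlap reduction."""

import numpy as np
import pytest

import stemloop_sieve as sls
from stemloop_sieve.background import ScoredCandidate
from stemloop_sieve.enumeration import PrecursorCandidate
from stemloop_sieve.evaluation import average_roc, reduce_by_overlap
from stemloop_sieve.io import AnnotationRecord, GenomicInterval
from stemloop_sieve.measures import MeasureVector


def _cand(start, end, strand="+", contig="c", loop=None):
    loop = loop or (start + (end - start) // 2 - 2, start + (end - start) // 2 + 2)
    return PrecursorCandidate(
        interval=GenomicInterval(contig, start, end, strand),
        seq="A" * (end - start), structure="." * (end - start), mfe=-25.0,
        loop=GenomicInterval(contig, loop[0], loop[1], strand),
        arm5_len=16, arm3_len=16,
    )


def _scored(start, end, cscore, strand="+", contig="c"):
    return ScoredCandidate(
        _cand(start, end, strand, contig),
        MeasureVector(-30, 2, 0.9, 2), {}, cscore,
    )


class TestLabelCandidates:
    def test_overlap_strand_and_partition_rules(self):
        known = [GenomicInterval("c", 150, 220, "+")]
        pos = _cand(100, 200)
        adjacent = _cand(220, 300)
        other_strand = _cand(150, 220, strand="-")
        labelled = sls.label_candidates([pos, adjacent, other_strand], known)
        assert labelled.positives == [pos]
        assert set(map(id, labelled.negatives)) == {id(adjacent), id(other_strand)}

    def test_annotation_order_irrelevant(self):
        known = [GenomicInterval("c", 0, 50, "+"), GenomicInterval("c", 500, 600, "+")]
        cands = [_cand(40, 120), _cand(300, 380), _cand(550, 640)]
        a = sls.label_candidates(cands, known)
        b = sls.label_candidates(cands, known[::-1])
        assert a.positives == b.positives
        assert a.negatives == b.negatives


class TestBestMatchWithMature:
    def _annotation(self, mature_start, mature_end):
        return AnnotationRecord(
            precursor=GenomicInterval("c", 100, 200, "+"),
            matures=[GenomicInterval("c", mature_start, mature_end, "+")],
            name="mir-x",
        )

    def test_mature_inside_5prime_arm(self):
        cand = _cand(100, 200, loop=(145, 155))
        best, ok = sls.best_match_with_mature([cand], self._annotation(105, 127))
        assert best is cand and ok

    def test_two_nt_protrusion_tolerated_three_rejected(self):
        cand = _cand(100, 200, loop=(145, 155))
        _, ok2 = sls.best_match_with_mature([cand], self._annotation(98, 120))
        _, ok3 = sls.best_match_with_mature([cand], self._annotation(97, 120))
        assert ok2 and not ok3

    def test_mature_crossing_loop_rejected(self):
        cand = _cand(100, 200, loop=(145, 155))
        _, ok = sls.best_match_with_mature([cand], self._annotation(130, 152))
        assert not ok

    def test_greatest_overlap_wins(self):
        small = _cand(190, 260)
        big = _cand(120, 210)
        best, _ = sls.best_match_with_mature([small, big], self._annotation(105, 127))
        assert best is big

    def test_no_overlap_signals(self):
        with pytest.raises(ValueError, match="no candidate"):
            sls.best_match_with_mature([_cand(300, 400)], self._annotation(105, 127))


class TestUndersampling:
    def test_sample_shape_and_membership(self):
        negatives = list(range(200))
        samples = sls.undersample_negatives(negatives, 44, n_samples=50, seed=1)
        assert len(samples) == 50
        for s in samples:
            assert len(s) == 44
            assert len(set(s)) == 44
            assert all(x in negatives for x in s)

    def test_seed_reproducible(self):
        negatives = list(range(100))
        a = sls.undersample_negatives(negatives, 10, 5, seed=3)
        b = sls.undersample_negatives(negatives, 10, 5, seed=3)
        assert a == b

    def test_too_few_negatives_rejected(self):
        with pytest.raises(ValueError):
            sls.undersample_negatives([1, 2], 3, 1, seed=0)


def mann_whitney_auc(pos, neg):
    """Brute-force pairwise comparison with ties counted 1/2."""
    wins = sum(
        1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        curve = sls.roc([0.9, 0.8], [0.1, 0.2])
        assert curve.auc == 1.0
        assert curve.optimal_cutoff == 0.8

    def test_all_tied_scores_give_half(self):
        assert sls.roc([0.5] * 5, [0.5] * 5).auc == 0.5

    def test_curve_anchored_at_corners(self):
        curve = sls.roc([0.3, 0.9], [0.2, 0.7])
        assert curve.points[0] == (0.0, 0.0)
        assert curve.points[-1] == (1.0, 1.0)

    def test_auc_equals_mann_whitney_with_half_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            pos = rng.integers(0, 8, size=rng.integers(1, 12)) / 8
            neg = rng.integers(0, 8, size=rng.integers(1, 12)) / 8
            curve = sls.roc(pos, neg)
            assert curve.auc == pytest.approx(mann_whitney_auc(pos, neg))

    def test_optimal_cutoff_bruteforce_and_tie_rule(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            pos = rng.integers(0, 5, size=6) / 5
            neg = rng.integers(0, 5, size=6) / 5
            curve = sls.roc(pos, neg)
            thresholds = np.unique(np.concatenate([pos, neg]))
            deltas = {
                t: np.mean(pos >= t) - np.mean(neg >= t) for t in thresholds
            }
            best = max(deltas.values())
            expected = min(t for t, d in deltas.items() if d == best)
            assert curve.optimal_cutoff == expected

    def test_cutoff_unmoved_by_low_negative(self):
        base = sls.roc([0.9, 0.8], [0.1, 0.2])
        extended = sls.roc([0.9, 0.8], [0.1, 0.2, 0.01])
        assert extended.optimal_cutoff == base.optimal_cutoff


class TestAverageRoc:
    def test_identical_samples_average_to_themselves(self):
        curve = sls.roc([0.9, 0.7], [0.2, 0.4])
        avg = average_roc([curve] * 5)
        assert avg.mean_auc == curve.auc
        assert avg.mean_cutoff == curve.optimal_cutoff

    def test_many_sample_average_stable_across_seed_choices(self):
        # overlapping but separated score distributions
        rng = np.random.default_rng(5)
        pos = np.clip(rng.normal(0.7, 0.2, size=30), 0, 1)
        neg = list(np.clip(rng.normal(0.4, 0.2, size=300), 0, 1))
        means = []
        for seed in (1, 2):
            samples = sls.undersample_negatives(neg, 30, n_samples=200, seed=seed)
            means.append(average_roc([sls.roc(pos, s) for s in samples]).mean_auc)
        assert abs(means[0] - means[1]) < 0.01

    def test_mean_auc_within_sample_range(self):
        rng = np.random.default_rng(2)
        curves = [
            sls.roc(rng.random(6), rng.random(6)) for _ in range(20)
        ]
        avg = average_roc(curves)
        aucs = [c.auc for c in curves]
        assert min(aucs) <= avg.mean_auc <= max(aucs)
        assert avg.mean_tpr[0] >= 0.0 and avg.mean_tpr[-1] == 1.0


def bruteforce_reduce(scored):
    """Independent fix-point of the elimination rule: removed iff overlapped
    by a surviving candidate with strictly higher cscore (well-founded by
    descending score)."""
    order = sorted(
        scored, key=lambda c: (-c.cscore, -len(c.candidate.interval),
                               c.candidate.interval.start),
    )
    surviving: list = []
    for cand in order:
        if not any(
            s.cscore > cand.cscore
            and s.candidate.interval.overlaps(cand.candidate.interval)
            for s in surviving
        ):
            surviving.append(cand)
    return sorted(surviving, key=lambda c: c.candidate.interval.start)


class TestReduceByOverlap:
    def test_higher_score_eliminates_overlapped(self):
        a = _scored(0, 100, 0.9)
        b = _scored(50, 150, 0.5)
        assert reduce_by_overlap([a, b]) == [a]

    def test_disjoint_candidates_all_kept(self):
        a = _scored(0, 100, 0.9)
        b = _scored(200, 300, 0.5)
        assert reduce_by_overlap([b, a]) == [a, b]

    def test_cutoff_applied_first(self):
        a = _scored(0, 100, 0.9)
        b = _scored(200, 300, 0.1)
        assert reduce_by_overlap([a, b], cutoff=0.5) == [a]

    def test_shadowed_candidate_survives_chain(self):
        # A eliminates B; C only overlapped B, so C survives
        a = _scored(0, 100, 0.9)
        b = _scored(90, 190, 0.5)
        c = _scored(180, 280, 0.3)
        assert reduce_by_overlap([a, b, c]) == [a, c]

    def test_matches_bruteforce_fixpoint_on_random_chains(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(2, 12))
            scored = []
            pos = 0
            for _ in range(n):
                pos += int(rng.integers(10, 120))
                length = int(rng.integers(60, 160))
                scored.append(_scored(pos, pos + length, float(rng.integers(0, 10)) / 10))
            result = reduce_by_overlap(scored)
            assert result == bruteforce_reduce(scored)

    def test_pairwise_nonoverlapping_when_scores_distinct(self):
        rng = np.random.default_rng(4)
        scored = []
        pos = 0
        scores = rng.permutation(30) / 30
        for k in range(30):
            pos += int(rng.integers(10, 100))
            scored.append(_scored(pos, pos + int(rng.integers(50, 150)), float(scores[k])))
        result = reduce_by_overlap(scored)
        for i, a in enumerate(result):
            for b in result[i + 1 :]:
                assert not a.candidate.interval.overlaps(b.candidate.interval)
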