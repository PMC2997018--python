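"""The four candidate measures and their supporting Markov machinery."""

import math

import numpy as np
import pytest

import stemloop_sieve as sls
from stemloop_sieve.enumeration import PrecursorCandidate
from stemloop_sieve.fold import FoldResult, SecondaryStructure, base_pair_distance
from stemloop_sieve.io import GenomicInterval
from stemloop_sieve.markov import MarkovModel
from stemloop_sieve.measures import (
    MeasureParams,
    candidate_seed,
    evaluate_candidate,
    one_mutant_neighbourhood,
    train_context_models,
)


class TestAmfeMfei:
    @pytest.mark.parametrize(
        "mfe,length,expected", [(-45, 100, -45), (0, 70, 0), (-35, 70, -50)]
    )
    def test_amfe(self, mfe, length, expected):
        assert sls.amfe(mfe, length) == pytest.approx(expected)

    def test_amfe_zero_length_rejected(self):
        with pytest.raises(ValueError):
            sls.amfe(-10, 0)

    def test_mfei_examples_and_gc_zero_undefined(self):
        assert math.isnan(sls.mfei(-35, 70, 0.0))
        assert sls.mfei(-50, 100, 0.5) == pytest.approx(-1.0)
        assert sls.mfei(-50, 100, 1.0) == pytest.approx(-0.5)


class TestFoldingRobustness:
    def test_normalisation_per_100nt(self):
        seq = "GGGGGGGAAAAACCCCCCC"  # 19 nt
        diversity = sls.ensemble_diversity(seq).diversity
        assert sls.folding_robustness(seq) == pytest.approx(
            diversity * 100.0 / 19
        )

    def test_unpairable_sequence_is_zero(self):
        assert sls.folding_robustness("AAAAAAAAAACA") == 0.0

    def test_invariant_under_t_u_respelling(self):
        assert sls.folding_robustness("GGGGGAAUAUCCCCC") == pytest.approx(
            sls.folding_robustness("GGGGGAATATCCCCC")
        )


def _make_candidate(genome_seq, start, end, contig="c", strand="+"):
    seq = genome_seq[start:end]
    fr = sls.mfe_fold(seq)
    hp = fr.structure.hairpin_pairs
    li, lj = hp[0]
    return PrecursorCandidate(
        interval=GenomicInterval(contig, start, end, strand),
        seq=seq,
        structure=fr.structure.dotbracket,
        mfe=fr.mfe,
        loop=GenomicInterval(contig, start + li + 1, start + lj, strand),
        arm5_len=li + 1,
        arm3_len=len(seq) - lj,
    )


class TestContextModels:
    def test_pseudocount_arithmetic(self):
        model = MarkovModel.train("AAAA", pseudocount=1.0)
        # 3 observed A->A transitions + pseudocount 1, row total 3 + 4
        assert model.transition[0, 0] == pytest.approx(4 / 7)
        assert model.transition[0, 1] == pytest.approx(1 / 7)

    def test_alternating_context_dominated_by_observed_transitions(self):
        model = MarkovModel.train("ACACACACACAC", pseudocount=1.0)
        a, c = 0, 1
        assert model.transition[a, c] == model.transition[:, :].max(axis=None)
        assert model.transition[c, a] > model.transition[c, c]

    def test_contig_start_falls_back_to_genome_model(self):
        hairpin = sls.make_hairpin(arm_len=20, loop_len=6, gc_fraction=0.8,
                                   n_mismatches=0, rng_seed=0)
        genome = {"c": hairpin + "ACGU" * 300}
        cand = _make_candidate(genome["c"], 0, len(hairpin))
        models = train_context_models(genome, cand)
        assert models.fallback

    def test_flank_lengths_match_candidate_length(self):
        rng = np.random.default_rng(0)
        genome = {"c": "".join(rng.choice(list("ACGU"), 600))}
        cand = _make_candidate(
            genome["c"][:200] + sls.make_hairpin(rng_seed=1) + genome["c"][:200],
            200, 268,
        )
        genome2 = {"c": genome["c"][:200] + sls.make_hairpin(rng_seed=1) + genome["c"][:200]}
        models = train_context_models(genome2, cand)
        assert not models.fallback


class FakeFolder:
    """Scripted engine: returns canned structures by sequence length."""

    name = "fake"
    version = "0"

    def __init__(self, script):
        self.script = script

    def fold(self, seq):
        db = self.script(seq)
        return FoldResult(SecondaryStructure(db), -30.0)


class TestContextRobustness:
    def _candidate(self):
        seq = "GGGGGGGGAAAAACCCCCCCC"  # 21 nt
        db = "((((((((.....))))))))"
        return PrecursorCandidate(
            interval=GenomicInterval("c", 100, 121, "+"),
            seq=seq, structure=db, mfe=-25.0,
            loop=GenomicInterval("c", 108, 113, "+"),
            arm5_len=8, arm3_len=8,
        )

    def _genome(self):
        rng = np.random.default_rng(5)
        flank = "".join(rng.choice(list("ACGU"), 121))
        return {"c": flank[:100] + self._candidate().seq + flank[100:]}

    def test_perfect_preservation_gives_one(self):
        cand = self._candidate()

        def script(seq):
            off = (len(seq) - 21) // 2
            return "." * off + cand.structure + "." * (len(seq) - off - 21)

        value = sls.context_robustness(
            cand, self._genome(), n_contexts=6, seed=0, engine=FakeFolder(script)
        )
        assert value == 1.0

    def test_total_destruction_gives_zero(self):
        value = sls.context_robustness(
            self._candidate(), self._genome(), n_contexts=6, seed=0,
            engine=FakeFolder(lambda seq: "." * len(seq)),
        )
        assert value == 0.0

    def test_fixed_seed_reproducible(self):
        cand = self._candidate()
        genome = self._genome()
        a = sls.context_robustness(cand, genome, n_contexts=4, seed=11)
        b = sls.context_robustness(cand, genome, n_contexts=4, seed=11)
        assert a == b
        assert 0.0 <= a <= 1.0

    def test_even_count_median_averages_middle_two(self):
        cand = self._candidate()
        toggle = iter([True, False] * 3)

        def script(seq):
            off = (len(seq) - 21) // 2
            if next(toggle):
                return "." * off + cand.structure + "." * (len(seq) - off - 21)
            # keep half of the 8 pairs
            db = "." * off + "((((....().....))))".replace("(", "(", 1) + "." * (len(seq) - off - 21)
            kept = "((((............))))"
            half = "." * off + "((((" + "." * 13 + "))))" + "." * (len(seq) - off - 21)
            return half

        value = sls.context_robustness(
            cand, self._genome(), n_contexts=2, seed=0, engine=FakeFolder(script)
        )
        assert value == pytest.approx((1.0 + 0.5) / 2)


class TestMutationRobustness:
    def test_neighbourhood_is_exactly_3l(self):
        seq = "ACGUACGUAC"
        muts = one_mutant_neighbourhood(seq)
        assert len(muts) == 3 * len(seq)
        assert len(set(muts)) == 3 * len(seq)
        assert all(sum(a != b for a, b in zip(seq, m)) == 1 for m in muts)

    def test_n_positions_excluded(self):
        assert len(one_mutant_neighbourhood("ACNGU")) == 3 * 4

    def test_unpairable_candidate_scores_zero(self):
        length = 20
        cand = PrecursorCandidate(
            interval=GenomicInterval("c", 0, length, "+"),
            seq="A" * length, structure="." * length, mfe=0.0,
            loop=GenomicInterval("c", 8, 12, "+"), arm5_len=8, arm3_len=8,
        )
        assert sls.mutation_robustness(cand) == 0.0

    def test_matches_bruteforce_recomputation(self):
        hairpin = sls.make_hairpin(arm_len=14, loop_len=6, gc_fraction=0.7,
                                   n_mismatches=1, rng_seed=2)  # 34 nt
        cand = _make_candidate(hairpin, 0, len(hairpin))
        ours = sls.mutation_robustness(cand)
        # independent loop over the mutants
        original = SecondaryStructure(cand.structure)
        distances = []
        for pos in range(len(hairpin)):
            for base in "ACGU":
                if base == hairpin[pos]:
                    continue
                mutant = hairpin[:pos] + base + hairpin[pos + 1 :]
                distances.append(
                    base_pair_distance(original, sls.mfe_fold(mutant).structure)
                )
        oracle = float(np.median(distances)) * 100.0 / len(hairpin)
        assert ours == pytest.approx(oracle)


class TestEvaluateCandidate:
    def test_batch_independence_of_measure_vectors(self, tiny_genome, tiny_candidates):
        genome = tiny_genome.as_genome()
        params = MeasureParams(n_contexts=4, seed=3)
        # two shortest candidates keep the 1-mutant folding cheap
        cands = sorted(tiny_candidates, key=lambda c: len(c.seq))[:2]
        whole = [evaluate_candidate(c, genome, params) for c in cands]
        shuffled = [evaluate_candidate(c, genome, params) for c in cands[::-1]]
        assert whole[0] == shuffled[1]
        assert whole[1] == shuffled[0]

    def test_candidate_seed_stable_and_in_range(self, tiny_candidates):
        c = tiny_candidates[0]
        assert candidate_seed(7, c) == candidate_seed(7, c)
        assert 0 <= candidate_seed(7, c) < 2**31
        assert candidate_seed(7, c) != candidate_seed(8, c)

    def test_stable_gc_hairpin_less_diverse_than_marginal_au_hairpin(self):
        stable = sls.make_hairpin(arm_len=25, loop_len=8, gc_fraction=0.9,
                                  n_mismatches=0, rng_seed=4)
        marginal = sls.make_hairpin(arm_len=25, loop_len=8, gc_fraction=0.15,
                                    n_mismatches=3, rng_seed=4)
        assert sls.folding_robustness(stable) < sls.folding_robustness(marginal)
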