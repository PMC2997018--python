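"""Per-candidate robustness and stability measures.

Four measures are computed for every precursor candidate:

* **AMFE** -- length-adjusted minimum free energy, 100 * MFE / length
  (kcal/mol per 100 nt).  More negative is better: normalising by length
  removes the advantage long structures have simply by containing more
  pairs.
* **Robustness of folding** -- the Boltzmann ensemble diversity anchored at
  the MFE structure, normalised per 100 nt.  Lower values mean the MFE
  stem-loop dominates the thermodynamic ensemble.
* **Robustness to context** -- the candidate is refolded inside random
  flanking contexts drawn from first-order Markov models trained on its own
  genomic neighbourhood; the measure is the median fraction of the original
  base pairs preserved (in [0, 1], higher is better).
* **Robustness to mutations** -- every single-point mutant is folded and the
  measure is the median base-pair distance to the original structure,
  normalised per 100 nt (lower is better).

Medians (not means) summarise the context and mutation replicates: the
underlying distributions are typically skewed and the median is the more
robust centrality measure.  All per-candidate computation is independent of
other candidates, so the candidate set can be partitioned into batches whose
merged output is identical to a single-batch run.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np

from .enumeration import PrecursorCandidate
from .fold import (
    SecondaryStructure,
    base_pair_distance,
    ensemble_diversity,
    mfe_fold,
    structure_preserved_fraction,
)
from .io import GenomicInterval, reverse_complement
from .markov import MarkovModel

MEASURE_NAMES = (
    "amfe", "folding_robustness", "context_robustness", "mutation_robustness",
)

#: Direction in which a measure value gets *worse* (for significance
#: calibration): stability and distance measures worsen upward, the
#: preserved-structure fraction worsens downward.
WORSE_DIRECTION = {
    "amfe": "higher",
    "folding_robustness": "higher",
    "context_robustness": "lower",
    "mutation_robustness": "higher",
}


@dataclass(frozen=True)
class MeasureVector:
    amfe: float
    folding_robustness: float
    context_robustness: float
    mutation_robustness: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in MEASURE_NAMES}


def amfe(mfe: float, length: int) -> float:
    """Adjusted MFE: 100 * MFE / length (kcal/mol per 100 nt)."""
    if length <= 0:
        raise ValueError("length must be positive")
    return 100.0 * mfe / length


def mfei(mfe: float, length: int, gc: float) -> float:
    """Minimum free energy index: AMFE / (100 * GC fraction).

    Ill-defined for GC-free sequences (a real occurrence in AT-rich genomic
    regions); returns NaN in that case.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if gc <= 0.0:
        return math.nan
    return amfe(mfe, length) / (100.0 * gc)


def folding_robustness(seq: str, engine=None) -> float:
    """Ensemble diversity of the candidate sequence per 100 nt."""
    return ensemble_diversity(seq, engine=engine).diversity * 100.0 / len(seq)


@dataclass
class ContextModels:
    upstream: MarkovModel
    downstream: MarkovModel
    fallback: bool = False  # True when the genome-wide model had to stand in


def _flanks(genome_seq: str, interval: GenomicInterval) -> tuple[str, str]:
    """Genomic flanking sequences of the candidate, each as long as the
    candidate itself (truncated at contig ends), in transcript orientation."""
    length = len(interval)
    left = genome_seq[max(0, interval.start - length) : interval.start]
    right = genome_seq[interval.end : interval.end + length]
    if interval.strand == "-":
        return reverse_complement(right), reverse_complement(left)
    return left, right


def train_context_models(
    genome: dict[str, str],
    candidate: PrecursorCandidate,
    min_context: int = 10,
    genome_model: MarkovModel | None = None,
) -> ContextModels:
    """First-order models of the candidate's upstream and downstream
    genomic context (transition pseudocount 1; initial = marginal base
    frequency of the training context).

    Contexts shorter than ``min_context`` nt (candidate at a contig end)
    fall back to a genome-wide model, flagged in the result.
    """
    up_seq, down_seq = _flanks(genome[candidate.interval.contig], candidate.interval)

    def _train(ctx: str) -> MarkovModel | None:
        if len(ctx) < min_context:
            return None
        try:
            return MarkovModel.train(ctx, pseudocount=1.0)
        except ValueError:  # e.g. all-N context
            return None

    up = _train(up_seq)
    down = _train(down_seq)
    fallback = up is None or down is None
    if fallback:
        if genome_model is None:
            genome_model = MarkovModel.train(genome.values())
        up = up or genome_model
        down = down or genome_model
    return ContextModels(up, down, fallback)


def context_robustness(
    candidate: PrecursorCandidate,
    genome: dict[str, str],
    n_contexts: int = 100,
    seed: int | np.random.Generator = 0,
    engine=None,
    models: ContextModels | None = None,
) -> float:
    """Median fraction of the candidate's base pairs preserved when refolded
    inside `n_contexts` random Markov-generated flanking contexts."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if models is None:
        models = train_context_models(genome, candidate)
    original = candidate.secondary_structure
    if not original.pairs:
        raise ValueError("candidate has no base pairs")
    length = len(candidate.seq)
    fractions = np.empty(n_contexts)
    for k in range(n_contexts):
        up = models.upstream.sample(length, rng)
        down = models.downstream.sample(length, rng)
        refolded = mfe_fold(up + candidate.seq + down, engine=engine)
        fractions[k] = structure_preserved_fraction(
            original, refolded.structure, offset=len(up)
        )
    return float(np.median(fractions))


def one_mutant_neighbourhood(seq: str) -> list[str]:
    """All single-point mutants of `seq` (3 per non-N position, in 5'->3'
    position order; N positions are never mutated)."""
    out = []
    for i, base in enumerate(seq):
        if base == "N":
            continue
        for alt in "ACGU":
            if alt != base:
                out.append(seq[:i] + alt + seq[i + 1 :])
    return out


def mutation_robustness(candidate: PrecursorCandidate, engine=None) -> float:
    """Median base-pair distance between the candidate structure and each of
    its folded 1-mutants, per 100 nt."""
    original = candidate.secondary_structure
    length = len(candidate.seq)
    distances = [
        base_pair_distance(original, mfe_fold(mut, engine=engine).structure)
        for mut in one_mutant_neighbourhood(candidate.seq)
    ]
    if not distances:
        return 0.0
    return float(np.median(distances)) * 100.0 / length


@dataclass
class MeasureParams:
    n_contexts: int = 100
    seed: int = 0
    min_context: int = 10


def candidate_seed(base_seed: int, candidate: PrecursorCandidate) -> int:
    """Stable per-candidate RNG seed derived from the stage seed and the
    candidate's coordinates, so that measure values do not depend on how the
    candidate set is partitioned into batches."""
    key = (f"{candidate.interval.contig}:{candidate.interval.start}-"
           f"{candidate.interval.end}({candidate.interval.strand})")
    return (int(base_seed) * 2654435761 + zlib.crc32(key.encode())) % (2**31)


def evaluate_candidate(
    candidate: PrecursorCandidate,
    genome: dict[str, str],
    params: MeasureParams | None = None,
    engine=None,
    genome_model: MarkovModel | None = None,
) -> MeasureVector:
    """All four measures for one candidate."""
    params = params or MeasureParams()
    models = train_context_models(
        genome, candidate, params.min_context, genome_model
    )
    return MeasureVector(
        amfe=amfe(candidate.mfe, len(candidate.seq)),
        folding_robustness=folding_robustness(candidate.seq, engine=engine),
        context_robustness=context_robustness(
            candidate, genome, params.n_contexts,
            seed=candidate_seed(params.seed, candidate),
            engine=engine, models=models,
        ),
        mutation_robustness=mutation_robustness(candidate, engine=engine),
    )


def evaluate_candidates(
    candidates: list[PrecursorCandidate],
    genome: dict[str, str],
    params: MeasureParams | None = None,
    engine=None,
) -> list[MeasureVector]:
    """Measure a batch of candidates (order-independent per candidate)."""
    params = params or MeasureParams()
    genome_model: MarkovModel | None = None
    needs_fallback = any(
        c.interval.start < params.min_context
        or len(genome[c.interval.contig]) - c.interval.end < params.min_context
        for c in candidates
    )
    if needs_fallback:
        genome_model = MarkovModel.train(genome.values())
    return [
        evaluate_candidate(c, genome, params, engine, genome_model)
        for c in candidates
    ]
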