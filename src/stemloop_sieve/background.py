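"""Artificial-genome background and the combined significance score (cscore).

A first-order Markov model fitted to the study genome generates an
artificial genome with matching dinucleotide statistics.  Running the full
enumeration and measurement pipeline on that artificial genome yields, for
each measure, an empirical distribution of values attainable by stem-loops
that owe their robustness to base composition alone.  The significance of a
real candidate's measure value is the fraction of background candidates with
strictly *worse* values; the cscore is the product of the four
significances, ranging from 0 (worse than the entire background on at least
one measure) to 1 (better than the entire background on all four).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .enumeration import EnumerationParams, PrecursorCandidate, enumerate_candidates
from .markov import MarkovModel
from .measures import (
    MEASURE_NAMES,
    WORSE_DIRECTION,
    MeasureParams,
    MeasureVector,
    evaluate_candidates,
)


def train_genome_markov(genome: Iterable[str] | str | dict[str, str]) -> MarkovModel:
    """First-order model of the genome's dinucleotide statistics
    (N-containing dinucleotides skipped; initial = marginal base frequency)."""
    if isinstance(genome, dict):
        genome = list(genome.values())
    return MarkovModel.train(genome, pseudocount=0.0)


def generate_artificial_genome(
    model: MarkovModel, length: int = 5_000_000, seed: int = 0
) -> str:
    """A single Markov-generated sequence of exactly `length` nt."""
    rng = np.random.default_rng(seed)
    return model.sample(length, rng)


@dataclass
class EmpiricalBackground:
    """Per-measure sorted value arrays from artificial-genome candidates."""

    values: dict[str, np.ndarray]  # sorted ascending
    orientations: dict[str, str] = field(
        default_factory=lambda: dict(WORSE_DIRECTION)
    )
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {name: len(arr) for name, arr in self.values.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"unequal background array lengths: {lengths}")
        if self.n < 1:
            raise ValueError("background needs at least one candidate")
        for name, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if np.any(np.diff(arr) < 0):
                arr = np.sort(arr)
            self.values[name] = arr

    @property
    def n(self) -> int:
        return len(next(iter(self.values.values())))

    @classmethod
    def from_vectors(
        cls, vectors: Sequence[MeasureVector], provenance: dict | None = None
    ) -> "EmpiricalBackground":
        values = {
            name: np.sort([getattr(v, name) for v in vectors])
            for name in MEASURE_NAMES
        }
        return cls(values=values, provenance=provenance or {})

    def to_json(self, path: str | Path) -> None:
        payload = {
            "values": {k: list(map(float, v)) for k, v in self.values.items()},
            "orientations": self.orientations,
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "EmpiricalBackground":
        payload = json.loads(Path(path).read_text())
        return cls(
            values={k: np.asarray(v, float) for k, v in payload["values"].items()},
            orientations=payload["orientations"],
            provenance=payload.get("provenance", {}),
        )


def build_background(
    artificial_genome: str,
    enum_params: EnumerationParams | None = None,
    measure_params: MeasureParams | None = None,
    max_candidates: int | None = None,
    subsample_seed: int = 0,
    engine=None,
    provenance: dict | None = None,
) -> EmpiricalBackground:
    """Enumerate and measure candidates in the artificial genome.

    Background candidates pass through exactly the same filters and measure
    parameters as real candidates, keeping the distributions comparable.
    ``max_candidates`` optionally subsamples the candidate set (seeded,
    uniform) before the expensive measure stage.
    """
    genome = {"artificial": artificial_genome}
    candidates = enumerate_candidates(genome, enum_params, engine=engine)
    if not candidates:
        raise ValueError(
            "artificial genome yielded no candidates; use a longer genome"
        )
    if max_candidates is not None and len(candidates) > max_candidates:
        rng = np.random.default_rng(subsample_seed)
        idx = np.sort(rng.choice(len(candidates), max_candidates, replace=False))
        candidates = [candidates[i] for i in idx]
    vectors = evaluate_candidates(candidates, genome, measure_params, engine=engine)
    prov = dict(provenance or {})
    prov.setdefault("n_candidates", len(candidates))
    return EmpiricalBackground.from_vectors(vectors, provenance=prov)


def significance(value: float, background: np.ndarray, orientation: str) -> float:
    """Fraction of background values strictly worse than `value`.

    Ties count as not-worse: a candidate identical to the background cannot
    claim superiority over it.
    """
    arr = np.asarray(background, dtype=float)
    if arr.size == 0:
        raise ValueError("empty background array")
    if orientation == "higher":
        worse = arr.size - np.searchsorted(arr, value, side="right")
    elif orientation == "lower":
        worse = np.searchsorted(arr, value, side="left")
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return float(worse) / arr.size


@dataclass
class ScoredCandidate:
    candidate: PrecursorCandidate
    measures: MeasureVector
    significances: dict[str, float]
    cscore: float


def cscore(
    measures: MeasureVector, background: EmpiricalBackground
) -> tuple[dict[str, float], float]:
    """Per-measure significances and their product."""
    sigs = {
        name: significance(
            getattr(measures, name),
            background.values[name],
            background.orientations[name],
        )
        for name in MEASURE_NAMES
    }
    product = float(np.prod(list(sigs.values())))
    return sigs, product


def score_candidates(
    candidates: Sequence[PrecursorCandidate],
    vectors: Sequence[MeasureVector],
    background: EmpiricalBackground,
) -> list[ScoredCandidate]:
    out = []
    for cand, vec in zip(candidates, vectors, strict=True):
        sigs, product = cscore(vec, background)
        out.append(ScoredCandidate(cand, vec, sigs, product))
    return out
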