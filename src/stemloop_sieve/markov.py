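"""Single-state first-order nucleotide Markov chains.

Used both to model the genomic context flanking a candidate (for the
context-robustness measure) and to generate the dinucleotide-matched
artificial genome against which measure significances are calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

BASES = "ACGU"
_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class MarkovModel:
    """Initial distribution over A/C/G/U plus a 4x4 row-stochastic
    transition matrix."""

    initial: np.ndarray
    transition: np.ndarray

    def __post_init__(self) -> None:
        initial = np.asarray(self.initial, dtype=float)
        transition = np.asarray(self.transition, dtype=float)
        object.__setattr__(self, "initial", initial)
        object.__setattr__(self, "transition", transition)
        if initial.shape != (4,) or transition.shape != (4, 4):
            raise ValueError("model must be a length-4 initial and 4x4 transition")
        if np.any(initial < 0) or np.any(transition < 0):
            raise ValueError("negative probabilities")
        if abs(initial.sum() - 1.0) > 1e-9:
            raise ValueError("initial distribution does not sum to 1")
        if np.any(np.abs(transition.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition rows do not sum to 1")

    @classmethod
    def uniform(cls) -> "MarkovModel":
        return cls(np.full(4, 0.25), np.full((4, 4), 0.25))

    @classmethod
    def train(
        cls,
        sequences: Iterable[str] | str,
        pseudocount: float = 0.0,
    ) -> "MarkovModel":
        """Fit from observed dinucleotide counts pooled over sequences.

        N-containing dinucleotides are skipped and N does not contribute to
        the marginal.  ``pseudocount`` is added to every transition cell
        (context models use 1 to avoid zero-probability deadlocks on short
        training contexts; genome-wide models use 0).  A row with no
        observations and no pseudocount falls back to uniform.
        """
        if isinstance(sequences, str):
            sequences = [sequences]
        counts = np.full((4, 4), float(pseudocount))
        marginal = np.zeros(4)
        seen_any = False
        for seq in sequences:
            codes = np.array([_INDEX.get(b, -1) for b in seq], dtype=np.int64)
            valid = codes >= 0
            if valid.any():
                seen_any = True
                np.add.at(marginal, codes[valid], 1)
            ok = valid[:-1] & valid[1:]
            if ok.any():
                np.add.at(counts, (codes[:-1][ok], codes[1:][ok]), 1)
        if not seen_any:
            raise ValueError("no A/C/G/U bases in training data")
        rows = counts.sum(axis=1, keepdims=True)
        transition = np.where(rows > 0, counts / np.where(rows > 0, rows, 1), 0.25)
        initial = marginal / marginal.sum()
        return cls(initial, transition)

    def sample(self, length: int, rng: np.random.Generator) -> str:
        """Draw a sequence: first base from the initial distribution, each
        subsequent base from the transition row of its predecessor."""
        if length <= 0:
            return ""
        cum_init = np.cumsum(self.initial)
        cum_rows = np.cumsum(self.transition, axis=1)
        u = rng.random(length)
        out = np.empty(length, dtype=np.int64)
        out[0] = np.searchsorted(cum_init, u[0], side="right")
        for k in range(1, length):
            out[k] = np.searchsorted(cum_rows[out[k - 1]], u[k], side="right")
        out = np.minimum(out, 3)  # guard against u == 1.0 edge
        return "".join(BASES[i] for i in out)

    def dinucleotide_frequencies(self) -> np.ndarray:
        """Stationary-initial joint dinucleotide frequencies
        P(ab) = pi_a * T[a, b] using the model's initial as marginal."""
        return self.initial[:, None] * self.transition
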