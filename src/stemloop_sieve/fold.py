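"""Thermodynamic secondary-structure engine contract and structure algebra.

The default engine binds ViennaRNA at its standard parameters (37 degC,
Turner energies).  Absolute MFE values depend on the engine version, which is
therefore recorded in run provenance.  The engine is pluggable: anything with
``fold`` / ``pair_probabilities`` methods can stand in (tests use a scripted
fake to pin down edge-case behaviour).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

from .io import canonicalise

#: Boltzmann factor kT at 37 degC, kcal/mol (Vienna reports dekacal/mol).
KT_37C = 0.6163207755


class FoldingError(RuntimeError):
    """Engine failure, annotated with the offending sequence."""


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free secondary structure in dot-bracket notation."""

    dotbracket: str

    def __post_init__(self) -> None:
        depth = 0
        for ch in self.dotbracket:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise ValueError("unbalanced dot-bracket string")
            elif ch != ".":
                raise ValueError(f"illegal dot-bracket character {ch!r}")
        if depth != 0:
            raise ValueError("unbalanced dot-bracket string")

    def __len__(self) -> int:
        return len(self.dotbracket)

    @cached_property
    def pairs(self) -> frozenset[tuple[int, int]]:
        """Base pairs as (i, j) with i < j, 0-based."""
        stack: list[int] = []
        out = set()
        for i, ch in enumerate(self.dotbracket):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                out.add((stack.pop(), i))
        return frozenset(out)

    @cached_property
    def hairpin_pairs(self) -> tuple[tuple[int, int], ...]:
        """Closing pairs of hairpin loops (pairs enclosing no other pair),
        in 5'-to-3' order."""
        paired = sorted(self.pairs)
        out = []
        for (i, j) in paired:
            if not any(i < a and b < j for a, b in paired):
                out.append((i, j))
        return tuple(sorted(out))


@dataclass(frozen=True)
class FoldResult:
    structure: SecondaryStructure
    mfe: float  # kcal/mol


@dataclass(frozen=True)
class EnsembleStats:
    """Boltzmann-ensemble summary: expected base-pair distance to the MFE
    structure, <d_bp> = sum_i d_bp(s0, s_i) exp(-dG_i/kT) / Z."""

    diversity: float


class ViennaFolder:
    """Reference engine: ViennaRNA with standard parameters at 37 degC."""

    name = "vienna"

    def __init__(self) -> None:
        import RNA

        self._rna = RNA

    @property
    def version(self) -> str:
        return getattr(self._rna, "__version__", "unknown")

    def fold(self, seq: str) -> FoldResult:
        seq = canonicalise(seq)
        if len(seq) == 0:
            raise FoldingError("cannot fold an empty sequence")
        try:
            db, mfe = self._rna.fold(seq)
        except Exception as exc:  # pragma: no cover - engine internal
            raise FoldingError(f"engine failed on {seq[:40]!r}...") from exc
        # Vienna energies are exact multiples of 0.01 kcal/mol; rounding
        # removes float32 conversion noise so values round-trip through text
        return FoldResult(SecondaryStructure(db), round(float(mfe), 2))

    def pair_probabilities(self, seq: str) -> tuple[FoldResult, dict[tuple[int, int], float]]:
        """MFE fold plus Boltzmann pair probabilities p_ij (0-based keys)."""
        seq = canonicalise(seq)
        if len(seq) == 0:
            raise FoldingError("cannot fold an empty sequence")
        try:
            fc = self._rna.fold_compound(seq)
            db, mfe = fc.mfe()
            fc.exp_params_rescale(mfe)
            fc.pf()
            bpp = fc.bpp()  # 1-indexed upper-triangular matrix
        except Exception as exc:  # pragma: no cover
            raise FoldingError(f"engine failed on {seq[:40]!r}...") from exc
        probs: dict[tuple[int, int], float] = {}
        n = len(seq)
        for i in range(1, n + 1):
            row = bpp[i]
            for j in range(i + 1, n + 1):
                p = row[j]
                if p > 0.0:
                    probs[(i - 1, j - 1)] = p
        # Vienna energies are exact multiples of 0.01 kcal/mol; rounding
        # removes float32 conversion noise so values round-trip through text
        return FoldResult(SecondaryStructure(db), round(float(mfe), 2)), probs


_DEFAULT_ENGINE: ViennaFolder | None = None


def get_engine(name: str = "vienna"):
    """Engine factory for the ``folding.engine`` config key."""
    global _DEFAULT_ENGINE
    if name != "vienna":
        raise ValueError(f"unknown folding engine {name!r}")
    if _DEFAULT_ENGINE is None:
        _DEFAULT_ENGINE = ViennaFolder()
    return _DEFAULT_ENGINE


def mfe_fold(seq: str, engine=None) -> FoldResult:
    """Minimum-free-energy fold at 37 degC (deterministic per engine version)."""
    return (engine or get_engine()).fold(seq)


def base_pair_distance(a: SecondaryStructure, b: SecondaryStructure) -> int:
    """Size of the symmetric difference of the two base-pair sets.

    A metric on equal-length structures; zero iff the pair sets coincide.
    """
    if len(a) != len(b):
        raise ValueError(f"structure length mismatch: {len(a)} vs {len(b)}")
    return len(a.pairs ^ b.pairs)


def diversity_from_pair_probs(
    mfe_pairs: frozenset[tuple[int, int]],
    probs: dict[tuple[int, int], float],
) -> float:
    """Closed form for the expected base-pair distance to the MFE structure:

        <d_bp> = sum_{(i,j) in s0} (1 - p_ij) + sum_{(i,j) not in s0} p_ij

    Exact with respect to the defining Boltzmann sum, since d_bp decomposes
    over individual pairs.
    """
    d = sum(p for ij, p in probs.items() if ij not in mfe_pairs)
    d += sum(1.0 - probs.get(ij, 0.0) for ij in mfe_pairs)
    return float(d)


def ensemble_diversity(seq: str, engine=None) -> EnsembleStats:
    """Expected base-pair distance between the MFE structure and the
    thermodynamic ensemble (anchored at s0, not the engine's centroid-free
    native diversity)."""
    fold_result, probs = (engine or get_engine()).pair_probabilities(seq)
    return EnsembleStats(diversity_from_pair_probs(fold_result.structure.pairs, probs))


def structure_preserved_fraction(
    original: SecondaryStructure,
    refolded: SecondaryStructure,
    offset: int,
) -> float:
    """Fraction of the original base pairs still present when the sequence
    is embedded at ``offset`` inside a longer refolded sequence."""
    if not original.pairs:
        raise ValueError("original structure has no base pairs")
    if offset < 0 or offset + len(original) > len(refolded):
        raise ValueError("offset places the original outside the refolded structure")
    kept = sum(
        1 for (i, j) in original.pairs
        if (i + offset, j + offset) in refolded.pairs
    )
    return kept / len(original.pairs)
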