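"""Reproducible synthetic genomes with planted pre-miRNA-like hairpins.

Every stage of the sieve can be exercised without downloading a real genome:
a background sequence drawn from a first-order Markov model stands in for
the genome, and hairpins with prescribed arm length, loop length, GC content
and arm mismatches are planted at recorded positions to act as known
precursors.  A fixture is fully determined by (model, plant specs, seed).

What this emulates -- and what it does not: the fixtures reproduce the
*compositional* background against which real precursors stand out, but not
transcription, chromatin context, repeat families or evolutionary
conservation.  Passing tests on planted genomes therefore demonstrates that
the sieve separates robust stem-loops from composition-matched background,
not that it would achieve the same rates on a real genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fold import mfe_fold
from .io import GenomicInterval, reverse_complement
from .markov import BASES, MarkovModel

#: Bases that pair with a given base under Watson-Crick or G:U wobble rules.
_PAIRING_PARTNERS = {"A": "U", "C": "G", "G": "CU", "U": "AG"}


@dataclass(frozen=True)
class HairpinSpec:
    """Parameters of one planted hairpin (defaults give a robust, clearly
    pre-miRNA-like stem-loop: 30-bp arms, 8-nt loop, GC-rich, 2 mismatches)."""

    arm_len: int = 30
    loop_len: int = 8
    gc_fraction: float = 0.7
    n_mismatches: int = 2

    def __post_init__(self) -> None:
        if self.arm_len < 1:
            raise ValueError("arm_len must be >= 1")
        if self.loop_len < 3:
            raise ValueError("loop_len must be >= 3 (minimum hairpin loop)")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        if not 0 <= self.n_mismatches <= self.arm_len:
            raise ValueError("n_mismatches must be in [0, arm_len]")

    @property
    def length(self) -> int:
        return 2 * self.arm_len + self.loop_len


def make_hairpin(
    spec: HairpinSpec | None = None,
    rng_seed: int | np.random.Generator = 0,
    **spec_kwargs,
) -> str:
    """A hairpin sequence: random 5' arm at the requested GC content, random
    loop, and a 3' arm that is the reverse complement of the 5' arm except
    at `n_mismatches` positions (mismatches are true non-pairing bases, not
    G:U wobbles)."""
    spec = spec or HairpinSpec(**spec_kwargs)
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    gc = spec.gc_fraction
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G U
    arm5 = "".join(rng.choice(list(BASES), spec.arm_len, p=p))
    loop = "".join(rng.choice(list(BASES), spec.loop_len))
    arm3 = list(reverse_complement(arm5))
    if spec.n_mismatches:
        positions = rng.choice(spec.arm_len, spec.n_mismatches, replace=False)
        for pos in positions:
            partner = arm5[spec.arm_len - 1 - pos]
            choices = [b for b in BASES if b not in _PAIRING_PARTNERS[partner]]
            arm3[pos] = choices[rng.integers(len(choices))]
    return arm5 + loop + "".join(arm3)


@dataclass
class PlantedGenome:
    """A Markov background with hairpins planted at known positions."""

    seq: str
    truth: list[GenomicInterval]
    params: dict = field(default_factory=dict)

    def as_genome(self, contig: str = "synth") -> dict[str, str]:
        return {contig: self.seq}


def _validate_plant(hairpin: str, max_mfe: float = -20.0, min_arm: int = 16,
                    engine=None) -> None:
    """Planted hairpins in the robust regime must pass the candidate filters
    when folded in isolation; generation fails loudly otherwise."""
    fr = mfe_fold(hairpin, engine=engine)
    hp = fr.structure.hairpin_pairs
    if len(hp) != 1:
        raise ValueError("planted hairpin does not fold into a single stem-loop")
    li, lj = hp[0]
    if not (fr.mfe <= max_mfe and li + 1 >= min_arm and len(hairpin) - lj >= min_arm):
        raise ValueError(
            f"planted hairpin fails candidate filters (mfe={fr.mfe:.1f})"
        )


def make_planted_genome(
    background_model: MarkovModel | None = None,
    genome_len: int = 1_000_000,
    plants: list[HairpinSpec] | int = 20,
    seed: int = 0,
    spacing: int = 300,
    validate: bool = True,
    contig: str = "synth",
    engine=None,
) -> PlantedGenome:
    """Draw a background genome and insert well-spaced hairpins.

    `plants` is either a list of specs or a count of default-spec plants.
    Plant positions are drawn uniformly, rejecting placements closer than
    `spacing` nt to another plant or a sequence end; a spec too crowded to
    place raises.  The strong-regime filter check (`validate`) runs at
    generation time so broken fixtures never reach a test.
    """
    rng = np.random.default_rng(seed)
    if isinstance(plants, int):
        plants = [HairpinSpec() for _ in range(plants)]
    total_plant = sum(s.length for s in plants)
    if genome_len < total_plant + spacing * (len(plants) + 1):
        raise ValueError("genome too short for the requested plants and spacing")
    model = background_model or MarkovModel.uniform()
    seq = list(model.sample(genome_len, rng))
    placed: list[tuple[int, int]] = []
    truth: list[GenomicInterval] = []
    for spec in plants:
        hairpin = make_hairpin(spec, rng)
        if validate and spec.arm_len >= 25 and spec.gc_fraction >= 0.6 and spec.n_mismatches <= 2:
            _validate_plant(hairpin, engine=engine)
        for _ in range(10_000):
            start = int(rng.integers(spacing, genome_len - spec.length - spacing))
            end = start + spec.length
            if all(start - e >= spacing or s - end >= spacing for s, e in placed):
                break
        else:
            raise ValueError("could not place plant; genome overcrowded")
        seq[start:end] = hairpin
        placed.append((start, end))
        truth.append(GenomicInterval(contig, start, end, "+"))
    truth.sort()
    return PlantedGenome(
        "".join(seq),
        truth,
        params={
            "genome_len": genome_len,
            "seed": seed,
            "spacing": spacing,
            "plants": [vars(s) for s in plants],
            "model_initial": list(map(float, model.initial)),
            "model_transition": [list(map(float, row)) for row in model.transition],
        },
    )
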