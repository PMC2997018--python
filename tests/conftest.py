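"""Shared fixtures.

The expensive end-to-end artefacts (a planted genome run through the whole
sieve) are session-scoped so that recovery, filter-invariant and ROC tests
all share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import stemloop_sieve as sls
from stemloop_sieve.background import (
    build_background,
    generate_artificial_genome,
    score_candidates,
    train_genome_markov,
)
from stemloop_sieve.enumeration import EnumerationParams
from stemloop_sieve.evaluation import label_candidates
from stemloop_sieve.measures import MeasureParams, evaluate_candidates

# ---------------------------------------------------------------------------
# Study conditions of the large synthetic run (desk scale).
#
# The planted genome carries 20 robust hairpins (30-bp arms, 8-nt loop,
# GC 0.7, 2 mismatches) in a uniform first-order Markov background.  The
# sieve runs at its default scan parameters on the plus strand; 60 negatives
# and 60 background candidates are sampled for the measure stage and the
# refolding-context count is 25.  Problem sizes are fixed here, once, for
# the whole suite.
# ---------------------------------------------------------------------------
GENOME_LEN = 300_000
N_PLANTS = 20
GENOME_SEED = 42
N_MEASURED_NEGATIVES = 50
N_BACKGROUND_CANDIDATES = 50
N_CONTEXTS = 25
BACKGROUND_GENOME_LEN = 40_000

ENUM_PARAMS = EnumerationParams(step=1, strands="+")
MEASURE_PARAMS = MeasureParams(n_contexts=N_CONTEXTS, seed=7)


@pytest.fixture(scope="session")
def planted_genome() -> sls.PlantedGenome:
    return sls.make_planted_genome(
        genome_len=GENOME_LEN, plants=N_PLANTS, seed=GENOME_SEED
    )


@pytest.fixture(scope="session")
def planted_candidates(planted_genome):
    return sls.enumerate_candidates(planted_genome.as_genome(), ENUM_PARAMS)


@pytest.fixture(scope="session")
def planted_scored(planted_genome, planted_candidates):
    """Positives (plant-overlapping) and sampled negatives, measured and
    scored against a dinucleotide-matched artificial background."""
    genome = planted_genome.as_genome()
    labelled = label_candidates(planted_candidates, planted_genome.truth)
    rng = np.random.default_rng(123)
    neg_idx = sorted(
        rng.choice(len(labelled.negatives), N_MEASURED_NEGATIVES, replace=False)
    )
    measured = labelled.positives + [labelled.negatives[i] for i in neg_idx]
    vectors = evaluate_candidates(measured, genome, MEASURE_PARAMS)
    model = train_genome_markov(genome)
    artificial = generate_artificial_genome(model, BACKGROUND_GENOME_LEN, seed=9)
    background = build_background(
        artificial, ENUM_PARAMS, MEASURE_PARAMS,
        max_candidates=N_BACKGROUND_CANDIDATES, subsample_seed=5,
    )
    scored = score_candidates(measured, vectors, background)
    n_pos = len(labelled.positives)
    return {
        "positives": scored[:n_pos],
        "negatives": scored[n_pos:],
        "background": background,
        "labelled": labelled,
    }


@pytest.fixture(scope="session")
def tiny_genome() -> sls.PlantedGenome:
    """A 12-kb genome with 2 plants for fast pipeline-level tests."""
    return sls.make_planted_genome(genome_len=12_000, plants=2, seed=5)


@pytest.fixture(scope="session")
def tiny_candidates(tiny_genome):
    return sls.enumerate_candidates(tiny_genome.as_genome(), ENUM_PARAMS)
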