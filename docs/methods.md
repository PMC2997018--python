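# Methods

`stemloop-sieve` implements a single-genome strategy for reducing the vast
set of genomic stem-loops to a ranked list of pre-miRNA precursor
candidates.  It makes no use of conservation or of classifiers trained on
known precursors: candidates are ranked purely by stability and robustness
properties expected of a processable hairpin, calibrated against what base
composition alone can produce.

## Candidate enumeration

A window of *W* = 200 nt (roughly three times a typical ~70-nt precursor,
so that a hairpin plus flanking sequence fits) slides along each scanned
strand at a step of 1 nt.  Each window is scored by the best pairing that
its 5′ half could form with its 3′ half — an inverted-repeat detector
implemented as a local alignment of the first half against the reverse of
the second half with pair-stability weights

| column | weight |
|---|---|
| G·C | +3 |
| A·U | +2 |
| G·U wobble | +1 |
| non-pairing column | −4 |
| gap | −4 |

The weights order pairs by thermodynamic stability.  The mismatch/gap
penalty is chosen steep enough that the expected per-column score on random
sequence is negative, which puts the score statistics in the logarithmic
(Karlin–Altschul) regime: the optimal local match is then a discrete
inverted repeat that persists unchanged while the window slides across it,
so consecutive windows tie exactly and merge.  A maximal run of equal
scores (a plateau) becomes a *candidate region* iff its score is positive
and strictly greater than both flanking scores; the region spans the union
of its windows.  On a 1-Mb synthetic genome at GC 0.5 this keeps ~1.5% of
windows, comfortably inside the intended ≥10× reduction, and at a density
comparable to the ~0.8% candidate-per-window rate implied by the published
full-genome counts.  With the shallower mismatch/gap penalty of −1 the
score field is in the linear regime, plateaus disappear and ~20% of windows
survive as local maxima — that is why the steeper penalty is the default.
All weights are configurable (`scan.weight_*`).

Each region is folded (ViennaRNA, standard parameters, 37 °C); the largest
canonical stem-loop is extracted by extending every hairpin loop outward
through stacks, bulges and interior loops until a multiloop branch or the
exterior loop, keeping the largest span (ties: 5′-most).  The extracted
subsequence is refolded; if the refold is itself multi-branched, extraction
and refolding repeat (at most 3 rounds, then reject).  A candidate is kept
iff its refolded MFE ≤ −20 kcal/mol (inclusive) and both stem arms — all
nucleotides 5′ respectively 3′ of the terminal loop — are ≥ 16 nt.
Candidates sharing exact terminal-loop coordinates are deduplicated,
keeping the longest (ties: 5′-most).  Both strands are scanned by default
(`scan.strands`), since G·U wobble makes folding strand-asymmetric;
minus-strand candidates carry minus-strand genomic intervals.  Windows with
more than 20 Ns are skipped; N never pairs, is never mutated, and drops out
of GC and Markov statistics.

## The four measures

For a candidate of length *L* with MFE structure *s₀*:

* **AMFE** = 100·MFE/*L* (kcal/mol per 100 nt).  Removes the length
  advantage of larger structures.  The GC-normalised variant MFEI =
  AMFE/(100·GC) is available but not part of the score: it is undefined for
  the GC-free candidates that AT-rich regions produce (the function returns
  NaN there), and the background calibration below already compensates
  partially for composition.
* **Robustness of folding** — the Boltzmann-ensemble diversity anchored at
  the MFE structure, ⟨d_bp⟩ = Σᵢ d_bp(s₀, sᵢ)·e^(−ΔGᵢ/kT)/Z, normalised per
  100 nt.  It is computed by the exact closed form
  ⟨d_bp⟩ = Σ_{(i,j)∈s₀}(1−p_ij) + Σ_{(i,j)∉s₀} p_ij over partition-function
  pair probabilities (O(n²) instead of enumerating the ensemble; the
  identity holds because base-pair distance decomposes over pairs).  Note
  this is *not* the engine's native "ensemble diversity", which is the
  structure-free expected pairwise distance; the s₀-anchored sum is the
  quantity defined above and the two differ.
* **Robustness to context** — two single-state first-order Markov models
  are trained on the *L* nt immediately upstream and downstream of the
  candidate (transition pseudocount 1 per cell, initial distribution =
  context base frequencies; contexts truncated at contig ends are accepted
  down to 10 nt, below which a genome-wide model stands in, flagged).  The
  candidate is refolded inside 100 sampled (upstream, downstream) context
  pairs of length *L* each, and the measure is the median fraction of the
  original base pairs present in the refold (pair identity, offset-mapped;
  unpaired-position agreement deliberately earns no credit).
* **Robustness to mutations** — all 3·*L* single-point mutants are folded
  and the measure is the median base-pair distance to *s₀*, normalised per
  100 nt (normalisation applied after the median; the order is irrelevant
  for a scalar factor).

Context and mutation replicates are summarised by the median, not the mean:
the replicate distributions are skewed and occasionally bimodal (a context
either leaves a stem intact or recruits it into a larger structure), and
the median is robust to those tails.  An even replicate count takes the
mean of the two middle values.

## Background calibration and the cscore

A first-order Markov model is fitted to the study genome's dinucleotide
frequencies and generates a single artificial genome (default 5 Mb,
`background.background_length`).  The artificial genome goes through the
*same* enumeration filters and measure parameters as the real one, yielding
an empirical distribution per measure.  The significance of a candidate's
value is the fraction of background candidates with strictly *worse*
values — worse meaning higher for AMFE, folding and mutation robustness,
lower for context robustness.  Ties count as not-worse (a candidate
indistinguishable from background earns nothing by it), and the candidate
itself is never part of the background.  The **cscore** is the product of
the four significances: 0 if the candidate is worse than the entire
background on any measure, 1 if strictly better on all four, monotone
non-decreasing in each significance.  One artificial genome per input
genome is the default; `background.replicates`-style stratification for
heterogeneous genomes is deliberately out of scope.

## Evaluation protocol

Candidates overlapping (≥1 shared nt, same contig and strand) a known
precursor are positives; all others negatives.  Because the sets are
imbalanced by four orders of magnitude, 1000 negative subsets of
positive-set size are drawn (without replacement within a subset,
independent across subsets) and a ROC curve is computed per subset by
sweeping the observed scores (score ≥ threshold ⇒ called positive).  The
trapezoid AUC then equals the Mann–Whitney statistic with ties counted ½.
The optimal cutoff maximises TPR − FPR; ties resolve to the lowest such
threshold (favouring sensitivity).  Sample curves are averaged vertically
(mean TPR on a fixed 101-point FPR grid), AUCs and cutoffs arithmetically.
Post-hoc reduction removes candidates below the average optimal cutoff,
then any candidate overlapped by a surviving candidate with strictly
higher cscore, processed in descending score order.  A best-match check
reports whether an annotated mature sequence lies within a stem arm of the
highest-overlap candidate, tolerating up to 2 nt of protrusion per endpoint
(annotations frequently miss a dangling end).

## Synthetic fixtures

The generator plants hairpins with prescribed arm length, loop length, GC
content and arm mismatches (defaults 30/8/0.7/2 — a robust, clearly
precursor-like construct) into a Markov background at recorded positions
≥300 nt apart (so neighbouring plants never merge into one candidate
region).  Plants in the strong regime (arm ≥ 25, GC ≥ 0.6, ≤ 2 mismatches)
are folded at generation time and must pass the −20 kcal/mol / 16-nt
filters in isolation.  Fixtures are byte-reproducible from (model, specs,
seed).  They emulate compositional background only — no transcription,
repeats, or conservation — so passing tests show separation of robust
stem-loops from composition-matched background, not performance on real
genomes.

## Numerical and implementation choices

* Internal coordinates are 0-based half-open on every interval; GFF3's
  1-based inclusive convention exists only at file boundaries.  T/U are
  unified to RNA internally; FASTA output is written back as DNA.
* MFE values are rounded to 0.01 kcal/mol (the engine's exact energy
  quantum) so tables round-trip through text losslessly.  The engine
  version is recorded in run provenance because absolute MFEs are
  version-dependent.
* The window DP kernel is numba-compiled; the first call in a fresh
  environment pays a few seconds of compilation (cached afterwards).
* Per-candidate RNG seeds are derived from the stage seed and the candidate
  coordinates (crc32), making measure values independent of batch
  partitioning: a k-batch run merges byte-identically with a 1-batch run.
* Significance lookups use binary search over the sorted background arrays;
  the contract is the strict count, the algorithm is incidental.

## Problem sizes used by the test suite

The published analyses ran whole insect genomes (hundreds of Mb) on a
compute cluster; this package's suite reproduces the behaviour at desk
scale, chosen from measured per-stage costs (an MFE fold of a 200-nt region
costs ~40 ms): the window-reduction bound is checked on a 1-Mb genome at
step 1 (scan only); the ranking experiment plants 20 hairpins in a 300-kb
uniform-background genome, measures the plant-overlapping candidates plus
50 sampled negatives with 25 refolding contexts, calibrates against a 40-kb
artificial genome (≤50 measured background candidates), and averages 100
undersampled ROC curves.  On those conditions the planted hairpins separate
cleanly from background (mean AUC ≥ 0.8, median cscore of positives well
above negatives), mirroring the direction of the published homolog /
non-homolog score separation.

## Known limitations

* The published window DP itself is unavailable; the local-alignment
  pairing potential is this package's own reconstruction (weights
  configurable) and candidate sets will differ in detail from the original
  implementation's.
* Only canonical (single-loop) stem-loops are enumerated; genuine
  multi-branched precursors are invisible by construction.
* A single background genome assumes compositional homogeneity;
  heterogeneous genomes (e.g. mixed eu-/heterochromatin) would warrant
  stratified backgrounds.
* Homolog identification via reciprocal-best alignment, database loading
  and classifier comparisons are out of scope.
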