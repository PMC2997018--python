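"""Genome-wide enumeration of extended stem-loop candidates.

A fixed-width window slides along each scanned strand; a dynamic-programming
score measures how well the two window halves could pair with each other
(i.e. how strong an inverted repeat the window straddles).  Score plateaus
that are strict local maxima of the profile become candidate regions; each
region is folded, its largest canonical stem-loop is extracted and refolded,
and the result is kept only if it is stable (MFE <= -20 kcal/mol) with both
stem arms at least 16 nt long.  Candidates sharing terminal-loop coordinates
are deduplicated, keeping the longest.

The pairing-potential score is a banded-free local alignment of the 5' half
against the reversed 3' half under pair-stability weights (G:C +3, A:U +2,
G:U wobble +1) with mismatch and gap penalties steep enough that random
sequence stays in the logarithmic (Karlin-Altschul) regime.  In that regime
the best cross-half match changes only when the underlying inverted repeat
enters or leaves the window, so consecutive windows frequently tie -- which
is what makes merging equal-score windows into a single region effective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .fold import FoldResult, SecondaryStructure, mfe_fold
from .io import GenomicInterval, reverse_complement

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3, "N": 4}


@dataclass(frozen=True)
class ScanWeights:
    """Column weights for the cross-half pairing alignment (integer units)."""

    gc: int = 3
    au: int = 2
    gu: int = 1
    mismatch: int = -4
    gap: int = -4

    def matrix(self) -> np.ndarray:
        wt = np.full((5, 5), self.mismatch, dtype=np.int32)
        pairs = [
            (2, 1, self.gc), (1, 2, self.gc),
            (0, 3, self.au), (3, 0, self.au),
            (2, 3, self.gu), (3, 2, self.gu),
        ]
        for a, b, v in pairs:
            wt[a, b] = v
        # N never pairs
        wt[4, :] = self.mismatch
        wt[:, 4] = self.mismatch
        return wt


DEFAULT_WEIGHTS = ScanWeights()


def encode(seq: str) -> np.ndarray:
    """Encode an RNA/DNA string as int8 codes (A=0, C=1, G=2, U/T=3, N=4)."""
    try:
        return np.frombuffer(
            bytes(_BASE_CODE[b] for b in seq), dtype=np.int8
        ).copy()
    except KeyError as exc:
        raise ValueError(f"cannot encode base {exc.args[0]!r}") from None


@njit(cache=True)
def _scan_kernel(enc, window, step, wt, gap, max_n):  # pragma: no cover - numba
    n = enc.size
    half = window // 2
    nwin = (n - window) // step + 1
    scores = np.zeros(nwin, dtype=np.int32)
    skipped = np.zeros(nwin, dtype=np.bool_)
    dp = np.zeros((half + 1, half + 1), dtype=np.int32)
    ncum = np.zeros(n + 1, dtype=np.int32)
    for i in range(n):
        ncum[i + 1] = ncum[i] + (1 if enc[i] == 4 else 0)
    for k in range(nwin):
        s = k * step
        if ncum[s + window] - ncum[s] > max_n:
            skipped[k] = True
            continue
        best = 0
        for i in range(1, half + 1):
            a = enc[s + i - 1]
            for j in range(1, half + 1):
                b = enc[s + window - j]  # j-th base of the reversed 3' half
                m = dp[i - 1, j - 1] + wt[a, b]
                g = dp[i - 1, j] - gap
                if g > m:
                    m = g
                g = dp[i, j - 1] - gap
                if g > m:
                    m = g
                if m < 0:
                    m = 0
                dp[i, j] = m
                if m > best:
                    best = m
        scores[k] = best
    return scores, skipped


def pairing_potential(window: str, weights: ScanWeights = DEFAULT_WEIGHTS) -> int:
    """Best cross-half pairing score of a single window (see module docs).

    The empty alignment scores 0, so windows with no complementarity score 0.
    """
    if len(window) % 2 != 0:
        raise ValueError(f"window length must be even, got {len(window)}")
    if len(window) == 0:
        return 0
    enc = encode(window.upper().replace("T", "U"))
    scores, _ = _scan_kernel(
        enc, len(window), 1, weights.matrix(), -weights.gap, len(window)
    )
    return int(scores[0])


@dataclass
class ScanProfile:
    """Score-per-start-position profile of a scanned sequence."""

    scores: np.ndarray  # int32, one entry per window
    skipped: np.ndarray  # bool, True where the window had too many Ns
    window: int
    step: int


def scan_windows(
    seq: str,
    window: int = 200,
    step: int = 1,
    weights: ScanWeights = DEFAULT_WEIGHTS,
    max_n: int = 20,
) -> ScanProfile:
    """Slide a window along `seq` and score every position.

    Windows containing more than `max_n` N bases score 0 and are flagged
    skipped.
    """
    if window % 2 != 0:
        raise ValueError("window length must be even")
    if len(seq) < window:
        return ScanProfile(
            np.zeros(0, np.int32), np.zeros(0, bool), window, step
        )
    enc = encode(seq)
    scores, skipped = _scan_kernel(
        enc, window, step, weights.matrix(), -weights.gap, max_n
    )
    return ScanProfile(scores, skipped, window, step)


@dataclass(frozen=True)
class CandidateRegion:
    """A merged plateau of equal-score windows that is a strict local maximum."""

    interval: GenomicInterval
    score: int


def plateau_maxima(scores: np.ndarray) -> list[tuple[int, int, int]]:
    """Strict plateau maxima of a profile as (first_window, last_window, score).

    A maximal run of equal scores qualifies iff its score is positive and
    strictly greater than both flanking scores (sequence boundaries count as
    minus infinity).
    """
    n = len(scores)
    out: list[tuple[int, int, int]] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and scores[j + 1] == scores[i]:
            j += 1
        left_ok = i == 0 or scores[i - 1] < scores[i]
        right_ok = j == n - 1 or scores[j + 1] < scores[i]
        if scores[i] > 0 and left_ok and right_ok:
            out.append((i, j, int(scores[i])))
        i = j + 1
    return out


def find_candidate_regions(
    profile: ScanProfile,
    contig: str = "seq",
    strand: str = "+",
) -> list[CandidateRegion]:
    """Candidate regions of a profile, in scanned-sequence coordinates.

    Each region spans the union of the windows in its plateau.
    """
    regions = []
    for i, j, score in plateau_maxima(profile.scores):
        start = i * profile.step
        end = j * profile.step + profile.window
        regions.append(
            CandidateRegion(GenomicInterval(contig, start, end, strand), score)
        )
    return regions


# ---------------------------------------------------------------------------
# Hairpin extraction and filtering
# ---------------------------------------------------------------------------


class NoHairpinError(ValueError):
    """The structure contains no hairpin loop (open chain)."""


def extract_largest_hairpin(fold: FoldResult) -> tuple[int, int]:
    """Span of the largest canonical stem-loop in a folded structure.

    Starting from each hairpin loop, the stem is extended outward through
    stacked pairs, bulges and interior loops until a multiloop branch point
    or the exterior loop is reached.  Returns the (start, end) half-open span
    from the first to the last paired base of that stem-loop; ties go to the
    5'-most.
    """
    struct = fold.structure
    pairs = sorted(struct.pairs)
    if not pairs:
        raise NoHairpinError("open-chain structure has no hairpin")
    # parent[(i,j)] = the pair immediately enclosing (i,j)
    parent: dict[tuple[int, int], tuple[int, int] | None] = {}
    n_children: dict[tuple[int, int], int] = {p: 0 for p in pairs}
    open_stack: list[int] = []
    close_of: dict[int, int] = {i: j for i, j in pairs}
    for i, ch in enumerate(struct.dotbracket):
        if ch == "(":
            open_stack.append(i)
        elif ch == ")":
            oi = open_stack.pop()
            pair = (oi, i)
            parent[pair] = (
                (open_stack[-1], close_of[open_stack[-1]]) if open_stack else None
            )
    for pair, par in parent.items():
        if par is not None:
            n_children[par] += 1
    best_span: tuple[int, int] | None = None
    for hp in struct.hairpin_pairs:
        cur = hp
        while True:
            par = parent[cur]
            if par is None or n_children[par] != 1:
                break
            cur = par
        span = (cur[0], cur[1] + 1)
        if (
            best_span is None
            or span[1] - span[0] > best_span[1] - best_span[0]
            or (span[1] - span[0] == best_span[1] - best_span[0] and span[0] < best_span[0])
        ):
            best_span = span
    assert best_span is not None
    return best_span


@dataclass(frozen=True)
class PrecursorCandidate:
    """An extended stem-loop candidate: a refolded canonical hairpin that
    passed the stability and arm-length filters."""

    interval: GenomicInterval
    seq: str  # transcript orientation, RNA alphabet
    structure: str  # dot-bracket
    mfe: float
    loop: GenomicInterval  # terminal loop, genomic coordinates
    arm5_len: int
    arm3_len: int

    @property
    def secondary_structure(self) -> SecondaryStructure:
        return SecondaryStructure(self.structure)


def passes_filters(
    mfe: float, arm5_len: int, arm3_len: int,
    max_mfe: float = -20.0, min_arm: int = 16,
) -> bool:
    """Stability and arm-length acceptance rule; the MFE bound is inclusive
    (an MFE of exactly -20 kcal/mol is accepted)."""
    return mfe <= max_mfe and arm5_len >= min_arm and arm3_len >= min_arm


def _to_genomic(region: GenomicInterval, local_start: int, local_end: int) -> GenomicInterval:
    """Map a local span within the scanned region sequence to genome
    coordinates (the scanned sequence of a minus-strand region is the
    reverse complement of the genomic slice)."""
    if region.strand == "+":
        return GenomicInterval(
            region.contig, region.start + local_start, region.start + local_end, "+"
        )
    return GenomicInterval(
        region.contig, region.end - local_end, region.end - local_start, "-"
    )


def refold_and_filter(
    region_seq: str,
    span: tuple[int, int],
    region: GenomicInterval,
    max_mfe: float = -20.0,
    min_arm: int = 16,
    max_iterations: int = 3,
    engine=None,
) -> PrecursorCandidate | None:
    """Refold an extracted stem-loop span and apply the acceptance filters.

    If the refolded structure is itself multi-looped, the largest hairpin is
    re-extracted and refolded again, up to `max_iterations` times; failure to
    converge to a single-hairpin structure is a rejection (None), as is
    failing the MFE or arm-length filter.
    """
    a, b = span
    for _ in range(max_iterations):
        sub = region_seq[a:b]
        if not sub:
            return None
        fr = mfe_fold(sub, engine=engine)
        hairpins = fr.structure.hairpin_pairs
        if len(hairpins) == 0:
            return None
        if len(hairpins) == 1:
            li, lj = hairpins[0]
            arm5 = li + 1
            arm3 = len(sub) - lj
            if not passes_filters(fr.mfe, arm5, arm3, max_mfe, min_arm):
                return None
            return PrecursorCandidate(
                interval=_to_genomic(region, a, b),
                seq=sub,
                structure=fr.structure.dotbracket,
                mfe=fr.mfe,
                loop=_to_genomic(region, a + li + 1, a + lj),
                arm5_len=arm5,
                arm3_len=arm3,
            )
        sa, sb = extract_largest_hairpin(fr)
        a, b = a + sa, a + sb
    return None


def dedup_by_loop(candidates: list[PrecursorCandidate]) -> list[PrecursorCandidate]:
    """Among candidates with identical terminal-loop coordinates keep only
    the longest (ties: 5'-most start)."""
    best: dict[tuple, PrecursorCandidate] = {}
    for cand in candidates:
        key = (cand.loop.contig, cand.loop.strand, cand.loop.start, cand.loop.end)
        cur = best.get(key)
        if (
            cur is None
            or len(cand.interval) > len(cur.interval)
            or (len(cand.interval) == len(cur.interval)
                and cand.interval.start < cur.interval.start)
        ):
            best[key] = cand
    return sorted(
        best.values(), key=lambda c: (c.interval.contig, c.interval.start,
                                      c.interval.end, c.interval.strand)
    )


@dataclass
class EnumerationParams:
    window: int = 200
    step: int = 1
    max_mfe: float = -20.0
    min_arm: int = 16
    strands: str = "both"  # "+", "-" or "both"
    weights: ScanWeights = field(default_factory=ScanWeights)
    max_n: int = 20


def enumerate_candidates(
    genome: list[tuple[str, str]] | dict[str, str],
    params: EnumerationParams | None = None,
    engine=None,
) -> list[PrecursorCandidate]:
    """Full enumeration pipeline over every contig and scanned strand.

    scan -> plateau local maxima -> fold region -> extract largest hairpin
    -> refold and filter -> deduplicate by terminal loop.  Output sorted by
    (contig, start).
    """
    params = params or EnumerationParams()
    if isinstance(genome, dict):
        genome = list(genome.items())
    strands = ["+", "-"] if params.strands == "both" else [params.strands]
    out: list[PrecursorCandidate] = []
    for contig, seq in genome:
        n = len(seq)
        for strand in strands:
            scanned = seq if strand == "+" else reverse_complement(seq)
            profile = scan_windows(
                scanned, params.window, params.step, params.weights, params.max_n
            )
            for i, j, score in plateau_maxima(profile.scores):
                local_start = i * params.step
                local_end = j * params.step + params.window
                if strand == "+":
                    region = GenomicInterval(contig, local_start, local_end, "+")
                else:
                    region = GenomicInterval(
                        contig, n - local_end, n - local_start, "-"
                    )
                region_seq = scanned[local_start:local_end]
                fr = mfe_fold(region_seq, engine=engine)
                try:
                    span = extract_largest_hairpin(fr)
                except NoHairpinError:
                    continue
                cand = refold_and_filter(
                    region_seq, span, region,
                    params.max_mfe, params.min_arm, engine=engine,
                )
                if cand is not None:
                    out.append(cand)
    return dedup_by_loop(out)
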