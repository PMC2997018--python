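"""Sequence and annotation I/O, genomic intervals, candidate tables.

All coordinates are 0-based half-open internally; GFF3's 1-based inclusive
convention is converted at the file boundary only.  Sequences are
canonicalised to uppercase RNA (T -> U) on ingestion; the original DNA/RNA
spelling of the source file is remembered per record so output can be written
back in the source alphabet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGUN")

_TO_RNA = str.maketrans("Tt", "Uu")
_TO_DNA = str.maketrans("Uu", "Tt")
_RC = str.maketrans("ACGUN", "UGCAN")


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed or contains illegal characters."""


class AnnotationParseError(ValueError):
    """Raised when an annotation file cannot be parsed."""


def canonicalise(seq: str) -> str:
    """Uppercase and respell to the internal RNA alphabet (T -> U)."""
    return seq.upper().translate(_TO_RNA)


def to_dna(seq: str) -> str:
    """Respell an internal RNA sequence as DNA (U -> T)."""
    return seq.translate(_TO_DNA)


def reverse_complement(seq: str) -> str:
    """Reverse complement over the internal alphabet; A<->U, G<->C, N<->N.

    An involution: ``reverse_complement(reverse_complement(x)) == x``.
    """
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"invalid bases for reverse complement: {sorted(bad)}")
    return seq.translate(_RC)[::-1]


def gc_fraction(seq: str) -> float:
    """G+C fraction over non-N positions; 0.0 for all-N/empty sequences."""
    acgu = sum(1 for b in seq if b != "N")
    if acgu == 0:
        return 0.0
    return sum(1 for b in seq if b in "GC") / acgu


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = True) -> bool:
        """True if the two intervals share at least one nucleotide."""
        if self.contig != other.contig:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval", slack: int = 0) -> bool:
        """True if `other` lies within this interval, each end allowed to
        protrude by at most `slack` nucleotides."""
        return (
            self.contig == other.contig
            and other.start >= self.start - slack
            and other.end <= self.end + slack
        )


@dataclass
class AnnotationRecord:
    """A known precursor with its (possibly empty) mature intervals."""

    precursor: GenomicInterval
    matures: list[GenomicInterval] = field(default_factory=list)
    name: str = ""


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (multi-)FASTA file into ``[(identifier, sequence), ...]``.

    Sequences are uppercased and respelled to the internal RNA alphabet;
    record order is preserved.  Illegal residues raise
    :class:`FastaParseError` naming the record and line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}:{lineno}: expected FASTA header, got {line.strip()[:30]!r}"
                )
            break
    records: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = canonicalise(str(rec.seq))
        bad = set(seq) - VALID_BASES
        if bad:
            raise FastaParseError(
                f"{path}: record {rec.id!r} contains illegal characters {sorted(bad)}"
            )
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                alphabet: str = "dna", width: int = 70) -> None:
    """Write records as FASTA; ``alphabet`` selects T (dna) or U (rna)."""
    with open(path, "w") as fh:
        for name, seq in records:
            out = to_dna(seq) if alphabet == "dna" else seq
            fh.write(f">{name}\n")
            for i in range(0, len(out), width):
                fh.write(out[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

_PRECURSOR_TYPES = {"miRNA_primary_transcript", "pre_miRNA", "precursor"}
_MATURE_TYPES = {"miRNA", "mature", "miRNA_mature"}


def _attach_matures(
    precursors: list[AnnotationRecord],
    orphans: list[tuple[GenomicInterval, str]],
    slack: int = 2,
) -> list[AnnotationRecord]:
    """Attach mature intervals to precursors by containment (2-nt slack)."""
    for mat, name in orphans:
        host = None
        for rec in precursors:
            if rec.precursor.strand != mat.strand:
                continue
            if rec.precursor.contains(mat, slack=slack):
                host = rec
                break
        if host is None:
            warnings.warn(
                f"mature feature {name or mat} not contained in any precursor; "
                "kept as orphan",
                stacklevel=3,
            )
            precursors.append(AnnotationRecord(precursor=mat, name=name or "orphan"))
        else:
            host.matures.append(mat)
    return precursors


def read_annotations(path: str | Path, dialect: str = "gff3") -> list[AnnotationRecord]:
    """Read precursor/mature annotations from GFF3 (miRBase style) or BED.

    GFF3 matures are attached to precursors via ``Derives_from``/``Parent``
    attributes when present, otherwise by containment.  BED intervals
    contained inside a longer interval on the same strand are treated as
    matures of that interval.
    """
    if dialect == "gff3":
        return _read_gff3(path)
    if dialect == "bed":
        return _read_bed(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _read_gff3(path: str | Path) -> list[AnnotationRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    precursors: list[AnnotationRecord] = []
    by_id: dict[str, AnnotationRecord] = {}
    matures: list[tuple[GenomicInterval, str, str | None]] = []
    for feat in db.all_features():
        # GFF3 is 1-based inclusive: internal start = start - 1
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end,
                             feat.strand if feat.strand in "+-" else "+")
        name = (feat.attributes.get("Name") or feat.attributes.get("ID") or [feat.id])[0]
        if feat.featuretype in _PRECURSOR_TYPES:
            rec = AnnotationRecord(precursor=iv, name=name)
            precursors.append(rec)
            for key in feat.attributes.get("ID", []):
                by_id[key] = rec
        elif feat.featuretype in _MATURE_TYPES:
            parent = (feat.attributes.get("Derives_from")
                      or feat.attributes.get("Parent") or [None])[0]
            matures.append((iv, name, parent))
    orphans: list[tuple[GenomicInterval, str]] = []
    for iv, name, parent in matures:
        if parent is not None and parent in by_id:
            by_id[parent].matures.append(iv)
        else:
            orphans.append((iv, name))
    return _attach_matures(precursors, orphans)


def _read_bed(path: str | Path) -> list[AnnotationRecord]:
    rows: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise AnnotationParseError(f"{path}:{lineno}: too few BED fields")
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"bed_{lineno}"
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "+"
            rows.append((GenomicInterval(contig, start, end, strand), name))
    # longest intervals become precursors; contained intervals become matures
    rows.sort(key=lambda r: -len(r[0]))
    precursors: list[AnnotationRecord] = []
    orphans: list[tuple[GenomicInterval, str]] = []
    for iv, name in rows:
        host = next(
            (rec for rec in precursors
             if rec.precursor.strand == iv.strand
             and rec.precursor.contains(iv)
             and len(rec.precursor) > len(iv)),
            None,
        )
        if host is None:
            precursors.append(AnnotationRecord(precursor=iv, name=name))
        else:
            host.matures.append(iv)
    return _attach_matures(precursors, orphans)


# ---------------------------------------------------------------------------
# Candidate tables
# ---------------------------------------------------------------------------

CANDIDATE_COLUMNS = [
    "contig", "start", "end", "strand", "sequence", "structure", "mfe",
    "loop_start", "loop_end", "arm5_len", "arm3_len",
]

MEASURE_COLUMNS = [
    "amfe", "folding_robustness", "context_robustness", "mutation_robustness",
]

SCORE_COLUMNS = [
    "sig_amfe", "sig_folding_robustness", "sig_context_robustness",
    "sig_mutation_robustness", "cscore",
]


def candidates_to_frame(candidates: Sequence) -> pd.DataFrame:
    """Convert PrecursorCandidate/ScoredCandidate objects to a DataFrame."""
    rows = []
    for c in candidates:
        cand = getattr(c, "candidate", c)
        row = {
            "contig": cand.interval.contig,
            "start": cand.interval.start,
            "end": cand.interval.end,
            "strand": cand.interval.strand,
            "sequence": cand.seq,
            "structure": cand.structure,
            "mfe": cand.mfe,
            "loop_start": cand.loop.start,
            "loop_end": cand.loop.end,
            "arm5_len": cand.arm5_len,
            "arm3_len": cand.arm3_len,
        }
        measures = getattr(c, "measures", None)
        if measures is not None:
            row.update(measures.as_dict())
        sigs = getattr(c, "significances", None)
        if sigs is not None:
            row.update({f"sig_{k}": v for k, v in sigs.items()})
            row["cscore"] = c.cscore
        rows.append(row)
    return pd.DataFrame(rows)


def write_candidates(candidates: Sequence, path: str | Path,
                     format: str = "tsv") -> None:
    """Write candidates (and any attached measures/scores) to TSV or GFF3."""
    frame = candidates_to_frame(candidates)
    if format == "tsv":
        frame.to_csv(path, sep="\t", index=False)
    elif format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for _, r in frame.iterrows():
                attrs = [
                    f"ID=candidate_{r['contig']}_{r['start']}_{r['end']}_{r['strand'].replace('-', 'm')}",
                    f"sequence={r['sequence']}",
                    f"structure={r['structure']}",
                    f"loop={int(r['loop_start']) + 1}..{int(r['loop_end'])}",
                ]
                if "cscore" in frame.columns:
                    attrs.append(f"cscore={r['cscore']:.6g}")
                fh.write(
                    "\t".join([
                        str(r["contig"]), "stemloop-sieve", "stem_loop",
                        str(int(r["start"]) + 1), str(int(r["end"])),
                        f"{r['mfe']:.2f}", r["strand"], ".", ";".join(attrs),
                    ]) + "\n"
                )
    else:
        raise ValueError(f"unknown candidate format {format!r}")


def read_candidates(path: str | Path) -> pd.DataFrame:
    """Read a candidate TSV back into a DataFrame (exact round-trip of
    coordinates and sequences)."""
    return pd.read_csv(
        path, sep="\t",
        dtype={"contig": str, "strand": str, "sequence": str, "structure": str},
    )
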