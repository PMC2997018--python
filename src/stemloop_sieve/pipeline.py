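"""End-to-end orchestration: enumerate -> measure -> background -> score ->
evaluate, with per-stage outputs, provenance metadata and batch partitioning.

Measurement is per-candidate independent (seeds are derived from candidate
coordinates), so a k-batch run merged in coordinate order is byte-identical
to a single-batch run.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .background import (
    EmpiricalBackground,
    build_background,
    generate_artificial_genome,
    score_candidates,
    train_genome_markov,
)
from .config import RunConfig
from .enumeration import PrecursorCandidate, enumerate_candidates
from .evaluation import (
    average_roc,
    label_candidates,
    reduce_by_overlap,
    roc,
    undersample_negatives,
)
from .fold import get_engine
from .io import (
    AnnotationRecord,
    GenomicInterval,
    candidates_to_frame,
    read_annotations,
    read_candidates,
    read_fasta,
    write_candidates,
)
from .measures import MeasureVector, evaluate_candidates

logger = logging.getLogger("stemloop_sieve")


def candidates_from_frame(frame: pd.DataFrame) -> list[PrecursorCandidate]:
    """Rebuild candidate objects from a candidate table."""
    out = []
    for _, r in frame.iterrows():
        out.append(
            PrecursorCandidate(
                interval=GenomicInterval(r["contig"], int(r["start"]),
                                         int(r["end"]), r["strand"]),
                seq=r["sequence"],
                structure=r["structure"],
                mfe=float(r["mfe"]),
                loop=GenomicInterval(r["contig"], int(r["loop_start"]),
                                     int(r["loop_end"]), r["strand"]),
                arm5_len=int(r["arm5_len"]),
                arm3_len=int(r["arm3_len"]),
            )
        )
    return out


def measure_in_batches(
    candidates: list[PrecursorCandidate],
    genome: dict[str, str],
    config: RunConfig,
    n_batches: int = 1,
    engine=None,
) -> list[MeasureVector]:
    """Measure candidates split into `n_batches` contiguous batches; the
    merged result is identical to a single-batch run."""
    params = config.measure_params()
    vectors: list[MeasureVector] = []
    for batch in np.array_split(np.arange(len(candidates)), max(1, n_batches)):
        vectors.extend(
            evaluate_candidates([candidates[i] for i in batch], genome,
                                params, engine=engine)
        )
    return vectors


def run_pipeline(
    fasta: str | Path,
    outdir: str | Path,
    config: RunConfig | None = None,
    annotations: str | Path | None = None,
    annotation_dialect: str = "gff3",
    n_batches: int = 1,
) -> Path:
    """Run every stage on a genome FASTA, writing stage outputs under
    `outdir` (resumable inputs for the single-stage CLI commands)."""
    config = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    engine = get_engine(config.folding_engine)
    genome_records = read_fasta(fasta)
    genome = dict(genome_records)

    logger.info("enumerating candidates")
    candidates = enumerate_candidates(
        genome_records, config.enumeration_params(), engine=engine
    )
    write_candidates(candidates, outdir / "candidates.tsv")

    logger.info("measuring %d candidates in %d batch(es)", len(candidates), n_batches)
    vectors = measure_in_batches(candidates, genome, config, n_batches, engine)
    measured = candidates_to_frame(candidates)
    for name in ("amfe", "folding_robustness", "context_robustness",
                 "mutation_robustness"):
        measured[name] = [getattr(v, name) for v in vectors]
    measured.to_csv(outdir / "measures.tsv", sep="\t", index=False)

    logger.info("building artificial-genome background (%d nt)",
                config.background_length)
    model = train_genome_markov(genome)
    artificial = generate_artificial_genome(
        model, config.background_length, config.background_seed
    )
    background = build_background(
        artificial,
        config.enumeration_params(),
        config.measure_params(),
        max_candidates=config.background_max_candidates,
        subsample_seed=config.background_seed,
        engine=engine,
        provenance={
            "seed": config.background_seed,
            "length": config.background_length,
            "initial": list(map(float, model.initial)),
        },
    )
    background.to_json(outdir / "background.json")

    logger.info("scoring candidates")
    scored = score_candidates(candidates, vectors, background)
    write_candidates(scored, outdir / "scored.tsv")

    report: dict = {
        "n_candidates": len(candidates),
        "n_background_candidates": background.n,
    }
    if annotations is not None:
        records = read_annotations(annotations, annotation_dialect)
        report.update(evaluate_scored(scored, records, config))
    provenance = {
        "config": config.to_flat(),
        "engine": {"name": engine.name, "version": engine.version},
        "n_batches": n_batches,
        "contigs": {name: len(seq) for name, seq in genome.items()},
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=1))
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    return outdir


def evaluate_scored(
    scored: list,
    annotations: list[AnnotationRecord],
    config: RunConfig | None = None,
    max_negatives: int | None = None,
) -> dict:
    """Undersampled ROC evaluation of cscore rankings against annotations."""
    config = config or RunConfig()
    labelled = label_candidates(scored, annotations)
    if not labelled.positives or not labelled.negatives:
        return {
            "n_positives": len(labelled.positives),
            "n_negatives": len(labelled.negatives),
            "note": "need both positives and negatives for ROC evaluation",
        }
    negatives = labelled.negatives
    pos_scores = [c.cscore for c in labelled.positives]
    samples = undersample_negatives(
        negatives, len(labelled.positives), config.undersamples,
        config.undersample_seed,
    )
    curves = [roc(pos_scores, [c.cscore for c in neg]) for neg in samples]
    avg = average_roc(curves)
    kept = reduce_by_overlap(scored, avg.mean_cutoff)
    above = [c for c in scored if c.cscore >= avg.mean_cutoff]
    tpr = float(np.mean([s >= avg.mean_cutoff for s in pos_scores]))
    fpr = float(np.mean([c.cscore >= avg.mean_cutoff for c in negatives]))
    return {
        "n_positives": len(labelled.positives),
        "n_negatives": len(negatives),
        "n_undersamples": len(samples),
        "mean_auc": avg.mean_auc,
        "mean_optimal_cutoff": avg.mean_cutoff,
        "sensitivity_at_cutoff": tpr,
        "specificity_at_cutoff": 1.0 - fpr,
        "n_above_cutoff": len(above),
        "n_after_overlap_reduction": len(kept),
    }


def plot_roc_curves(curves, avg, path: str | Path, title: str = "cscore") -> None:
    """Per-sample (dashed) and average (solid) ROC curves."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for curve in curves[:50]:
        xs, ys = zip(*curve.points)
        ax.plot(xs, ys, color="grey", lw=0.3, ls="--", alpha=0.4)
    ax.plot(avg.fpr_grid, avg.mean_tpr, color="C0", lw=2,
            label=f"mean AUC = {avg.mean_auc:.3f}")
    ax.plot([0, 1], [0, 1], color="k", lw=0.5, ls=":")
    ax.set_xlabel("FPR")
    ax.set_ylabel("TPR")
    ax.set_title(title)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def summarize_run(outdir: str | Path) -> dict:
    """Machine-readable summary of a completed (or partial) run directory."""
    outdir = Path(outdir)
    summary: dict = {"run_dir": str(outdir), "missing_stages": []}
    for stage, filename in [
        ("candidates", "candidates.tsv"),
        ("measures", "measures.tsv"),
        ("background", "background.json"),
        ("scored", "scored.tsv"),
        ("report", "report.json"),
    ]:
        path = outdir / filename
        if not path.exists():
            summary["missing_stages"].append(stage)
            continue
        if filename.endswith(".tsv"):
            summary[f"n_{stage}"] = len(read_candidates(path))
        elif stage == "background":
            summary["n_background_candidates"] = EmpiricalBackground.from_json(path).n
        else:
            summary.update(json.loads(path.read_text()))
    return summary


def format_summary(summary: dict) -> str:
    lines = [f"run: {summary.get('run_dir', '?')}"]
    for key, value in summary.items():
        if key in ("run_dir", "missing_stages"):
            continue
        if isinstance(value, float):
            lines.append(f"  {key}: {value:.4f}")
        else:
            lines.append(f"  {key}: {value}")
    if summary.get("missing_stages"):
        lines.append("  missing stages: " + ", ".join(summary["missing_stages"]))
    return "\n".join(lines)
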