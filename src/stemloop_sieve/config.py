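"""Run configuration: every tunable of the pipeline with its default.

Defaults reproduce the published protocol: 200-nt scan window, -20 kcal/mol
stability bound, 16-nt minimum arms, 100 random refolding contexts, a single
5-Mb artificial background genome and 1000 negative undersamples.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from .enumeration import EnumerationParams, ScanWeights
from .measures import MeasureParams


@dataclass
class RunConfig:
    # enumeration
    window: int = 200
    step: int = 1
    max_mfe: float = -20.0
    min_arm: int = 16
    strands: str = "both"
    weight_gc: int = 3
    weight_au: int = 2
    weight_gu: int = 1
    weight_mismatch: int = -4
    weight_gap: int = -4
    max_n_per_window: int = 20
    # measures
    contexts: int = 100
    contexts_seed: int = 1
    # background
    background_length: int = 5_000_000
    background_seed: int = 2
    background_max_candidates: int | None = None
    # evaluation
    undersamples: int = 1000
    undersample_seed: int = 3
    # engine
    folding_engine: str = "vienna"

    def scan_weights(self) -> ScanWeights:
        return ScanWeights(
            gc=self.weight_gc, au=self.weight_au, gu=self.weight_gu,
            mismatch=self.weight_mismatch, gap=self.weight_gap,
        )

    def enumeration_params(self) -> EnumerationParams:
        return EnumerationParams(
            window=self.window, step=self.step, max_mfe=self.max_mfe,
            min_arm=self.min_arm, strands=self.strands,
            weights=self.scan_weights(), max_n=self.max_n_per_window,
        )

    def measure_params(self) -> MeasureParams:
        return MeasureParams(n_contexts=self.contexts, seed=self.contexts_seed)

    def to_flat(self) -> dict[str, str]:
        """Flat dotted-key representation (``scan.window = 200`` style)."""
        sections = {
            "window": "scan", "step": "scan", "strands": "scan",
            "max_n_per_window": "scan",
            "weight_gc": "scan", "weight_au": "scan", "weight_gu": "scan",
            "weight_mismatch": "scan", "weight_gap": "scan",
            "max_mfe": "filter", "min_arm": "filter",
            "contexts": "measure", "contexts_seed": "measure",
            "background_length": "background", "background_seed": "background",
            "background_max_candidates": "background",
            "undersamples": "evaluate", "undersample_seed": "evaluate",
            "folding_engine": "folding",
        }
        out = {}
        for key, value in asdict(self).items():
            out[f"{sections[key]}.{key}"] = "" if value is None else str(value)
        return out

    def save(self, path: str | Path) -> None:
        lines = [f"{k} = {v}" for k, v in sorted(self.to_flat().items())]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        values: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            values[key.split(".")[-1]] = value
        kwargs = {}
        for f in fields(cls):
            if f.name not in values:
                continue
            raw = values[f.name]
            if raw == "":
                kwargs[f.name] = None
            elif f.type in ("int", "int | None"):
                kwargs[f.name] = int(raw)
            elif f.type == "float":
                kwargs[f.name] = float(raw)
            else:
                kwargs[f.name] = raw
        return cls(**kwargs)
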