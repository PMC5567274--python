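"""Central registry of pipeline thresholds and run settings.

Every numeric constant the pipeline uses lives here with its default:
exact-test alpha, the dAF > 0.20 LOH tie-break, the scar-score length
thresholds (NtAI 11 Mb, LST 3/10 Mb with ploidy factor 15.5, HRD-LOH
15 Mb with chromosome 17 excluded), the artifact-signature cutoff (30%),
the carrier criteria (germline AF > 0.30, depth > 30) and the burden
denominator (30 Mb).  The config round-trips through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .scores import ScoreConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    genome: str = "mini-test"
    alpha: float = 0.05
    delta_af_threshold: float = 0.20
    scores: ScoreConfig = field(default_factory=ScoreConfig)
    artifact_threshold: float = 0.30
    carrier_min_af: float = 0.30
    carrier_min_depth: int = 30
    burden_target_mb: float = 30.0
    seed: int = 0
    input_dir: str | None = None
    output_dir: str = "brcaloh_out"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scores"]["hrd_loh_excluded_chromosomes"] = list(
            d["scores"]["hrd_loh_excluded_chromosomes"]
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sc = dict(d.pop("scores", {}))
        if "hrd_loh_excluded_chromosomes" in sc:
            sc["hrd_loh_excluded_chromosomes"] = tuple(
                str(c) for c in sc["hrd_loh_excluded_chromosomes"]
            )
        known = {f.name for f in fields(cls)} - {"scores"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(scores=ScoreConfig(**sc), **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
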