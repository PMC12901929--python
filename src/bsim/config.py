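"""Run configuration: one master seed plus per-stage sections, YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .ec import ECConfig, JitterConfig, SRMRConfig
from .periphery import TSNConfig
from .scenes import SpatializerConfig
from .srt import SolverConfig


@dataclass
class CohortSection:
    n: int = 20
    asym_fraction: float = 0.1
    isc_sd_db: float = 3.0
    jitter_db: float = 3.0
    measurement_noise_sd_db: float = 1.0


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "results"
    log_level: str = "INFO"
    solver: SolverConfig = field(default_factory=SolverConfig)
    ec: ECConfig = field(default_factory=ECConfig)
    jitter: JitterConfig = field(default_factory=JitterConfig)
    srmr: SRMRConfig = field(default_factory=SRMRConfig)
    tsn: TSNConfig = field(default_factory=TSNConfig)
    spatializer: SpatializerConfig = field(default_factory=SpatializerConfig)
    cohort: CohortSection = field(default_factory=CohortSection)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        # numpy arrays (e.g. TSN reference thresholds) -> lists
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if hasattr(obj, "tolist"):
                return obj.tolist()
            return obj

        Path(path).write_text(yaml.safe_dump(clean(data), sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        sections = {
            "solver": SolverConfig, "ec": ECConfig, "jitter": JitterConfig,
            "srmr": SRMRConfig, "tsn": TSNConfig, "spatializer": SpatializerConfig,
            "cohort": CohortSection,
        }
        kwargs = {}
        for f in fields(cls):
            if f.name not in data:
                continue
            if f.name in sections:
                sec_cls = sections[f.name]
                sec_fields = {sf.name for sf in fields(sec_cls)}
                kwargs[f.name] = sec_cls(**{k: v for k, v in data[f.name].items() if k in sec_fields})
            else:
                kwargs[f.name] = data[f.name]
        return cls(**kwargs)
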