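"""Declarative pipeline configuration.

The analysis couples many thresholds (caller parameters, radii, percentile,
resampling sizes); silent defaults are the main reproducibility hazard, so
the whole run is driven by one JSON document validated against the parameter
types before any compute, and every threshold and seed is recorded in the
run manifest.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .calling import HmmParams, WindowParams

__all__ = ["SimulateBlock", "ResamplingBlock", "PipelineConfig"]


@dataclass
class SimulateBlock:
    n_chromosomes: int = 4
    snps_per_chromosome: int = 1500
    chromosome_length_bp: int = 60_000_000
    n_samples_tumor: int = 60
    n_samples_control: int = 90
    het_rate: float = 0.3
    error_rate: float = 0.02
    nocall_rate_tumor: float = 0.042
    nocall_rate_control: float = 0.005
    n_hotspots: int = 6
    hotspot_freq_tumor: float = 0.5
    hotspot_freq_control: float = 0.1
    hotspot_length_bp: int = 4_000_000
    private_roh_rate: float = 0.3
    private_roh_mean_len_bp: float = 2_500_000.0


@dataclass
class ResamplingBlock:
    n_iter: int = 1000
    subsample_size: int = 30
    alpha: float = 0.05
    paired: bool = True


@dataclass
class PipelineConfig:
    out_dir: str = "results/pipeline"
    genotypes_tumor: str | None = None   # None -> simulate
    genotypes_control: str | None = None
    copy_number: str | None = None
    caller: str = "both"                 # hmm | window | both
    hmm: HmmParams = field(default_factory=HmmParams)
    window: WindowParams = field(default_factory=WindowParams)
    simulate: SimulateBlock = field(default_factory=SimulateBlock)
    resampling: ResamplingBlock = field(default_factory=ResamplingBlock)
    proximity_radius_bp: int = 5_000_000
    mirna_radius_bp: int = 1_000_000
    percentile: float = 95.0
    fra_rohf_threshold: float = 0.5
    n_fras: int = 8
    n_mirna: int = 60
    seed: int = 1

    def __post_init__(self) -> None:
        if isinstance(self.hmm, dict):
            self.hmm = HmmParams(**self.hmm)
        if isinstance(self.window, dict):
            self.window = WindowParams(**self.window)
        if isinstance(self.simulate, dict):
            self.simulate = SimulateBlock(**self.simulate)
        if isinstance(self.resampling, dict):
            self.resampling = ResamplingBlock(**self.resampling)
        if self.caller not in {"hmm", "window", "both"}:
            raise ValueError("caller must be hmm, window or both")
        if self.proximity_radius_bp <= 0 or self.mirna_radius_bp <= 0:
            raise ValueError("radii must be positive")
        for p in (self.genotypes_tumor, self.genotypes_control, self.copy_number):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return asdict(self)
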