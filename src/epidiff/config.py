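"""Pipeline configuration: every numeric knob in one place."""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass
class PipelineConfig:
    """Parameters shared by all stages.

    Defaults follow standard whole-genome bisulfite practice for this
    kind of two-species comparison: a >=5-read coverage floor on
    cytosine sites, 200 bp DMR windows advanced in 100 bp steps with a
    Benjamini-Hochberg q < 0.05 cut-off, siRNA clusters built from reads
    separated by < 100 bp and kept when they carry >= 5 reads per
    million mapped and >= 10 distinct sequences, 1 kb gene flanks, a
    fungal substitution rate of 1.05e-9 per site per year for LTR
    dating, and 10 kb non-overlapping windows for genome tracks.
    """

    min_coverage: int = 5          # reads required at a cytosine site
    window_size: int = 200         # bp, DMR window
    window_step: int = 100         # bp, DMR window step
    min_sites: int = 4             # covered CG sites per species per window
    q_threshold: float = 0.05      # BH q-value cut-off for DMR windows
    cluster_gap: int = 100         # bp, reads closer than this cluster
    cluster_min_rpm: float = 5.0   # reads per million mapped
    cluster_min_distinct: int = 10  # distinct sequences per cluster
    flank: int = 1000              # bp, gene flank for genic regions
    subst_rate: float = 1.05e-9    # substitutions/site/year
    track_window: int = 10_000     # bp, genome-track window
    bimodal_low: float = 0.10      # "lowly methylated" site threshold
    bimodal_high: float = 0.80     # "highly methylated" site threshold
    alpha: float = 0.01            # significance level for pattern tests
    body_bins: int = 20            # metagene body bins
    flank_bins: int = 10           # metagene flank bins (100 bp each)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.window_step > self.window_size:
            raise ValueError("window_step must be <= window_size")
        if not (0 < self.bimodal_low < self.bimodal_high < 1):
            raise ValueError("need 0 < bimodal_low < bimodal_high < 1")
        for name in (
            "min_coverage", "window_size", "window_step", "q_threshold",
            "cluster_gap", "cluster_min_rpm", "cluster_min_distinct",
            "flank", "subst_rate", "track_window", "alpha",
            "body_bins", "flank_bins",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))
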