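"""Pipeline configuration: every analysis threshold in one place.

Defaults are the study-design constants used throughout the package
(censoring at Ct 36 -> 40, detection at 0.5, 2-SD viability QC, 120 cells
per time point, FDR 0.05 / p 0.01 network thresholds, k = 5 trajectory
classes, 2 modules, edge-ratio layer cutoffs 4 and 0.5).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    out_dir: str = "ctnet_run"
    seed: int = 0
    # inputs; empty string means "simulate"
    ct_table: str = ""
    network: str = ""
    motif_table: str = ""
    # normalization
    ref_gene: str = "GAPDH"
    anchor_gene: str = "SPI1"
    qc_k_sd: float = 2.0
    n_per_time: int = 120
    scale_factor: float = 1.0
    # analysis thresholds
    fdr: float = 0.05
    network_pval: float = 0.01
    kmeans_k: int = 5
    n_modules: int = 2
    module_time_h: float = 24.0
    enriched_module: int = 1
    # simulation
    simulate: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    _PATH_FIELDS = ("out_dir", "ct_table", "network", "motif_table")

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded, so the same
        analysis rerun elsewhere hashes identically)."""
        payload = {k: v for k, v in self.to_dict().items() if k not in self._PATH_FIELDS}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
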