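"""Typed pipeline configuration with YAML round-tripping."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Everything a full pipeline run needs, serializable to YAML.

    Input paths may be None: stages whose inputs are absent are skipped
    (and the synthetic stage can generate them instead).
    """

    # inputs
    apical_path: str | None = None
    expression_path: str | None = None
    expression_meta_path: str | None = None
    deg_path: str | None = None
    gmt_path: str | None = None
    # synthetic stage
    simulate: bool = False
    n_genes: int = 2000
    responsive_fraction: float = 0.10
    doses: tuple[float, ...] = (0.0, 300.0, 500.0, 750.0, 1000.0, 1500.0)
    n_per_group: int = 6
    # thresholds
    bmr: float = 0.10
    bmr_sd_units: float = 1.349
    fit_p_min: float = 0.1
    ratio_max: float = 40.0
    fc_min: float = 1.5
    deg_fc: float = 1.5
    deg_fdr: float = 0.05
    enrich_p: float = 0.1
    enrich_min_genes: int = 10
    k_values: tuple[float, ...] = (2.0, 3.0, 5.0, 10.0)
    n_sim: int = 10000
    # run
    strategies: tuple[str, ...] = ("all_genes", "lowest20_genes")
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self):
        if not (0 < self.bmr < 1):
            raise ValueError("bmr must be in (0, 1)")
        if self.bmr_sd_units <= 0:
            raise ValueError("bmr_sd_units must be > 0")
        if not (0 <= self.fit_p_min < 1):
            raise ValueError("fit_p_min must be in [0, 1)")
        if self.ratio_max <= 1:
            raise ValueError("ratio_max must exceed 1")
        if self.fc_min < 1 or self.deg_fc < 1:
            raise ValueError("fold-change thresholds are linear, >= 1")
        if not (0 < self.deg_fdr <= 1) or not (0 < self.enrich_p <= 1):
            raise ValueError("FDR/enrichment thresholds must be in (0, 1]")
        if any(k < 1 for k in self.k_values):
            raise ValueError("K thresholds must be >= 1")
        if self.n_sim < 1:
            raise ValueError("n_sim must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("doses", "k_values", "strategies"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def as_dict(self) -> dict:
        d = asdict(self)
        for key in ("doses", "k_values", "strategies"):
            d[key] = list(d[key])
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
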