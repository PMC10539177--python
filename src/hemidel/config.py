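"""Pipeline configuration and logging setup.

A :class:`PipelineConfig` names every input file and stage parameter,
round-trips through YAML, and hashes canonically so that every output
of a run can be stamped with the exact configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

LOGGER_NAME = "hemidel"


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    # input paths
    seg: str = "segments.seg.tsv"
    variants: str = "variants.tsv"
    expression: str = "expression.tsv"
    samples: str = "samples.tsv"
    genes: str = "genes.bed"
    ko_lethal: str = "ko_lethal.tsv"
    dependency_crispr: str = "dependency_crispr.tsv"
    dependency_shrna: str = "dependency_shrna.tsv"
    outdir: str = "hemidel_out"
    # stage parameters
    chrom: str = "7"
    deletion_cutoff: float = -0.1
    cdr_thresholds: list[float] = field(default_factory=lambda: [0.70, 0.80, 0.90])
    hierarchy_cutoff: float = 0.05
    expression_scale: str = "linear"
    low_expression_floor: float = 1.0
    max_low_fraction: float = 0.10
    min_del_freq: float = 0.70
    hi_tiers: list[float] = field(default_factory=lambda: [0.80, 0.85, 0.90, 0.95, 1.00])
    signature_tier: int = 95
    linkage: str = "ward"
    metric: str = "euclidean"
    max_signature_size: int = 6
    fc_cut: float = 1.0
    neglog_q_cut: float = 5.0
    dep_score_cut: float = -0.5
    dep_min_fraction: float = 0.5
    sl_rule: str = "lethal_or_vulnerable"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not all(0 < t <= 1 for t in self.cdr_thresholds):
            raise ConfigError("cdr_thresholds must lie in (0, 1]")
        if not 0 < self.hierarchy_cutoff < 1:
            raise ConfigError("hierarchy_cutoff must lie in (0, 1)")
        if self.expression_scale not in ("linear", "log2"):
            raise ConfigError("expression_scale must be 'linear' or 'log2'")
        if self.sl_rule not in ("lethal_or_vulnerable", "all_three"):
            raise ConfigError(f"unknown sl_rule {self.sl_rule!r}")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def hash(self) -> str:
        """Canonical short hash of the full parameter set."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def setup_logging(level: str = "INFO") -> logging.Logger:
    """Configure the package logger to stderr (idempotent)."""
    logger = logging.getLogger(LOGGER_NAME)
    logger.setLevel(level.upper())
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s: %(message)s")
        )
        logger.addHandler(handler)
    return logger
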