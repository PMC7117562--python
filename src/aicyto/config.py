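"""Run configuration: every tunable of the pipeline in one place.

A config can come from a YAML/JSON file, from CLI flags, or both; CLI
values win on conflict.  The canonical JSON serialization is hashed and
embedded in every output file for provenance, so a report can always be
traced back to the exact settings that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Any

import yaml

__all__ = ["RunConfig", "load_config", "setup_logging"]


@dataclass(frozen=True)
class RunConfig:
    # densitometry
    white_level: str | float = "max"   # "max" | "background" | number
    epsilon: float = 1e-4
    min_area: int = 10
    channel_policy: str = "luminance"
    on_overlap: str = "error"          # "error" | "warn" | "ignore"
    # ploidy
    di_bin_width: float = 0.05
    modal_bin_width: float | None = None  # None -> 5% of median control IOD
    mild_threshold: float = 1.1
    moderate_threshold: float = 1.40
    # cohort statistics
    t_variant: str = "pooled"          # "pooled" | "welch"
    alternative_policy: str = "progression"
    alpha: float = 0.05
    # simulation
    seed: int = 0

    def validate(self) -> "RunConfig":
        if not (isinstance(self.white_level, (int, float))
                or self.white_level in ("max", "background")):
            raise ValueError(f"bad white_level {self.white_level!r}")
        if not 0 < self.epsilon < 1:
            raise ValueError("epsilon must lie in (0, 1)")
        if self.on_overlap not in ("error", "warn", "ignore"):
            raise ValueError(f"bad on_overlap {self.on_overlap!r}")
        if self.di_bin_width <= 0:
            raise ValueError("di_bin_width must be positive")
        if not 1.0 < self.mild_threshold < self.moderate_threshold:
            raise ValueError("need 1 < mild_threshold < moderate_threshold")
        if self.t_variant not in ("pooled", "welch"):
            raise ValueError(f"bad t_variant {self.t_variant!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        return self

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def hash(self) -> str:
        """Short stable digest of the canonical JSON serialization."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def with_overrides(self, **kwargs: Any) -> "RunConfig":
        clean = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **clean).validate()


def load_config(path: str | Path | None = None, **overrides: Any) -> RunConfig:
    """Build a RunConfig from an optional YAML/JSON file plus overrides."""
    base: dict[str, Any] = {}
    if path is not None:
        doc = yaml.safe_load(Path(path).read_text())
        if doc is None:
            doc = {}
        if not isinstance(doc, dict):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(doc) - set(RunConfig.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        base = doc
    cfg = RunConfig(**base)
    return cfg.with_overrides(**overrides)


def setup_logging(verbose: bool = False) -> logging.Logger:
    logger = logging.getLogger("aicyto")
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
    return logger
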