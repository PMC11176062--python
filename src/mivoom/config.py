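"""Run configuration: YAML round-trip, scale presets, and config hashing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

__all__ = ["RunConfig", "load_config", "config_hash", "SCALE_PRESETS"]

#: Problem-size presets. ``desk`` targets interactive validation runs; ``full``
#: mirrors the cohort-scale analysis (14k genes, ~1k samples).
SCALE_PRESETS = {
    "desk": {
        "n_samples": 600,
        "n_genes": 2000,
        "lib_size_mean": 1e6,
        "m_imputations": 5,
        "bin_size": 100,
        "max_iter": 5,
    },
    "full": {
        "n_samples": 1065,
        "n_genes": 14000,
        "lib_size_mean": 30e6,
        "m_imputations": 10,
        "bin_size": 50,
        "max_iter": 10,
    },
}


@dataclass
class RunConfig:
    outdir: str = "out"
    seed: int = 0
    scale: str = "desk"

    # data: either a fixture directory (written by `simulate`) or explicit paths
    fixture: str | None = None
    counts: str | None = None
    metadata: str | None = None
    annotation: str | None = None
    gmt: list[str] = field(default_factory=list)

    exposures: list[str] = field(default_factory=lambda: ["sle_sum", "cte_sum"])
    variants: list[str] = field(default_factory=lambda: ["primary", "gestational_age", "no_mediators"])

    # simulation settings (None -> scale preset)
    n_samples: int | None = None
    n_genes: int | None = None
    lib_size_mean: float | None = None
    missing: bool = True

    # multiple-imputation settings (None -> scale preset)
    m_imputations: int | None = None
    bin_size: int | None = None
    max_iter: int | None = None

    # enrichment settings
    methods: list[str] = field(default_factory=lambda: ["ora", "camera", "zscore", "plage", "gage"])
    rule: str = "wilkinson"
    min_size: int = 10
    max_size: int = 500

    def __post_init__(self):
        if self.scale not in SCALE_PRESETS:
            raise ValueError(f"unknown scale preset {self.scale!r}")

    def resolved(self, key: str):
        value = getattr(self, key)
        return SCALE_PRESETS[self.scale][key] if value is None else value

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def config_hash(cfg: RunConfig) -> str:
    """Hash of the analysis-relevant configuration (output location excluded)."""
    d = cfg.to_dict()
    d.pop("outdir", None)
    canonical = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
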