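"""Run configuration: YAML validation with strict keys and filled defaults."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, fields
from pathlib import Path

import yaml

MANDATORY_PATHS = ("genome", "annotation")
OPTIONAL_PATHS = ("reads", "rrna", "snorna", "mirna", "te", "ncrna",
                  "genic", "intergenic")


@dataclass
class RunConfig:
    genome: str
    annotation: str
    reads: str | None = None
    rrna: str | None = None
    snorna: str | None = None
    mirna: str | None = None
    te: str | None = None
    ncrna: str | None = None
    genic: str | None = None
    intergenic: str | None = None
    adapter: str | None = None
    up: int = 25
    down: int = 80
    min_len: int = 15
    max_len: int = 29
    tolerance: int = 2
    order: str = "methods"
    seed: int = 0
    outdir: str = "trnafrag_out"

    def config_hash(self) -> str:
        payload = "|".join(f"{f.name}={getattr(self, f.name)}" for f in fields(self))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def validate_config(file: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Unknown keys are rejected by name; missing mandatory paths and
    nonexistent referenced files are errors; defaults are filled for
    everything else (up=25, down=80, min_len=15, max_len=29, tolerance=2,
    order=methods).
    """
    raw = yaml.safe_load(Path(file).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    missing = [k for k in MANDATORY_PATHS if not raw.get(k)]
    if missing:
        raise ValueError(f"missing mandatory keys: {missing}")
    cfg = RunConfig(**raw)
    if cfg.tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    if cfg.min_len > cfg.max_len:
        raise ValueError("min_len must be <= max_len")
    if cfg.up < 0 or cfg.down < 0:
        raise ValueError("extensions must be non-negative")
    base = Path(file).parent
    for key in MANDATORY_PATHS + OPTIONAL_PATHS:
        val = getattr(cfg, key)
        if val is None:
            continue
        p = Path(val)
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise ValueError(f"config key {key!r}: path {p} does not exist")
        setattr(cfg, key, str(p))
    return cfg
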