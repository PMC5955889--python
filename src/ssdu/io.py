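"""Configuration, ensemble tables, and provenance records.

Ensemble tables are tab-separated text with the fixed header
``r a b y1 y2 y3 energy`` and one conformation per row, floats written in
their shortest round-trip decimal form so a write/read cycle is exact.
Configuration is YAML with every key validated against the module
invariants; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .geometry import Conformation

__all__ = ["RunConfig", "load_config", "save_config", "read_ensemble",
           "write_ensemble", "write_provenance"]

ENSEMBLE_COLUMNS = ["r", "a", "b", "y1", "y2", "y3", "energy"]


@dataclass
class RunConfig:
    """All pipeline parameters with their documented defaults.

    Refinement defaults follow the published protocol (K=1000, eps=1.0,
    n_min=100, eta=0.3, three iterations); post-processing defaults are the
    9 A / 30 clusters / 10 members greedy-clustering rule.
    """

    K: int = 1000
    eps: float = 1.0
    n_min: int = 100
    eta: float = 0.3
    beta: float = 2.0
    k_bar: Optional[int] = None
    max_iter: int = 3
    degree: int = 4
    n_permissive: int = 3
    threshold: float = 9.0
    max_clusters: int = 30
    min_size: int = 10
    temperature: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            ("K", self.K >= 1, "must be >= 1"),
            ("eps", self.eps > 0, "must be positive"),
            ("n_min", self.n_min >= 1, "must be >= 1"),
            ("eta", 0.0 < self.eta <= 1.0, "must be in (0, 1]"),
            ("beta", self.beta >= 0, "must be non-negative"),
            ("max_iter", self.max_iter >= 1, "must be >= 1"),
            ("degree", self.degree in (2, 4, 6), "must be one of 2, 4, 6"),
            ("n_permissive", self.n_permissive in (2, 3), "must be 2 or 3"),
            ("threshold", self.threshold > 0, "must be positive"),
            ("max_clusters", self.max_clusters >= 1, "must be >= 1"),
            ("min_size", self.min_size >= 1, "must be >= 1"),
            ("temperature", self.temperature > 0, "must be positive"),
        ]
        for key, ok, msg in checks:
            if not ok:
                raise ValueError(f"config key `{key}` {msg} (got {getattr(self, key)!r})")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a YAML config; an empty file gives all defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(unknown)}")
    return RunConfig(**data)


def save_config(config: RunConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def _fmt(v: float) -> str:
    """Shortest round-trip decimal representation."""
    return repr(float(v))


def write_ensemble(ensemble: Sequence[Conformation], path: Union[str, Path]) -> None:
    """Write the TSV ensemble table (missing energies are written as nan)."""
    lines = ["\t".join(ENSEMBLE_COLUMNS)]
    for c in ensemble:
        e = float("nan") if c.energy is None else c.energy
        lines.append("\t".join(_fmt(v) for v in (*c.psi, e)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_ensemble(path: Union[str, Path]) -> List[Conformation]:
    """Read a TSV ensemble table; malformed rows fail with their line number."""
    df = pd.read_csv(path, sep=r"\t", engine="python", skipinitialspace=True,
                     dtype=str, skip_blank_lines=True)
    df.columns = [c.strip() for c in df.columns]
    if list(df.columns) != ENSEMBLE_COLUMNS:
        raise ValueError(
            f"{path}: expected header {' '.join(ENSEMBLE_COLUMNS)}, got {' '.join(df.columns)}"
        )
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            vals = [float(str(v).strip()) for v in row]
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {i}: {exc}") from exc
        energy = None if np.isnan(vals[6]) else vals[6]
        try:
            out.append(Conformation.from_psi(vals[:6], energy=energy))
        except ValueError as exc:
            raise ValueError(f"{path}: invalid conformation at line {i}: {exc}") from exc
    return out


def write_provenance(path: Union[str, Path], config: dict, seed: int,
                     extra: Optional[dict] = None) -> None:
    """Machine-readable run record: config hash, seed, package version."""
    from . import __version__

    canonical = yaml.safe_dump(config, sort_keys=True)
    record = {
        "config": config,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": int(seed),
        "ssdu_version": __version__,
        "numpy_version": np.__version__,
    }
    if extra:
        record.update(extra)
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
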