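"""Configuration, species-table I/O, and synthetic fixture generation.

Species rate tables are plain TSV with the header

    species  gene_id  kd_m_per_min  kd_g_per_min

emulating published per-gene paired transcript/protein decay-constant
compilations.  A seeded log-normal generator stands in for such
supplements so every downstream analysis is testable without external
data: per-gene transcript decay rates and integration times T are drawn
log-normally around configurable medians (decay-rate compilations are
approximately log-normal across genes), and kd_g = kd_m / T.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pipeline import SpeciesRateTable

__all__ = [
    "RunConfig",
    "SyntheticSpeciesSpec",
    "read_species_table",
    "write_species_table",
    "generate_synthetic_species",
]


@dataclass
class RunConfig:
    """Serializable bundle of model, simulation and estimation settings."""

    alpha: float = 1.0
    leak: float = 0.01
    k_m: float = 0.1
    kd_m: float = 0.1
    k_g: float = 0.0
    kd_g: float = 0.01
    n_inputs: int = 16
    duration: float = 1e5
    sample_interval: float = 10.0
    burn_in: float | None = None
    seed: int = 0
    eta: float = 1.0
    nb: int | None = None
    fractions: tuple[float, ...] = (0.5, 0.625, 0.75, 0.875, 1.0)
    n_replicates: int = 5
    ba_tol: float = 1e-6
    output_dir: str = "."

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fractions"] = list(d["fractions"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "fractions" in d:
            d["fractions"] = tuple(d["fractions"])
        return cls(**d)

    def dump(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    @property
    def config_hash(self) -> str:
        """Stable short hash identifying this configuration in output files."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class SyntheticSpeciesSpec:
    """Log-normal generator settings for a synthetic per-gene rate table."""

    species: str
    n_genes: int = 1000
    median_kd_m: float = 0.1  # 1/min
    median_T: float = 20.0  # dimensionless kd_m/kd_g
    sigma_log_kd_m: float = 0.5  # geometric spread (std of ln kd_m)
    sigma_log_T: float = 0.8  # geometric spread (std of ln T)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species label must be non-empty")
        if self.n_genes < 10:
            raise ValueError("need at least 10 genes")
        if not (self.median_kd_m > 0 and self.median_T > 0):
            raise ValueError("medians must be > 0")
        if self.sigma_log_kd_m < 0 or self.sigma_log_T < 0:
            raise ValueError("spreads must be >= 0")


def generate_synthetic_species(spec: SyntheticSpeciesSpec) -> SpeciesRateTable:
    """Synthetic paired decay-rate table with log-normal gene-to-gene spread.

    The sample median of T converges to ``spec.median_T`` (the log-normal
    median is its scale parameter); zero spread collapses every gene to
    the median exactly.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    kd_m = spec.median_kd_m * np.exp(
        rng.normal(0.0, spec.sigma_log_kd_m, spec.n_genes)
        if spec.sigma_log_kd_m > 0
        else np.zeros(spec.n_genes)
    )
    T = spec.median_T * np.exp(
        rng.normal(0.0, spec.sigma_log_T, spec.n_genes)
        if spec.sigma_log_T > 0
        else np.zeros(spec.n_genes)
    )
    frame = pd.DataFrame(
        {
            "species": spec.species,
            "gene_id": [f"{spec.species}_g{i:05d}" for i in range(spec.n_genes)],
            "kd_m_per_min": kd_m,
            "kd_g_per_min": kd_m / T,
        }
    )
    return SpeciesRateTable(frame)


def read_species_table(path: str | Path) -> SpeciesRateTable:
    """Read a TSV species rate table, reporting malformed rows by line number."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in SpeciesRateTable.REQUIRED if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("kd_m_per_min", "kd_g_per_min"):
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[vals.isna() | (vals <= 0)]
        if len(bad):
            # +2: header line plus 1-based numbering
            lines = [int(i) + 2 for i in bad]
            raise ValueError(
                f"{path}: invalid {col} on line(s) {lines} "
                "(must be a positive number)"
            )
        frame[col] = vals
    return SpeciesRateTable(frame)


def write_species_table(table: SpeciesRateTable, path: str | Path) -> None:
    """Write a species rate table as TSV with full float precision."""
    table.frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
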