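"""Canonical file formats: cell table, clinical table, run config.

The cell table is comma-separated UTF-8 with a header and "." decimals;
missing values are empty fields. Required columns: ``cell_id``, ``core_id``,
``patient_id``, ``x_um``, ``y_um`` (micrometres), ``compartment``, plus at
least one of ``marker_<name>`` (intensities), ``pos_<name>`` (0/1 calls) or
``phenotype`` (precomputed labels). Unknown columns are preserved.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

REQUIRED_CELL_COLUMNS = ("cell_id", "core_id", "patient_id",
                         "x_um", "y_um", "compartment")
CLINICAL_COLUMNS = ("patient_id", "age", "stage", "grade", "debulking",
                    "chemo_sensitivity", "os_months", "os_event",
                    "pfs_months", "pfs_event")


def read_cell_table(path) -> pd.DataFrame:
    """Read and validate the canonical per-cell table."""
    cells = pd.read_csv(path, float_precision="round_trip")
    for col in REQUIRED_CELL_COLUMNS:
        if col not in cells.columns:
            raise ValueError(f"cell table is missing required column {col!r}")
    has_signal = (any(c.startswith("marker_") for c in cells.columns)
                  or any(c.startswith("pos_") for c in cells.columns)
                  or "phenotype" in cells.columns)
    if not has_signal:
        raise ValueError("cell table needs marker_<name>, pos_<name> "
                         "or phenotype columns")
    for col in ("x_um", "y_um"):
        num = pd.to_numeric(cells[col], errors="coerce")
        if num.isna().any():
            row = int(cells.index[num.isna()][0]) + 2   # 1-based + header
            raise ValueError(f"non-numeric {col} at file row {row}")
        cells[col] = num
    dup = cells.duplicated(subset=["core_id", "cell_id"])
    if dup.any():
        pair = cells.loc[dup, ["core_id", "cell_id"]].iloc[0].tolist()
        raise ValueError(f"duplicate (core_id, cell_id) = {tuple(pair)}")
    return cells


def read_clinical_table(path) -> pd.DataFrame:
    clinical = pd.read_csv(path)
    if "patient_id" not in clinical.columns:
        raise ValueError("clinical table is missing required column 'patient_id'")
    if clinical["patient_id"].duplicated().any():
        raise ValueError("duplicate patient_id in clinical table")
    return clinical


def write_csv(df: pd.DataFrame, path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index)
    return path


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Exactly one of ``cells_path`` (with optional ``clinical_path``) or
    ``simulate`` (keyword dict for :class:`~spatialtma.simulate.SimulationConfig`)
    must be set.
    """

    out_dir: str = "spatialtma_run"
    seed: int = 0
    cells_path: str | None = None
    clinical_path: str | None = None
    simulate: dict | None = None
    panel: str = "panel1"
    thresholds: dict[str, float] | None = None
    k: int = 15
    n: int = 6
    k_grid: tuple[int, ...] | None = None
    n_grid: tuple[int, ...] | None = None
    split_mode: str = "mean"
    endpoints: tuple[str, ...] = ("os", "pfs")
    horizon_months: float = 60.0
    similarity_threshold: float = 0.95
    neighborhood_names: dict[int, str] = field(default_factory=dict)
    ratios: list[dict] = field(default_factory=list)   # {"numerator": name, "denominator": name}
    mini_batch: bool = False
    figures: bool = True

    def validate(self) -> None:
        if (self.cells_path is None) == (self.simulate is None):
            raise ValueError("exactly one of cells_path or simulate must be set")
        if self.k < 1 or self.n < 1:
            raise ValueError("k and n must be >= 1")
        if self.seed is None:
            raise ValueError("seed must be set")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.neighborhood_names:
            cfg.neighborhood_names = {int(k): v
                                      for k, v in cfg.neighborhood_names.items()}
        cfg.validate()
        return cfg

    def to_jsonable(self) -> dict:
        out = {}
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if isinstance(v, tuple):
                v = list(v)
            out[name] = v
        return out

    def config_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
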