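"""Tabular input schemas, validated readers, and the pipeline configuration."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError

__all__ = ["TableSchema", "SCHEMAS", "read_table", "write_table", "PipelineConfig"]


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[str, ...]
    numeric: tuple[str, ...] = ()
    integer: tuple[str, ...] = ()
    boolean: tuple[str, ...] = ()
    key: tuple[str, ...] = ()


SCHEMAS: dict[str, TableSchema] = {
    "redox": TableSchema(
        name="redox",
        columns=("time_days", "replicate", "species", "amount_umol_per_gDW"),
        numeric=("time_days", "amount_umol_per_gDW"),
        key=("time_days", "replicate", "species"),
    ),
    "germination": TableSchema(
        name="germination",
        columns=("dose", "n_tested", "n_germinated"),
        numeric=("dose",),
        integer=("n_tested", "n_germinated"),
    ),
    "qpcr": TableSchema(
        name="qpcr",
        columns=("sample_id", "gene", "time_days", "replicate", "cycle", "fluorescence", "spiked"),
        numeric=("time_days", "fluorescence"),
        integer=("cycle",),
        boolean=("spiked",),
        key=("sample_id", "gene", "cycle"),
    ),
    "efficiency_ct": TableSchema(
        name="efficiency_ct",
        columns=("gene", "time_days", "replicate", "efficiency", "ct"),
        numeric=("time_days", "efficiency", "ct"),
        key=("gene", "time_days", "replicate"),
    ),
    "array": TableSchema(
        name="array",
        columns=("probe_id", "array_id", "time_days", "block", "spot_index", "M", "A"),
        numeric=("time_days", "M", "A"),
        integer=("spot_index",),
        key=("probe_id", "array_id", "time_days", "spot_index"),
    ),
}

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def _sniff_sep(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        first = fh.readline()
    return "\t" if first.count("\t") > first.count(",") else ","


def read_table(path: str | Path, schema: str | TableSchema) -> pd.DataFrame:
    """Read and validate a delimited table against a named schema.

    CSV/TSV is sniffed from the header line.  Missing columns, non-numeric
    cells and duplicate keys raise :class:`SchemaError` with the offending
    column and 1-based data row number.
    """
    if isinstance(schema, str):
        try:
            schema = SCHEMAS[schema]
        except KeyError:
            raise SchemaError(f"unknown schema '{schema}'") from None
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)
    missing = [c for c in schema.columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    out = pd.DataFrame(index=df.index)
    for col in schema.columns:
        raw = df[col]
        if col in schema.numeric or col in schema.integer:
            vals = pd.to_numeric(raw, errors="coerce")
            bad = vals.isna() & (raw.str.strip() != "")
            empty = raw.str.strip() == ""
            problem = bad | empty
            if problem.any():
                row = int(problem.idxmax()) + 1
                raise SchemaError(f"{path}: non-numeric value {raw[problem.idxmax()]!r} in column '{col}', data row {row}")
            if col in schema.integer:
                if not np.allclose(vals, np.round(vals)):
                    frac = ~np.isclose(vals, np.round(vals))
                    row = int(np.argmax(frac.to_numpy())) + 1
                    raise SchemaError(f"{path}: non-integer value in column '{col}', data row {row}")
                out[col] = vals.astype(int)
            else:
                out[col] = vals.astype(float)
        elif col in schema.boolean:
            lowered = raw.str.strip().str.lower()
            ok = lowered.isin(_TRUE | _FALSE)
            if not ok.all():
                row = int((~ok).idxmax()) + 1
                raise SchemaError(f"{path}: non-boolean value {raw[(~ok).idxmax()]!r} in column '{col}', data row {row}")
            out[col] = lowered.isin(_TRUE)
        else:
            out[col] = raw
    if schema.key:
        dup = out.duplicated(subset=list(schema.key))
        if dup.any():
            row = int(dup.idxmax()) + 1
            raise SchemaError(f"{path}: duplicate key {tuple(schema.key)} at data row {row}")
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as CSV with stable float formatting (round-trip safe)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g")


@dataclass
class PipelineConfig:
    """Single configuration object every stage reads its parameters from."""

    # input tables (None = stage skipped)
    redox_table: str | None = None
    germination_table: str | None = None
    qpcr_table: str | None = None
    array_table: str | None = None
    output_dir: str = "results/pipeline"

    # redox stage
    couple_potentials_mV: dict = field(default_factory=dict)  # couple -> E0' override
    species_map: dict = field(default_factory=dict)  # couple -> [thiol, disulphide]
    hydration_mL_per_gDW: float = 1.0
    temperature_K: float = 298.15
    pH: float = 7.0
    detection_limit_M: float | None = None

    # viability stage
    probit_level: float = 0.95
    probit_ci_method: str = "delta"

    # qPCR stage
    reference_gene: str = "PBGD"
    control_time_days: float = 0.0
    stability_p_threshold: float = 0.05
    efficiency_method: str = "growth-rate"

    # array stage
    fdr_level: float = 0.05
    fold_threshold_log2: float = 1.0
    min_replicates: int = 2
    cluster_k: int = 16
    loess_span: float = 0.3
    min_block_spots: int = 20

    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
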