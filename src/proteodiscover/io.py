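"""Tabular readers/writers and run configuration.

Plain TSV/CSV is the canonical interchange format: a protein matrix is
a rectangular table whose first column is the sample id and whose
remaining columns are protein ids, with an optional first-line
``#scale=raw|log10`` directive and an optional sidecar of per-protein
detection limits.  Every table written by the pipeline carries the
run-config hash in a leading comment line so outputs are traceable to
the exact thresholds that produced them.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .containers import ProteinMatrix, RAW, SCALES, validate_sample_meta

log = logging.getLogger(__name__)

__all__ = [
    "read_protein_matrix",
    "write_protein_matrix",
    "read_sample_meta",
    "write_sample_meta",
    "write_table",
    "RunConfig",
]


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_protein_matrix(
    path,
    sep: str | None = None,
    scale: str | None = None,
    limits_path=None,
) -> ProteinMatrix:
    """Read a samples x proteins table.

    The measurement scale comes from an explicit ``scale=`` argument or
    a ``#scale=...`` directive on the first line (argument wins).
    Duplicate sample or protein ids and non-numeric cells are rejected
    with coordinates.
    """
    path = Path(path)
    s = _sep_for(path, sep)
    with open(path) as fh:
        first = fh.readline().strip()
    skip = 0
    if first.startswith("#"):
        skip = 1
        directive = first.lstrip("#").strip()
        if directive.startswith("scale=") and scale is None:
            scale = directive.split("=", 1)[1]
    if scale is None:
        scale = RAW
    if scale not in SCALES:
        raise ValueError(f"scale must be one of {SCALES}, got {scale!r}")

    with open(path) as fh:
        for _ in range(skip):
            fh.readline()
        raw_header = fh.readline().rstrip("\n").split(s)
    cols = pd.Index(raw_header[1:])
    dupes = cols[cols.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate protein column(s): {dupes}")
    df = pd.read_csv(path, sep=s, skiprows=skip, index_col=0)
    df.index.name = "sample_id"
    df.columns.name = "protein_id"
    non_numeric = df.columns[~df.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(non_numeric):
        col = non_numeric[0]
        bad_rows = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
        raise ValueError(
            f"non-numeric cell(s) in column {col!r}, row(s) {bad_rows[:5]}"
        )
    limits = None
    if limits_path is not None:
        lp = Path(limits_path)
        limits = pd.read_csv(lp, sep=_sep_for(lp, sep), index_col=0)
    return ProteinMatrix(df, scale=scale, limits=limits)


def write_protein_matrix(matrix: ProteinMatrix, path, sep: str | None = None) -> None:
    path = Path(path)
    s = _sep_for(path, sep)
    with open(path, "w") as fh:
        fh.write(f"#scale={matrix.scale}\n")
        matrix.data.to_csv(fh, sep=s)
    if matrix.limits is not None:
        lp = path.with_name(path.stem + ".limits" + path.suffix)
        matrix.limits.to_csv(lp, sep=s)


def read_sample_meta(path, sep: str | None = None) -> pd.DataFrame:
    """Read and validate a sample metadata table (sample_id first column).

    Required columns: group, age, sex.  Missing optional columns are
    tolerated with a logged notice; downstream stages degrade gracefully
    (e.g. a missing ledd column drops the medication-dose covariate).
    """
    path = Path(path)
    meta = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0)
    meta.index.name = "sample_id"
    from .containers import OPTIONAL_META_COLUMNS

    absent = [c for c in OPTIONAL_META_COLUMNS if c not in meta.columns]
    if absent:
        log.info("sample metadata: optional column(s) absent: %s", absent)
    return validate_sample_meta(meta)


def write_sample_meta(meta: pd.DataFrame, path, sep: str | None = None) -> None:
    path = Path(path)
    meta.to_csv(path, sep=_sep_for(path, sep))


def write_table(df: pd.DataFrame, path, config_hash: str | None = None,
                sep: str | None = None, index: bool = True) -> None:
    """Write a tidy report table, stamping the config hash as a comment."""
    path = Path(path)
    s = _sep_for(path, sep)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep=s, index=index)


@dataclass
class RunConfig:
    """All pipeline thresholds (published defaults) plus run plumbing."""

    seed: int = 0
    out_dir: str = "proteodiscover_out"
    log_level: str = "INFO"

    # QC thresholds
    cv_threshold: float = 0.2
    lod_max_frac: float = 0.25
    scale_gate_low: float = 0.4
    scale_gate_high: float = 2.5

    # discovery / replication
    nomination_p: float = 0.005
    fdr_alpha: float = 0.05

    # stability selection
    stability_iterations: int = 10_000
    frac_samples_out: float = 0.10
    frac_features_out: float = 0.30
    top_k: int = 10

    # simulator overrides (field name -> value), applied to SimConfig
    sim: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
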