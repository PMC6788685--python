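"""Core in-memory containers for the pipeline.

The analysis substrate is a samples x proteins matrix of aptamer
relative-fluorescence units (RFU), either raw or log10-transformed,
with optional per-protein detection limits, plus a per-sample
phenotype table (group, age, sex, site, batch, medication dose ...).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RAW = "raw"
LOG10 = "log10"
SCALES = (RAW, LOG10)

GROUP_LEVELS = ("NC", "PD", "ALS")
SEX_LEVELS = ("F", "M")

#: optional SampleMeta columns tolerated when absent
OPTIONAL_META_COLUMNS = (
    "site",
    "batch",
    "ledd",
    "treated",
    "disease_duration",
    "education",
)


@dataclass
class ProteinMatrix:
    """Samples x proteins measurement table.

    Parameters
    ----------
    data
        DataFrame indexed by sample id with one column per protein id.
        Values are raw RFU (nonnegative) or log10 RFU depending on
        ``scale``.
    scale
        Either ``"raw"`` or ``"log10"``.
    limits
        Optional per-protein detection limits, indexed by protein id
        with columns ``llod`` and ``ulod`` in raw RFU.
    """

    data: pd.DataFrame
    scale: str = RAW
    limits: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein ids: {dup}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("matrix values must be numeric")
        if self.scale == RAW and np.nanmin(values, initial=0.0) < 0:
            raise ValueError("raw RFU matrix contains negative values")
        if self.limits is not None:
            missing = [c for c in ("llod", "ulod") if c not in self.limits.columns]
            if missing:
                raise ValueError(f"limits table lacks columns: {missing}")
            bad = self.limits["llod"] >= self.limits["ulod"]
            if bad.any():
                raise ValueError(
                    f"llod >= ulod for proteins: {self.limits.index[bad].tolist()[:5]}"
                )

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def protein_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def copy(self) -> "ProteinMatrix":
        return ProteinMatrix(
            self.data.copy(),
            scale=self.scale,
            limits=None if self.limits is None else self.limits.copy(),
        )

    def subset(self, samples=None, proteins=None) -> "ProteinMatrix":
        data = self.data
        if samples is not None:
            data = data.loc[samples]
        if proteins is not None:
            data = data[list(proteins)]
        limits = self.limits
        if limits is not None and proteins is not None:
            limits = limits.loc[limits.index.intersection(data.columns)]
        return ProteinMatrix(data, scale=self.scale, limits=limits)


def validate_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-sample phenotype table.

    Requires columns ``group`` (NC/PD/ALS), ``age`` (years) and ``sex``
    (F/M), indexed by unique sample id.  Optional columns (site, batch,
    ledd, treated, disease_duration, education) pass through untouched.
    """
    required = ("group", "age", "sex")
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata lacks required columns: {missing}")
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dup}")
    bad_groups = set(meta["group"].dropna().unique()) - set(GROUP_LEVELS)
    if bad_groups:
        raise ValueError(
            f"unknown group level(s) {sorted(bad_groups)}; allowed: {list(GROUP_LEVELS)}"
        )
    bad_sex = set(meta["sex"].dropna().unique()) - set(SEX_LEVELS)
    if bad_sex:
        raise ValueError(
            f"unknown sex level(s) {sorted(bad_sex)}; allowed: {list(SEX_LEVELS)}"
        )
    if not np.issubdtype(np.asarray(meta["age"]).dtype, np.number):
        raise ValueError("age column must be numeric (years)")
    return meta


def align_meta(matrix: ProteinMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Return metadata reindexed to the matrix samples, erroring on gaps."""
    missing = matrix.sample_ids.difference(meta.index)
    if len(missing):
        raise ValueError(f"metadata missing for samples: {missing.tolist()[:5]}")
    return meta.loc[matrix.sample_ids]
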