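"""Preprocessing and QC of aptamer-panel protein data.

The chain mirrors standard practice for SOMAScan-style panels:
hybridization normalization against spiked-in controls, per-sample
median normalization, a scale-factor acceptance gate (0.4-2.5),
a triplicate coefficient-of-variation filter (CV > 0.2 in any
reference-pool triplicate excludes the protein), a limit-of-detection
filter (>25 % of measurements outside LLOD/ULOD excludes the protein),
and finally the log10 transform used by all downstream models.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import LOG10, RAW, ProteinMatrix

log = logging.getLogger(__name__)

__all__ = [
    "QCReport",
    "hybridization_normalize",
    "median_normalize",
    "gate_scale_factors",
    "triplicate_cv_filter",
    "lod_filter",
    "log10_transform",
    "run_qc",
]


@dataclass
class QCReport:
    """Accounting of the QC chain: factors, CVs and exclusions."""

    hybridization_factors: pd.Series | None = None
    median_factors: pd.Series | None = None
    #: True = sample passed the scale-factor gate
    scale_factor_pass: pd.Series | None = None
    cv_table: pd.DataFrame | None = None
    #: tidy exclusions: columns (id, kind, reason) with kind in
    #: {protein, sample} and reason in {cv, lod, scale_factor}
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["id", "kind", "reason"])
    )
    n_assayed: int = 0
    n_retained: int = 0

    def excluded_proteins(self) -> list[str]:
        m = self.exclusions["kind"] == "protein"
        return sorted(self.exclusions.loc[m, "id"].unique())

    def excluded_samples(self) -> list[str]:
        m = self.exclusions["kind"] == "sample"
        return sorted(self.exclusions.loc[m, "id"].unique())

    def add_exclusions(self, ids, kind: str, reason: str) -> None:
        if len(ids):
            add = pd.DataFrame({"id": list(ids), "kind": kind, "reason": reason})
            self.exclusions = pd.concat([self.exclusions, add], ignore_index=True)


def hybridization_normalize(
    matrix: ProteinMatrix,
    control_ids,
    reference_levels: pd.Series | None = None,
) -> tuple[ProteinMatrix, pd.Series]:
    """Remove per-sample hybridization artifacts using spiked-in controls.

    ``factor_i = median over controls c of (reference_level_c / observed_ic)``;
    every protein of sample *i* is multiplied by ``factor_i``.  When no
    external reference is supplied, each control's across-sample median
    is used as its reference level.
    """
    if matrix.scale != RAW:
        raise ValueError("hybridization normalization operates on raw RFU")
    control_ids = list(control_ids)
    missing = [c for c in control_ids if c not in matrix.protein_ids]
    if missing:
        raise KeyError(f"control protein(s) not in matrix: {missing}")
    obs = matrix.data[control_ids]
    if (obs <= 0).to_numpy().any():
        bad = obs.index[(obs <= 0).any(axis=1)].tolist()
        raise ValueError(f"nonpositive control readings in samples: {bad[:5]}")
    if reference_levels is None:
        reference_levels = obs.median(axis=0)
    else:
        reference_levels = pd.Series(reference_levels).reindex(control_ids)
        if reference_levels.isna().any() or (reference_levels <= 0).any():
            raise ValueError("reference levels must be positive and cover all controls")
    factors = (reference_levels / obs).median(axis=1)
    factors.name = "hybridization_factor"
    out = ProteinMatrix(
        matrix.data.mul(factors, axis=0), scale=RAW, limits=matrix.limits
    )
    return out, factors


def median_normalize(matrix: ProteinMatrix) -> tuple[ProteinMatrix, pd.Series]:
    """Per-sample median normalization against across-sample protein medians.

    With ``r_j`` the across-sample median of protein *j*,
    ``factor_i = median over j of (r_j / x_ij)``.  Afterwards
    ``median_j(r_j / x'_ij) = 1`` exactly, for every sample.
    """
    if matrix.scale != RAW:
        raise ValueError("median normalization operates on raw RFU")
    if matrix.n_samples < 2:
        raise ValueError("median normalization needs at least 2 samples")
    r = matrix.data.median(axis=0)
    if (r == 0).any():
        bad = r.index[r == 0].tolist()
        raise ValueError(f"zero across-sample median for proteins: {bad[:5]}")
    factors = (r / matrix.data).median(axis=1)
    factors.name = "median_factor"
    out = ProteinMatrix(
        matrix.data.mul(factors, axis=0), scale=RAW, limits=matrix.limits
    )
    return out, factors


def gate_scale_factors(
    factors: pd.Series, low: float = 0.4, high: float = 2.5
) -> pd.Series:
    """Acceptance gate on normalization scale factors.

    Samples pass iff ``low <= factor <= high`` (inclusive bounds pass;
    the published range is stated without boundary semantics, so the
    inclusive reading is pinned here).
    """
    factors = pd.Series(factors)
    if (factors <= 0).any():
        raise ValueError("scale factors must be positive")
    passed = (factors >= low) & (factors <= high)
    passed.name = "scale_factor_pass"
    return passed


def triplicate_cv_filter(
    qc_runs: pd.DataFrame, threshold: float = 0.2
) -> tuple[pd.DataFrame, list[str]]:
    """Per-protein CV from reference-pool triplicates, and the exclusion set.

    ``qc_runs`` is a tidy table (pool, replicate, protein_id, rfu) with
    exactly three replicates per (pool, protein).  CV = sample standard
    deviation (ddof=1) / mean on raw RFU, one per triplicate; a protein
    is excluded iff any triplicate CV exceeds ``threshold`` (strict).

    Returns the tidy CV table (protein_id, pool, cv, flag) and the
    sorted excluded protein ids.
    """
    required = {"pool", "replicate", "protein_id", "rfu"}
    missing = required - set(qc_runs.columns)
    if missing:
        raise ValueError(f"qc_runs lacks columns: {sorted(missing)}")
    counts = qc_runs.groupby(["pool", "protein_id"], observed=True).size()
    if (counts != 3).any():
        bad = counts[counts != 3].index.tolist()
        raise ValueError(f"each (pool, protein) needs exactly 3 replicates; bad: {bad[:5]}")
    g = qc_runs.groupby(["pool", "protein_id"], observed=True)["rfu"]
    mean = g.mean()
    if (mean <= 0).any():
        bad = mean[mean <= 0].index.tolist()
        raise ValueError(f"nonpositive triplicate mean for: {bad[:5]}")
    cv = (g.std(ddof=1) / mean).rename("cv").reset_index()
    cv["flag"] = cv["cv"] > threshold
    excluded = sorted(cv.loc[cv["flag"], "protein_id"].unique())
    return cv[["protein_id", "pool", "cv", "flag"]], excluded


def lod_filter(
    matrix: ProteinMatrix, max_frac: float = 0.25
) -> tuple[list[str], pd.DataFrame]:
    """Exclude proteins with too many measurements outside detection limits.

    A protein is excluded iff ``(count below llod + count above ulod) /
    n_samples > max_frac`` (strict).  Proteins without limit annotations
    are passed through with a logged warning -- panels whose vendor did
    not publish limits simply skip this filter.
    """
    if matrix.scale != RAW:
        raise ValueError("LOD filter operates on raw RFU")
    details = []
    excluded = []
    limits = matrix.limits if matrix.limits is not None else pd.DataFrame()
    n_missing = 0
    for pid in matrix.protein_ids:
        if pid not in limits.index or limits.loc[pid, ["llod", "ulod"]].isna().any():
            n_missing += 1
            details.append((pid, np.nan, False))
            continue
        llod, ulod = limits.loc[pid, "llod"], limits.loc[pid, "ulod"]
        x = matrix.data[pid].to_numpy()
        frac = ((x < llod).sum() + (x > ulod).sum()) / len(x)
        flag = frac > max_frac
        details.append((pid, frac, flag))
        if flag:
            excluded.append(pid)
    if n_missing:
        log.warning(
            "LOD filter: %d protein(s) lack llod/ulod annotations and were passed through",
            n_missing,
        )
    table = pd.DataFrame(details, columns=["protein_id", "frac_outside", "flag"])
    return excluded, table


def log10_transform(matrix: ProteinMatrix) -> ProteinMatrix:
    """log10-transform a raw-RFU matrix (all models run on this scale)."""
    if matrix.scale != RAW:
        raise ValueError("matrix is already log10-transformed")
    vals = matrix.data.to_numpy()
    if (vals <= 0).any():
        n_bad = int((vals <= 0).sum())
        raise ValueError(f"log10 transform requires strictly positive values ({n_bad} violations)")
    return ProteinMatrix(np.log10(matrix.data), scale=LOG10, limits=matrix.limits)


def run_qc(
    matrix: ProteinMatrix,
    qc_runs: pd.DataFrame | None = None,
    control_ids=None,
    cv_threshold: float = 0.2,
    lod_max_frac: float = 0.25,
    gate_low: float = 0.4,
    gate_high: float = 2.5,
    apply_lod: bool = True,
) -> tuple[ProteinMatrix, QCReport]:
    """Full QC chain; returns the log10 matrix of retained samples/proteins.

    Order: hybridization normalization (if controls given), median
    normalization, scale-factor gate on both factor sets, CV filter (if
    triplicates given), LOD filter, log10 transform.  The CV and LOD
    filters act on disjoint evidence, so their composition is
    order-independent.
    """
    report = QCReport(n_assayed=matrix.n_proteins)
    work = matrix
    if control_ids is not None:
        work, hyb = hybridization_normalize(work, control_ids)
        report.hybridization_factors = hyb
        hyb_pass = gate_scale_factors(hyb, gate_low, gate_high)
    else:
        hyb_pass = pd.Series(True, index=matrix.sample_ids)
    work, med = median_normalize(work)
    report.median_factors = med
    med_pass = gate_scale_factors(med, gate_low, gate_high)
    report.scale_factor_pass = hyb_pass & med_pass
    failed_samples = report.scale_factor_pass.index[~report.scale_factor_pass]
    report.add_exclusions(failed_samples, "sample", "scale_factor")
    if len(failed_samples):
        log.info("scale-factor gate excluded %d sample(s)", len(failed_samples))
        work = work.subset(samples=report.scale_factor_pass.index[report.scale_factor_pass])

    excluded: set[str] = set()
    if qc_runs is not None:
        cv_table, cv_excluded = triplicate_cv_filter(qc_runs, threshold=cv_threshold)
        report.cv_table = cv_table
        report.add_exclusions(cv_excluded, "protein", "cv")
        excluded.update(cv_excluded)
        log.info("CV filter excluded %d protein(s)", len(cv_excluded))
    if apply_lod and work.limits is not None:
        lod_excluded, _ = lod_filter(work, max_frac=lod_max_frac)
        report.add_exclusions(lod_excluded, "protein", "lod")
        excluded.update(lod_excluded)
        log.info("LOD filter excluded %d protein(s)", len(lod_excluded))

    keep = [p for p in work.protein_ids if p not in excluded]
    report.n_retained = len(keep)
    work = work.subset(proteins=keep)
    return log10_transform(work), report
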