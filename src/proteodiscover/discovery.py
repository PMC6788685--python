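"""Covariate-adjusted discovery of disease-associated proteins.

Each protein's log10 level is modeled by ordinary least squares as the
effect of disease group (PD = 1, NC = 0) adjusted for covariates (age,
sex, levodopa-equivalent dose in the single-site design; age, sex,
clinical site and assay batch in the multisite design).  Candidates are
nominated at a nominal group-effect p < 0.005 and the whole tested
family is Benjamini-Hochberg adjusted.  Nominated candidates are
hierarchically clustered (euclidean distance, average linkage) on
per-protein z-scores to expose the colinear blocks that motivate
stability-selection ranking.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .containers import LOG10, ProteinMatrix, align_meta

log = logging.getLogger(__name__)

__all__ = [
    "build_design",
    "fit_protein_lm",
    "run_discovery",
    "nominate_candidates",
    "bh_adjust",
    "cluster_candidates",
    "ClusterResult",
    "linkage_to_newick",
]

#: covariates treated as categorical and expanded to reference-coded indicators
CATEGORICAL_COVARIATES = ("site", "batch")


def build_design(
    meta: pd.DataFrame,
    covariates=("age", "sex", "ledd"),
    group_col: str = "group",
    group_levels: tuple[str, str] = ("NC", "PD"),
) -> pd.DataFrame:
    """Design matrix: intercept, group indicator, then covariate columns.

    Group is coded ``group_levels[1]`` = 1 (PD) versus reference 0 (NC);
    sex is coded female = 1 / male = 0, so coefficient signs read as the
    direction of change in PD and in females.  Categorical covariates
    (site, batch) expand to reference-coded indicator columns.  Samples
    with missing covariate values are dropped with a logged count.
    """
    keep = meta[group_col].isin(group_levels)
    sub = meta.loc[keep]
    cols = {"const": np.ones(len(sub)), "group": (sub[group_col] == group_levels[1]).astype(float)}
    X = pd.DataFrame(cols, index=sub.index)
    for cov in covariates:
        if cov not in sub.columns:
            raise KeyError(f"covariate {cov!r} not in sample metadata")
        if cov == "sex":
            X["sex"] = (sub["sex"] == "F").astype(float)
        elif cov in CATEGORICAL_COVARIATES:
            dummies = pd.get_dummies(sub[cov], prefix=cov, drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
        else:
            X[cov] = pd.to_numeric(sub[cov], errors="coerce")
    n_before = len(X)
    X = X.dropna()
    n_dropped = n_before - len(X)
    if n_dropped:
        log.info("design matrix: dropped %d sample(s) with missing covariates", n_dropped)
    return X


def _check_full_rank(X: np.ndarray, columns) -> None:
    # name the offending columns via the QR diagonal
    r = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    bad = [columns[i] for i in np.flatnonzero(diag <= tol)]
    if bad:
        raise ValueError(f"design matrix is rank deficient; collinear term(s): {bad}")


def _ols_multi(Y: np.ndarray, X: np.ndarray, term_idx: int):
    """OLS of every column of Y on the shared design X.

    Returns (beta, se, t, p, df_resid) for the term at ``term_idx``.
    One factorization serves all responses, which is what makes a
    968-protein family fit in milliseconds.
    """
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more samples ({n}) than design columns ({k})")
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta_all = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta_all
    df = n - k
    sigma2 = (resid**2).sum(axis=0) / df
    scale = np.maximum((Y**2).sum(axis=0), 1.0)
    if np.any(sigma2 <= 1e-12 * scale / df):
        raise ValueError("zero residual variance (response perfectly fit by the design)")
    se = np.sqrt(sigma2 * XtX_inv[term_idx, term_idx])
    beta = beta_all[term_idx]
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, se, t, p, df, beta_all


def fit_protein_lm(y: pd.Series, design: pd.DataFrame, term: str = "group") -> dict:
    """OLS fit of one protein's log10 levels on a design matrix.

    The reported statistic is the coefficient of ``term`` with its
    residual-df t test (two-sided p from the t distribution).
    """
    common = design.index.intersection(y.dropna().index)
    X = design.loc[common].to_numpy(dtype=float)
    yv = y.loc[common].to_numpy(dtype=float)
    _check_full_rank(X, list(design.columns))
    ti = list(design.columns).index(term)
    beta, se, t, p, df, _ = _ols_multi(yv[:, None], X, ti)
    return {
        "beta": float(beta[0]),
        "se": float(se[0]),
        "t": float(t[0]),
        "p": float(p[0]),
        "df": int(df),
        "n_used": len(common),
    }


def run_discovery(
    matrix: ProteinMatrix,
    meta: pd.DataFrame,
    covariates=("age", "sex", "ledd"),
    term: str = "group",
) -> pd.DataFrame:
    """Per-protein association table for the discovery design.

    One OLS row per protein (group coefficient, se, t, two-sided p);
    BH q-values are computed across the whole tested family.  Returns a
    tidy table indexed by protein_id with columns
    beta, se, t, p, q, direction, n_used.
    """
    if matrix.scale != LOG10:
        raise ValueError("discovery models run on log10 levels; transform first")
    meta = align_meta(matrix, meta)
    design = build_design(meta, covariates=covariates)
    Y = matrix.data.loc[design.index].to_numpy(dtype=float)
    X = design.to_numpy(dtype=float)
    _check_full_rank(X, list(design.columns))
    ti = list(design.columns).index(term)
    beta, se, t, p, df, _ = _ols_multi(Y, X, ti)
    out = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "t": t,
            "p": p,
            "q": bh_adjust(p),
            "direction": np.sign(beta).astype(int),
            "n_used": len(design),
        },
        index=matrix.protein_ids.rename("protein_id"),
    )
    return out


def nominate_candidates(table: pd.DataFrame, p_threshold: float = 0.005) -> list[str]:
    """Candidate ids with group-effect p strictly below the threshold.

    Sorted by ascending p, ties broken by protein id for determinism.
    """
    hits = table.loc[table["p"] < p_threshold].reset_index()
    order = hits.sort_values(["p", "protein_id"])
    return order["protein_id"].tolist()


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ClusterResult:
    """Both-axis hierarchical clustering of the candidate panel."""

    protein_linkage: np.ndarray
    sample_linkage: np.ndarray
    protein_order: list[str]
    sample_order: list[str]
    #: per-protein z-scored values, rows/cols in dendrogram leaf order
    scaled: pd.DataFrame


def cluster_candidates(matrix: ProteinMatrix, candidate_ids) -> ClusterResult:
    """Cluster candidate proteins and samples for heatmap display.

    Values are centered and scaled per protein, then both axes are
    agglomeratively clustered with euclidean distance and average
    linkage.  A zero-variance protein cannot be scaled and is rejected.
    """
    candidate_ids = list(candidate_ids)
    if len(candidate_ids) < 2:
        raise ValueError("clustering needs at least 2 candidate proteins")
    missing = [c for c in candidate_ids if c not in matrix.protein_ids]
    if missing:
        raise KeyError(f"candidate id(s) not in matrix: {missing[:5]}")
    sub = matrix.data[candidate_ids]
    sd = sub.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = sd.index[sd == 0].tolist()
        raise ValueError(f"constant protein(s) cannot be scaled: {bad[:5]}")
    z = (sub - sub.mean(axis=0)) / sd
    prot_Z = hierarchy.linkage(z.to_numpy().T, method="average", metric="euclidean")
    samp_Z = hierarchy.linkage(z.to_numpy(), method="average", metric="euclidean")
    prot_order = [candidate_ids[i] for i in hierarchy.leaves_list(prot_Z)]
    samp_order = [z.index[i] for i in hierarchy.leaves_list(samp_Z)]
    return ClusterResult(
        protein_linkage=prot_Z,
        sample_linkage=samp_Z,
        protein_order=prot_order,
        sample_order=samp_order,
        scaled=z.loc[samp_order, prot_order],
    )


def linkage_to_newick(Z: np.ndarray, labels) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)
    labels = list(labels)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
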