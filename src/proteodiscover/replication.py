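"""Multisite replication and disease-specificity analyses.

The replication design mirrors discovery with two prespecified changes:
clinical site and assay batch enter as categorical covariates (the
move from a single-site, single-plate run to a multisite, five-plate
run), and medication dose is dropped (not uniformly available).
Replication of a candidate requires FDR significance in both cohorts
*and* the same direction of effect.  Specificity is probed with a
three-group (NC/PD/ALS) model, and medication confounding with a
rank-sum comparison of never-treated versus treated PD participants.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import LOG10, ProteinMatrix, align_meta
from .discovery import _check_full_rank, _ols_multi, bh_adjust, build_design

__all__ = [
    "run_replication",
    "check_replication",
    "multigroup_specificity",
    "never_treated_comparison",
]


def run_replication(
    matrix: ProteinMatrix,
    meta: pd.DataFrame,
    protein_ids,
    covariates=("age", "sex", "site", "batch"),
) -> pd.DataFrame:
    """Mirror the discovery model for a preselected id list.

    BH correction runs over this k-test family only (the prespecified
    top-k candidates), not the whole panel.  Ids absent from the
    replication panel are reported as untestable rather than failed.
    """
    if matrix.scale != LOG10:
        raise ValueError("replication models run on log10 levels; transform first")
    protein_ids = list(protein_ids)
    testable = [p for p in protein_ids if p in matrix.protein_ids]
    untestable = [p for p in protein_ids if p not in matrix.protein_ids]

    meta = align_meta(matrix, meta)
    meta = meta.loc[meta["group"].isin(("PD", "NC"))]
    design = build_design(meta, covariates=covariates)
    Y = matrix.data.loc[design.index, testable].to_numpy(dtype=float)
    X = design.to_numpy(dtype=float)
    _check_full_rank(X, list(design.columns))
    ti = list(design.columns).index("group")
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
            "testable": True,
        },
        index=pd.Index(testable, name="protein_id"),
    )
    if untestable:
        pad = pd.DataFrame(
            {
                "beta": np.nan, "se": np.nan, "t": np.nan, "p": np.nan,
                "q": np.nan, "direction": 0, "n_used": 0, "testable": False,
            },
            index=pd.Index(untestable, name="protein_id"),
        )
        out = pd.concat([out, pad]).loc[protein_ids]
    return out


def check_replication(
    discovery_rows: pd.DataFrame,
    replication_rows: pd.DataFrame,
    alpha: float = 0.05,
) -> list[str]:
    """Ids replicated across cohorts: q < alpha in both AND same sign.

    Symmetric in its two inputs.
    """
    common = discovery_rows.index.intersection(replication_rows.index)
    d = discovery_rows.loc[common]
    r = replication_rows.loc[common]
    ok = (
        (d["q"] < alpha)
        & (r["q"] < alpha)
        & (np.sign(d["beta"]) == np.sign(r["beta"]))
        & (np.sign(d["beta"]) != 0)
    )
    return sorted(common[ok.fillna(False)])


def multigroup_specificity(
    matrix: ProteinMatrix,
    meta: pd.DataFrame,
    protein_ids,
    covariates=("age", "sex", "site"),
) -> pd.DataFrame:
    """Three-group model separating PD-specific from shared disease effects.

    Disease group (NC reference) enters as a reference-coded factor;
    the PD and ALS coefficients are extracted per protein and BH
    adjustment pools all extracted coefficients into one family.
    """
    if matrix.scale != LOG10:
        raise ValueError("specificity models run on log10 levels")
    protein_ids = [p for p in protein_ids if p in matrix.protein_ids]
    meta = align_meta(matrix, meta)
    present = set(meta["group"].unique())
    missing = {"NC", "PD", "ALS"} - present
    if missing:
        raise ValueError(f"missing disease group level(s): {sorted(missing)}")

    sub = meta.loc[meta["group"].isin(("NC", "PD", "ALS"))]
    X = pd.DataFrame({"const": 1.0}, index=sub.index)
    X["group_PD"] = (sub["group"] == "PD").astype(float)
    X["group_ALS"] = (sub["group"] == "ALS").astype(float)
    for cov in covariates:
        if cov == "sex":
            X["sex"] = (sub["sex"] == "F").astype(float)
        elif cov in ("site", "batch"):
            X = pd.concat(
                [X, pd.get_dummies(sub[cov], prefix=cov, drop_first=True, dtype=float)],
                axis=1,
            )
        else:
            X[cov] = pd.to_numeric(sub[cov], errors="coerce")
    X = X.dropna()
    Y = matrix.data.loc[X.index, protein_ids].to_numpy(dtype=float)
    Xv = X.to_numpy(dtype=float)
    _check_full_rank(Xv, list(X.columns))
    cols = list(X.columns)
    res = {}
    for grp in ("PD", "ALS"):
        ti = cols.index(f"group_{grp}")
        beta, se, t, p, df, _ = _ols_multi(Y, Xv, ti)
        res[grp] = (beta, se, p)
    pooled_p = np.concatenate([res["PD"][2], res["ALS"][2]])
    pooled_q = bh_adjust(pooled_p)
    k = len(protein_ids)
    return pd.DataFrame(
        {
            "beta_pd": res["PD"][0],
            "p_pd": res["PD"][2],
            "q_pd": pooled_q[:k],
            "beta_als": res["ALS"][0],
            "p_als": res["ALS"][2],
            "q_als": pooled_q[k:],
            "n_used": len(X),
        },
        index=pd.Index(protein_ids, name="protein_id"),
    )


def never_treated_comparison(values: pd.Series, treated: pd.Series) -> tuple[float, float]:
    """Rank-sum test of one protein's levels: treated vs never-treated PD.

    Exact two-sided Mann-Whitney p for combined n <= 20 without ties;
    normal approximation with tie correction otherwise.  Returns
    (U statistic, two-sided p).
    """
    treated = treated.loc[values.index].astype(bool)
    x = values[treated].to_numpy(dtype=float)
    y = values[~treated].to_numpy(dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both treated and never-treated subgroups must be nonempty")
    n = len(x) + len(y)
    has_ties = len(np.unique(np.concatenate([x, y]))) < n
    method = "exact" if (n <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))
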