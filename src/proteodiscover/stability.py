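"""Stability-selection ranking of candidate biomarkers.

Candidates are ranked by how often the LASSO assigns them a nonzero
coefficient across many jackknifed iterations, each leaving out 10 % of
samples and 30 % of features ("double jackknife").  Repeated subsampling
plus an L1 selector is what lets a sparse, stable subset emerge from a
colinear candidate panel where a single LASSO fit would pick an
arbitrary representative per correlated block.

The inner solver is coordinate descent on the Gram matrix
(covariance updates), jit-compiled; at ~100 features it solves a full
20-point penalty path in about a millisecond, which is what makes
10^4-10^5 iterations routine.  scikit-learn's ``lasso_path`` serves as
an independent oracle for it in the test suite.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .containers import LOG10, ProteinMatrix

log = logging.getLogger(__name__)

__all__ = [
    "StabilityConfig",
    "jackknife_masks",
    "lasso_select",
    "lasso_path_gram",
    "stability_rank",
    "top_k",
]


@dataclass
class StabilityConfig:
    """Jackknife and penalty-path settings.

    The original analysis ran 100,000 iterations; 10,000 is the default
    here and leaves ranks essentially unchanged (frequencies are
    binomial proportions, so their Monte-Carlo error at 10^4 draws is
    already below 0.005).
    """

    iterations: int = 10_000
    frac_samples_out: float = 0.10
    frac_features_out: float = 0.30
    #: explicit descending penalty grid; None = per-subsample geometric
    #: grid of ``n_lambda`` points from lambda_max down to
    #: ``lambda_min_ratio * lambda_max``
    lambda_grid: np.ndarray | None = None
    n_lambda: int = 20
    #: penalty floor as a fraction of lambda_max; 0.3 keeps the per-
    #: iteration active set sparse (a lower floor lets most in-bag
    #: features enter somewhere on the grid, flattening the ranking)
    lambda_min_ratio: float = 0.3
    decision_rule: str = "any_lambda"   # or "fixed_index"
    fixed_index: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        for name in ("frac_samples_out", "frac_features_out"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1); got {v}")
        if self.lambda_grid is not None:
            g = np.asarray(self.lambda_grid, dtype=float)
            if g.ndim != 1 or len(g) < 1 or np.any(g <= 0):
                raise ValueError("lambda_grid must be a 1-D array of positive penalties")
            if len(g) > 1 and np.any(np.diff(g) >= 0):
                raise ValueError("lambda_grid must be strictly decreasing")
        if self.decision_rule not in ("any_lambda", "fixed_index"):
            raise ValueError(f"unknown decision_rule {self.decision_rule!r}")
        if self.decision_rule == "fixed_index" and self.fixed_index is None:
            raise ValueError("decision_rule 'fixed_index' requires fixed_index")


def jackknife_masks(n_samples: int, n_features: int, config: StabilityConfig):
    """Stream of (sample index array, feature index array) per iteration.

    Each iteration removes ``round(frac * n)`` indices uniformly without
    replacement, independently across iterations; the stream is fully
    reproducible from the config seed.
    """
    config.validate()
    n_s_out = int(round(config.frac_samples_out * n_samples))
    n_f_out = int(round(config.frac_features_out * n_features))
    if n_samples - n_s_out < 1 or n_features - n_f_out < 1:
        raise ValueError("jackknife would leave no samples or no features in-bag")
    rng = np.random.default_rng(config.seed)
    for _ in range(config.iterations):
        s_in = np.sort(rng.choice(n_samples, size=n_samples - n_s_out, replace=False))
        f_in = np.sort(rng.choice(n_features, size=n_features - n_f_out, replace=False))
        yield s_in, f_in


@njit(cache=True)
def _cd_path(G, c, lams, tol, max_iter):
    """Coordinate descent for 0.5*||y - X b||^2 + lam*||b||_1 on the
    Gram representation (G = X'X, c = X'y), warm-started along a
    descending penalty grid.

    Returns (ever_active, abs_coef_sum, converged_all).
    """
    p = G.shape[0]
    beta = np.zeros(p)
    ever = np.zeros(p, np.bool_)
    absum = np.zeros(p)
    ok = True
    for li in range(lams.shape[0]):
        lam = lams[li]
        converged = False
        for _ in range(max_iter):
            maxd = 0.0
            for j in range(p):
                gjj = G[j, j]
                if gjj <= 0.0:
                    continue
                r = c[j] - np.dot(G[j], beta) + gjj * beta[j]
                if r > lam:
                    bn = (r - lam) / gjj
                elif r < -lam:
                    bn = (r + lam) / gjj
                else:
                    bn = 0.0
                d = abs(bn - beta[j])
                if d > maxd:
                    maxd = d
                beta[j] = bn
            if maxd < tol:
                converged = True
                break
        if not converged:
            ok = False
        for j in range(p):
            if beta[j] != 0.0:
                ever[j] = True
                absum[j] += abs(beta[j])
    return ever, absum, ok


def _grid(lam_max: float, config: StabilityConfig) -> np.ndarray:
    if config.lambda_grid is not None:
        return np.asarray(config.lambda_grid, dtype=float)
    if lam_max <= 0:
        return np.array([1.0])
    return np.geomspace(lam_max, config.lambda_min_ratio * lam_max, config.n_lambda)


def lasso_path_gram(X: np.ndarray, y: np.ndarray, lams: np.ndarray,
                    tol: float = 1e-7, max_iter: int = 1000):
    """Selection indicators and mean |coefficient| along a penalty grid.

    ``X`` must have standardized columns and ``y`` must be centered
    (the caller owns standardization so that the penalty acts evenly).
    A non-converged solve is retried once with a larger budget, then the
    (partial) result is used with a logged count.
    """
    G = X.T @ X
    c = X.T @ y
    ever, absum, ok = _cd_path(G, c, lams, tol, max_iter)
    if not ok:
        ever, absum, ok = _cd_path(G, c, lams, tol, 20 * max_iter)
        if not ok:
            log.warning("lasso path did not converge at tol=%g", tol)
    return ever, absum, ok


def lasso_select(
    X: np.ndarray,
    y: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    decision_rule: str = "any_lambda",
    fixed_index: int | None = None,
    n_lambda: int = 20,
    lambda_min_ratio: float = 0.3,
) -> np.ndarray:
    """Feature indices with a nonzero LASSO coefficient under the rule.

    Expects standardized columns and centered ``y``.  With the default
    ``any_lambda`` rule a feature counts as selected if its coefficient
    is nonzero anywhere on the grid, i.e. selection over a penalty
    region rather than at a single tuned penalty.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    lam_max = float(np.abs(X.T @ y).max()) if X.size else 0.0
    cfg = StabilityConfig(
        lambda_grid=lambda_grid, n_lambda=n_lambda,
        lambda_min_ratio=lambda_min_ratio, decision_rule=decision_rule,
        fixed_index=fixed_index,
    )
    cfg.validate()
    lams = _grid(lam_max, cfg)
    if decision_rule == "any_lambda":
        ever, _, _ = lasso_path_gram(X, y, lams)
        return np.flatnonzero(ever)
    # fixed_index: solve down to that grid point and report its support
    G = X.T @ X
    c = X.T @ y
    beta = _solve_single(G, c, lams[: fixed_index + 1])
    return np.flatnonzero(beta != 0.0)


@njit(cache=True)
def _solve_single(G, c, lams):
    p = G.shape[0]
    beta = np.zeros(p)
    for li in range(lams.shape[0]):
        lam = lams[li]
        for _ in range(2000):
            maxd = 0.0
            for j in range(p):
                gjj = G[j, j]
                if gjj <= 0.0:
                    continue
                r = c[j] - np.dot(G[j], beta) + gjj * beta[j]
                if r > lam:
                    bn = (r - lam) / gjj
                elif r < -lam:
                    bn = (r + lam) / gjj
                else:
                    bn = 0.0
                d = abs(bn - beta[j])
                if d > maxd:
                    maxd = d
                beta[j] = bn
            if maxd < 1e-9:
                break
    return beta


def stability_rank(
    matrix: ProteinMatrix,
    labels: pd.Series,
    candidate_ids,
    config: StabilityConfig | None = None,
) -> pd.DataFrame:
    """Selection-frequency ranking of the candidate panel.

    ``labels`` maps sample id to disease group; the group is coded
    numerically (PD = 1, NC = 0) and centered, and a linear LASSO is run
    within each jackknife subsample on columns standardized *within*
    that subsample.  Frequency = selected iterations / iterations the
    protein was in-bag.  Ranks sort by descending frequency with ties
    broken by mean |coefficient| across selected iterations, then id.
    """
    if config is None:
        config = StabilityConfig()
    config.validate()
    if matrix.scale != LOG10:
        raise ValueError("stability ranking runs on log10 levels")
    candidate_ids = list(candidate_ids)
    missing = [c for c in candidate_ids if c not in matrix.protein_ids]
    if missing:
        raise KeyError(f"candidate id(s) not in matrix: {missing[:5]}")
    labels = labels.loc[matrix.sample_ids]
    classes = pd.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 label classes, got {list(classes)}")
    yfull = (labels == "PD").to_numpy(dtype=float) if "PD" in set(classes) \
        else (labels == classes[1]).to_numpy(dtype=float)
    Xfull = np.ascontiguousarray(matrix.data[candidate_ids].to_numpy(dtype=float))
    n, p = Xfull.shape

    eligible = np.zeros(p, dtype=np.int64)
    selected = np.zeros(p, dtype=np.int64)
    abs_coef = np.zeros(p)
    n_nonconv = 0
    for s_in, f_in in jackknife_masks(n, p, config):
        Xs = Xfull[np.ix_(s_in, f_in)]
        ys = yfull[s_in]
        ys = ys - ys.mean()
        mu = Xs.mean(axis=0)
        sd = Xs.std(axis=0)
        ok_col = sd > 0
        Xs = (Xs - mu) / np.where(ok_col, sd, 1.0)
        Xs[:, ~ok_col] = 0.0
        lam_max = float(np.abs(Xs.T @ ys).max())
        lams = _grid(lam_max, config)
        ever, absum, conv = lasso_path_gram(Xs, ys, lams)
        if not conv:
            n_nonconv += 1
        eligible[f_in] += 1
        selected[f_in[ever]] += 1
        abs_coef[f_in] += absum / len(lams)
    if n_nonconv:
        log.warning("%d/%d iterations had a non-converged path", n_nonconv, config.iterations)

    freq = np.where(eligible > 0, selected / np.maximum(eligible, 1), 0.0)
    mean_abs = np.where(selected > 0, abs_coef / np.maximum(selected, 1), 0.0)
    out = pd.DataFrame(
        {
            "frequency": freq,
            "eligible": eligible,
            "selected": selected,
            "mean_abs_coef": mean_abs,
        },
        index=pd.Index(candidate_ids, name="protein_id"),
    )
    order = out.reset_index().sort_values(
        ["frequency", "mean_abs_coef", "protein_id"], ascending=[False, False, True]
    )
    out = out.loc[order["protein_id"]]
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def top_k(ranking: pd.DataFrame, k: int = 10) -> list[str]:
    """The k top-ranked protein ids (rank 1 first)."""
    return ranking.sort_values("rank").index[:k].tolist()
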