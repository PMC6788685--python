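"""Preanalytical and medication-state robustness checks.

A credible plasma biomarker must not move with dopaminergic medication
state or with mundane differences in sample handling.  The medication
check is a per-protein paired t test on log10 levels across matched
on/off-medication draws, backed by an exact sign-flip permutation test
that drops the normality assumption; the handling check is a raw-RFU
percent change between identical reference-pool aliquots with and
without rough handling, flagged at |change| > 30 %.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "onoff_wide",
    "paired_ttest",
    "paired_permutation",
    "handling_percent_change",
]


def onoff_wide(onoff: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pivot a long (subject_id, state, protein_id, rfu) table to two
    aligned subjects x proteins frames (ON, OFF) of log10 levels."""
    required = {"subject_id", "state", "protein_id", "rfu"}
    missing = required - set(onoff.columns)
    if missing:
        raise ValueError(f"on/off table lacks columns: {sorted(missing)}")
    wide = onoff.pivot_table(
        index="subject_id", columns=["state", "protein_id"], values="rfu"
    )
    on = np.log10(wide["ON"])
    off = np.log10(wide["OFF"])
    off = off[on.columns]
    return on, off


def paired_ttest(on: pd.DataFrame, off: pd.DataFrame) -> pd.DataFrame:
    """Classic paired t test per protein on matched log10 levels.

    ``on`` and ``off`` are aligned subjects x proteins frames.  Zero
    within-pair variance leaves t undefined; such proteins are reported
    with p = 1.0 and a ``degenerate`` flag rather than NaN, so a fully
    unaffected protein is counted as unremarkable, not missing.
    """
    if on.shape != off.shape or list(on.columns) != list(off.columns):
        raise ValueError("on/off frames must be aligned (same subjects and proteins)")
    n = len(on)
    if n < 2:
        raise ValueError("paired t test needs at least 2 pairs")
    d = on.to_numpy(dtype=float) - off.to_numpy(dtype=float)
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    t = np.where(degenerate, np.nan, t)
    p = np.where(degenerate, 1.0, p)
    return pd.DataFrame(
        {"mean_diff": mean, "t": t, "df": n - 1, "p": p, "degenerate": degenerate},
        index=on.columns.rename("protein_id"),
    )


def paired_permutation(
    on: pd.DataFrame,
    off: pd.DataFrame,
    max_exact_n: int = 12,
    n_mc: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Sign-flip permutation test of the paired mean difference.

    Statistic: |mean difference|.  For n <= ``max_exact_n`` pairs all
    2^n sign assignments are enumerated (the observed assignment is one
    of them, so p >= 2^-n and p is a multiple of 2^-n); otherwise
    ``n_mc`` random flips are drawn and the add-one convention
    ``p = (1 + #{null >= observed}) / (n_mc + 1)`` guarantees validity.
    """
    if on.shape != off.shape or list(on.columns) != list(off.columns):
        raise ValueError("on/off frames must be aligned (same subjects and proteins)")
    n = len(on)
    if n < 2:
        raise ValueError("paired permutation test needs at least 2 pairs")
    d = on.to_numpy(dtype=float) - off.to_numpy(dtype=float)   # n x P
    obs = np.abs(d.mean(axis=0))
    eps = 1e-12
    if n <= max_exact_n:
        bits = np.arange(2**n, dtype=np.int64)
        signs = np.where(
            (bits[:, None] >> np.arange(n)[None, :]) & 1, 1.0, -1.0
        )  # 2^n x n
        null = np.abs(signs @ d) / n                            # 2^n x P
        p = (null >= obs[None, :] - eps).mean(axis=0)
        exact = True
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_mc, n))
        null = np.abs(signs @ d) / n
        hits = (null >= obs[None, :] - eps).sum(axis=0)
        p = (1.0 + hits) / (n_mc + 1.0)
        exact = False
    return pd.DataFrame(
        {"mean_diff": d.mean(axis=0), "p": p, "exact": exact},
        index=on.columns.rename("protein_id"),
    )


def handling_percent_change(
    baseline_pool: pd.Series,
    perturbed_pool: pd.Series,
    flag_threshold: float = 0.30,
) -> pd.DataFrame:
    """Relative raw-RFU change between matched reference-pool aliquots.

    ``change = (perturbed - baseline) / baseline`` per protein, flagged
    iff |change| strictly exceeds the threshold (default 30 %).
    Computed on raw RFU, not log10.
    """
    baseline_pool = pd.Series(baseline_pool)
    perturbed_pool = pd.Series(perturbed_pool)
    if not baseline_pool.index.equals(perturbed_pool.index):
        common = baseline_pool.index.intersection(perturbed_pool.index)
        if len(common) != len(baseline_pool) or len(common) != len(perturbed_pool):
            raise ValueError("baseline and perturbed pools must cover the same proteins")
        perturbed_pool = perturbed_pool.loc[baseline_pool.index]
    if (baseline_pool <= 0).any():
        raise ValueError("baseline pool must be strictly positive raw RFU")
    change = (perturbed_pool - baseline_pool) / baseline_pool
    return pd.DataFrame(
        {"pct_change": change, "flagged": change.abs() > flag_threshold},
        index=baseline_pool.index.rename("protein_id"),
    )
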