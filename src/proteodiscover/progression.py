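"""Baseline biomarkers and subsequent cognitive course.

Three complementary views of "does the baseline blood level predict
cognitive decline":

* cross-sectional Spearman correlation with the baseline cognitive
  score (typically weak -- the biomarkers are prognostic, not
  concurrent);
* a linear mixed-effects model of longitudinal scores with a
  time-by-protein interaction (score units per year per log10-RFU) and
  a participant random intercept;
* conversion-to-impairment survival: cognitive states per visit
  (consensus diagnosis, or MoCA norms 26-30 normal / 21-25 MCI / <=20
  dementia), first qualifying worsening transition as the event, and a
  Cox proportional-hazards model on baseline-biomarker tertiles
  adjusted for age, sex and disease duration, with an optional
  education sensitivity model compared by likelihood ratio.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "spearman_baseline",
    "fit_lmm",
    "LmmResult",
    "classify_cognitive_state",
    "derive_events",
    "assign_tertiles",
    "fit_cox",
    "CoxResult",
    "compare_cox_education",
]

MOCA_RANGE = (0, 30)
DRS_RANGE = (0, 144)


def spearman_baseline(
    biomarkers: pd.DataFrame, baseline_scores: pd.Series
) -> pd.DataFrame:
    """Spearman rank correlation of each biomarker with the baseline score.

    Average ranks for ties, two-sided p, BH adjustment across the
    biomarker family.  Requires >= 3 complete pairs per biomarker.
    """
    from .discovery import bh_adjust

    rows = []
    for col in biomarkers.columns:
        pair = pd.concat([biomarkers[col], baseline_scores], axis=1).dropna()
        if len(pair) < 3:
            raise ValueError(f"biomarker {col!r}: fewer than 3 complete pairs")
        rho, p = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
        rows.append((col, rho, p, len(pair)))
    out = pd.DataFrame(rows, columns=["biomarker", "rho", "p", "n"]).set_index("biomarker")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


@dataclass
class LmmResult:
    gamma: float          # time x protein interaction, score units / yr / log10-RFU
    se: float
    p: float
    ci_low: float
    ci_high: float
    method: str           # "mixed" or "ols_fallback"
    n_participants: int
    n_obs: int


def fit_lmm(
    records: pd.DataFrame,
    baseline_protein: pd.Series,
    covariates: pd.DataFrame,
    include_education: bool = False,
    reml: bool = True,
) -> LmmResult:
    """Mixed-effects model of cognitive score trajectories.

    ``score ~ age + sex + disease_duration + baseline_score + time +
    time:protein`` with a participant random intercept, fitted by REML
    (default).  ``records`` is long (participant_id, visit_time_yr,
    score); ``baseline_protein`` maps participant to the baseline log10
    biomarker level; ``covariates`` carries age, sex, disease_duration
    (and education when requested) per participant.  The time main
    effect accompanies the interaction so the interaction is
    interpretable.  A singular random-effects fit falls back to the
    fixed-effects model with a logged warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = records.copy()
    df["protein"] = df["participant_id"].map(baseline_protein)
    first_visit = df.groupby("participant_id")["visit_time_yr"].transform("min")
    base = (
        df.sort_values("visit_time_yr")
        .groupby("participant_id")["score"]
        .first()
        .rename("baseline_score")
    )
    # the baseline score is a covariate, so the baseline visit leaves the
    # response (keeping it would put its noise on both sides of the model)
    df = df.loc[df["visit_time_yr"] > first_visit]
    df = df.join(base, on="participant_id")
    cov = covariates.copy()
    if "sex" in cov.columns and cov["sex"].dtype == object:
        cov["sex"] = (cov["sex"] == "F").astype(float)
    df = df.join(cov, on="participant_id")
    df["time"] = df["visit_time_yr"]
    df["time_protein"] = df["time"] * df["protein"]

    fixed = ["age", "sex", "disease_duration", "baseline_score", "time", "time_protein"]
    if include_education:
        fixed.append("education")
    df = df.dropna(subset=fixed + ["score"])
    formula = "score ~ " + " + ".join(fixed)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["participant_id"])
        try:
            fit = model.fit(reml=reml)
            singular = (
                not np.isfinite(fit.bse_fe.get("time_protein", np.nan))
                or np.isnan(fit.pvalues.get("time_protein", np.nan))
            )
        except Exception:   # pragma: no cover - rare solver failure
            fit, singular = None, True

    if fit is not None and not singular:
        gamma = float(fit.fe_params["time_protein"])
        se = float(fit.bse_fe["time_protein"])
        p = float(fit.pvalues["time_protein"])
        method = "mixed"
    else:
        log.warning("singular mixed-effects fit; falling back to fixed-effects OLS")
        ols = smf.ols(formula, df).fit()
        gamma = float(ols.params["time_protein"])
        se = float(ols.bse["time_protein"])
        p = float(ols.pvalues["time_protein"])
        method = "ols_fallback"
    z = stats.norm.ppf(0.975)
    return LmmResult(
        gamma=gamma,
        se=se,
        p=p,
        ci_low=gamma - z * se,
        ci_high=gamma + z * se,
        method=method,
        n_participants=df["participant_id"].nunique(),
        n_obs=len(df),
    )


def classify_cognitive_state(score: float, scale: str = "MoCA") -> str:
    """Cognitive state from a screening score.

    MoCA norms: 26-30 normal, 21-25 MCI, 20 or less dementia.  DRS
    states come from consensus diagnosis and are supplied externally,
    never computed here.
    """
    if scale == "DRS":
        raise ValueError("DRS cognitive states are supplied externally, not derived")
    if scale != "MoCA":
        raise ValueError(f"unknown scale {scale!r}")
    if not (MOCA_RANGE[0] <= score <= MOCA_RANGE[1]):
        raise ValueError(f"MoCA score {score} outside {MOCA_RANGE}")
    if score >= 26:
        return "normal"
    if score >= 21:
        return "MCI"
    return "dementia"


_SEVERITY = {"normal": 0, "MCI": 1, "dementia": 2}


def derive_events(states: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Time-to-conversion events from per-visit cognitive states.

    ``states`` is long (participant_id, visit_time_yr, state) with
    state in {normal, MCI, dementia}.  Participants with dementia at
    baseline, or with any normal state following a baseline MCI, are
    excluded.  An event is the first worsening transition (normal->MCI,
    normal->dementia, MCI->dementia) and its time is that visit's time;
    otherwise the participant is censored at the last visit.

    Returns (records, exclusions): records has columns time, event
    indexed by participant_id; exclusions has columns participant_id,
    reason.
    """
    required = {"participant_id", "visit_time_yr", "state"}
    missing = required - set(states.columns)
    if missing:
        raise ValueError(f"state table lacks columns: {sorted(missing)}")
    bad = set(states["state"].unique()) - set(_SEVERITY)
    if bad:
        raise ValueError(f"unknown cognitive state(s): {sorted(bad)}")
    rows, excl = [], []
    for pid, g in states.sort_values("visit_time_yr").groupby("participant_id", sort=True):
        seq = g["state"].tolist()
        times = g["visit_time_yr"].to_numpy(dtype=float)
        baseline = seq[0]
        if baseline == "dementia":
            excl.append((pid, "dementia_at_baseline"))
            continue
        if baseline == "MCI" and any(s == "normal" for s in seq[1:]):
            excl.append((pid, "reversion_to_normal"))
            continue
        event_time = None
        for prev, cur, t_cur in zip(seq[:-1], seq[1:], times[1:]):
            if _SEVERITY[cur] > _SEVERITY[prev]:
                event_time = t_cur
                break
        if event_time is not None:
            rows.append((pid, float(event_time), True))
        else:
            rows.append((pid, float(times[-1]), False))
    records = pd.DataFrame(rows, columns=["participant_id", "time", "event"]).set_index(
        "participant_id"
    )
    exclusions = pd.DataFrame(excl, columns=["participant_id", "reason"])
    return records, exclusions


def assign_tertiles(values: pd.Series) -> pd.Series:
    """Low / medium / high labels from the 1/3 and 2/3 sample quantiles.

    Linear-interpolation quantiles; ties at a cut go to the lower
    tertile.  Degenerate cuts (all values equal, or a cut collapse from
    heavy ties) are rejected.
    """
    values = pd.Series(values).astype(float)
    if len(values) < 3:
        raise ValueError("tertile assignment needs at least 3 values")
    q1, q2 = np.quantile(values.to_numpy(), [1 / 3, 2 / 3])
    if q1 == q2:
        raise ValueError("degenerate tertile cuts (1/3 and 2/3 quantiles coincide)")
    labels = np.where(values <= q1, "low", np.where(values <= q2, "medium", "high"))
    return pd.Series(pd.Categorical(labels, categories=["low", "medium", "high"]),
                     index=values.index, name="tertile")


@dataclass
class CoxResult:
    """Hazard ratios with Wald 95% CIs per model term."""

    table: pd.DataFrame       # HR, ci_low, ci_high, p per term
    log_likelihood: float
    n: int
    n_events: int

    def hr(self, term: str) -> float:
        return float(self.table.loc[term, "HR"])


def _encode_survival(records: pd.DataFrame, include_education: bool,
                     tertile_ref: str, contrast: str, covariates) -> pd.DataFrame:
    df = records.copy()
    if ((df["time"] <= 0) & df["event"]).any():
        raise ValueError("event with nonpositive time")
    if "sex" in df.columns and df["sex"].dtype == object:
        df["sex"] = (df["sex"] == "F").astype(float)
    cols = {"time": df["time"], "event": df["event"].astype(int)}
    for cov in covariates:
        cols[cov] = df[cov]
    if include_education:
        cols["education"] = df["education"]
    if contrast == "low_vs_rest":
        cols["tertile_low"] = (df["tertile"] == "low").astype(float)
    else:
        for level in ("low", "medium", "high"):
            if level != tertile_ref:
                cols[f"tertile_{level}"] = (df["tertile"] == level).astype(float)
    return pd.DataFrame(cols, index=df.index).dropna()


def fit_cox(
    records: pd.DataFrame,
    include_education: bool = False,
    tertile_ref: str = "high",
    contrast: str = "categorical",
    covariates=("age", "sex", "disease_duration"),
) -> CoxResult:
    """Cox proportional-hazards model of conversion risk.

    Partial likelihood with Efron tie handling; the biomarker tertile
    enters as a categorical term (reference = highest tertile by
    default, so the headline HR reads lowest-versus-highest), or as a
    single lowest-versus-rest indicator with ``contrast='low_vs_rest'``.
    Adjusts for age, sex and disease duration, plus years of education
    on request.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    if contrast not in ("categorical", "low_vs_rest"):
        raise ValueError(f"unknown contrast {contrast!r}")
    df = _encode_survival(records, include_education, tertile_ref, contrast, covariates)
    if df["event"].sum() < 1:
        raise ValueError("Cox model needs at least one event")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as err:
        raise ValueError(
            f"Cox partial likelihood failed to converge (possible complete "
            f"separation / monotone likelihood): {err}"
        ) from err
    table = pd.DataFrame(
        {
            "HR": np.exp(cph.params_),
            "ci_low": np.exp(cph.confidence_intervals_.iloc[:, 0]),
            "ci_high": np.exp(cph.confidence_intervals_.iloc[:, 1]),
            "p": cph.summary["p"],
            "coef": cph.params_,
            "se": cph.standard_errors_,
        }
    )
    return CoxResult(
        table=table,
        log_likelihood=float(cph.log_likelihood_),
        n=len(df),
        n_events=int(df["event"].sum()),
    )


def compare_cox_education(records: pd.DataFrame, **kw) -> tuple[float, int, float]:
    """Likelihood-ratio comparison of the Cox model with vs without education.

    Returns (chi2, df, p).  Mirrors the standard nested-model ANOVA for
    proportional-hazards fits.
    """
    m1 = fit_cox(records, include_education=False, **kw)
    m2 = fit_cox(records, include_education=True, **kw)
    chi2 = 2.0 * (m2.log_likelihood - m1.log_likelihood)
    df = len(m2.table) - len(m1.table)
    p = float(stats.chi2.sf(max(chi2, 0.0), df))
    return float(chi2), int(df), p
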