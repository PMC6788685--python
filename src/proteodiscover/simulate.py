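"""Synthetic multicohort plasma-proteomics generator.

Emulates the statistical structure the downstream pipeline assumes:
log-normal raw RFUs, additive group / age / sex effects on the log10
scale, multiplicative site and batch shifts, block-correlated proteins,
limit-of-detection censoring pressure, QC triplicates with controlled
coefficients of variation, paired on/off-medication samples, and
longitudinal cognitive trajectories whose slopes depend on the baseline
level of a designated biomarker.

Every draw flows from a single configured seed; each generator stage
uses an independent child stream so stages can be re-run reproducibly
(see :func:`stage_rng`).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ProteinMatrix, RAW, validate_sample_meta
from .progression import assign_tertiles

__all__ = [
    "SimConfig",
    "GroundTruth",
    "stage_rng",
    "generate_cohort",
    "generate_qc_triplicates",
    "generate_longitudinal",
    "generate_paired_onoff",
    "generate_conversion_times",
    "generate_handling_pools",
]

#: fixed spawn keys of the per-stage child random streams
STAGE_KEYS = {
    "cohort": 0,
    "qc_triplicates": 1,
    "longitudinal": 2,
    "paired_onoff": 3,
    "conversion": 4,
    "handling": 5,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Child random generator for a named pipeline stage.

    Children are spawned from ``SeedSequence(seed, spawn_key=(k,))``
    with a fixed per-stage key, so re-running one stage reproduces its
    stream regardless of what other stages were run.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(STAGE_KEYS[stage],)))


@dataclass
class SimConfig:
    """Generator configuration; defaults emulate the discovery cohort.

    Group sizes, demographics, panel size and the fraction of proteins
    failing each QC rule follow the published cohort composition; the
    planted group effect sizes are a testability choice (the study does
    not report effects on the RFU scale).
    """

    n_pd: int = 96
    n_nc: int = 45
    n_proteins: int = 1129
    n_planted: int = 20
    #: planted PD-vs-NC effect on the log10-RFU scale (alternating sign)
    delta: float = 0.1
    age_slope: float = 0.002     # log10-RFU per year
    sex_offset: float = 0.02     # log10-RFU, female vs male
    n_sites: int = 1
    site_sd: float = 0.05        # SD of per-(site, protein) log10 shifts
    n_batches: int = 1
    batch_sd: float = 0.05
    block_size: int = 10         # proteins per correlated block
    block_rho: float = 0.5       # within-block correlation
    noise_sd: float = 0.15       # residual log10-RFU SD
    llod: float = 200.0          # raw RFU
    ulod: float = 63000.0
    #: fraction of proteins designed to exceed the >25 %-outside-LOD rule
    censor_frac_target: float = 125 / 1129
    seed: int = 0

    # QC-triplicate controls
    n_high_cv: int = 36
    qc_cv_high: float = 0.5
    qc_cv_low: float = 0.05

    # medication substudy controls
    n_medication_effects: int = 2
    medication_effect: float = 0.05   # log10 units added in the ON state
    pair_noise_sd: float = 0.01

    #: fraction of PD participants never treated with dopaminergic drugs
    never_treated_frac: float = 0.08

    # planted longitudinal / survival effects recorded in GroundTruth
    lmm_gamma: float = 0.09      # score units / year / log10-RFU
    cox_loghr: float = float(np.log(2.27))  # lowest vs highest tertile

    def validate(self) -> None:
        for name in ("n_pd", "n_nc", "n_proteins", "n_sites", "n_batches", "block_size"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.n_pd + self.n_nc < 1:
            raise ValueError("n_pd + n_nc must be at least 1")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be at least 1")
        if self.n_planted < 0 or self.n_planted > self.n_proteins:
            raise ValueError(
                f"n_planted must lie in [0, n_proteins]; got n_planted={self.n_planted}, "
                f"n_proteins={self.n_proteins}"
            )
        if not (0.0 <= self.block_rho < 1.0):
            raise ValueError(f"block_rho must lie in [0, 1); got {self.block_rho}")
        for name in ("delta", "age_slope", "sex_offset", "site_sd", "batch_sd", "noise_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not self.llod < self.ulod:
            raise ValueError(f"llod must be < ulod; got llod={self.llod}, ulod={self.ulod}")
        if not (0.0 <= self.censor_frac_target <= 1.0):
            raise ValueError("censor_frac_target must lie in [0, 1]")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """What was planted, so tests can score recovery without peeking."""

    planted_protein_ids: list[str]
    delta_per_protein: pd.Series          # signed log10 effect, all proteins
    lmm_gamma: float
    cox_loghr: float
    medication_effect_ids: list[str] = field(default_factory=list)
    cv_flagged_ids: list[str] = field(default_factory=list)
    lod_censored_ids: list[str] = field(default_factory=list)
    seed: int = 0


def _protein_ids(n: int) -> pd.Index:
    return pd.Index([f"prot_{i:04d}" for i in range(1, n + 1)], name="protein_id")


def _sample_ids(n: int, prefix: str = "s") -> pd.Index:
    return pd.Index([f"{prefix}{i:04d}" for i in range(1, n + 1)], name="sample_id")


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(
    config: SimConfig,
    truth: GroundTruth | None = None,
    sample_prefix: str = "s",
) -> tuple[ProteinMatrix, pd.DataFrame, GroundTruth]:
    """Generate a raw-RFU cohort with known planted structure.

    Raw RFU are ``10 ** (baseline_j + delta_j * 1[PD] + age_slope * (age - mean age)
    + sex_offset * 1[female] + site_shift + batch_shift + correlated noise)``.
    Ages and sexes are drawn identically for PD and NC, so the two
    groups match in expectation and the only systematic group signal is
    the planted one.

    Passing an existing ``truth`` reuses its planted proteins and signed
    effects (for proteins present), emulating an independent replication
    cohort that shares the biology of the discovery cohort.
    """
    config.validate()
    rng = stage_rng(config.seed, "cohort")
    n = config.n_pd + config.n_nc
    proteins = _protein_ids(config.n_proteins)
    samples = _sample_ids(n, prefix=sample_prefix)

    is_pd = np.zeros(n, dtype=bool)
    is_pd[: config.n_pd] = True

    age = _truncnorm(rng, 70.0, 8.0, 45.0, 95.0, n)
    female = rng.random(n) < 0.5
    site = rng.integers(config.n_sites, size=n)
    batch = rng.integers(config.n_batches, size=n)

    # planted group effects, alternating sign
    if truth is None:
        planted_idx = rng.choice(config.n_proteins, size=config.n_planted, replace=False)
        planted_idx.sort()
        delta = np.zeros(config.n_proteins)
        signs = np.where(np.arange(config.n_planted) % 2 == 0, 1.0, -1.0)
        delta[planted_idx] = signs * config.delta
        planted_ids = proteins[planted_idx].tolist()
    else:
        delta = (
            truth.delta_per_protein.reindex(proteins)
            .fillna(0.0)
            .to_numpy()
        )
        planted_idx = np.flatnonzero(delta != 0.0)
        planted_ids = proteins[planted_idx].tolist()

    # baselines and designed LOD-censoring pressure
    baseline = rng.uniform(2.5, 4.5, size=config.n_proteins)
    n_censor = int(round(config.censor_frac_target * config.n_proteins))
    eligible = np.setdiff1d(np.arange(config.n_proteins), planted_idx)
    n_censor = min(n_censor, eligible.size)
    censor_idx = rng.choice(eligible, size=n_censor, replace=False)
    # sit the baseline just above the lower detection limit so ~35 % of
    # measurements fall below it -- safely past the 25 % exclusion rule
    baseline[censor_idx] = np.log10(config.llod) + 0.385 * config.noise_sd

    site_shift = rng.normal(0.0, config.site_sd, size=(config.n_sites, config.n_proteins))
    batch_shift = rng.normal(0.0, config.batch_sd, size=(config.n_batches, config.n_proteins))
    if config.n_sites == 1:
        site_shift[:] = 0.0
    if config.n_batches == 1:
        batch_shift[:] = 0.0

    # block-correlated residuals: shared latent factor per (sample, block)
    n_blocks = int(np.ceil(config.n_proteins / config.block_size))
    block_of = np.repeat(np.arange(n_blocks), config.block_size)[: config.n_proteins]
    factor = rng.standard_normal((n, n_blocks))
    idio = rng.standard_normal((n, config.n_proteins))
    rho = config.block_rho
    noise = config.noise_sd * (np.sqrt(rho) * factor[:, block_of] + np.sqrt(1.0 - rho) * idio)

    log10_vals = (
        baseline[None, :]
        + delta[None, :] * is_pd[:, None]
        + config.age_slope * (age - age.mean())[:, None]
        + config.sex_offset * female[:, None].astype(float)
        + site_shift[site, :]
        + batch_shift[batch, :]
        + noise
    )
    data = pd.DataFrame(10.0 ** log10_vals, index=samples, columns=proteins)
    limits = pd.DataFrame(
        {"llod": config.llod, "ulod": config.ulod}, index=proteins
    )
    matrix = ProteinMatrix(data, scale=RAW, limits=limits)

    treated = np.where(
        is_pd, rng.random(n) >= config.never_treated_frac, False
    )
    ledd = np.where(treated, rng.gamma(6.0, 100.0, size=n), 0.0)
    disease_duration = np.where(is_pd, rng.gamma(2.5, 2.5, size=n), 0.0)
    education = np.clip(rng.normal(15.0, 2.5, size=n), 8.0, 22.0)

    meta = pd.DataFrame(
        {
            "group": np.where(is_pd, "PD", "NC"),
            "age": age,
            "sex": np.where(female, "F", "M"),
            "site": [f"site{k + 1}" for k in site],
            "batch": [f"batch{k + 1}" for k in batch],
            "ledd": ledd,
            "treated": treated,
            "disease_duration": disease_duration,
            "education": education,
        },
        index=samples,
    )
    validate_sample_meta(meta)

    out_truth = GroundTruth(
        planted_protein_ids=planted_ids,
        delta_per_protein=pd.Series(delta, index=proteins, name="delta"),
        lmm_gamma=config.lmm_gamma,
        cox_loghr=config.cox_loghr,
        medication_effect_ids=[] if truth is None else list(truth.medication_effect_ids),
        cv_flagged_ids=[],
        lod_censored_ids=proteins[censor_idx].tolist(),
        seed=config.seed,
    )
    return matrix, meta, out_truth


def generate_qc_triplicates(config: SimConfig, n_pools: int = 3) -> pd.DataFrame:
    """Reference-pool QC runs: ``n_pools`` pools, each in triplicate.

    Replicates are log-normal around a pool-specific mean with a true
    coefficient of variation of ``qc_cv_low``, except for ``n_high_cv``
    designated proteins generated at ``qc_cv_high`` (noisy aptamers the
    CV filter should catch).  Returns a tidy table with columns
    ``pool, replicate, protein_id, rfu``.
    """
    config.validate()
    if n_pools < 1:
        raise ValueError(f"n_pools must be >= 1, got {n_pools}")
    rng = stage_rng(config.seed, "qc_triplicates")
    proteins = _protein_ids(config.n_proteins)
    n_high = min(config.n_high_cv, config.n_proteins)
    high_idx = rng.choice(config.n_proteins, size=n_high, replace=False)
    cv = np.full(config.n_proteins, config.qc_cv_low)
    cv[high_idx] = config.qc_cv_high
    # lognormal sigma giving exactly the target population CV
    sigma = np.sqrt(np.log1p(cv**2))

    rows = []
    for pool in range(1, n_pools + 1):
        pool_mean = 10.0 ** rng.uniform(2.5, 4.5, size=config.n_proteins)
        z = rng.standard_normal((3, config.n_proteins))
        vals = pool_mean[None, :] * np.exp(sigma[None, :] * z - 0.5 * sigma[None, :] ** 2)
        for rep in range(1, 4):
            rows.append(
                pd.DataFrame(
                    {
                        "pool": f"pool{pool}",
                        "replicate": rep,
                        "protein_id": proteins,
                        "rfu": vals[rep - 1],
                    }
                )
            )
    out = pd.concat(rows, ignore_index=True)
    out.attrs["high_cv_ids"] = proteins[np.sort(high_idx)].tolist()
    return out


def generate_longitudinal(
    matrix: ProteinMatrix,
    meta: pd.DataFrame,
    truth: GroundTruth,
    n_visits: int = 4,
    visit_gap_yr: float = 1.0,
    protein_id: str | None = None,
    base_slope: float = -1.0,
    baseline_score: float = 137.0,
    intercept_sd: float = 5.0,
    resid_sd: float = 2.0,
    scale: str = "DRS",
) -> pd.DataFrame:
    """Longitudinal cognitive scores for the PD participants.

    ``score_it = (baseline_score + b_i) + (base_slope + gamma * x_i) * t + e_it``
    with a participant-level random intercept ``b_i`` and ``x_i`` the
    participant's baseline log10 level of the designated protein, so
    higher protein levels slow (gamma > 0) or accelerate (gamma < 0)
    decline.  Returns a long table (participant_id, visit_time_yr,
    scale, score).
    """
    if n_visits < 2:
        raise ValueError(f"n_visits must be >= 2, got {n_visits}")
    rng = stage_rng(truth.seed, "longitudinal")
    if protein_id is None:
        if not truth.planted_protein_ids:
            raise ValueError("no planted proteins; pass protein_id explicitly")
        protein_id = truth.planted_protein_ids[0]
    pd_ids = meta.index[meta["group"] == "PD"]
    x = np.log10(matrix.data.loc[pd_ids, protein_id].to_numpy()) \
        if matrix.scale == RAW else matrix.data.loc[pd_ids, protein_id].to_numpy()

    b = rng.normal(0.0, intercept_sd, size=len(pd_ids))
    t = np.arange(n_visits) * visit_gap_yr
    slope = base_slope + truth.lmm_gamma * x
    e = rng.normal(0.0, resid_sd, size=(len(pd_ids), n_visits))
    scores = (baseline_score + b)[:, None] + slope[:, None] * t[None, :] + e
    out = pd.DataFrame(
        {
            "participant_id": np.repeat(pd_ids, n_visits),
            "visit_time_yr": np.tile(t, len(pd_ids)),
            "scale": scale,
            "score": scores.ravel(),
        }
    )
    out.attrs["protein_id"] = protein_id
    return out


def generate_paired_onoff(
    config: SimConfig, n_subjects: int = 10
) -> tuple[pd.DataFrame, list[str]]:
    """Paired on/off-medication samples sharing subject baselines.

    The ON state adds ``config.medication_effect`` log10 units to
    ``config.n_medication_effects`` designated proteins; all other
    proteins differ only by measurement noise.  Returns a long table
    (subject_id, state, protein_id, rfu) plus the affected protein ids.
    """
    config.validate()
    if n_subjects < 2:
        raise ValueError(f"n_subjects must be >= 2, got {n_subjects}")
    rng = stage_rng(config.seed, "paired_onoff")
    proteins = _protein_ids(config.n_proteins)
    n_eff = min(config.n_medication_effects, config.n_proteins)
    eff_idx = np.sort(rng.choice(config.n_proteins, size=n_eff, replace=False))
    effect = np.zeros(config.n_proteins)
    effect[eff_idx] = config.medication_effect

    baseline = rng.uniform(2.5, 4.5, size=config.n_proteins)
    subj = baseline[None, :] + rng.normal(0.0, 0.1, size=(n_subjects, config.n_proteins))
    off = subj + rng.normal(0.0, config.pair_noise_sd, size=subj.shape)
    on = subj + effect[None, :] + rng.normal(0.0, config.pair_noise_sd, size=subj.shape)

    subjects = [f"subj{i:02d}" for i in range(1, n_subjects + 1)]
    frames = []
    for state, vals in (("ON", on), ("OFF", off)):
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(subjects, config.n_proteins),
                    "state": state,
                    "protein_id": np.tile(proteins, n_subjects),
                    "rfu": (10.0 ** vals).ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True), proteins[eff_idx].tolist()


def generate_conversion_times(
    matrix: ProteinMatrix,
    meta: pd.DataFrame,
    truth: GroundTruth,
    protein_id: str | None = None,
    followup_yr: float = 5.0,
    baseline_hazard: float = 0.13,
    age_coef: float = 0.0,
    sex_coef: float = 0.0,
) -> pd.DataFrame:
    """Exponential conversion times stratified by baseline biomarker tertile.

    Hazard for PD participant *i* is ``baseline_hazard * exp(cox_loghr *
    1[lowest tertile] + age_coef * (age - mean) + sex_coef * 1[female])``
    with administrative censoring at ``followup_yr``.  Returns survival
    records (participant_id, time, event, tertile + covariates).
    """
    rng = stage_rng(truth.seed, "conversion")
    if protein_id is None:
        if not truth.planted_protein_ids:
            raise ValueError("no planted proteins; pass protein_id explicitly")
        protein_id = truth.planted_protein_ids[0]
    if protein_id not in matrix.protein_ids:
        raise ValueError(f"tertile-defining protein {protein_id!r} not in matrix")
    pd_ids = meta.index[meta["group"] == "PD"]
    x = matrix.data.loc[pd_ids, protein_id]
    if matrix.scale == RAW:
        x = np.log10(x)
    tertile = assign_tertiles(x)

    sub = meta.loc[pd_ids]
    loglin = (
        truth.cox_loghr * (tertile == "low").astype(float).to_numpy()
        + age_coef * (sub["age"].to_numpy() - sub["age"].mean())
        + sex_coef * (sub["sex"] == "F").to_numpy().astype(float)
    )
    hazard = baseline_hazard * np.exp(loglin)
    t_event = rng.exponential(1.0 / hazard)
    event = t_event <= followup_yr
    time = np.minimum(t_event, followup_yr)
    if followup_yr == 0:
        event[:] = False
        time[:] = 0.0
    return pd.DataFrame(
        {
            "participant_id": pd_ids,
            "time": time,
            "event": event,
            "tertile": tertile.to_numpy(),
            "age": sub["age"].to_numpy(),
            "sex": sub["sex"].to_numpy(),
            "disease_duration": sub["disease_duration"].to_numpy(),
            "education": sub["education"].to_numpy(),
        }
    ).set_index("participant_id")


def generate_handling_pools(
    config: SimConfig,
    n_perturbed: int = 30,
    perturb_change: float = 0.5,
) -> tuple[pd.Series, pd.Series, list[str]]:
    """Two aliquots of one reference pool, one subjected to rough handling.

    ``n_perturbed`` designated proteins change by ``±perturb_change``
    (relative, on raw RFU) in the perturbed aliquot; all others are
    identical.  Returns (baseline, perturbed, perturbed protein ids).
    """
    config.validate()
    rng = stage_rng(config.seed, "handling")
    proteins = _protein_ids(config.n_proteins)
    base = pd.Series(10.0 ** rng.uniform(2.5, 4.5, size=config.n_proteins), index=proteins)
    n_pert = min(n_perturbed, config.n_proteins)
    pert_idx = np.sort(rng.choice(config.n_proteins, size=n_pert, replace=False))
    mult = np.ones(config.n_proteins)
    signs = np.where(rng.random(n_pert) < 0.5, 1.0, -1.0)
    mult[pert_idx] = 1.0 + signs * perturb_change
    perturbed = base * mult
    return base, perturbed, proteins[pert_idx].tolist()
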