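"""Published demographic summaries of the study cohorts.

These per-group summary statistics (group sizes, mean age, sex split,
site and plate composition) are the conditions the synthetic-data
generator emulates, and the basis for recomputing pooled cohort-level
demographics.  All ages are years at plasma sampling.
"""
from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GroupSummary:
    n: int
    age_mean: float
    age_sd: float
    n_female: int


@dataclass(frozen=True)
class CohortSummary:
    name: str
    groups: dict[str, GroupSummary]
    n_proteins_assayed: int
    n_proteins_retained: int

    def size(self, groups: tuple[str, ...] = ("PD", "NC")) -> int:
        """Total participants across the listed disease groups."""
        return sum(self.groups[g].n for g in groups)

    def pooled_age_mean(self, groups: tuple[str, ...] = ("PD", "NC")) -> float:
        """Sample-size-weighted mean age across the listed groups."""
        n = self.size(groups)
        return sum(self.groups[g].n * self.groups[g].age_mean for g in groups) / n

    def female_fraction(self, groups: tuple[str, ...] = ("PD", "NC")) -> float:
        return sum(self.groups[g].n_female for g in groups) / self.size(groups)


#: Single-site discovery cohort: 1,129-plex aptamer panel, 968 proteins
#: retained after CV and limit-of-detection filters.
DISCOVERY = CohortSummary(
    name="discovery",
    groups={
        "PD": GroupSummary(n=96, age_mean=69.9, age_sd=7.52, n_female=42),
        "NC": GroupSummary(n=45, age_mean=70.2, age_sd=10.04, n_female=22),
    },
    n_proteins_assayed=1129,
    n_proteins_retained=968,
)

#: Multisite replication cohort: 1,305-plex panel, 33 proteins removed by
#: the CV filter (no detection limits available for this panel version).
REPLICATION = CohortSummary(
    name="replication",
    groups={
        "PD": GroupSummary(n=215, age_mean=66.8, age_sd=8.6, n_female=101),
        "NC": GroupSummary(n=102, age_mean=66.1, age_sd=10.5, n_female=51),
        "ALS": GroupSummary(n=59, age_mean=61.9, age_sd=10.5, n_female=26),
    },
    n_proteins_assayed=1305,
    n_proteins_retained=1272,
)

#: Replication-cohort site composition (PD, NC) per clinical site.
REPLICATION_SITES = {
    "PennState": {"PD": 100, "NC": 78},
    "UTSW": {"PD": 115, "NC": 24},
}

#: Replication-cohort assay plate composition (PD, NC) per batch.
REPLICATION_BATCHES = {
    "plate1": {"PD": 49, "NC": 21},
    "plate2": {"PD": 49, "NC": 20},
    "plate3": {"PD": 48, "NC": 24},
    "plate4": {"PD": 48, "NC": 24},
    "plate5": {"PD": 21, "NC": 13},
}

#: Paired on/off-medication substudy: 10 PD participants (5 F / 5 M)
#: sampled on dopaminergic medication and after overnight washout.
ONOFF_N_SUBJECTS = 10

#: Discovery-cohort proteins excluded by each QC filter.
DISCOVERY_CV_EXCLUDED = 36
DISCOVERY_LOD_EXCLUDED = 125
REPLICATION_CV_EXCLUDED = 33
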