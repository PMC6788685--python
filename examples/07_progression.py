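"""Baseline biomarker level and subsequent cognitive decline.

A linear mixed-effects model estimates the time-by-protein interaction
(score units per year per log10-RFU); cognitive states derived per
visit feed a tertile-stratified Cox model of conversion to MCI or
dementia.
"""
import numpy as np

from proteodiscover.progression import compare_cox_education, fit_cox, fit_lmm
from proteodiscover.simulate import (
    SimConfig,
    generate_cohort,
    generate_conversion_times,
    generate_longitudinal,
)

cfg = SimConfig(n_pd=300, n_nc=0, n_proteins=50, n_planted=2,
                censor_frac_target=0.0, lmm_gamma=0.5, seed=8)
matrix, meta, truth = generate_cohort(cfg)
biomarker = truth.planted_protein_ids[0]

longi = generate_longitudinal(matrix, meta, truth, n_visits=5, protein_id=biomarker)
x = np.log10(matrix.data.loc[meta.group == "PD", biomarker])
cov = meta.loc[meta.group == "PD", ["age", "sex", "disease_duration", "education"]]
lmm = fit_lmm(longi, x, cov)
print(f"time-by-protein interaction: {lmm.gamma:+.3f} "
      f"(95% CI {lmm.ci_low:+.3f} to {lmm.ci_high:+.3f}; planted {truth.lmm_gamma})")
print("-> a positive interaction means higher baseline levels slow decline.")

surv = generate_conversion_times(matrix, meta, truth, protein_id=biomarker)
cox = fit_cox(surv)
hr = cox.table.loc["tertile_low"]
print(f"\nCox conversion model ({cox.n_events} events / {cox.n} participants):")
print(f"lowest vs highest tertile HR {hr['HR']:.2f} "
      f"(95% CI {hr['ci_low']:.2f}-{hr['ci_high']:.2f}, p={hr['p']:.3g}; "
      f"planted {np.exp(truth.cox_loghr):.2f})")
chi2, df, p = compare_cox_education(surv)
print(f"adding education: LRT chi2={chi2:.2f} (df={df}, p={p:.2f}) "
      "-> education does not change the hazard picture.")
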