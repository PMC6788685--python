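"""Rank candidate biomarkers by LASSO selection frequency.

Across thousands of jackknifed iterations (10% of samples and 30% of
features left out), each in-bag candidate either receives a nonzero
LASSO coefficient or not; the selection frequency ranks candidates more
robustly than a single p-value ordering in a colinear panel.
"""
from proteodiscover.qc import log10_transform
from proteodiscover.simulate import SimConfig, generate_cohort
from proteodiscover.stability import StabilityConfig, stability_rank, top_k

cfg = SimConfig(n_pd=96, n_nc=45, n_proteins=140, n_planted=5, delta=0.15,
                censor_frac_target=0.0, n_high_cv=0, seed=4)
matrix, meta, truth = generate_cohort(cfg)

ranking = stability_rank(
    log10_transform(matrix), meta["group"], list(matrix.protein_ids),
    StabilityConfig(iterations=2000, seed=4),
)
top10 = top_k(ranking, 10)
print(ranking.head(10)[["frequency", "eligible", "rank"]].round(3))
print(f"\nplanted markers in the top 10: "
      f"{len(set(top10) & set(truth.planted_protein_ids))}/5")
print("-> planted signals hold selection frequencies near 1.0; chance "
      "correlations in the null bulk sit far lower.")
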