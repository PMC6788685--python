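"""Covariate-adjusted discovery of disease-associated proteins.

Each protein's log10 level is regressed on disease group (PD vs NC),
age, sex and medication dose; candidates are nominated at p < 0.005 and
the family is Benjamini-Hochberg adjusted.
"""
from proteodiscover.discovery import cluster_candidates, nominate_candidates, run_discovery
from proteodiscover.qc import log10_transform
from proteodiscover.simulate import SimConfig, generate_cohort

cfg = SimConfig(n_pd=96, n_nc=45, n_proteins=500, n_planted=15, delta=0.15,
                censor_frac_target=0.0, seed=3)
matrix, meta, truth = generate_cohort(cfg)
table = run_discovery(log10_transform(matrix), meta)
candidates = nominate_candidates(table)

hits = set(candidates) & set(truth.planted_protein_ids)
print(f"tested {len(table)} proteins; {len(candidates)} candidates at p < 0.005")
print(f"planted effects among candidates: {len(hits)}/{len(truth.planted_protein_ids)}")
print(table.loc[candidates[:5], ["beta", "p", "q", "direction"]].round(4))

res = cluster_candidates(log10_transform(matrix), candidates)
print(f"\nhierarchical clustering (euclidean, average linkage): "
      f"{len(res.protein_order)} candidates, first merge height "
      f"{res.protein_linkage[0, 2]:.2f}")
print("-> the candidate list is enriched for the planted biology; the "
      "dendrogram exposes correlated blocks that motivate stability ranking.")
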