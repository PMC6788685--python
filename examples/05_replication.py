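"""Replicate discovery candidates in an independent multisite cohort.

The replication model mirrors discovery but adds clinical site and
assay batch as covariates; a candidate replicates only with FDR q < 0.05
in both cohorts AND the same direction of effect.
"""
from proteodiscover.discovery import nominate_candidates, run_discovery
from proteodiscover.qc import log10_transform
from proteodiscover.replication import check_replication, run_replication
from proteodiscover.simulate import SimConfig, generate_cohort

disc_cfg = SimConfig(n_pd=96, n_nc=45, n_proteins=300, n_planted=8, delta=0.2,
                     censor_frac_target=0.0, seed=5)
matrix, meta, truth = generate_cohort(disc_cfg)
disc = run_discovery(log10_transform(matrix), meta)
top = nominate_candidates(disc)[:10]

rep_cfg = disc_cfg.replace(n_pd=215, n_nc=102, n_sites=2, n_batches=5, seed=6)
rmat, rmeta, _ = generate_cohort(rep_cfg, truth=truth, sample_prefix="r")
rep = run_replication(log10_transform(rmat), rmeta, top)

replicated = check_replication(disc.loc[top], rep)
side = disc.loc[top, ["beta", "q"]].join(rep[["beta", "q"]], lsuffix="_disc", rsuffix="_repl")
side["replicated"] = side.index.isin(replicated)
print(side.round(4))
print(f"\n{len(replicated)} of {len(top)} candidates replicated with "
      "concordant direction despite site and batch shifts")
print("-> shared planted biology replicates; site/batch confounds are "
      "absorbed by the expanded design.")
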