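"""Simulate a study-like cohort: genotypes, gene models, counts, ages.

Generates 75 diploid samples over a 4-chromosome toy genome with
Hardy-Weinberg genotypes in LD blocks, planted cis effects, one large
trans master-regulator hub (shared with a cis signal) and one medium
hub, an age covariate (mean 14.3, SD 8.8 months), and negative-
binomial counts over the latent expression layer.
"""

from pathlib import Path

import pandas as pd

import eqtlscan as eq

workdir = Path("scratch/example_cohort")
paths = eq.simulate_study(workdir, seed=42)

truth = pd.read_csv(paths["truth"], sep="\t")
counts = pd.read_csv(paths["counts"], sep="\t", index_col=0)
print(f"wrote {sorted(p.name for p in workdir.iterdir())}")
print(f"counts matrix: {counts.shape[0]} genes x {counts.shape[1]} samples")
print(truth["class"].value_counts().rename("planted effects").to_string())
hub = truth.loc[truth["class"] == "trans", "snp_id"].mode()[0]
n_targets = (truth["snp_id"] == hub).sum()
print(f"largest planted hub: {hub} touching {n_targets} genes")
# The truth table is the ledger of planted SNP-gene effects; downstream
# examples measure how much of it the pipeline recovers.
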