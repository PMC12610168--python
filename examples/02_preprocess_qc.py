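"""Genotype and expression QC on the simulated cohort.

Applies the production filters: MAF > 0.01, LD pruning at r^2 < 0.2
(50-SNP window, 5-SNP step), restriction to SNPs within 100 kb of an
expressed gene, removal of genes with < 200 total counts or zeros in
>= 70 of 75 samples, and median-of-ratios + log2 normalization.

Run 01_simulate_cohort.py first (or this script will do it for you).
"""

from pathlib import Path

import eqtlscan as eq
from eqtlscan.config import PipelineConfig

workdir = Path("scratch/example_cohort")
if not (workdir / "genotypes.vcf").exists():
    eq.simulate_study(workdir, seed=42)

cfg = PipelineConfig(seed=42)
out = eq.run_preprocess(workdir, cfg)

import pandas as pd
report = pd.read_csv(workdir / "qc_report.tsv", sep="\t")
print(report.to_string(index=False))
# Each row is the survivor count after one filter. LD pruning removes
# most of each correlated block; the near-gene restriction then keeps
# only variants that can ever enter a cis test or sit near expression.
print(f"\nnormalized expression: {out['expression'].shape[0]} genes x "
      f"{out['expression'].shape[1]} samples")
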