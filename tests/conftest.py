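import numpy as np
import pandas as pd
import pytest

import eqtlscan as eq


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small but complete simulated cohort shared across tests.

    75 samples, 2 chromosomes, 40 genes, 160 SNPs, planted cis effects
    and one 20-target trans hub that also carries a cis signal.
    """
    genes, variants = eq.simulate_genome(
        n_chrom=2, chrom_len=6_000_000, n_genes=40, n_snps=160, seed=11
    )
    dosages = eq.simulate_genotypes(variants, 75, maf_low=0.15, maf_high=0.5,
                                    ld_block=1, seed=11)
    covariates = eq.simulate_covariates(75, seed=11)
    truth = eq.plant_effects(
        genes, variants, cis_fraction=0.2, cis_beta=1.5,
        hotspot_spec=[(20, 1.5)], shared_hub=True, seed=11,
    )
    latent, counts = eq.simulate_expression(
        dosages, truth, covariates, genes["gene_id"], seed=11
    )
    return {
        "genes": genes, "variants": variants, "dosages": dosages,
        "covariates": covariates, "truth": truth,
        "latent": latent, "counts": counts,
    }


@pytest.fixture()
def three_variant_fixture():
    """Three hand-built variants over four samples, with one missing call."""
    variants = pd.DataFrame({
        "snp_id": ["1:100", "1:250", "2:90"],
        "chrom": ["1", "1", "2"],
        "pos": [100, 250, 90],
        "ref": ["A", "C", "G"],
        "alt": ["T", "G", "A"],
        "maf": [np.nan] * 3,
    })
    dosages = pd.DataFrame(
        np.array([[0, 1, 2], [1, -1, 0], [2, 0, 1], [0, 2, 2]], dtype=np.int8),
        index=pd.Index(["S1", "S2", "S3", "S4"], name="sample_id"),
        columns=variants["snp_id"],
    )
    return variants, dosages
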