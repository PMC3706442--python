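import numpy as np
import pandas as pd
import pytest

from triherit.datatypes import SNP_COLUMNS, GenotypePanel


def make_panel(dosages, ids=None, plates=None, **snp_meta):
    """Hand-built panel from a (snps x samples) dosage list."""
    dosages = np.asarray(dosages, dtype=float)
    m, n = dosages.shape
    meta = {
        "snp": [f"s{i}" for i in range(m)],
        "chrom": "1",
        "pos": (np.arange(m) + 1) * 100,
        "ref": "A",
        "alt": "G",
        "imputed": False,
        "stratum": "genotyped",
        "info": 1.0,
    }
    meta.update(snp_meta)
    snps = pd.DataFrame(meta)[SNP_COLUMNS]
    return GenotypePanel(
        ids=ids or [f"i{j}" for j in range(n)],
        snps=snps,
        dosages=dosages,
        plates=plates,
    )


@pytest.fixture
def tiny_panel():
    rng = np.random.default_rng(0)
    return make_panel(rng.binomial(2, 0.3, size=(20, 12)).astype(float))


@pytest.fixture(scope="session")
def hwe_panel():
    """Medium panel simulated under HWE, shared across tests."""
    from triherit.simulate import GenoSimConfig, simulate_genotypes

    return simulate_genotypes(
        GenoSimConfig(n_individuals=500, n_snps=2000, seed=42)
    )
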