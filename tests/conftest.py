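import numpy as np
import pytest

import pleiomap as pm


@pytest.fixture(scope="session")
def small_cohort():
    """800 individuals, one chromosome, a single additive QTL (two traits)."""
    cfg = pm.SimulationConfig(
        n_individuals=800,
        n_chromosomes=1,
        n_variants_per_chrom=250,
        n_founder_haplotypes=100,
        switch_rate=0.05,
        traits=["size", "muscle"],
        Vg=np.array([[0.3, -0.1], [-0.1, 0.3]]),
        Ve=np.array([[0.7, 0.0], [0.0, 0.7]]),
        qtl_spec=[
            pm.QtlSpec(
                "chr1", 1_500_000, [0.4, -0.4], frequency_target=0.3, name="causal"
            )
        ],
        seed=42,
    )
    geno = pm.simulate_genotypes(cfg)
    pheno, truth = pm.simulate_phenotypes(geno, cfg)
    return cfg, geno, pheno, truth


@pytest.fixture(scope="session")
def small_grm_eigen(small_cohort):
    _, geno, _, _ = small_cohort
    return pm.eigendecompose(pm.compute_grm(geno))


def simple_z_scan(y, dosages):
    """Independent z/t statistics from plain intercept+dosage regression."""
    y = np.asarray(y, float)
    yc = y - y.mean()
    Xc = dosages - dosages.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    sx[sx == 0] = np.inf
    r = (yc @ Xc) / (sx * np.sqrt(yc @ yc))
    r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    n = len(y)
    return r * np.sqrt((n - 2) / (1 - r**2))
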