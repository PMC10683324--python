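"""Mixed-model engine: GRM algebra, REML recovery, scan calibration."""

import numpy as np
import pandas as pd
import pytest

import pleiomap as pm
from pleiomap.containers import GenotypeMatrix
from pleiomap.lmm import Grm, eigendecompose


def geno_from(dosages):
    dosages = np.asarray(dosages, float)
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(m)],
            "chrom": "chr1",
            "pos": 1000 * np.arange(1, m + 1),
            "ref": "A",
            "alt": "C",
            "alt_freq": dosages.mean(axis=0) / 2,
            "accuracy": np.nan,
        }
    )
    return GenotypeMatrix(dosages, variants, [f"s{i}" for i in range(n)])


class TestGrm:
    def test_single_marker_closed_form(self):
        # p = 0.5, dosages (0,1,2): W = (-1,0,1), denom = 0.5
        geno = geno_from([[0.0], [1.0], [2.0]])
        grm = pm.compute_grm(geno)
        expected = np.array([[2.0, 0.0, -2.0], [0.0, 0.0, 0.0], [-2.0, 0.0, 2.0]])
        assert np.allclose(grm.matrix, expected)

    def test_identical_genotype_rows_identical_grm_rows(self):
        rng = np.random.default_rng(0)
        dos = rng.integers(0, 3, size=(6, 50)).astype(float)
        dos[3] = dos[0]
        grm = pm.compute_grm(geno_from(dos))
        assert np.allclose(grm.matrix[0], grm.matrix[3])

    def test_unrelated_individuals_near_zero_offdiagonal(self):
        cfg = pm.SimulationConfig(
            n_individuals=300, n_chromosomes=1, n_variants_per_chrom=5000,
            n_founder_haplotypes=300, switch_rate=0.9, proxy_rate=0.0,
            traits=["a"], seed=2,
        )
        grm = pm.compute_grm(pm.simulate_genotypes(cfg))
        off = grm.matrix[np.triu_indices(300, 1)]
        assert abs(off.mean()) < 0.02

    def test_monomorphic_only_is_error(self):
        with pytest.raises(ValueError, match="monomorphic"):
            pm.compute_grm(geno_from(np.full((4, 3), 2.0)))

    def test_eigen_reconstructs(self, small_grm_eigen):
        eig = small_grm_eigen
        rec = eig.vectors @ np.diag(eig.values) @ eig.vectors.T
        rel = np.linalg.norm(rec - eig.source.matrix) / np.linalg.norm(
            eig.source.matrix
        )
        assert rel < 1e-6


class TestNullFit:
    def test_permuted_phenotype_has_no_heritability(self, small_cohort,
                                                    small_grm_eigen):
        _, geno, pheno, _ = small_cohort
        rng = np.random.default_rng(5)
        y = rng.permutation(pheno.trait("size"))
        fit = pm.fit_null(y, small_grm_eigen)
        assert fit.h2 < 0.1

    def test_h2_half_recovered_across_seeds(self):
        cfg = pm.SimulationConfig(
            n_individuals=2000, n_chromosomes=2, n_variants_per_chrom=600,
            n_founder_haplotypes=150, switch_rate=0.3, traits=["a"],
            Vg=np.array([[0.5]]), Ve=np.array([[0.5]]), seed=11,
        )
        geno = pm.simulate_genotypes(cfg)
        eigen = pm.eigendecompose(pm.compute_grm(geno))
        h2 = []
        for s in range(10):
            cfg.seed = 100 + s
            pheno, _ = pm.simulate_phenotypes(geno, cfg)
            h2.append(pm.fit_null(pheno.trait("a"), eigen).h2)
        assert all(0.4 <= v <= 0.6 for v in h2)

    def test_identity_grm_matches_iid_closed_form(self):
        rng = np.random.default_rng(8)
        n = 300
        y = rng.normal(2.0, 1.3, n)
        eigen = eigendecompose(Grm(matrix=np.eye(n), n_markers=1))
        fit = pm.fit_null(y, eigen)
        # variance partition: total equals the REML (ddof=1) variance
        s2 = y.var(ddof=1)
        assert fit.sigma_g2 + fit.sigma_e2 == pytest.approx(s2, rel=1e-6)
        # dense-matrix REML log-likelihood oracle at the fitted components
        V = fit.sigma_g2 * np.eye(n) + fit.sigma_e2 * np.eye(n)
        Vi = np.linalg.inv(V)
        X = np.ones((n, 1))
        XtViX = X.T @ Vi @ X
        P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
        ll = -0.5 * (
            np.linalg.slogdet(V)[1]
            + np.linalg.slogdet(XtViX)[1]
            + float(y @ P @ y)
            + (n - 1) * np.log(2 * np.pi)
        )
        assert fit.loglik == pytest.approx(ll, abs=1e-6)


class TestStScan:
    def test_zero_heritability_degenerates_to_ols(self, small_cohort,
                                                  small_grm_eigen):
        _, geno, pheno, _ = small_cohort
        y = pheno.trait("size")
        null0 = pm.NullFit(sigma_g2=0.0, sigma_e2=1.0, loglik=0.0, converged=True)
        res = pm.st_scan(y, geno, small_grm_eigen, null0)
        n = len(y)
        for j in [0, 57, 200]:
            x = geno.dosages[:, j]
            X = np.column_stack([np.ones(n), x])
            beta, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
            sigma2 = float(rss[0]) / (n - 2)
            se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
            assert res.table.loc[j, "beta"] == pytest.approx(beta[1], abs=1e-8)
            assert res.table.loc[j, "se"] == pytest.approx(se, abs=1e-8)

    def test_null_type_one_error_calibrated(self):
        # polygenic phenotype from one chromosome, null variants on another
        cfg = pm.SimulationConfig(
            n_individuals=1000, n_chromosomes=2, n_variants_per_chrom=600,
            n_founder_haplotypes=150, switch_rate=0.4, traits=["a"],
            Vg=np.array([[0.4]]), Ve=np.array([[0.6]]), seed=21,
        )
        geno = pm.simulate_genotypes(cfg)
        chr1 = (geno.variants["chrom"] == "chr1").to_numpy()
        eigen = pm.eigendecompose(pm.compute_grm(geno, np.flatnonzero(chr1)))
        # rebuild phenotype using only chr1 as background
        g1 = geno.subset_variants(chr1)
        cfg1 = pm.SimulationConfig(
            n_individuals=1000, n_chromosomes=1, n_variants_per_chrom=600,
            traits=["a"], Vg=np.array([[0.4]]), Ve=np.array([[0.6]]), seed=22,
        )
        pheno, _ = pm.simulate_phenotypes(g1, cfg1)
        y = pheno.trait("a")
        null = pm.fit_null(y, eigen)
        res = pm.st_scan(y, geno.subset_variants(~chr1), eigen, null)
        frac = (res.table["p"] < 0.05).mean()
        assert abs(frac - 0.05) < 0.02

    def test_conditioning_on_self_reported_collinear(self, small_cohort,
                                                     small_grm_eigen):
        _, geno, pheno, _ = small_cohort
        y = pheno.trait("size")
        j = geno.variant_index("causal")
        null = pm.fit_null(y, small_grm_eigen, geno.dosages[:, [j]])
        res = pm.st_scan(
            y, geno, small_grm_eigen, null, covariates=geno.dosages[:, [j]]
        )
        row = res.table[res.table["variant_id"] == "causal"].iloc[0]
        assert np.isnan(row["p"]) and row["reason"] == "collinear_or_monomorphic"

    def test_effect_size_recovery_within_3se(self):
        cfg = pm.SimulationConfig(
            n_individuals=1500, n_chromosomes=1, n_variants_per_chrom=300,
            n_founder_haplotypes=120, switch_rate=0.2, traits=["a"],
            Vg=np.array([[0.3]]), Ve=np.array([[0.7]]), seed=31,
            qtl_spec=[pm.QtlSpec("chr1", 2_000_000, [0.25],
                                 frequency_target=0.3, name="q")],
        )
        geno = pm.simulate_genotypes(cfg)
        eigen = pm.eigendecompose(pm.compute_grm(geno))
        hits = 0
        for s in range(12):
            cfg.seed = 200 + s
            pheno, _ = pm.simulate_phenotypes(geno, cfg)
            y = pheno.trait("a")
            null = pm.fit_null(y, eigen)
            res = pm.st_scan(y, geno, eigen, null)
            row = res.table[res.table["variant_id"] == "q"].iloc[0]
            hits += abs(row["beta"] - 0.25) <= 3 * row["se"]
        assert hits >= 11

    def test_missing_phenotypes_subset_consistently(self, small_cohort,
                                                    small_grm_eigen):
        _, geno, pheno, _ = small_cohort
        y = pheno.trait("size").copy()
        y[:50] = np.nan
        null = pm.fit_null(y, small_grm_eigen)
        res = pm.st_scan(y, geno, small_grm_eigen, null)
        assert (res.table["n"] == len(y) - 50).all()


class TestMultivariate:
    def test_univariate_limit_matches_fit_null(self, small_cohort,
                                               small_grm_eigen):
        _, geno, pheno, _ = small_cohort
        y = pheno.trait("size")
        uv = pm.fit_null(y, small_grm_eigen)
        mv = pm.fit_null_mv(y[:, None], small_grm_eigen)
        assert mv.Vg[0, 0] == pytest.approx(uv.sigma_g2, abs=2e-2)
        assert mv.Ve[0, 0] == pytest.approx(uv.sigma_e2, abs=2e-2)

    def test_genetic_correlation_recovered(self):
        rho = 0.8
        Vg = 0.4 * np.array([[1, rho], [rho, 1]])
        Ve = 0.6 * np.eye(2)
        cfg = pm.SimulationConfig(
            n_individuals=1500, n_chromosomes=1, n_variants_per_chrom=500,
            n_founder_haplotypes=150, switch_rate=0.3, traits=["a", "b"],
            Vg=Vg, Ve=Ve, seed=41,
        )
        geno = pm.simulate_genotypes(cfg)
        eigen = pm.eigendecompose(pm.compute_grm(geno))
        rgs = []
        for s in range(5):
            cfg.seed = 300 + s
            pheno, _ = pm.simulate_phenotypes(geno, cfg)
            mv = pm.fit_null_mv(pheno.values, eigen)
            rgs.append(mv.Vg[0, 1] / np.sqrt(mv.Vg[0, 0] * mv.Vg[1, 1]))
        assert all(0.6 <= r <= 0.95 for r in rgs)

    def test_mt_scan_univariate_limit(self, small_cohort, small_grm_eigen):
        _, geno, pheno, _ = small_cohort
        y = pheno.trait("size")
        null = pm.fit_null(y, small_grm_eigen)
        st = pm.st_scan(y, geno, small_grm_eigen, null)
        mv = pm.fit_null_mv(y[:, None], small_grm_eigen)
        mt = pm.mt_scan(y[:, None], geno, small_grm_eigen, mv)
        lp_st = -np.log10(st.table["p"].to_numpy())
        lp_mt = -np.log10(mt.table["p"].to_numpy())
        sel = lp_st > 1
        assert np.allclose(lp_st[sel], lp_mt[sel], rtol=0.1)

    def test_mt_null_calibration(self):
        # polygenic six-trait background from chr1; chr2 variants are null
        Vg = 0.3 * (0.5 * np.eye(6) + 0.5 * np.ones((6, 6)))
        cfg = pm.SimulationConfig(
            n_individuals=1000, n_chromosomes=2, n_variants_per_chrom=600,
            n_founder_haplotypes=150, switch_rate=0.4, proxy_rate=0.0,
            traits=list("abcdef"), Vg=Vg, Ve=0.7 * np.eye(6), seed=61,
        )
        geno = pm.simulate_genotypes(cfg)
        chr1 = (geno.variants["chrom"] == "chr1").to_numpy()
        eigen = pm.eigendecompose(pm.compute_grm(geno, np.flatnonzero(chr1)))
        cfg1 = pm.SimulationConfig(
            n_individuals=1000, n_chromosomes=1, n_variants_per_chrom=600,
            traits=list("abcdef"), Vg=Vg, Ve=0.7 * np.eye(6), seed=62,
        )
        pheno, _ = pm.simulate_phenotypes(geno.subset_variants(chr1), cfg1)
        mv = pm.fit_null_mv(pheno.values, eigen)
        assert mv.converged
        mt = pm.mt_scan(pheno.values, geno.subset_variants(~chr1), eigen, mv)
        frac = (mt.table["p"] < 0.05).mean()
        assert abs(frac - 0.05) < 0.01
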