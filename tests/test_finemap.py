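"""LD matrices, credible sets, IBSS posterior vs brute-force enumeration."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

import pleiomap as pm
from pleiomap.containers import GenotypeMatrix
from pleiomap.finemap import LdMatrix

from conftest import simple_z_scan


def geno_from(dosages):
    dosages = np.asarray(dosages, float)
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(m)],
            "chrom": "chr1",
            "pos": 1000 * np.arange(1, m + 1),
            "ref": "A", "alt": "C",
            "alt_freq": np.nanmean(dosages, axis=0) / 2,
            "accuracy": np.nan,
        }
    )
    return GenotypeMatrix(dosages, variants, [f"s{i}" for i in range(n)])


def region_with_causal(seed, n=1000, m=60, beta=0.35, freq=0.3):
    """One-chromosome region with a single causal variant; returns z, ld, id."""
    cfg = pm.SimulationConfig(
        n_individuals=n, n_chromosomes=1, n_variants_per_chrom=m,
        n_founder_haplotypes=100, switch_rate=0.05, traits=["y"],
        Vg=np.zeros((1, 1)), Ve=np.eye(1),
        qtl_spec=[pm.QtlSpec("chr1", (m // 2) * 12_500, [beta],
                             frequency_target=freq, name="causal")],
        seed=seed,
    )
    geno = pm.simulate_genotypes(cfg)
    pheno, _ = pm.simulate_phenotypes(geno, cfg)
    y = pheno.trait("y")
    z = simple_z_scan(y, geno.dosages)
    return geno, y, z, pm.ld_matrix(geno)


class TestLdMatrix:
    def test_duplicated_column_r2_one(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, 50).astype(float)
        ld = pm.ld_matrix(geno_from(np.column_stack([x, x])))
        assert ld.r2[0, 1] == pytest.approx(1.0)

    def test_flipped_allele_r2_one(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, 50).astype(float)
        ld = pm.ld_matrix(geno_from(np.column_stack([x, 2 - x])))
        assert ld.r2[0, 1] == pytest.approx(1.0)
        assert ld.r[0, 1] == pytest.approx(-1.0)

    def test_independent_variants_near_zero(self):
        rng = np.random.default_rng(2)
        dos = rng.binomial(2, 0.4, size=(2000, 40)).astype(float)
        ld = pm.ld_matrix(geno_from(dos))
        iu = np.triu_indices(40, 1)
        assert np.nanmean(ld.r2[iu]) < 0.005  # E[r2] ~ 1/n

    def test_monomorphic_undefined(self):
        dos = np.column_stack([np.full(20, 2.0),
                               np.tile([0.0, 1.0], 10)])
        ld = pm.ld_matrix(geno_from(dos))
        assert np.isnan(ld.r2[0, 1]) and np.isnan(ld.r2[0, 0])


class TestLdCredibleSet:
    def test_isolated_lead_is_singleton(self):
        rng = np.random.default_rng(3)
        dos = rng.binomial(2, 0.4, size=(500, 5)).astype(float)
        ld = pm.ld_matrix(geno_from(dos))
        cs = pm.ld_credible_set("v2", ld, r2_min=0.90)
        assert cs.members == ["v2"] and cs.lead == "v2"

    def test_threshold_counts_and_nesting(self):
        # r2 to lead by construction: (1.0, ~0.95, ~0.85)
        rng = np.random.default_rng(4)
        n = 4000
        lead = rng.binomial(2, 0.5, n).astype(float)
        near = lead.copy()
        flip = rng.random(n) < 0.012
        near[flip] = rng.binomial(2, 0.5, flip.sum())
        far = lead.copy()
        flip2 = rng.random(n) < 0.09
        far[flip2] = rng.binomial(2, 0.5, flip2.sum())
        ld = pm.ld_matrix(geno_from(np.column_stack([lead, near, far])))
        assert ld.r2[0, 1] > 0.90 > ld.r2[0, 2] > 0.80
        cs90 = pm.ld_credible_set("v0", ld, 0.90)
        cs80 = pm.ld_credible_set("v0", ld, 0.80)
        assert cs90.size == 2 and cs80.size == 3
        assert cs90.member_set() <= cs80.member_set()

    def test_nesting_on_simulated_regions(self):
        for seed in range(5):
            geno, _, z, ld = region_with_causal(seed, n=500, m=40)
            lead = str(geno.variant_ids[np.argmax(np.abs(z))])
            cs90 = pm.ld_credible_set(lead, ld, 0.90)
            cs80 = pm.ld_credible_set(lead, ld, 0.80)
            assert cs90.member_set() <= cs80.member_set()

    def test_monomorphic_lead_is_error(self):
        dos = np.column_stack([np.full(20, 2.0), np.tile([0.0, 1.0], 10)])
        ld = pm.ld_matrix(geno_from(dos))
        with pytest.raises(ValueError, match="monomorphic"):
            pm.ld_credible_set("v0", ld)


def enumeration_alpha(z, R, n, prior_var_grid):
    """Brute-force single-effect posterior by numerical integration.

    For each variant j, the marginal likelihood of the data under 'variant
    j is the single causal one' is integrated numerically over the effect
    size; the prior variance is chosen (as in the fitted model) by
    maximizing the average marginal likelihood over the same grid.
    """
    p = len(z)
    nn = n - 1
    d = np.full(p, float(nn))
    Xty = np.sqrt(nn) * z

    def marglik_j(j, v0):
        def integrand(b):
            # likelihood kernel in b (terms independent of j dropped)
            return np.exp(-0.5 * (d[j] * b**2 - 2 * b * Xty[j])) * (
                np.exp(-0.5 * b**2 / v0) / np.sqrt(2 * np.pi * v0)
            )
        s = np.sqrt(1.0 / (d[j] + 1.0 / v0))
        center = Xty[j] / (d[j] + 1.0 / v0)
        val, _ = integrate.quad(
            integrand, center - 10 * s, center + 10 * s, epsabs=0, epsrel=1e-12
        )
        return val

    best = None
    for v0 in prior_var_grid:
        vals = np.array([marglik_j(j, v0) for j in range(p)])
        tot = vals.mean()
        if best is None or tot > best[0]:
            best = (tot, vals)
    vals = best[1]
    return vals / vals.sum()


class TestIbss:
    def test_single_effect_matches_enumeration(self):
        # 3 variants in weak LD, L=1: IBSS must equal exact enumeration
        rng = np.random.default_rng(7)
        n = 400
        dos = rng.binomial(2, [0.3, 0.5, 0.4], size=(n, 3)).astype(float)
        y = 0.25 * dos[:, 1] + rng.standard_normal(n)
        z = simple_z_scan(y, dos)
        ld = pm.ld_matrix(geno_from(dos))
        grid = np.geomspace(1e-4, 1.0, 13)
        fit = pm.ibss_fit(z, ld, n=n, L=1, prior_var_grid=grid)
        # enumeration ignores off-diagonal LD; keep it tiny
        assert np.max(np.abs(ld.r2 - np.eye(3))) < 0.02
        expected = enumeration_alpha(z, ld.r, n, grid)
        assert np.allclose(fit.alpha[0], expected, atol=1e-6)

    def test_lone_strong_signal_gets_pip_one(self):
        rng = np.random.default_rng(8)
        n = 2000
        dos = rng.binomial(2, 0.4, size=(n, 20)).astype(float)
        y = 0.45 * dos[:, 7] + rng.standard_normal(n)
        z = simple_z_scan(y, dos)
        assert abs(z[7]) > 8
        ld = pm.ld_matrix(geno_from(dos))
        sets = pm.ibss_finemap(z, ld, n=n, L=5)
        assert len(sets) == 1
        assert sets[0].members == ["v7"]
        assert sets[0].pip["v7"] > 0.99

    def test_two_independent_causals_found_separately(self):
        hits = 0
        for seed in range(25):
            rng = np.random.default_rng(100 + seed)
            n = 1200
            m = 40
            cfg = pm.SimulationConfig(
                n_individuals=n, n_chromosomes=1, n_variants_per_chrom=m,
                n_founder_haplotypes=100, switch_rate=0.05, traits=["y"],
                Vg=np.zeros((1, 1)), Ve=np.eye(1), seed=500 + seed,
            )
            geno = pm.simulate_genotypes(cfg)
            i1, i2 = 8, 32  # distant columns, low LD
            x1, x2 = geno.dosages[:, i1], geno.dosages[:, i2]
            y = 0.35 * x1 + 0.35 * x2 + rng.standard_normal(n)
            z = simple_z_scan(y, geno.dosages)
            ld = pm.ld_matrix(geno)
            sets = pm.ibss_finemap(z, ld, n=n, L=5)
            ids = [cs.member_set() for cs in sets]
            id1, id2 = geno.variant_ids[i1], geno.variant_ids[i2]
            got1 = any(id1 in s for s in ids)
            got2 = any(id2 in s for s in ids)
            disjoint = all(
                not (a & b) for k, a in enumerate(ids) for b in ids[k + 1:]
            )
            hits += got1 and got2 and disjoint
        assert hits >= 20

    def test_purity_filter_discards_diffuse_sets(self):
        rng = np.random.default_rng(9)
        n = 300
        dos = rng.binomial(2, 0.4, size=(n, 30)).astype(float)
        y = rng.standard_normal(n)  # no signal at all
        z = simple_z_scan(y, dos)
        ld = pm.ld_matrix(geno_from(dos))
        sets = pm.ibss_finemap(z, ld, n=n, L=3)
        assert sets == []


class TestMtCredibleSet:
    def _setup(self, p_group1, p_group2, qualify_p1, qualify_p2):
        rng = np.random.default_rng(11)
        dos = rng.binomial(2, 0.5, size=(300, 4)).astype(float)
        dos[:, 1] = dos[:, 0]  # v1 duplicates v0
        dos[:, 3] = dos[:, 2]  # v3 duplicates v2
        geno = geno_from(dos)
        ld = pm.ld_matrix(geno)

        def mt(p_lead, lead_idx, traits):
            t = geno.variants[["variant_id", "chrom", "pos"]].copy()
            t["wald"] = 10.0
            t["df"] = 6
            t["p"] = [p_lead if j == lead_idx else 0.5 for j in range(4)]
            t["n"] = 300
            t["reason"] = ""
            return pm.MtGwasResult(traits=traits, table=t)

        def st(p_best, trait):
            t = geno.variants[["variant_id", "chrom", "pos"]].copy()
            t["alt_freq"] = 0.5
            t["beta"] = 0.1
            t["se"] = 0.02
            t["t"] = 3.0
            t["p"] = [p_best, 0.5, 0.5, 0.5]
            t["n"] = 300
            t["reason"] = ""
            return pm.GwasResult(trait=trait, table=t)

        mt_results = {
            "size": mt(p_group1, 0, ["a", "b"]),
            "muscle": mt(p_group2, 2, ["c", "d"]),
        }
        st_results = {"a": st(qualify_p1, "a"), "c": st(qualify_p2, "c")}
        groups = {"size": ["a", "b"], "muscle": ["c", "d"]}
        region = ("chr1", 1, 10_000)
        return mt_results, st_results, groups, ld, region

    def test_both_groups_qualify_merges(self):
        mt_r, st_r, groups, ld, region = self._setup(1e-10, 1e-9, 1e-8, 1e-8)
        cs = pm.mt_credible_set(mt_r, st_r, groups, ld, region)
        assert cs.method == "MT-merged"
        assert cs.member_set() == {"v0", "v1", "v2", "v3"}

    def test_one_group_qualifies(self):
        mt_r, st_r, groups, ld, region = self._setup(1e-10, 1e-9, 1e-8, 1e-3)
        cs = pm.mt_credible_set(mt_r, st_r, groups, ld, region)
        assert cs.member_set() == {"v0", "v1"}

    def test_neither_qualifies(self):
        mt_r, st_r, groups, ld, region = self._setup(1e-10, 1e-9, 1e-3, 1e-3)
        assert pm.mt_credible_set(mt_r, st_r, groups, ld, region) is None


class TestOverlapSummary:
    def _cs(self, members, method="LD90"):
        return pm.CredibleSet(method=method, lead=members[0], members=members)

    def test_identical_sets(self):
        s = pm.cs_overlap_summary([self._cs(["a", "b"]), self._cs(["a", "b"])])
        assert s["all_identical"] and s["share_at_least_one"]

    def test_partial_overlap_count(self):
        s = pm.cs_overlap_summary([self._cs(["a", "b"]), self._cs(["b", "c"])])
        assert s["pairwise_shared"][(0, 1)] == 1
        assert not s["all_identical"]

    def test_ibss_containment(self):
        ibss = self._cs(["a"], method="IBSS")
        ld = self._cs(["a", "b", "c"])
        s = pm.cs_overlap_summary([ibss, ld])
        assert s["ibss_contained_in_ld"]["a"]
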