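"""Coding enrichment tails, Poisson-binomial oracle, variance shares."""

import itertools

import numpy as np
import pytest
from scipy import stats

import pleiomap as pm
from pleiomap.enrichment import poisson_binomial_tail

# union sizes of the 11 multi-trait credible sets (330 members total)
CS_SIZES = [2, 57, 6, 1, 116, 11, 86, 5, 6, 20, 20]
RATE = 0.0034


class TestCodingEnrichment:
    def test_expected_count_and_tail_match_printed_values(self):
        res = pm.coding_enrichment(CS_SIZES, RATE, observed_total=6,
                                   observed_cs_with_coding=5)
        assert res.expected_total == pytest.approx(1.122, abs=1e-9)
        assert round(res.expected_total, 1) == 1.1
        assert res.p_total == pytest.approx(1.1e-3, rel=0.1)

    def test_relaxed_ld_scenario(self):
        # r2 >= 0.80: 11 CS averaging 73 members, 11 coding variants observed
        res = pm.coding_enrichment([73] * 11, RATE, observed_total=11,
                                   observed_cs_with_coding=8)
        assert res.p_total == pytest.approx(1.3e-4, rel=0.05)

    def test_zero_rate_degenerate(self):
        with pytest.raises(ValueError):
            pm.coding_enrichment(CS_SIZES, 0.0, 0, 0)

    def test_observed_exceeding_members_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            pm.coding_enrichment([3, 3], 0.1, observed_total=7,
                                 observed_cs_with_coding=1)

    def test_monte_carlo_agrees_with_exact(self):
        exact = pm.coding_enrichment([10, 20, 30], 0.05, observed_total=6,
                                     observed_cs_with_coding=3)
        mc = pm.coding_enrichment([10, 20, 30], 0.05, observed_total=6,
                                  observed_cs_with_coding=3,
                                  method="monte_carlo", n_reps=200_000, seed=1)
        se_tot = np.sqrt(exact.p_total * (1 - exact.p_total) / 200_000)
        se_cs = np.sqrt(exact.p_cs_count * (1 - exact.p_cs_count) / 200_000)
        assert abs(mc.p_total - exact.p_total) <= 3 * se_tot
        assert abs(mc.p_cs_count - exact.p_cs_count) <= 3 * se_cs

    def test_p_total_monotone_in_observed(self):
        ps = [
            pm.coding_enrichment(CS_SIZES, RATE, k, 1).p_total
            for k in range(0, 8)
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_expected_linear_in_rate(self):
        e1 = pm.coding_enrichment(CS_SIZES, 0.001, 0, 0).expected_total
        e2 = pm.coding_enrichment(CS_SIZES, 0.002, 0, 0).expected_total
        assert e2 == pytest.approx(2 * e1)


class TestPoissonBinomial:
    @pytest.mark.parametrize("k_sets", [3, 8, 12])
    def test_dp_equals_brute_force_enumeration(self, k_sets):
        rng = np.random.default_rng(k_sets)
        probs = rng.uniform(0.01, 0.6, k_sets)
        for k in range(k_sets + 1):
            # enumerate all 2^k outcome patterns
            brute = 0.0
            for pattern in itertools.product([0, 1], repeat=k_sets):
                if sum(pattern) >= k:
                    brute += np.prod(
                        [p if b else 1 - p for p, b in zip(probs, pattern)]
                    )
            assert poisson_binomial_tail(probs, k) == pytest.approx(
                brute, abs=1e-12
            )

    def test_tail_beyond_support_is_zero(self):
        assert poisson_binomial_tail(np.array([0.5, 0.5]), 3) == 0.0


class TestLeadCoding:
    def test_printed_value(self):
        p = pm.lead_coding_test(11, RATE, 5)
        assert p == pytest.approx(2.1e-10, rel=0.05)
        assert p < 1e-8

    def test_degenerate_cases(self):
        assert pm.lead_coding_test(11, RATE, 0) == 1.0
        assert pm.lead_coding_test(5, 1.0, 3) == pytest.approx(1.0)

    def test_binomial_oracle(self):
        # independent check against the binomial pmf summed directly
        expected = sum(
            stats.binom.pmf(k, 11, RATE) for k in range(5, 12)
        )
        assert pm.lead_coding_test(11, RATE, 5) == pytest.approx(expected)


class TestJointEffectsAndShares:
    def _cohort(self, seed, betas=(0.3, 0.25)):
        cfg = pm.SimulationConfig(
            n_individuals=1200, n_chromosomes=1, n_variants_per_chrom=200,
            n_founder_haplotypes=100, switch_rate=0.1, traits=["y"],
            Vg=np.array([[0.3]]), Ve=np.array([[0.7]]),
            qtl_spec=[
                pm.QtlSpec("chr1", 500_000, [betas[0]],
                           frequency_target=0.3, name="q1"),
                pm.QtlSpec("chr1", 3_500_000, [betas[1]],
                           frequency_target=0.4, name="q2"),
            ],
            seed=seed,
        )
        geno = pm.simulate_genotypes(cfg)
        pheno, _ = pm.simulate_phenotypes(geno, cfg)
        eigen = pm.eigendecompose(pm.compute_grm(geno))
        return geno, pheno.trait("y"), eigen

    def test_single_candidate_matches_scan(self):
        geno, y, eigen = self._cohort(1)
        null = pm.fit_null(y, eigen)
        beta, se = pm.joint_variant_effects(y, geno, ["q1"], eigen, null)
        scan = pm.st_scan(y, geno, eigen, null)
        row = scan.table[scan.table["variant_id"] == "q1"].iloc[0]
        assert beta[0] == pytest.approx(row["beta"], abs=1e-8)
        assert se[0] == pytest.approx(row["se"], abs=1e-8)

    def test_joint_fit_recovers_both_effects(self):
        hits = 0
        for seed in range(12):
            geno, y, eigen = self._cohort(100 + seed)
            null = pm.fit_null(y, eigen)
            beta, se = pm.joint_variant_effects(
                y, geno, ["q1", "q2"], eigen, null
            )
            hits += (abs(beta[0] - 0.3) <= 3 * se[0]) and (
                abs(beta[1] - 0.25) <= 3 * se[1]
            )
        assert hits >= 11

    def test_collinear_candidates_rejected(self):
        geno, y, eigen = self._cohort(2)
        dup = geno.dosages.copy()
        dup[:, 10] = dup[:, geno.variant_index("q1")]
        geno2 = pm.GenotypeMatrix(dup, geno.variants.copy(),
                                  list(geno.individual_ids))
        null = pm.fit_null(y, eigen)
        other = str(geno.variant_ids[10])
        with pytest.raises(ValueError, match="collinear"):
            pm.joint_variant_effects(y, geno2, ["q1", other], eigen, null)

    def test_share_formula(self):
        vs = pm.variance_shares(["v"], betas=[1.0], frequencies=[0.5],
                                sigma_g2_without=5.0)
        assert vs.shares[0] == pytest.approx(0.10)

    def test_zero_effect_variant_negligible_share(self):
        geno, y, eigen = self._cohort(3)
        null = pm.fit_null(y, eigen)
        neutral = str(geno.variant_ids[150])
        beta, _ = pm.joint_variant_effects(y, geno, [neutral], eigen, null)
        freq = float(geno.alt_freq()[150])
        vs = pm.variance_shares([neutral], beta, [freq], null.sigma_g2)
        assert vs.shares[0] < 0.05

    def test_zero_sigma_g2_is_error(self):
        with pytest.raises(ValueError):
            pm.variance_shares(["v"], [0.1], [0.3], sigma_g2_without=0.0)

    def test_share_recovery_and_polygenic_reduction_agree(self):
        # q1 built to explain ~12% of genetic variance
        shares, reductions = [], []
        for seed in range(5):
            geno, y, eigen = self._cohort(200 + seed, betas=(0.25, 0.0))
            null = pm.fit_null(y, eigen)
            beta, _ = pm.joint_variant_effects(y, geno, ["q1"], eigen, null)
            freq = float(geno.alt_freq()[geno.variant_index("q1")])
            sg2_with = pm.refit_sigma_g2_with_candidates(y, geno, ["q1"], eigen)
            vs = pm.variance_shares(["q1"], beta, [freq], null.sigma_g2,
                                    sigma_g2_with=sg2_with)
            shares.append(vs.aggregate_share)
            reductions.append(vs.polygenic_reduction)
        # truth: 2*0.3*0.7*0.25^2 / (0.3 + that) ~ 0.08
        x = geno.dosages[:, geno.variant_index("q1")]
        assert 0.02 < np.mean(shares) < 0.2
        assert abs(np.mean(shares) - np.mean(reductions)) < 0.08
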