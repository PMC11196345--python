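"""Generator correctness: Mendelian transmission, conditional moments,
phenotype scaling, and reproducibility."""

import numpy as np
import pytest
from scipy import stats

from hereg_gxe import gxe_sim, hereg_core


class TestParentGenotypes:
    def test_degenerate_frequencies_are_monomorphic(self):
        assert np.all(gxe_sim.draw_parent_genotypes(10, 1.0, seed=0) == 1)
        assert np.all(gxe_sim.draw_parent_genotypes(10, 0.0, seed=0) == 0)

    def test_hwe_genotype_frequencies(self, rng):
        # K=50,000 families -> 100,000 parents; HWE at p=0.5 gives
        # (1/4, 1/2, 1/4) within 3 binomial SE
        alleles = gxe_sim.draw_parent_genotypes(50_000, 0.5, seed=rng)
        counts = alleles.sum(axis=2).reshape(-1)
        n = len(counts)
        for geno, expected in [(0, 0.25), (1, 0.5), (2, 0.25)]:
            freq = np.mean(counts == geno)
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(freq - expected) < 3 * se

    @pytest.mark.parametrize("bad_p", [-0.1, 1.5])
    def test_frequency_domain_error(self, bad_p):
        with pytest.raises(ValueError, match="frequency"):
            gxe_sim.draw_parent_genotypes(10, bad_p)

    def test_family_count_domain_error(self):
        with pytest.raises(ValueError, match="K"):
            gxe_sim.draw_parent_genotypes(0, 0.5)


@pytest.fixture(scope="module")
def transmission():
    rng = np.random.default_rng(7)
    parents = gxe_sim.draw_parent_genotypes(100_000, 0.5, seed=rng)
    g1, g2, pi = gxe_sim.mendelian_transmit(parents, seed=rng)
    return parents, g1, g2, pi


class TestMendelianTransmission:
    def test_ibd_masses(self, transmission):
        # segregation forces P(pi = 0, 1/2, 1) = (1/4, 1/2, 1/4)
        _, _, _, pi = transmission
        K = len(pi)
        for val, expected in [(0.0, 0.25), (0.5, 0.5), (1.0, 0.25)]:
            freq = np.mean(pi == val)
            se = np.sqrt(expected * (1 - expected) / K)
            assert abs(freq - expected) < 4 * se

    def test_ibd_variance_one_eighth(self, transmission):
        _, _, _, pi = transmission
        K = len(pi)
        # SE of the sample variance from the exact fourth moment of pi
        se = np.sqrt((0.03125 - 0.125 ** 2) / K)
        assert abs(pi.var() - 0.125) < 4 * se

    @pytest.mark.parametrize("p", [0.2, 0.5])
    def test_genotype_pair_frequencies_by_ibd_class(self, p):
        """Joint genotype-pair frequencies within each IBD class follow the
        tabulated conditional probabilities (chi-square GOF, alpha=0.01)."""
        rng = np.random.default_rng(11)
        parents = gxe_sim.draw_parent_genotypes(100_000, p, seed=rng)
        g1, g2, pi = gxe_sim.mendelian_transmit(parents, seed=rng)
        q = 1 - p
        # conditional P(g1, g2 | pi) for ordered pairs, keyed (g1, g2)
        expected = {
            0.0: {(2, 2): p**4, (0, 0): q**4, (1, 1): 4*p*p*q*q,
                  (2, 1): 2*p**3*q, (1, 2): 2*p**3*q,
                  (1, 0): 2*p*q**3, (0, 1): 2*p*q**3,
                  (2, 0): p*p*q*q, (0, 2): p*p*q*q},
            0.5: {(2, 2): p**3, (0, 0): q**3, (1, 1): p*q,
                  (2, 1): p*p*q, (1, 2): p*p*q,
                  (1, 0): p*q*q, (0, 1): p*q*q},
            1.0: {(2, 2): p*p, (0, 0): q*q, (1, 1): 2*p*q},
        }
        for ibd, table in expected.items():
            mask = pi == ibd
            pairs = list(zip(g1[mask].tolist(), g2[mask].tolist()))
            n = len(pairs)
            probs = np.array(list(table.values()))
            probs = probs / probs.sum()  # classes with pi fixed renormalize
            observed = np.array([pairs.count(k) for k in table])
            assert observed.sum() == n  # no pair outside the table
            chi2 = stats.chisquare(observed, probs * n)
            assert chi2.pvalue > 0.01

    def test_shape_validation(self):
        with pytest.raises(ValueError, match="shape"):
            gxe_sim.mendelian_transmit(np.zeros((5, 2)))


class TestGenotypeValues:
    model = gxe_sim.GxEModel.crossover(a=1.0, d=0.0)

    @pytest.mark.parametrize("genotype,env,expected", [
        ("BB", 0, 1.0), ("BB", 1, -1.0),
        ("bb", 0, -1.0), ("bb", 1, 1.0),
        ("Bb", 0, 0.0), ("Bb", 1, 0.0),
        (2, 0, 1.0), (0, 1, 1.0),  # allele counts accepted
    ])
    def test_crossover_scheme_values(self, genotype, env, expected):
        assert gxe_sim.assign_genotype_value(genotype, env, self.model) == expected

    def test_scheme_ii_flips_additive_keeps_dominance(self):
        m = gxe_sim.GxEModel.crossover(a=0.7, d=0.2)
        assert m.effects[1]["BB"] == -m.effects[0]["BB"]
        assert m.effects[1]["bb"] == -m.effects[0]["bb"]
        assert m.effects[1]["Bb"] == m.effects[0]["Bb"]

    def test_unknown_genotype_and_environment(self):
        with pytest.raises(ValueError, match="genotype"):
            gxe_sim.assign_genotype_value("AA", 0, self.model)
        with pytest.raises(ValueError, match="environment"):
            gxe_sim.assign_genotype_value("BB", 5, self.model)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            gxe_sim.GxEModel.crossover(1.0, weights=(0.6, 0.6))


class TestLocusCalibration:
    def test_additive_calibration(self):
        # d=0: sigma_a^2 = 2pq a^2, so a = sqrt(h2/(2pq))
        spec = gxe_sim.LocusSpec(p=0.3, target_h2=0.25)
        assert spec.a == pytest.approx(np.sqrt(0.25 / (2 * 0.3 * 0.7)))
        assert spec.sigma_a2 == pytest.approx(0.25)

    def test_dominance_calibration_positive_root(self):
        spec = gxe_sim.LocusSpec(p=0.3, target_h2=0.25, d=0.4)
        assert spec.sigma_a2 == pytest.approx(0.25)
        assert spec.a > 0

    def test_infeasible_variance_budget(self):
        # sigma_a2 = 0.5 plus sigma_d2 = 4 p^2 q^2 d^2 = 0.64 exceeds 1
        with pytest.raises(ValueError, match="sigma_a"):
            gxe_sim.LocusSpec(p=0.5, target_h2=0.5, d=1.6)


class TestSibPairSimulation:
    def test_null_model_slope_centered_on_zero(self):
        slopes = []
        for r in range(100):
            s = gxe_sim.simulate_sibpairs(500, 500, p=0.3, target_h2=0.0,
                                          seed=np.random.default_rng([31, r]))
            fit = hereg_core.he_fit(hereg_core.PairedResponse.from_sibpairs(s))
            slopes.append(fit.slope)
        sem = np.std(slopes, ddof=1) / 10
        assert abs(np.mean(slopes)) < 3 * sem

    def test_slope_recovers_minus_two_h2(self):
        # pooled crossover sample, h2=0.25 -> mean HE slope near -0.5
        slopes = []
        for r in range(60):
            s = gxe_sim.simulate_sibpairs(2500, 2500, p=0.3, target_h2=0.25,
                                          seed=np.random.default_rng([32, r]))
            fit = hereg_core.he_fit(hereg_core.PairedResponse.from_sibpairs(s))
            slopes.append(fit.slope)
        sem = np.std(slopes, ddof=1) / np.sqrt(60)
        assert abs(np.mean(slopes) + 0.5) < 3 * sem

    def test_conditional_means_match_scheme_independent_values(self):
        """E[Y | pi] steps down by sigma_a2 per half-unit of IBD:
        sig2 + 2(1-pi) sigma_a2 with sig2 the residual-difference variance
        (twice the per-individual residual), identically for both schemes."""
        spec = gxe_sim.LocusSpec(p=0.3, target_h2=0.25)
        sig2 = 2 * spec.sigma_e2
        targets = {1.0: sig2, 0.5: sig2 + spec.sigma_a2,
                   0.0: sig2 + 2 * spec.sigma_a2}
        for scheme_kw in ({"K1": 100_000, "K2": 0}, {"K1": 0, "K2": 100_000}):
            s = gxe_sim.simulate_sibpairs(p=0.3, target_h2=0.25, seed=5,
                                          **scheme_kw)
            Y = (s.y1 - s.y2) ** 2
            for ibd, target in targets.items():
                sel = Y[s.pi == ibd]
                sem = sel.std(ddof=1) / np.sqrt(len(sel))
                assert abs(sel.mean() - target) < 4 * sem

    def test_phenotype_variance_near_one(self):
        s = gxe_sim.simulate_sibpairs(5000, 5000, p=0.5, target_h2=0.25,
                                      seed=9)
        y = np.concatenate([s.y1, s.y2])
        assert 0.95 < y.var() < 1.05

    def test_environment_assignment_by_family_order(self):
        s = gxe_sim.simulate_sibpairs(30, 70, p=0.4, target_h2=0.1, seed=1)
        assert np.all(s.env[:30] == 0) and np.all(s.env[30:] == 1)
        assert s.env_counts == {0: 30, 1: 70}

    def test_continuous_effect_variant_adds_variance(self):
        # a_family ~ N(a, E^2): linkage-visible variance 2pq (a^2 + E^2)
        slopes = []
        for r in range(60):
            s = gxe_sim.simulate_sibpairs(2000, 2000, p=0.5, target_h2=0.1,
                                          effect_sd=0.3,
                                          seed=np.random.default_rng([33, r]))
            fit = hereg_core.he_fit(hereg_core.PairedResponse.from_sibpairs(s))
            slopes.append(fit.slope)
        expected = -2 * (0.1 + 2 * 0.5 * 0.5 * 0.09)
        sem = np.std(slopes, ddof=1) / np.sqrt(60)
        assert abs(np.mean(slopes) - expected) < 3 * sem

    def test_reproducibility_bit_identical(self):
        a = gxe_sim.simulate_sibpairs(200, 200, p=0.3, target_h2=0.25, seed=42)
        b = gxe_sim.simulate_sibpairs(200, 200, p=0.3, target_h2=0.25, seed=42)
        assert a.to_dataframe().equals(b.to_dataframe())

    def test_too_few_families(self):
        with pytest.raises(ValueError, match="K1"):
            gxe_sim.simulate_sibpairs(1, 0, p=0.5, target_h2=0.1)


class TestUnrelatedSimulation:
    def test_hwe_consistency(self):
        s = gxe_sim.simulate_unrelated(20_000, 3, 1, 0.1, p=0.3, seed=3)
        for k in range(3):
            counts = np.bincount(s.genotypes[:, k], minlength=3)
            expected = 20_000 * np.array([0.49, 0.42, 0.09])
            assert stats.chisquare(counts, expected).pvalue > 0.01

    def test_sample_standardization_exact(self):
        s = gxe_sim.simulate_unrelated(500, 10, 5, 0.2, seed=4)
        assert np.allclose(s.z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(s.z.var(axis=0), 1, atol=1e-12)

    def test_single_marker_special_case(self):
        s = gxe_sim.simulate_unrelated(400, 1, 1, 0.25, p=0.3, seed=5)
        assert s.m == 1 and len(s.causal) == 1

    def test_crossover_gxe_cancels_marginal_effect(self):
        model = gxe_sim.GxEModel.crossover(1.0)
        tvals = []
        for r in range(80):
            s = gxe_sim.simulate_unrelated(500, 1, 1, 0.2, gxe=model, p=0.3,
                                           seed=np.random.default_rng([34, r]))
            tvals.append(hereg_core.gwas_fit(s.y, s.z[:, 0]).t)
        sem = np.std(tvals, ddof=1) / np.sqrt(80)
        assert abs(np.mean(tvals)) < 3 * sem

    def test_causal_count_domain_error(self):
        with pytest.raises(ValueError, match="n_causal"):
            gxe_sim.simulate_unrelated(100, 5, 6, 0.1)

    def test_marker_correlation_induces_ld(self):
        C = np.array([[1.0, 0.8], [0.8, 1.0]])
        s = gxe_sim.simulate_unrelated(5000, 2, 2, 0.1, p=0.3,
                                       marker_corr=C, seed=6)
        r = np.corrcoef(s.z[:, 0], s.z[:, 1])[0, 1]
        assert r > 0.5  # latent-scale LD carries to genotypes


class TestGenomeIBDPairs:
    def test_pi_tilde_moments(self):
        g = gxe_sim.simulate_genomewide_ibd_pairs(200_000, 0.5, L=32, seed=8)
        assert abs(g.pi_tilde.mean() - 0.5) < 4 * np.sqrt(1 / 512 / 200_000)
        # Var = 1/(16 L) = 1/512 at L = 32
        assert abs(g.pi_tilde.var() - 1 / 512) < 0.05 / 512

    def test_null_slope_centered_on_zero(self):
        slopes = []
        for r in range(50):
            g = gxe_sim.simulate_genomewide_ibd_pairs(
                20_000, 0.0, seed=np.random.default_rng([35, r]))
            fit = hereg_core.he_fit(hereg_core.PairedResponse.from_genome_ibd(g))
            slopes.append(fit.slope)
        sem = np.std(slopes, ddof=1) / np.sqrt(50)
        assert abs(np.mean(slopes)) < 3 * sem

    def test_slope_recovers_minus_two_htilde2(self):
        slopes = []
        for r in range(40):
            g = gxe_sim.simulate_genomewide_ibd_pairs(
                200_000, 0.5, seed=np.random.default_rng([36, r]))
            fit = hereg_core.he_fit(hereg_core.PairedResponse.from_genome_ibd(g))
            slopes.append(fit.slope)
        sem = np.std(slopes, ddof=1) / np.sqrt(40)
        assert abs(np.mean(slopes) + 1.0) < 3 * sem

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            gxe_sim.simulate_genomewide_ibd_pairs(100, 0.2, L=0.0)
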