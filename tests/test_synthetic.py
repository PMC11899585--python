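"""Generator-level checks: structural equations, scenario wiring,
interaction injection, and reproducibility."""

import numpy as np
import pytest

import medcnn
from medcnn.synthetic import (
    NONLINEAR_TRANSFORMS,
    gen_exposure,
    gen_mediator,
    gen_network_features,
    gen_outcome,
    generate_dataset,
    inject_interactions,
    make_scenario,
    replicate_config,
)


class TestExposure:
    def test_codomain_and_length(self, rng):
        a = gen_exposure(1000, rng)
        assert a.shape == (1000,)
        assert set(np.unique(a)) <= {0, 1}

    def test_balanced_at_large_n(self, rng):
        a = gen_exposure(100_000, rng)
        assert 0.49 <= a.mean() <= 0.51

    def test_deterministic_under_seed(self):
        a1 = gen_exposure(1, np.random.default_rng(7))
        a2 = gen_exposure(1, np.random.default_rng(7))
        assert a1 == a2

    def test_rejects_nonpositive_n(self, rng):
        with pytest.raises(ValueError):
            gen_exposure(0, rng)


class TestMediatorOutcome:
    def test_group_mean_matches_structural_equation(self, rng):
        a = gen_exposure(100_000, rng)
        m = gen_mediator(a, beta0=2.0, beta1=5.0, sigma_M=2.0, rng=rng)
        assert m[a == 1].mean() == pytest.approx(7.0, abs=0.05)
        assert m[a == 0].mean() == pytest.approx(2.0, abs=0.05)

    def test_degenerate_noise_limit(self, rng):
        a = np.array([0, 1, 1, 0])
        m = gen_mediator(a, 2.0, 5.0, 1e-12, rng)
        np.testing.assert_allclose(m, 2.0 + 5.0 * a, atol=1e-9)

    def test_outcome_substitution(self, rng):
        y = gen_outcome(np.ones(4), np.full(4, 7.0), 1.5, 2.0, 5.0, 1e-12, rng)
        np.testing.assert_allclose(y, 38.5, atol=1e-9)

    def test_outcome_length_mismatch(self, rng):
        with pytest.raises(ValueError, match="length mismatch"):
            gen_outcome(np.ones(3), np.ones(4), 1, 1, 1, 1, rng)

    def test_ols_recovers_generating_coefficients(self, rng):
        import statsmodels.api as sm

        n = 100_000
        a = gen_exposure(n, rng)
        m = gen_mediator(a, 2.0, 5.0, 2.0, rng)
        y = gen_outcome(a, m, 1.5, 2.0, 5.0, 2.0, rng)
        res = sm.OLS(y, np.column_stack([np.ones(n), a, m])).fit()
        for est, se, truth in zip(res.params, res.bse, (1.5, 2.0, 5.0)):
            assert abs(est - truth) < 3 * se


class TestNetworkFeatures:
    def test_shapes_and_total_columns(self, rng):
        m = rng.normal(size=50)
        Z = gen_network_features(m, (100, 150, 120, 130, 140), "linear", rng)
        assert len(Z) == 5
        assert sum(z.shape[1] for z in Z) == 640
        assert all(z.shape[0] == 50 for z in Z)

    def test_noiseless_linear_columns_perfectly_correlated(self, rng):
        m = rng.normal(size=200)
        Z = gen_network_features(m, (6,), "linear", rng, noise_sd=0.0)
        for j in range(6):
            r = np.corrcoef(Z[0][:, j], m)[0, 1]
            assert abs(r) == pytest.approx(1.0, abs=1e-12)

    def test_nonlinear_columns_not_affine_in_mediator(self, rng):
        m = rng.normal(loc=4.5, scale=3.0, size=400)
        Z = gen_network_features(m, (8,), "nonlinear", rng, noise_sd=0.0)
        # columns 0, 4 use x^2: perfect rank correlation with m^2, |pearson|<1
        from scipy.stats import spearmanr

        col = Z[0][:, 0]
        assert abs(spearmanr(col, m**2).statistic) == pytest.approx(1.0, abs=1e-12)
        assert abs(np.corrcoef(col, m)[0, 1]) < 0.999

    def test_transform_dictionary_cycles(self, rng):
        m = np.linspace(-1, 1, 100)
        Z = gen_network_features(m, (9,), "nonlinear", rng, noise_sd=0.0)
        # column 4 reuses the same transform as column 0 (cycle length 4)
        assert len(NONLINEAR_TRANSFORMS) == 4

    def test_rejects_bad_sizes(self, rng):
        with pytest.raises(ValueError):
            gen_network_features(np.ones(5), (), "linear", rng)
        with pytest.raises(ValueError):
            gen_network_features(np.ones(5), (3, 0), "linear", rng)


class TestInteractions:
    def test_stated_rule_arithmetic(self):
        Z = np.zeros((1, 11))
        Z[0, 4] = 1.0   # 5th feature (1-based)
        Z[0, 9] = 3.0   # 10th feature
        out = inject_interactions(Z, interval=5, strength=2.0)
        assert out[0, 10] == pytest.approx(6.0)  # 11th feature += 2*1*3

    def test_all_other_columns_untouched(self, rng):
        Z = rng.normal(size=(20, 23))
        out = inject_interactions(Z, interval=5, strength=2.0)
        # 0-based targets: columns 11 and 21 (1-based) after pairs (5,10), (15,20)
        modified = {10, 20}
        for j in range(23):
            same = np.array_equal(out[:, j], Z[:, j])
            assert same == (j not in modified)

    def test_zero_strength_is_identity(self, rng):
        Z = rng.normal(size=(10, 15))
        np.testing.assert_array_equal(inject_interactions(Z, 5, 0.0), Z)

    def test_too_narrow_matrix_returned_unchanged(self, rng, caplog):
        Z = rng.normal(size=(5, 8))
        with caplog.at_level("WARNING"):
            out = inject_interactions(Z, interval=5, strength=2.0)
        np.testing.assert_array_equal(out, Z)
        assert "too narrow" in caplog.text


class TestScenarios:
    @pytest.mark.parametrize(
        "scenario,alpha2,beta1",
        [("null_1", 0.0, 0.0), ("null_2", 0.0, 5.0), ("null_3", 5.0, 0.0)],
    )
    def test_null_scenarios_zero_the_right_paths(self, scenario, alpha2, beta1):
        cfg = make_scenario(scenario)
        assert cfg.alpha2 == alpha2
        assert cfg.beta1 == beta1

    def test_alternative_true_effects(self):
        cfg = make_scenario("alternative", beta1_override=5.0)
        assert cfg.true_nie == 25.0
        assert cfg.true_nde == 2.0
        assert cfg.network_sizes == (100, 150, 120, 130, 140)
        assert cfg.n == 1000

    def test_beta1_override_grid_enforced(self):
        with pytest.raises(ValueError):
            make_scenario("alternative", beta1_override=2.5)
        with pytest.raises(ValueError):
            make_scenario("nope")


class TestGenerateDataset:
    def test_bit_reproducible_under_seed(self):
        cfg = medcnn.make_scenario("alternative", n=100, network_sizes=(10, 12),
                                   seed=9)
        d1, d2 = generate_dataset(cfg), generate_dataset(cfg)
        np.testing.assert_array_equal(d1.A, d2.A)
        np.testing.assert_array_equal(d1.Y, d2.Y)
        for z1, z2 in zip(d1.Z, d2.Z):
            np.testing.assert_array_equal(z1, z2)

    def test_replicates_differ_but_are_reproducible(self):
        cfg = medcnn.make_scenario("alternative", n=80, network_sizes=(10,))
        c1 = replicate_config(cfg, master_seed=3, replicate=0)
        c2 = replicate_config(cfg, master_seed=3, replicate=1)
        assert c1.seed != c2.seed
        assert replicate_config(cfg, 3, 0).seed == c1.seed

    def test_total_effect_identity_at_generator_level(self):
        """Regressing Y on A alone recovers TE = alpha1 + alpha2*beta1."""
        import statsmodels.api as sm

        cfg = medcnn.make_scenario("alternative", beta1_override=5.0,
                                   n=200_000, network_sizes=(8,), seed=5)
        rng = np.random.default_rng(cfg.seed)
        a = gen_exposure(cfg.n, rng)
        m = gen_mediator(a, cfg.beta0, cfg.beta1, cfg.sigma_M, rng)
        y = gen_outcome(a, m, cfg.alpha0, cfg.alpha1, cfg.alpha2, cfg.sigma_Y, rng)
        res = sm.OLS(y, np.column_stack([np.ones(cfg.n), a])).fit()
        te = cfg.true_nie + cfg.true_nde
        assert abs(res.params[1] - te) < 3 * res.bse[1]
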