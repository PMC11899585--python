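"""The alternating estimator's building blocks: loss, closed-form targets,
regression updates, convergence measure, and a small end-to-end fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import medcnn
from medcnn.datatypes import MediationParams
from medcnn.fitting import (
    DegenerateDesignError,
    FitConfig,
    compute_targets,
    convergence_pct,
    fit,
    med_cnn_loss,
    update_params,
)

P = MediationParams(alpha0=1.5, alpha1=2.0, alpha2=5.0, beta0=2.0, beta1=5.0)


class TestLoss:
    def test_exact_fit_gives_zero(self):
        A = np.array([0.0, 1.0, 1.0])
        h = P.beta0 + P.beta1 * A
        Y = P.alpha0 + P.alpha1 * A + P.alpha2 * h
        assert med_cnn_loss(h, A, Y, P) == 0.0

    def test_single_sample_substitution(self):
        # y=38.5, A=1, h=8: (38.5-1.5-2-40)^2 + (8-2-5)^2 = 25 + 1
        assert med_cnn_loss([8.0], [1.0], [38.5], P) == pytest.approx(26.0)
        assert med_cnn_loss([7.0], [1.0], [38.5], P) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            med_cnn_loss([1.0, 2.0], [1.0], [1.0], P)


class TestTargets:
    def test_substitution_example(self):
        r = compute_targets(np.array([1.0]), np.array([38.5]), P)
        assert r[0] == pytest.approx((35.0 * 5 + 7) / 26)
        assert r[0] == pytest.approx(7.0)

    def test_alpha2_zero_reduces_to_mediator_prediction(self):
        p0 = MediationParams(1.5, 2.0, 0.0, 2.0, 5.0)
        A = np.array([0.0, 1.0])
        r = compute_targets(A, np.array([10.0, -3.0]), p0)
        np.testing.assert_allclose(r, p0.beta0 + p0.beta1 * A)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            compute_targets(np.array([1.0]), np.array([np.inf]), P)

    @settings(deadline=None, max_examples=25)
    @given(
        y=st.floats(-50, 50),
        a=st.sampled_from([0.0, 1.0]),
        a2=st.floats(-5, 5),
        b1=st.floats(-5, 5),
    )
    def test_target_is_argmin_of_per_sample_loss(self, y, a, a2, b1):
        """Grid-search oracle: r_i minimizes the joint loss over h."""
        p = MediationParams(1.5, 2.0, a2, 2.0, b1)
        r = compute_targets(np.array([a]), np.array([y]), p)[0]
        grid = np.linspace(r - 2.0, r + 2.0, 40_001)
        losses = (y - p.alpha0 - p.alpha1 * a - p.alpha2 * grid) ** 2 + (
            grid - p.beta0 - p.beta1 * a
        ) ** 2
        assert abs(grid[np.argmin(losses)] - r) < 1e-4
        # and analytically: the quadratic's stationary point equals r
        assert med_cnn_loss([r], [a], [y], p) <= losses.min() + 1e-9


class TestUpdateParams:
    def test_exact_recovery_without_noise(self, rng):
        A = rng.binomial(1, 0.5, 200).astype(float)
        # residual mediator variation keeps the outcome design full rank
        h = 2.0 + 5.0 * A + 1e-6 * rng.normal(size=200)
        Y = 1.5 + 2.0 * A + 5.0 * h
        est = update_params(h, A, Y)
        assert est.beta0 == pytest.approx(2.0, abs=1e-6)
        assert est.beta1 == pytest.approx(5.0, abs=1e-5)
        assert est.alpha2 == pytest.approx(5.0, abs=1e-5)
        assert est.cov_outcome.shape == (3, 3)

    def test_covariances_symmetric_psd(self, rng):
        A = rng.binomial(1, 0.5, 300).astype(float)
        h = rng.normal(size=300)
        Y = rng.normal(size=300)
        est = update_params(h, A, Y)
        for cov in (est.cov_outcome, est.cov_mediator):
            np.testing.assert_allclose(cov, cov.T, atol=1e-12)
            assert np.all(np.linalg.eigvalsh(cov) > -1e-12)

    def test_constant_exposure_is_degenerate(self, rng):
        with pytest.raises(DegenerateDesignError):
            update_params(rng.normal(size=50), np.zeros(50), rng.normal(size=50))

    def test_nie_invariant_to_affine_imm_rescaling(self, rng):
        """alpha2 scales by 1/c and beta1 by c, so the product is unchanged."""
        A = rng.binomial(1, 0.5, 500).astype(float)
        h = 2.0 + 5.0 * A + rng.normal(size=500)
        Y = 1.5 + 2.0 * A + 5.0 * h + rng.normal(size=500)
        e1 = update_params(h, A, Y)
        e2 = update_params(3.7 * h - 11.0, A, Y)
        assert e2.alpha2 * e2.beta1 == pytest.approx(e1.alpha2 * e1.beta1,
                                                     rel=1e-9)
        assert e2.alpha1 == pytest.approx(e1.alpha1, rel=1e-9)


class TestConvergence:
    def test_relative_change_hand_example(self):
        prev = MediationParams(1, 1, 10.0, 1, 1)
        curr = MediationParams(1, 1, 10.05, 1, 1)
        assert convergence_pct(prev, curr) == pytest.approx(0.5)

    def test_no_change_is_zero(self):
        assert convergence_pct(P, P) == 0.0

    def test_zero_previous_value_is_guarded(self):
        prev = MediationParams(0.0, 1, 1, 1, 1)
        curr = MediationParams(0.001, 1, 1, 1, 1)
        val = convergence_pct(prev, curr)
        assert np.isfinite(val) and val > 0


class TestFit:
    def test_small_linear_fit_recovers_signal(self, small_linear_dataset):
        res = fit(
            small_linear_dataset,
            FitConfig(seed=0, epochs_init=15, epochs=5, max_iter=3,
                      learning_rate=5e-3, batch_size=64),
        )
        d = small_linear_dataset
        # the IMM must track the latent mediator up to sign
        c = np.corrcoef(res.imm_train, d.M_true[res.train_index])[0, 1]
        assert abs(c) > 0.9
        assert res.effects.te == pytest.approx(res.effects.nie + res.effects.nde)
        assert res.iterations_used == len(res.trace)
        assert res.effects.se_nie is not None and res.effects.se_nie > 0
        # NIE within a generous band around the truth at this small n
        assert abs(res.effects.nie - 25.0) < 12.0

    def test_trivially_loose_threshold_converges_quickly(self, small_linear_dataset):
        res = fit(
            small_linear_dataset,
            FitConfig(seed=0, epochs_init=10, epochs=4, max_iter=10,
                      learning_rate=5e-3, batch_size=64, threshold=1e6),
        )
        assert res.converged
        assert res.iterations_used == 1

    def test_reproducible_under_seed(self, small_linear_dataset):
        kw = dict(epochs_init=6, epochs=3, max_iter=2, learning_rate=5e-3,
                  batch_size=64)
        r1 = fit(small_linear_dataset, FitConfig(seed=11, **kw))
        r2 = fit(small_linear_dataset, FitConfig(seed=11, **kw))
        assert r1.effects.nie == r2.effects.nie
        np.testing.assert_array_equal(r1.imm_train, r2.imm_train)

    def test_requires_both_exposure_classes(self, rng):
        d = medcnn.MediationDataset(
            A=np.zeros(60, dtype=int), Y=rng.normal(size=60),
            Z=[rng.normal(size=(60, 10))],
        )
        with pytest.raises(DegenerateDesignError):
            fit(d, FitConfig())

    def test_rejects_tiny_samples(self, rng):
        d = medcnn.MediationDataset(
            A=rng.binomial(1, 0.5, 20), Y=rng.normal(size=20),
            Z=[rng.normal(size=(20, 10))],
        )
        with pytest.raises(ValueError, match="50"):
            fit(d, FitConfig())
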