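import numpy as np
import pytest

from density_decode import (BehaviorSet, EncoderParams, MoGComponents,
                            PriorSpec, SimulationConfig, SpikeTable,
                            WeightMatrix, compute_weight_matrix,
                            decode_latent_variational,
                            estimate_behavior_threshold, fit_behavior_decoder,
                            fit_cavi, mixing_proportions, one_hot_weight_matrix,
                            posterior_pi, predict_behavior, rates,
                            simulate_session, soft_weight_matrix)
from density_decode.model_core import RateDesign


class TestWeightMatrix:
    def test_single_spike_soft_weights(self):
        r = np.array([[0.3, 0.7]])
        W = compute_weight_matrix(r, np.array([0]), np.array([0]), K=1, C=2, T=1)
        np.testing.assert_allclose(W.values[0, :, 0], [0.3, 0.7])

    def test_hard_responsibilities_equal_counts(self, rng):
        N, K, C, T = 60, 3, 2, 4
        tr = rng.integers(0, K, N)
        bi = rng.integers(0, T, N)
        lab = rng.integers(0, C, N)
        r = np.eye(C)[lab]
        W_soft = compute_weight_matrix(r, tr, bi, K, C, T)
        t = SpikeTable(K, T, tr, bi, rng.standard_normal((N, 2)))
        W_hard = one_hot_weight_matrix(t, lab, K, C, T)
        np.testing.assert_array_equal(W_soft.values, W_hard.values)

    def test_conservation(self, rng):
        """Sum over components of W equals the per-bin spike counts exactly."""
        N, K, C, T = 50, 4, 3, 5
        tr = rng.integers(0, K, N)
        bi = rng.integers(0, T, N)
        r = rng.dirichlet(np.ones(C), size=N)
        W = compute_weight_matrix(r, tr, bi, K, C, T)
        t = SpikeTable(K, T, tr, bi, rng.standard_normal((N, 1)))
        np.testing.assert_allclose(W.values.sum(axis=1), t.counts(), atol=1e-8)

    def test_all_labels_one_unit(self, rng):
        t = SpikeTable(2, 3, rng.integers(0, 2, 20), rng.integers(0, 3, 20),
                       rng.standard_normal((20, 2)))
        W = one_hot_weight_matrix(t, np.zeros(20, int), 2, 2, 3)
        np.testing.assert_array_equal(W.values[:, 0, :], t.counts())
        assert W.values[:, 1, :].sum() == 0

    def test_all_missing_gives_zero(self, rng):
        t = SpikeTable(2, 2, rng.integers(0, 2, 10), rng.integers(0, 2, 10),
                       rng.standard_normal((10, 2)))
        W = one_hot_weight_matrix(t, np.full(10, -1), 2, 3, 2)
        assert W.values.sum() == 0

    def test_label_out_of_range_rejected(self, rng):
        t = SpikeTable(1, 1, [0], [0], [[1.0]])
        with pytest.raises(ValueError):
            one_hot_weight_matrix(t, np.array([5]), 1, 2, 1)


class TestPosteriorPi:
    def test_zero_weights_uniform(self):
        th = np.column_stack([np.ones(4), np.zeros(4)])
        pi = posterior_pi(th, np.zeros((2, 3)), RateDesign(), T=3)
        np.testing.assert_allclose(pi, 0.25)

    def test_composition_identity(self, rng):
        th = rng.standard_normal((3, 2))
        y = rng.standard_normal((2, 4))
        d = RateDesign()
        np.testing.assert_array_equal(posterior_pi(th, y, d, T=4),
                                      mixing_proportions(rates(th, y, d, T=4)))

    def test_true_theta_reproduces_simulator_pi(self):
        s = simulate_session(SimulationConfig(K=5, T=6, C=2, D=2, seed=2))
        pi = posterior_pi(s.theta_true, s.behavior, s.config.design(), T=6)
        np.testing.assert_allclose(pi, s.pi_true, atol=1e-12)


class TestBehaviorDecoder:
    def test_planted_linear_signal_continuous(self, rng):
        """Continuous behavior exactly linear in one weight entry is recovered
        with near-perfect training R^2."""
        K, C, T = 30, 2, 5
        W = WeightMatrix(rng.poisson(5.0, size=(K, C, T)).astype(float))
        y = 2.0 * W.values[:, 0, :] + 1.0
        dec = fit_behavior_decoder(W, BehaviorSet("continuous", y),
                                   reg_grid=np.array([1e-4, 1e-3]))
        pred = predict_behavior(dec, W)
        ss = 1 - np.sum((pred - y) ** 2) / np.sum((y - y.mean()) ** 2)
        assert ss > 0.99

    def test_permuted_labels_at_chance(self, rng):
        """Binary labels independent of W decode at chance (binomial 3 sigma)."""
        K, C, T = 60, 2, 5
        W_tr = WeightMatrix(rng.poisson(5.0, size=(K, C, T)).astype(float))
        W_te = WeightMatrix(rng.poisson(5.0, size=(K, C, T)).astype(float))
        y = rng.integers(0, 2, K)
        dec = fit_behavior_decoder(W_tr, BehaviorSet("binary", y), seed=0)
        acc = np.mean(predict_behavior(dec, W_te) == rng.integers(0, 2, K))
        assert abs(acc - 0.5) <= 3 * np.sqrt(0.25 / K)

    def test_duplicate_trials_identical_predictions(self, rng):
        K, C, T = 10, 2, 4
        W = WeightMatrix(rng.poisson(4.0, size=(K, C, T)).astype(float))
        y = BehaviorSet("binary", (np.arange(K) % 2))
        dec = fit_behavior_decoder(W, y, seed=0)
        W2 = WeightMatrix(np.concatenate([W.values, W.values]))
        pred = predict_behavior(dec, W2)
        np.testing.assert_array_equal(pred[:K], pred[K:])

    def test_single_class_rejected(self, rng):
        W = WeightMatrix(rng.poisson(4.0, size=(6, 2, 3)).astype(float))
        with pytest.raises(ValueError, match="single class"):
            fit_behavior_decoder(W, BehaviorSet("binary", np.ones(6)))

    def test_probabilities_in_unit_interval(self, rng):
        W = WeightMatrix(rng.poisson(4.0, size=(12, 2, 3)).astype(float))
        y = BehaviorSet("binary", (np.arange(12) % 2))
        dec = fit_behavior_decoder(W, y, seed=0)
        p = dec.predict_proba(W)
        assert np.all((p >= 0) & (p <= 1))

    def test_feature_dim_mismatch_rejected(self, rng):
        W = WeightMatrix(rng.poisson(4.0, size=(8, 2, 3)).astype(float))
        dec = fit_behavior_decoder(W, BehaviorSet("binary", np.arange(8) % 2), seed=0)
        with pytest.raises(ValueError, match="features"):
            predict_behavior(dec, WeightMatrix(np.ones((2, 3, 3))))

    def test_prediction_invariant_to_spike_order(self, binary_session):
        """Shuffling spike rows upstream leaves the decoded behavior unchanged."""
        s = binary_session
        mog, theta, _ = fit_cavi(s.spikes, s.behavior, 2, seed=0, max_iter=10)
        rng = np.random.default_rng(0)
        perm = rng.permutation(s.spikes.n_spikes)
        shuffled = SpikeTable(s.spikes.K, s.spikes.T, s.spikes.trials[perm],
                              s.spikes.bins[perm], s.spikes.features[perm])
        W1 = soft_weight_matrix(s.spikes, mog, theta, s.behavior, RateDesign())
        W2 = soft_weight_matrix(shuffled, mog, theta, s.behavior, RateDesign())
        np.testing.assert_allclose(W1.values, W2.values, atol=1e-10)


class TestThresholdEstimate:
    def test_constant_training_behavior_gives_constant(self, binary_session):
        s = binary_session
        y_const = BehaviorSet("binary", np.ones(s.spikes.K))
        yhat = estimate_behavior_threshold(s.spikes, s.spikes, y_const)
        assert np.all(yhat == 1.0)

    def test_single_test_trial_shape(self, continuous_session):
        s = continuous_session
        sp_te, _ = s.spikes.restrict_trials(np.array([0]))
        sp_tr, _ = s.spikes.restrict_trials(np.arange(1, s.spikes.K))
        y_tr = s.behavior.subset(np.arange(1, s.spikes.K))
        yhat = estimate_behavior_threshold(sp_te, sp_tr, y_tr)
        assert yhat.shape == (1, s.spikes.T)

    def test_positive_r2_on_strong_modulation(self, continuous_session):
        s = continuous_session
        test_ids = np.arange(0, 5)
        train_ids = np.arange(5, s.spikes.K)
        sp_te, _ = s.spikes.restrict_trials(test_ids)
        sp_tr, _ = s.spikes.restrict_trials(train_ids)
        yhat = estimate_behavior_threshold(sp_te, sp_tr,
                                           s.behavior.subset(train_ids))
        y_true = s.behavior.subset(test_ids).values
        r2 = 1 - np.sum((yhat - y_true) ** 2) / np.sum((y_true - y_true.mean()) ** 2)
        assert r2 > 0


class TestLatentVariationalDecoding:
    def test_zero_behavior_weight_returns_prior(self):
        mog = MoGComponents(np.zeros((1, 2)), np.eye(2)[None])
        theta = EncoderParams(np.array([[1.0, 0.0]]), np.ones((1, 2)))
        rng = np.random.default_rng(0)
        spikes = SpikeTable(3, 4, rng.integers(0, 3, 30), rng.integers(0, 4, 30),
                            rng.standard_normal((30, 2)))
        out = decode_latent_variational(spikes, mog, theta, RateDesign(),
                                        PriorSpec(bernoulli_p=0.4))
        np.testing.assert_allclose(out["mean"], 0.4, atol=1e-12)

    def test_posterior_mean_in_unit_interval(self, binary_session):
        s = binary_session
        mog, theta, _ = fit_cavi(s.spikes, s.behavior, 2, seed=0, max_iter=15)
        out = decode_latent_variational(s.spikes, mog, theta, RateDesign())
        assert np.all((out["mean"] >= 0) & (out["mean"] <= 1))

    def test_classifies_strongly_modulated_trials(self):
        """Posterior mean separates trials with >90% accuracy when modulation
        is strong and spikes are plentiful."""
        cfg = SimulationConfig(K=20, T=15, C=2, D=1,
                               means=np.array([[-3.0], [3.0]]),
                               theta=np.array([[0.5, 2.5], [0.5, -2.5]]),
                               base_rate=35.0, seed=17)
        s = simulate_session(cfg)
        assert s.spikes.n_spikes / cfg.K >= 1000
        mog, theta, _ = fit_cavi(s.spikes, s.behavior, 2, seed=0)
        out = decode_latent_variational(s.spikes, mog, theta, RateDesign())
        acc = np.mean((out["mean"] > 0.5) == (s.behavior.values > 0.5))
        assert acc > 0.9
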