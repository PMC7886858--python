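import numpy as np
import pytest

from radgp import GPFitConfig, GPHyperparameters, GPModel, TrainingSet, fit_gp, rbf_kernel
from radgp.gp import JITTER, log_marginal_likelihood


def _random_instance(rng, n=12, d=3):
    X = rng.normal(size=(n, d))
    y = rng.normal(size=n)
    return TrainingSet(X, y)


class TestKernel:
    def test_self_similarity_is_one(self, rng):
        x = rng.normal(size=(1, 4))
        assert rbf_kernel(x, x, 2.0)[0, 0] == pytest.approx(1.0)

    def test_unit_lengthscale_distance(self):
        x1, x2 = np.zeros((1, 1)), np.array([[1.5]])
        assert rbf_kernel(x1, x2, 1.5)[0, 0] == pytest.approx(np.exp(-0.5))

    def test_symmetric_positive_semidefinite(self, rng):
        X = rng.normal(size=(20, 3))
        K = rbf_kernel(X, X, 1.0)
        np.testing.assert_allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-10

    def test_nonpositive_lengthscale_rejected(self):
        with pytest.raises(ValueError):
            rbf_kernel(np.zeros((2, 2)), np.zeros((2, 2)), 0.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rbf_kernel(np.zeros((2, 2)), np.zeros((2, 3)), 1.0)


class TestFit:
    def test_explicit_overrides_bypass_optimization(self, rng):
        m = fit_gp(_random_instance(rng), GPFitConfig(lengthscale=1.0, noise_variance=0.1))
        assert m.hyper == GPHyperparameters(1.0, 0.1)

    def test_identical_rows_rejected(self):
        X = np.ones((5, 2))
        with pytest.raises(ValueError, match="degenerate"):
            fit_gp(TrainingSet(X, np.arange(5.0)))

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_gp(TrainingSet(np.zeros((1, 2)), np.zeros(1)))

    def test_optimum_beats_random_probes(self, rng):
        train = _random_instance(rng, n=30, d=2)
        m = fit_gp(train, GPFitConfig(n_restarts=5, seed=0))
        for _ in range(20):
            probe = GPHyperparameters(
                float(10 ** rng.uniform(-2, 2)), float(10 ** rng.uniform(-5, 0))
            )
            assert m.log_marginal_likelihood >= log_marginal_likelihood(train, probe) - 1e-6

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            GPHyperparameters(-1.0, 0.1)
        with pytest.raises(ValueError):
            GPHyperparameters(1.0, 0.0)


class TestPredict:
    def test_far_point_reverts_to_prior(self, rng):
        train = _random_instance(rng)
        m = fit_gp(train, GPFitConfig(lengthscale=1.0, noise_variance=0.1, standardize=False))
        dist = m.predict_one(np.full(3, 1e6))
        assert dist.mean == pytest.approx(train.Y.mean())
        assert dist.variance == pytest.approx(1.0)

    def test_noise_free_interpolation(self, rng):
        train = _random_instance(rng)
        m = fit_gp(train, GPFitConfig(lengthscale=1.0, noise_variance=1e-10, standardize=False))
        dist = m.predict_one(train.X[3])
        assert abs(dist.mean - train.Y[3]) < 1e-4
        assert dist.variance < 1e-6

    def test_matches_dense_inversion_oracle(self, rng):
        for _ in range(20):
            n, d = int(rng.integers(3, 31)), int(rng.integers(1, 6))
            train = _random_instance(rng, n, d)
            l = float(rng.uniform(0.5, 3))
            s2 = float(rng.uniform(0.01, 1))
            m = fit_gp(train, GPFitConfig(lengthscale=l, noise_variance=s2, standardize=False))
            xs = rng.normal(size=(1, d))
            mu, v = m.predict(xs)
            A = rbf_kernel(train.X, train.X, l) + (s2 + JITTER) * np.eye(n)
            Ainv = np.linalg.inv(A)
            ks = rbf_kernel(xs, train.X, l)
            mu_o = ks @ Ainv @ (train.Y - train.Y.mean()) + train.Y.mean()
            v_o = 1.0 - ks @ Ainv @ ks.T
            assert abs(mu[0] - mu_o[0]) < 1e-8
            assert abs(v[0] - v_o[0, 0]) < 1e-8

    def test_dimension_mismatch_rejected(self, rng):
        m = fit_gp(_random_instance(rng), GPFitConfig(lengthscale=1.0, noise_variance=0.1))
        with pytest.raises(ValueError):
            m.predict(np.zeros((1, 7)))


class TestInvariants:
    def test_adding_training_point_never_increases_variance(self, rng):
        for _ in range(20):
            train = _random_instance(rng, n=10, d=2)
            extra_x = rng.normal(size=2)
            extra_y = rng.normal()
            bigger = TrainingSet(np.vstack([train.X, extra_x]), np.append(train.Y, extra_y))
            cfg = GPFitConfig(lengthscale=1.0, noise_variance=0.1, standardize=False)
            xs = rng.normal(size=(5, 2))
            _, v_small = fit_gp(train, cfg).predict(xs)
            _, v_big = fit_gp(bigger, cfg).predict(xs)
            assert np.all(v_big <= v_small + 1e-10)

    def test_prediction_invariant_to_row_permutation(self, rng):
        train = _random_instance(rng, n=15, d=3)
        perm = rng.permutation(15)
        shuffled = TrainingSet(train.X[perm], train.Y[perm])
        cfg = GPFitConfig(lengthscale=1.2, noise_variance=0.2, standardize=False)
        xs = rng.normal(size=(4, 3))
        mu_a, v_a = fit_gp(train, cfg).predict(xs)
        mu_b, v_b = fit_gp(shuffled, cfg).predict(xs)
        np.testing.assert_allclose(mu_a, mu_b, atol=1e-10)
        np.testing.assert_allclose(v_a, v_b, atol=1e-10)

    def test_standardization_makes_predictions_scale_invariant(self, rng):
        train = _random_instance(rng, n=15, d=3)
        scale = np.array([100.0, 0.01, 5.0])
        shift = np.array([-3.0, 40.0, 0.0])
        rescaled = TrainingSet(train.X * scale + shift, train.Y)
        cfg = GPFitConfig(lengthscale=1.0, noise_variance=0.1, standardize=True)
        xs = rng.normal(size=(4, 3))
        mu_a, v_a = fit_gp(train, cfg).predict(xs)
        mu_b, v_b = fit_gp(rescaled, cfg).predict(xs * scale + shift)
        np.testing.assert_allclose(mu_a, mu_b, atol=1e-8)
        np.testing.assert_allclose(v_a, v_b, atol=1e-8)


def test_serialization_round_trip(tmp_path, rng):
    train = _random_instance(rng)
    m = fit_gp(train, GPFitConfig(lengthscale=1.0, noise_variance=0.1))
    m.save(tmp_path / "model.json")
    m2 = GPModel.load(tmp_path / "model.json", train)
    xs = rng.normal(size=(3, 3))
    np.testing.assert_array_equal(m.predict(xs)[0], m2.predict(xs)[0])
    # wrong training data is refused
    other = _random_instance(rng)
    with pytest.raises(ValueError, match="fingerprint"):
        GPModel.load(tmp_path / "model.json", other)


def test_training_set_validation():
    with pytest.raises(ValueError):
        TrainingSet(np.zeros((3, 2)), np.zeros(4))
    with pytest.raises(ValueError):
        TrainingSet(np.array([[np.nan, 0.0]]), np.zeros(1))
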