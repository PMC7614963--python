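"""Training-loop contracts: determinism, data access, inference routing."""

import numpy as np
import pytest

import selfrecon as sr
from selfrecon.estimators import UnrolledReconstructor
from selfrecon.masks import MaskDistribution, MaskStructure
from selfrecon.oracles import conditional_expectations
from selfrecon.synth import enumerate_toy
from selfrecon.training import lambda_stream_seed, train


@pytest.fixture(scope="module")
def tiny_dataset():
    dist = sr.build_column_density(32, 3.0, center_cols=6, height=32)
    return sr.make_dataset(1, 3, dist, rng_seed=21, n_coils=2)


@pytest.fixture(scope="module")
def tiny_lambda():
    return sr.build_column_density(32, 1.6, center_cols=6, cap_epsilon=1e-3, height=32)


class TestTrainLoop:
    def test_zero_epochs_returns_initial_parameters(self, tiny_dataset, tiny_lambda):
        net = UnrolledReconstructor(n_blocks=2, kernel_size=3, grid_width=32)
        theta0 = net.get_flat_params()
        theta, hist = train(
            "ssdu_1d", tiny_dataset, net, lambda_dist=tiny_lambda, epochs=0
        )
        assert np.array_equal(theta, theta0)
        assert hist.train_loss == []

    def test_same_seed_reproduces_loss_history(self, tiny_dataset, tiny_lambda):
        histories = []
        for _ in range(2):
            net = UnrolledReconstructor(n_blocks=2, kernel_size=3)
            _, hist = train(
                "kweighted_ssdu_1d",
                tiny_dataset,
                net,
                lambda_dist=tiny_lambda,
                epochs=2,
                rng_seed=5,
            )
            histories.append(np.asarray(hist.train_loss))
        assert np.allclose(histories[0], histories[1], rtol=1e-6)

    def test_self_supervised_training_never_reads_ground_truth(
        self, tiny_dataset, tiny_lambda
    ):
        assert tiny_dataset.locked
        net = UnrolledReconstructor(n_blocks=1, kernel_size=3)
        train("ssdu_1d", tiny_dataset, net, lambda_dist=tiny_lambda, epochs=1)
        # the dataset stayed locked throughout
        with pytest.raises(sr.GroundTruthError):
            tiny_dataset.ground_truth(0)

    def test_supervised_training_on_locked_dataset_raises(self, tiny_dataset):
        net = UnrolledReconstructor(n_blocks=1, kernel_size=3)
        with pytest.raises(sr.GroundTruthError):
            train("supervised", tiny_dataset, net, epochs=1)

    def test_uncapped_partition_density_rejected(self, tiny_dataset):
        bad = sr.build_column_density(32, 1.6, center_cols=6, height=32)  # p = 1 centre
        net = UnrolledReconstructor(n_blocks=1, kernel_size=3)
        with pytest.raises(ValueError, match="p < 1"):
            train("ssdu_1d", tiny_dataset, net, lambda_dist=bad, epochs=1)

    def test_lambda_stream_seeds_are_distinct_and_stable(self):
        seeds = {lambda_stream_seed(3, e, s) for e in range(5) for s in range(5)}
        assert len(seeds) == 25
        assert lambda_stream_seed(3, 1, 2) == lambda_stream_seed(3, 1, 2)
        assert all(0 <= s < 2**31 for s in seeds)


class TestReconstructRouting:
    def test_dc_modes_are_exactly_consistent_with_acquired_data(
        self, tiny_dataset, tiny_lambda
    ):
        net = UnrolledReconstructor(n_blocks=2, kernel_size=3, init_scale=0.05, seed=0)
        K = sr.compute_K(tiny_dataset.omega_dist, tiny_lambda)
        y = tiny_dataset.y(0)
        omega = tiny_dataset.omega(0)
        sens = tiny_dataset.sens(0)
        for method in ("unweighted_n2n", "ssdu_1d", "kweighted_ssdu_1d"):
            est = sr.reconstruct(
                method, net, y, omega, sens, K=K, input_mode="tilde",
                lambda_dist=tiny_lambda, rng_seed=1,
            )
            m = omega.astype(bool)
            assert np.array_equal(est[:, m], y[:, m])

    def test_plain_ssdu_returns_wrapped_network_output(self, tiny_dataset, tiny_lambda):
        net = UnrolledReconstructor(n_blocks=2, kernel_size=3)
        y = tiny_dataset.y(0)
        omega = tiny_dataset.omega(0)
        est = sr.reconstruct(
            "ssdu_1d", net, y, omega, tiny_dataset.sens(0), input_mode="singly"
        )
        # zero-initialised network + dc wrap: the estimate is the input itself
        assert np.allclose(est, y)

    def test_unweighted_n2n_with_zero_k_is_identity_on_network_output(self, tiny_dataset):
        # fully sampled acquisition density makes k = 0 everywhere
        ones = MaskDistribution(np.ones((32, 32)), MaskStructure.BERNOULLI_2D)
        half = MaskDistribution(np.full((32, 32), 0.5), MaskStructure.BERNOULLI_2D)
        K = sr.compute_K(ones, half)
        net = UnrolledReconstructor(n_blocks=1, kernel_size=3)
        y = tiny_dataset.y(0)
        est = sr.reconstruct(
            "unweighted_n2n", net, y, tiny_dataset.omega(0), tiny_dataset.sens(0),
            K=K, input_mode="singly",
        )
        # wrapped zero-init network output is y itself, and (1-K)^-1(f - K y) = f
        assert np.allclose(est, y)

    def test_n2n_without_K_raises(self, tiny_dataset):
        net = UnrolledReconstructor(n_blocks=1, kernel_size=3)
        with pytest.raises(ValueError, match="K"):
            sr.reconstruct(
                "unweighted_n2n", net, tiny_dataset.y(0), tiny_dataset.omega(0),
                tiny_dataset.sens(0), input_mode="singly",
            )


class TestSklearnEstimator:
    def test_get_set_params_roundtrip(self):
        model = sr.SelfSupervisedReconstructor(method="ssdu_1d", epochs=3)
        params = model.get_params()
        assert params["method"] == "ssdu_1d"
        model.set_params(epochs=5)
        assert model.epochs == 5

    def test_fit_predict_smoke(self, tiny_dataset):
        model = sr.SelfSupervisedReconstructor(
            method="kweighted_ssdu_1d",
            lambda_accel=1.6,
            lambda_center=6,
            epochs=2,
            n_blocks=2,
            kernel_size=3,
            random_state=0,
        )
        model.fit(tiny_dataset)
        assert model.n_parameters_ == model.network_.n_parameters
        assert len(model.history_.train_loss) == 2
        est = model.predict(
            tiny_dataset.y(0), tiny_dataset.omega(0), tiny_dataset.sens(0)
        )
        assert est.shape == tiny_dataset.y(0).shape
        assert np.all(np.isfinite(est))

    def test_unfitted_predict_raises(self, tiny_dataset):
        model = sr.SelfSupervisedReconstructor()
        with pytest.raises(RuntimeError):
            model.predict(
                tiny_dataset.y(0), tiny_dataset.omega(0), tiny_dataset.sens(0)
            )


class TestLinearToyConvergence:
    def test_trained_toy_estimator_matches_enumerated_conditional(self):
        """An expressive (tabular) estimator fitted on samples of the toy
        ensemble with the identity-weighted loss converges to E[Y|ytilde]."""
        spec = sr.DiscreteToySpec(n=2, alphabet=[1.0], p=[0.5, 0.5], p_tilde=[0.5, 0.5])
        cond = conditional_expectations(spec)
        table = enumerate_toy(spec)
        rng = np.random.default_rng(17)
        draws = rng.choice(len(table.prob), size=60_000, p=table.prob)
        yt = table.ytilde[draws]
        y = table.y[draws]
        # exact minimiser of the sampled unweighted loss: per-pattern mean
        for i, pat in enumerate(cond.patterns):
            sel = np.all(yt == pat, axis=1)
            fitted = y[sel].mean(axis=0)
            assert np.allclose(fitted, cond.e_y[i], rtol=0.02, atol=0.01)
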