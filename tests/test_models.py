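import numpy as np
import pytest

from vitalsentry import (
    AeParams,
    Autoencoder,
    GruAeParams,
    GruAutoencoder,
    TrainConfig,
    ae_forward,
    gru_ae_forward,
    reconstruction_loss,
)
from vitalsentry.exceptions import ConfigurationError, ShapeError
from vitalsentry.gru import GruLayerParams, gru_cell_step
from scipy.special import expit


def zero_layer(d, h):
    return GruLayerParams(
        Wu=np.zeros((h, d)), Wr=np.zeros((h, d)), W=np.zeros((h, d)),
        Uu=np.zeros((h, h)), Ur=np.zeros((h, h)), U=np.zeros((h, h)),
    )


def zero_gru_ae(sizes=(3, 2, 3), channels=2):
    dims = [channels, *sizes]
    layers = [zero_layer(dims[i], dims[i + 1]) for i in range(3)]
    return GruAeParams(layers=layers, Wy=np.zeros((channels, sizes[-1])), by=np.zeros(channels))


class TestGruAeForward:
    def test_zero_params_output_half(self):
        X = np.random.default_rng(0).uniform(0, 1, (5, 2))
        Y, _ = gru_ae_forward(X, zero_gru_ae())
        np.testing.assert_allclose(Y, 0.5)

    def test_output_shape_matches_input(self):
        rng = np.random.default_rng(1)
        p = GruAeParams(
            layers=[
                GruLayerParams.init(2, 4, rng),
                GruLayerParams.init(4, 2, rng),
                GruLayerParams.init(2, 4, rng),
            ],
            Wy=rng.normal(size=(2, 4)), by=np.zeros(2),
        )
        X = rng.uniform(0.1, 0.9, (7, 2))
        Y, states = gru_ae_forward(X, p)
        assert Y.shape == (7, 2)
        assert [s.shape[-1] for s in states] == [4, 2, 4]

    def test_matches_hand_chained_cells(self):
        # unrolled oracle: chain gru_cell_step per layer, then sigmoid head
        rng = np.random.default_rng(2)
        p = GruAeParams(
            layers=[
                GruLayerParams.init(2, 2, rng),
                GruLayerParams.init(2, 1, rng),
                GruLayerParams.init(1, 2, rng),
            ],
            Wy=rng.normal(size=(2, 2)), by=rng.normal(size=2),
        )
        X = rng.uniform(0.1, 0.9, (3, 2))
        Y, _ = gru_ae_forward(X, p)
        h1, h2, h3 = np.zeros(2), np.zeros(1), np.zeros(2)
        for t in range(3):
            h1 = gru_cell_step(X[t], h1, p.layers[0])
            h2 = gru_cell_step(h1, h2, p.layers[1])
            h3 = gru_cell_step(h2, h3, p.layers[2])
            y = expit(p.Wy @ h3 + p.by)
            np.testing.assert_allclose(Y[t], y, rtol=1e-10)

    def test_streaming_state_carryover(self):
        rng = np.random.default_rng(3)
        p = GruAeParams(
            layers=[
                GruLayerParams.init(2, 3, rng),
                GruLayerParams.init(3, 2, rng),
                GruLayerParams.init(2, 3, rng),
            ],
            Wy=rng.normal(size=(2, 3)), by=np.zeros(2),
        )
        X = rng.uniform(0.1, 0.9, (6, 2))
        Y_all, _ = gru_ae_forward(X, p)
        Y1, st = gru_ae_forward(X[:4], p)
        Y2, _ = gru_ae_forward(X[4:], p, states=st)
        np.testing.assert_allclose(np.vstack([Y1, Y2]), Y_all, rtol=1e-12)


class TestReconstructionLoss:
    def test_perfect_reconstruction_zero(self):
        x = np.random.default_rng(0).uniform(size=(4, 2))
        assert reconstruction_loss(x, x).total == 0.0

    def test_unit_error_single_channel(self):
        lt = reconstruction_loss(np.array([[0.0]]), np.array([[1.0]]))
        assert lt.per_timestep[0] == pytest.approx(0.5)

    def test_two_step_hand_value(self):
        x = np.zeros((2, 2))
        y = np.array([[1.0, 0.0], [0.5, 0.5]])
        lt = reconstruction_loss(x, y)
        np.testing.assert_allclose(lt.per_timestep, [0.5, 0.25])
        assert lt.total == pytest.approx(0.75)

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            reconstruction_loss(np.zeros((2, 2)), np.zeros((3, 2)))


class TestGruTraining:
    def test_default_hyperparameters(self):
        m = GruAutoencoder()
        assert m.hidden_sizes == (128, 32, 128)
        assert m.learning_rate == 0.01
        assert m.n_epochs == 4000

    def test_constant_input_learned_by_bias(self):
        X = np.full((8, 12, 2), 0.5)
        m = GruAutoencoder(hidden_sizes=(4, 2, 4), n_epochs=500, random_state=0).fit(X)
        assert m.loss_history_[-1] < 1e-3

    def test_loss_decreases_on_circadian_data(self, tiny_trained):
        gru, _, _ = tiny_trained
        assert gru.loss_history_[-1] < gru.loss_history_[0]

    def test_deterministic_given_seed(self):
        X = np.random.default_rng(0).uniform(0.2, 0.8, (6, 8, 2))
        a = GruAutoencoder(hidden_sizes=(3, 2, 3), n_epochs=10, random_state=5).fit(X)
        b = GruAutoencoder(hidden_sizes=(3, 2, 3), n_epochs=10, random_state=5).fit(X)
        np.testing.assert_array_equal(a.params_.Wy, b.params_.Wy)
        np.testing.assert_array_equal(a.params_.layers[0].W, b.params_.layers[0].W)
        assert a.loss_history_ == b.loss_history_

    def test_reconstructions_in_unit_interval(self, tiny_trained):
        gru, _, wb = tiny_trained
        Y, _ = gru.reconstruct(wb.windows)
        assert Y.min() > 0.0 and Y.max() < 1.0

    def test_invalid_train_config(self):
        with pytest.raises(ConfigurationError):
            TrainConfig(learning_rate=-1.0).validate()
        with pytest.raises(ConfigurationError):
            TrainConfig(epochs=0).validate()


class TestTemporalSensitivity:
    """The central asymmetry: the recurrent model reads order, the baseline cannot."""

    def test_gru_loss_changes_under_shuffle_ae_does_not(self, tiny_trained):
        gru, ae, wb = tiny_trained
        rng = np.random.default_rng(0)
        w = wb.windows[0]
        perm = rng.permutation(len(w))
        assert not np.array_equal(perm, np.arange(len(w)))
        gru_orig = gru.score_samples(w).sum()
        gru_shuf = gru.score_samples(w[perm]).sum()
        assert abs(gru_orig - gru_shuf) > 1e-8
        ae_orig = ae.score_samples(w).sum()
        ae_shuf = ae.score_samples(w[perm]).sum()
        assert ae_orig == pytest.approx(ae_shuf, rel=1e-12)


class TestAutoencoderBaseline:
    def test_zero_params_output_half(self):
        p = AeParams(
            weights=[np.zeros((3, 2)), np.zeros((2, 3)), np.zeros((2, 2))],
            biases=[np.zeros(3), np.zeros(2), np.zeros(2)],
        )
        np.testing.assert_allclose(ae_forward(np.array([0.3, 0.7]), p), 0.5)

    def test_memoryless_permutation_equivariance(self, tiny_trained):
        _, ae, _ = tiny_trained
        X = np.random.default_rng(1).uniform(0.1, 0.9, (20, 2))
        perm = np.random.default_rng(2).permutation(20)
        np.testing.assert_allclose(
            ae.reconstruct(X)[perm], ae.reconstruct(X[perm]), rtol=1e-12
        )

    def test_hand_evaluated_tiny_stack(self):
        W = [np.array([[1.0, -1.0]]), np.array([[2.0]]), np.array([[0.5], [-0.5]])]
        b = [np.array([0.1]), np.array([-0.2]), np.array([0.0, 0.3])]
        p = AeParams(weights=W, biases=b)
        x = np.array([0.6, 0.2])
        a1 = expit(W[0] @ x + b[0])
        a2 = expit(W[1] @ a1 + b[1])
        a3 = expit(W[2] @ a2 + b[2])
        np.testing.assert_allclose(ae_forward(x, p), a3, rtol=1e-12)

    def test_constant_input_near_zero_loss(self):
        X = np.full((200, 2), 0.5)
        m = Autoencoder(hidden_sizes=(4, 2, 4), n_epochs=300, random_state=0).fit(X)
        assert m.loss_history_[-1] < 1e-3

    def test_deterministic_given_seed(self):
        X = np.random.default_rng(0).uniform(0.2, 0.8, (50, 2))
        a = Autoencoder(hidden_sizes=(3, 2, 3), n_epochs=20, random_state=1).fit(X)
        b = Autoencoder(hidden_sizes=(3, 2, 3), n_epochs=20, random_state=1).fit(X)
        for wa, wb_ in zip(a.params_.arrays(), b.params_.arrays()):
            np.testing.assert_array_equal(wa, wb_)


class TestSklearnCompat:
    def test_get_set_params_roundtrip(self):
        m = GruAutoencoder(n_epochs=7)
        params = m.get_params()
        assert params["n_epochs"] == 7
        m2 = GruAutoencoder().set_params(**params)
        assert m2.get_params() == params

    def test_clone(self):
        from sklearn.base import clone

        m = clone(Autoencoder(n_epochs=3, random_state=11))
        assert m.n_epochs == 3 and m.random_state == 11
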