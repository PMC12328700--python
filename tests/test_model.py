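"""Transformer architecture contracts and the hand-coded attention oracle."""

import numpy as np
import pytest
from scipy.special import erf

from trpca import ModelConfig, TrpcaModel
from trpca._autograd import Tensor


def token_norms(seq):
    return np.linalg.norm(seq, axis=-1)


@pytest.fixture()
def small_model():
    cfg = ModelConfig(pca_dim=8, projection_dim=4, nhead=2, attention_width=4,
                      task="regression")
    return TrpcaModel(cfg, seed=0)


class TestProjectMultiview:
    def test_output_shape(self):
        model = TrpcaModel(ModelConfig(pca_dim=256, task="regression"), seed=0)
        x = np.random.default_rng(0).normal(size=(2, 256))
        seq = model.project_multiview(x)
        assert seq.shape == (2, 256, 4)

    def test_tokens_unit_norm(self, small_model, rng):
        seq = small_model.project_multiview(rng.normal(size=(5, 8))).data
        assert np.abs(token_norms(seq) - 1.0).max() < 1e-6

    def test_matches_hand_linear_algebra(self):
        """2 -> 2x2 projection with hand-set weights, checked on paper."""
        cfg = ModelConfig(pca_dim=2, projection_dim=2, nhead=1, attention_width=1,
                          task="regression")
        model = TrpcaModel(cfg, seed=0)
        model.params["proj_w"].data = np.array([[1.0, 0.0, 2.0, 0.0],
                                                [0.0, 1.0, 0.0, -1.0]])
        model.params["proj_b"].data = np.zeros(4)
        out = model.project_multiview(np.array([[3.0, 4.0]])).data[0]
        # pre-norm tokens: [3, 4] and [6, -4]; then unit-normalized
        expected = np.array([[3.0, 4.0] / np.sqrt(25.0),
                             [6.0, -4.0] / np.sqrt(52.0)])
        assert np.allclose(out, expected, atol=1e-12)

    def test_width_mismatch_errors(self, small_model):
        with pytest.raises(ValueError, match="pca_dim"):
            small_model.project_multiview(np.zeros((2, 9)))


class TestNormalizedBlock:
    def test_zero_alphas_give_identity_on_normalized_input(self, small_model, rng):
        seq = small_model.project_multiview(rng.normal(size=(4, 8)))
        blk = small_model.blocks[0]
        blk["alpha_a"].data = np.array(0.0)
        blk["alpha_m"].data = np.array(0.0)
        out = small_model.normalized_block(seq, blk).data
        assert np.abs(out - seq.data).max() < 1e-7

    def test_output_tokens_unit_norm(self, small_model, rng):
        seq = small_model.project_multiview(rng.normal(size=(6, 8)))
        out = small_model.normalized_block(seq, small_model.blocks[0]).data
        assert np.abs(token_norms(out) - 1.0).max() < 1e-5

    def test_matches_hand_coded_attention_mlp_oracle(self, rng):
        """Tiny single-head block against an independent numpy oracle."""
        cfg = ModelConfig(pca_dim=3, projection_dim=2, nhead=1, attention_width=2,
                          task="regression")
        model = TrpcaModel(cfg, seed=7)
        p = model.blocks[0]
        x = rng.normal(size=(2, 3, 2))
        x = x / np.linalg.norm(x, axis=-1, keepdims=True)

        got = model.normalized_block(Tensor(x), p).data

        # -- oracle: plain numpy, no autograd machinery -------------------
        def norm(t):
            return t / np.sqrt((t ** 2).sum(-1, keepdims=True) + 1e-12)

        def gelu_np(t):
            return 0.5 * t * (1 + erf(t / np.sqrt(2)))

        up = x @ p["up_w"].data + p["up_b"].data
        q = up @ p["q_w"].data + p["q_b"].data
        k = up @ p["k_w"].data + p["k_b"].data
        v = up @ p["v_w"].data + p["v_b"].data
        att = np.empty_like(q)
        for b in range(x.shape[0]):
            scores = q[b] @ k[b].T / np.sqrt(2.0)  # head_dim = width / nhead = 2
            w = np.exp(scores - scores.max(axis=1, keepdims=True))
            w = w / w.sum(axis=1, keepdims=True)
            att[b] = w @ v[b]
        att = (att @ p["o_w"].data + p["o_b"].data) @ p["down_w"].data + p["down_b"].data
        h_a = norm(x + p["alpha_a"].data * (att - x))
        mlp = gelu_np(h_a @ p["mlp1_w"].data + p["mlp1_b"].data) @ p["mlp2_w"].data \
            + p["mlp2_b"].data
        expected = norm(h_a + p["alpha_m"].data * (mlp - h_a))
        assert np.abs(got - expected).max() < 1e-6

    def test_norms_hold_after_every_block(self, rng):
        cfg = ModelConfig(pca_dim=8, projection_dim=4, num_transformer_layers=3,
                          task="regression")
        model = TrpcaModel(cfg, seed=1)
        seq = model.project_multiview(rng.normal(size=(5, 8)))
        for blk in model.blocks:
            seq = model.normalized_block(seq, blk)
            assert np.abs(token_norms(seq.data) - 1.0).max() < 1e-5


class TestPoolAndForward:
    def test_pool_constant_tokens(self, small_model):
        seq = Tensor(np.full((2, 8, 4), 3.25))
        assert np.allclose(small_model.pool(seq).data, 3.25)

    def test_pool_shape_and_arithmetic(self):
        model = TrpcaModel(ModelConfig(pca_dim=256, task="regression"), seed=0)
        seq = Tensor(np.zeros((2, 256, 4)))
        assert model.pool(seq).shape == (2, 256)
        one = Tensor(np.array([[[1.0, 3.0]]]))
        small = TrpcaModel(ModelConfig(pca_dim=1, projection_dim=2, nhead=1,
                                       task="regression"), seed=0)
        assert small.pool(one).data[0, 0] == 2.0

    def test_pool_sequence_axis_option(self):
        cfg = ModelConfig(pca_dim=8, projection_dim=4, pool_axis="sequence",
                          task="regression")
        model = TrpcaModel(cfg, seed=0)
        assert model.pool(Tensor(np.zeros((3, 8, 4)))).shape == (3, 4)

    def test_forward_shapes_and_determinism(self, rng):
        reg = TrpcaModel(ModelConfig(pca_dim=8, task="regression"), seed=0)
        x = rng.normal(size=(1, 8))
        two = np.vstack([x, x])
        out = reg.forward(two).data
        assert out.shape == (2, 1)
        assert np.array_equal(out[0], out[1])
        cls = TrpcaModel(ModelConfig(pca_dim=8, task="classification",
                                     n_classes=5), seed=0)
        assert cls.forward(two).data.shape == (2, 5)

    def test_forward_reproducible_across_fresh_models(self, rng):
        x = rng.normal(size=(4, 8))
        a = TrpcaModel(ModelConfig(pca_dim=8, task="regression"), seed=42)
        b = TrpcaModel(ModelConfig(pca_dim=8, task="regression"), seed=42)
        assert np.array_equal(a.forward(x).data, b.forward(x).data)

    def test_zero_layers_reduces_to_closed_form(self, rng):
        """With no transformer blocks the network is head(pool(norm(proj(x))))."""
        cfg = ModelConfig(pca_dim=6, projection_dim=3, num_transformer_layers=0,
                          nhead=1, task="regression")
        model = TrpcaModel(cfg, seed=5)
        x = rng.normal(size=(4, 6))
        got = model.forward(x).data
        h = x @ model.params["proj_w"].data + model.params["proj_b"].data
        h = h.reshape(4, 6, 3)
        h = h / np.sqrt((h ** 2).sum(-1, keepdims=True) + 1e-12)
        pooled = h.mean(axis=2)
        expected = pooled @ model.params["reg_w"].data + model.params["reg_b"].data
        assert np.allclose(got, expected, atol=1e-12)


class TestMtl:
    def test_output_shapes(self, rng):
        cfg = ModelConfig(pca_dim=8, task="mtl", n_classes=4)
        model = TrpcaModel(cfg, seed=0)
        logits, ages = model.forward_mtl(rng.normal(size=(3, 8)))
        assert logits.shape == (3, 4)
        assert ages.shape == (3, 1)

    def test_gradients_reach_both_heads(self, rng):
        cfg = ModelConfig(pca_dim=8, task="mtl", n_classes=3)
        model = TrpcaModel(cfg, seed=0)
        logits, ages = model.forward_mtl(rng.normal(size=(4, 8)))
        loss = (logits * logits).mean() + (ages * ages).mean()
        loss.backward()
        assert model.params["cls_w"].grad is not None
        assert np.abs(model.params["cls_w"].grad).max() > 0
        assert model.params["reg_w"].grad is not None
        assert np.abs(model.params["reg_w"].grad).max() > 0

    def test_task_head_mismatch_errors(self, rng):
        reg = TrpcaModel(ModelConfig(pca_dim=8, task="regression"), seed=0)
        with pytest.raises(ValueError, match="forward_mtl"):
            reg.forward_mtl(rng.normal(size=(2, 8)))
        mtl = TrpcaModel(ModelConfig(pca_dim=8, task="mtl", n_classes=2), seed=0)
        with pytest.raises(ValueError, match="mtl"):
            mtl.forward(rng.normal(size=(2, 8)))


def test_config_validation():
    with pytest.raises(ValueError, match="divisible"):
        ModelConfig(attention_width=6, nhead=4)
    with pytest.raises(ValueError, match="n_classes"):
        ModelConfig(task="classification", n_classes=0)
    assert ModelConfig().attention_width == 8  # nhead x head_dim 1


def test_save_load_round_trip(tmp_path, rng):
    model = TrpcaModel(ModelConfig(pca_dim=8, task="regression"), seed=3)
    x = rng.normal(size=(3, 8))
    before = model.forward(x).data
    model.save(tmp_path / "ckpt")
    back = TrpcaModel.load(tmp_path / "ckpt")
    assert np.array_equal(back.forward(x).data, before)
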