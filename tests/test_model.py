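import numpy as np
import pytest

from coscreen.errors import ConfigError, DataError, IntegrityError
from coscreen.featurizers import ResidueEmbeddingMatrix
from coscreen.model import (
    AttentionMap,
    CoEmbedding,
    DTICoEmbedder,
    ModelConfig,
    attention_pool,
    bce_loss,
    co_embed_drug,
    co_embed_target,
    interaction_probability,
    load_model,
    mse_loss,
    predict_affinity,
    save_model,
)
from coscreen.model.layers import AttentionPooler, pad_stack


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def make_pooler(E=16, H=4, dk=8, dv=8, seed=0, merge="concat"):
    rng = np.random.default_rng(seed)
    return AttentionPooler(E, H, dk, dv, rng, head_merge=merge)


class TestAttentionPool:
    def test_single_residue_attention_is_one(self):
        pooler = make_pooler()
        mat = ResidueEmbeddingMatrix("t", np.random.default_rng(1).normal(size=(1, 16)), "p")
        _, amap = attention_pool(mat, pooler)
        assert np.allclose(amap.weights, 1.0)

    def test_identical_rows_give_uniform_attention(self):
        pooler = make_pooler()
        row = np.random.default_rng(2).normal(size=16)
        mat = ResidueEmbeddingMatrix("t", np.tile(row, (7, 1)), "p")
        _, amap = attention_pool(mat, pooler)
        assert np.allclose(amap.weights, 1.0 / 7)

    @pytest.mark.parametrize("L", [1, 2, 10, 500])
    def test_rows_sum_to_one(self, L, rng):
        pooler = make_pooler()
        mat = ResidueEmbeddingMatrix("t", rng.normal(size=(L, 16)), "p")
        _, amap = attention_pool(mat, pooler)
        assert np.allclose(amap.weights.sum(axis=1), 1.0, atol=1e-6)

    def test_permutation_equivariance(self, rng):
        pooler = make_pooler()
        values = rng.normal(size=(12, 16))
        perm = rng.permutation(12)
        pooled_a, amap_a = attention_pool(ResidueEmbeddingMatrix("t", values, "p"), pooler)
        pooled_b, amap_b = attention_pool(
            ResidueEmbeddingMatrix("t", values[perm], "p"), pooler
        )
        assert np.allclose(pooled_a, pooled_b, atol=1e-12)
        assert np.allclose(amap_b.weights, amap_a.weights[:, perm], atol=1e-12)

    def test_empty_rejected(self):
        pooler = make_pooler()
        with pytest.raises(DataError):
            attention_pool(ResidueEmbeddingMatrix("t", np.zeros((0, 16)), "p"), pooler)

    def test_mean_merge_width(self, rng):
        pooler = make_pooler(merge="mean")
        mat = ResidueEmbeddingMatrix("t", rng.normal(size=(5, 16)), "p")
        pooled, _ = attention_pool(mat, pooler)
        assert pooled.shape == (8,)

    def test_padding_receives_no_attention(self, rng):
        pooler = make_pooler()
        mats = [rng.normal(size=(3, 16)), rng.normal(size=(9, 16))]
        Mb, mask = pad_stack(mats)
        _, attn, _ = pooler.forward(Mb, mask)
        assert np.all(attn[0, :, 3:] == 0.0)
        assert np.allclose(attn.sum(axis=2), 1.0, atol=1e-6)


class TestAttentionMapType:
    def test_rejects_unnormalized(self):
        with pytest.raises(DataError, match="sum to 1"):
            AttentionMap("t", np.array([[0.5, 0.2]]))

    def test_rejects_negative(self):
        with pytest.raises(DataError):
            AttentionMap("t", np.array([[1.5, -0.5]]))


class TestScoringHeads:
    def test_orthogonal_gives_half(self):
        zd = CoEmbedding("d", np.array([1.0, 0.0]))
        zt = CoEmbedding("t", np.array([0.0, 1.0]))
        assert interaction_probability(zd, zt) == pytest.approx(0.5)

    def test_parallel_alpha5(self):
        # independent oracle: 1 / (1 + e^-5)
        z = np.array([0.3, -1.2, 0.5])
        p = interaction_probability(z, z, alpha=5.0)
        assert p == pytest.approx(1.0 / (1.0 + np.exp(-5.0)), abs=1e-12)
        assert p == pytest.approx(0.9933071, abs=1e-6)

    def test_antiparallel_and_symmetry(self):
        z = np.array([0.3, -1.2, 0.5])
        p_anti = interaction_probability(z, -z, alpha=5.0)
        assert p_anti == pytest.approx(0.0066929, abs=1e-6)
        assert p_anti + interaction_probability(z, z, alpha=5.0) == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=8)
        assert interaction_probability(2 * a, b) == pytest.approx(
            interaction_probability(a, b), abs=1e-12
        )
        assert interaction_probability(a, 0.1 * b) == pytest.approx(
            interaction_probability(a, b), abs=1e-12
        )

    def test_zero_vector_rejected(self):
        with pytest.raises(DataError):
            interaction_probability(np.zeros(3), np.ones(3))

    def test_probability_bounds_random_pairs(self, rng):
        lo, hi = sigmoid(-5), sigmoid(5)
        for _ in range(1000):
            a, b = rng.normal(size=16), rng.normal(size=16)
            p = interaction_probability(a, b, alpha=5.0)
            assert lo <= p <= hi

    def test_cosine_monotonicity(self, rng):
        pairs = [(rng.normal(size=8), rng.normal(size=8)) for _ in range(100)]
        cosines = [float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b))) for a, b in pairs]
        probs = [interaction_probability(a, b) for a, b in pairs]
        assert np.array_equal(np.argsort(cosines), np.argsort(probs))

    def test_affinity_examples(self):
        assert predict_affinity(np.zeros(4), np.ones(4)) == 0.0
        assert predict_affinity(np.array([1.0, 2.0]), np.array([3.0, -1.0])) == 1.0

    def test_affinity_bilinearity(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=8)
        assert predict_affinity(2 * a, b) == pytest.approx(2 * predict_affinity(a, b))
        assert predict_affinity(a, 3 * b) == pytest.approx(3 * predict_affinity(a, b))

    def test_width_mismatch(self):
        with pytest.raises(DataError):
            predict_affinity(np.ones(3), np.ones(4))


class TestLosses:
    def test_bce_half(self):
        assert bce_loss(np.full(5, 0.5), np.array([1, 0, 1, 1, 0])) == pytest.approx(
            np.log(2), abs=1e-12
        )

    def test_bce_perfect(self):
        p = np.array([1.0, 0.0, 1.0])
        y = np.array([1, 0, 1])
        assert bce_loss(p, y) <= 1e-6

    def test_bce_derived_single(self):
        assert bce_loss(np.array([0.25]), np.array([1])) == pytest.approx(
            -np.log(0.25), abs=1e-12
        )

    def test_bce_errors(self):
        with pytest.raises(DataError):
            bce_loss(np.array([0.5]), np.array([0.5]))
        with pytest.raises(DataError):
            bce_loss(np.array([0.5, 0.5]), np.array([1]))

    def test_mse(self):
        assert mse_loss(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0
        assert mse_loss(np.zeros(2), np.ones(2)) == 1.0
        assert mse_loss(np.array([3.0]), np.array([1.0])) == 4.0
        with pytest.raises(DataError):
            mse_loss(np.zeros(2), np.zeros(3))


class TestProjections:
    def test_determinism(self, small_model, rng):
        fp = (rng.random(64) > 0.5).astype(float)
        a = co_embed_drug(fp, small_model)
        b = co_embed_drug(fp, small_model)
        assert np.array_equal(a.vector, b.vector)
        assert a.vector.shape == (32,)

    def test_wrong_width_rejected(self, small_model):
        with pytest.raises(DataError, match="64"):
            co_embed_drug(np.ones(100), small_model)

    def test_target_projection_from_matrix(self, small_model, rng):
        mat = ResidueEmbeddingMatrix("t", rng.normal(size=(20, 32)), "p")
        z = co_embed_target(mat, small_model)
        assert z.vector.shape == (32,)
        assert z.owner_id == "t"

    def test_same_seed_identical_weights(self):
        cfg = ModelConfig(n_bits=32, embed_width=16, d=8, seed=42)
        a, b = DTICoEmbedder(cfg), DTICoEmbedder(cfg)
        for pa, pb in zip(a.params, b.params):
            assert np.array_equal(pa, pb)

    def test_normalized_flag_contract(self):
        z = CoEmbedding("x", np.array([3.0, 4.0])).unit()
        assert z.normalized and np.isclose(np.linalg.norm(z.vector), 1.0)
        with pytest.raises(DataError):
            CoEmbedding("x", np.array([3.0, 4.0]), normalized=True)


class TestGradients:
    def test_bce_gradient_finite_difference(self, small_model, rng):
        """Analytic gradient of the classification loss w.r.t. a projection
        weight matches central finite differences on a 5-pair batch."""
        from coscreen.training.fit import _classify_head_backward

        model = small_model
        X = (rng.random((5, 64)) > 0.5).astype(float)
        mats = [rng.normal(size=(int(rng.integers(4, 10)), 32)) for _ in range(5)]
        y = np.array([1.0, 0.0, 1.0, 1.0, 0.0])

        def loss_value():
            zd, _ = model.embed_drugs(X)
            zt, _, _, _ = model.embed_targets(mats)
            loss, _, _, _ = _classify_head_backward(zd, zt, y, model.config.alpha)
            return loss

        model.zero_grad()
        zd, d_cache = model.embed_drugs(X)
        zt, _, _, t_cache = model.embed_targets(mats)
        _, g_zd, g_zt, _ = _classify_head_backward(zd, zt, y, model.config.alpha)
        model.drug_net.backward(g_zd, d_cache)
        model.backward_targets(g_zt, t_cache)

        # probe several parameters across drug net, target net, and pooler
        checks = [
            (model.drug_net.layers[0].W, model.drug_net.layers[0].gW, (3, 5)),
            (model.target_net.layers[-1].W, model.target_net.layers[-1].gW, (0, 1)),
            (model.pooler.q, model.pooler.gq, (1, 2)),
            (model.pooler.Wk, model.pooler.gWk, (0, 3, 1)),
            (model.pooler.Wv, model.pooler.gWv, (2, 4, 0)),
        ]
        eps = 1e-6
        for param, grad, idx in checks:
            orig = param[idx]
            param[idx] = orig + eps
            up = loss_value()
            param[idx] = orig - eps
            down = loss_value()
            param[idx] = orig
            numeric = (up - down) / (2 * eps)
            assert numeric == pytest.approx(grad[idx], rel=1e-4, abs=1e-8)

    def test_mse_gradient_finite_difference(self, small_model, rng):
        from coscreen.training.fit import _regress_head_backward

        model = small_model
        X = (rng.random((4, 64)) > 0.5).astype(float)
        mats = [rng.normal(size=(6, 32)) for _ in range(4)]
        y = rng.normal(size=4)

        def loss_value():
            zd, _ = model.embed_drugs(X)
            zt, _, _, _ = model.embed_targets(mats)
            loss, _, _, _ = _regress_head_backward(zd, zt, y)
            return loss

        model.zero_grad()
        zd, d_cache = model.embed_drugs(X)
        zt, _, _, t_cache = model.embed_targets(mats)
        _, g_zd, g_zt, _ = _regress_head_backward(zd, zt, y)
        model.drug_net.backward(g_zd, d_cache)
        model.backward_targets(g_zt, t_cache)

        param, grad, idx = model.drug_net.layers[1].W, model.drug_net.layers[1].gW, (2, 2)
        eps = 1e-6
        orig = param[idx]
        param[idx] = orig + eps
        up = loss_value()
        param[idx] = orig - eps
        down = loss_value()
        param[idx] = orig
        assert (up - down) / (2 * eps) == pytest.approx(grad[idx], rel=1e-4, abs=1e-8)


class TestSerialization:
    def test_round_trip_scores_bitwise(self, small_model, tmp_path, rng):
        path = tmp_path / "model.npz"
        save_model(small_model, path)
        loaded = load_model(path)
        X = (rng.random((10, 64)) > 0.5).astype(float)
        mats = [rng.normal(size=(8, 32)) for _ in range(10)]
        zd_a, _ = small_model.embed_drugs(X)
        zd_b, _ = loaded.embed_drugs(X)
        zt_a, _, _, _ = small_model.embed_targets(mats)
        zt_b, _, _, _ = loaded.embed_targets(mats)
        assert np.array_equal(
            small_model.score_pairs(zd_a, zt_a), loaded.score_pairs(zd_b, zt_b)
        )
        assert loaded.config == small_model.config

    def test_truncated_file(self, small_model, tmp_path):
        path = tmp_path / "model.npz"
        save_model(small_model, path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(IntegrityError):
            load_model(path)

    def test_missing_alpha_is_error(self, small_model, tmp_path):
        import json

        path = tmp_path / "model.npz"
        save_model(small_model, path)
        with np.load(path) as data:
            arrays = {k: data[k] for k in data.files}
        config = json.loads(str(arrays["__config__"]))
        del config["alpha"]
        arrays["__config__"] = np.array(json.dumps(config))
        np.savez(path, **arrays)
        with pytest.raises(ConfigError, match="alpha"):
            load_model(path)

    def test_version_mismatch(self, small_model, tmp_path):
        path = tmp_path / "model.npz"
        save_model(small_model, path)
        with np.load(path) as data:
            arrays = {k: data[k] for k in data.files}
        arrays["__format_version__"] = np.array(99)
        np.savez(path, **arrays)
        with pytest.raises(IntegrityError, match="99"):
            load_model(path)


class TestConfig:
    def test_alpha_positive(self):
        with pytest.raises(ConfigError):
            ModelConfig(alpha=0.0)

    def test_depths_restricted(self):
        with pytest.raises(ConfigError):
            ModelConfig(drug_depth=2)
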