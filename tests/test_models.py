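"""Dual-encoder components and contrastive-loss analytics."""

import numpy as np
import pytest

from eegtext.autodiff import Tensor
from eegtext.models import (
    ContrastiveBatch,
    DualEncoderModel,
    EmbeddingTextEncoder,
    HashingTextEncoder,
    ProjectionHead,
    contrastive_loss,
    cosine_similarity_matrix,
    eeg_encode,
    info_nce,
    l2_normalize,
    load_checkpoint,
    project,
    save_checkpoint,
    text_encode,
)

WIDTHS = (6, 6, 12, 24, 48)  # narrow encoder keeps unit tests quick


@pytest.fixture(scope="module")
def model():
    return DualEncoderModel(HashingTextEncoder(dim=64), widths=WIDTHS,
                            head_hidden_dim=32, seed=0)


class TestLossAnalytics:
    @pytest.mark.parametrize("n", [2, 4, 64])
    def test_uniform_similarities_give_log_n(self, n):
        loss = info_nce(np.zeros((n, n)), tau=1.0)
        assert float(loss.data) == pytest.approx(np.log(n), abs=1e-6)

    def test_saturated_diagonal_near_zero(self):
        sim = np.full((8, 8), -10.0)
        np.fill_diagonal(sim, 10.0)
        assert float(info_nce(sim, tau=1.0).data) < 1e-6

    def test_identity_sim_two_pairs_one_direction(self):
        # per-row: -log(e / (e + 1)) = log(1 + e^-1) = 0.313262..
        loss = info_nce(np.eye(2), tau=1.0, symmetric=False)
        assert float(loss.data) == pytest.approx(0.3132617, abs=1e-6)

    def test_nonnegative_and_bounded_by_log_n(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            sim = rng.normal(size=(6, 6))
            sim += np.diag(np.abs(rng.normal(size=6)))  # favour the diagonal
            val = float(info_nce(sim, tau=0.5).data)
            assert val >= 0.0
            assert float(info_nce(np.zeros((6, 6)), 0.5).data) == pytest.approx(
                np.log(6), abs=1e-9)

    def test_decreasing_in_diagonal_similarity(self):
        rng = np.random.default_rng(1)
        sim = rng.normal(size=(5, 5))
        lo = float(info_nce(sim, tau=1.0).data)
        boosted = sim + np.eye(5) * 0.5
        assert float(info_nce(boosted, tau=1.0).data) < lo

    def test_symmetric_loss_invariant_to_modality_swap(self):
        rng = np.random.default_rng(2)
        sim = rng.normal(size=(7, 7))
        a = float(info_nce(sim, tau=0.3, symmetric=True).data)
        b = float(info_nce(sim.T, tau=0.3, symmetric=True).data)
        assert a == pytest.approx(b, rel=1e-12)

    def test_temperature_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        sim = rng.normal(size=(6, 6))
        for c in (0.1, 3.0, 17.0):
            a = float(info_nce(sim, tau=0.7).data)
            b = float(info_nce(sim * c, tau=0.7 * c).data)
            assert a == pytest.approx(b, rel=1e-9)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        sim = rng.normal(size=(5, 5))
        t = Tensor(sim.copy(), requires_grad=True)
        info_nce(t, tau=0.6).backward()
        eps = 1e-6
        for i in range(5):
            for j in range(5):
                hi, lo = sim.copy(), sim.copy()
                hi[i, j] += eps
                lo[i, j] -= eps
                num = (float(info_nce(hi, 0.6).data)
                       - float(info_nce(lo, 0.6).data)) / (2 * eps)
                assert t.grad[i, j] == pytest.approx(
                    num, rel=1e-4, abs=1e-8)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match="negatives"):
            info_nce(np.ones((1, 1)), tau=1.0)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            info_nce(np.zeros((3, 3)), tau=0.0)

    def test_batch_wrapper(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(4, 8))
        batch = ContrastiveBatch(x=x, y=x, tau=1.0)
        assert contrastive_loss(batch) < np.log(4)
        np.testing.assert_allclose(np.diag(batch.sim), 1.0, atol=1e-12)

    def test_batch_rejects_bad_temperature(self):
        with pytest.raises(ValueError):
            ContrastiveBatch(x=np.ones((2, 3)), y=np.ones((2, 3)), tau=-1.0)


class TestEEGEncoder:
    def test_output_shape_and_finite(self, model):
        windows = np.random.default_rng(0).normal(
            size=(4, 21, 1200)).astype(np.float32)
        out = eeg_encode(windows, model)
        assert out.shape == (4, 128)
        assert np.isfinite(out).all()

    def test_duplicated_rows_give_duplicated_embeddings(self, model):
        rng = np.random.default_rng(1)
        w = rng.normal(size=(1, 21, 1200)).astype(np.float32)
        windows = np.concatenate([w, w])
        out = eeg_encode(windows, model)
        np.testing.assert_array_equal(out[0], out[1])

    def test_impulse_sensitivity(self, model):
        zero = np.zeros((1, 21, 1200), dtype=np.float32)
        impulse = zero.copy()
        impulse[0, 10, 600] = 5.0
        a = eeg_encode(zero, model)
        b = eeg_encode(impulse, model)
        assert not np.allclose(a, b)

    def test_wrong_shape_rejected(self, model):
        with pytest.raises(ValueError, match="21, 1200"):
            eeg_encode(np.zeros((2, 20, 1200), dtype=np.float32), model)


class TestTextEncoders:
    def test_hashing_row_per_string(self):
        enc = HashingTextEncoder(dim=32)
        out = text_encode(["This is a normal recording"], enc)
        assert out.shape == (1, 32)

    def test_identical_strings_equal_rows(self):
        enc = HashingTextEncoder(dim=32)
        out = text_encode(["a", "a"], enc)
        np.testing.assert_array_equal(out[0], out[1])

    def test_disjoint_vocab_rows_differ(self):
        enc = HashingTextEncoder(dim=64)
        words_a = "alpha rhythm posterior symmetric"
        words_b = "spike discharge temporal lateralized"
        out = text_encode([words_a, words_b], enc)
        assert not np.allclose(out[0], out[1])

    def test_empty_list_gives_empty_embedding(self):
        enc = HashingTextEncoder(dim=16)
        assert text_encode([], enc).shape == (0, 16)

    def test_overlength_truncated_with_warning(self):
        enc = HashingTextEncoder(dim=16, max_tokens=4)
        with pytest.warns(UserWarning, match="truncated"):
            text_encode(["one two three four five six"], enc)

    def test_hashing_deterministic_across_instances(self):
        a = text_encode(["keppra given"], HashingTextEncoder(dim=32, seed=3))
        b = text_encode(["keppra given"], HashingTextEncoder(dim=32, seed=3))
        np.testing.assert_array_equal(a, b)

    def test_embedding_encoder_trainable_and_batch_safe(self):
        enc = EmbeddingTextEncoder(dim=16, vocab_size=128, seed=0)
        assert len(enc.parameters()) == 1
        out = enc.encode(["short", "a much longer string of tokens"])
        assert out.shape == (2, 16)
        out.sum().backward()
        assert enc.table.grad is not None
        # padding row receives no gradient
        np.testing.assert_array_equal(enc.table.grad[-1], 0.0)


class TestProjection:
    def test_unit_norm_rows(self):
        head = ProjectionHead(16, 64, seed=0)
        rng = np.random.default_rng(0)
        out = project(rng.normal(size=(5, 16)), head)
        np.testing.assert_allclose(np.linalg.norm(out.data, axis=1), 1.0,
                                   atol=1e-5)

    def test_zero_vector_fallback_warns(self):
        with pytest.warns(UserWarning, match="zero-norm"):
            out = l2_normalize(Tensor(np.zeros((2, 4))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_configurable_projection_dim(self):
        model = DualEncoderModel(HashingTextEncoder(dim=32), widths=WIDTHS,
                                 projection_dim=128, head_hidden_dim=32, seed=0)
        w = np.random.default_rng(0).normal(size=(2, 21, 1200)).astype(np.float32)
        model.eval()
        assert model.encode_eeg(w).data.shape == (2, 128)
        assert model.encode_text(["x"]).data.shape == (1, 128)

    def test_cosine_matrix_is_cosine(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(3, 5)), rng.normal(size=(3, 5))
        sim = cosine_similarity_matrix(x, y).data
        expected = (x / np.linalg.norm(x, axis=1, keepdims=True)) @ \
                   (y / np.linalg.norm(y, axis=1, keepdims=True)).T
        np.testing.assert_allclose(sim, expected, atol=1e-12)


class TestCheckpoint:
    def test_metadata_includes_montage_and_preprocessing(self, tmp_path, model):
        import json
        path = tmp_path / "meta.npz"
        save_checkpoint(model, path)
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
        assert len(meta["montage"]) == 21
        assert meta["preprocessing"]["window_stride"] == 519
        assert meta["preprocessing"]["divisor"] == 30.0
        assert meta["version"] == 1

    def test_round_trip(self, tmp_path, model):
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path, extra={"note": 1})
        restored, extra = load_checkpoint(path)
        assert extra == {"note": 1}
        w = np.random.default_rng(2).normal(size=(3, 21, 1200)).astype(np.float32)
        model.eval()
        restored.eval()
        np.testing.assert_allclose(eeg_encode(w, model), eeg_encode(w, restored),
                                   atol=1e-6)
        texts = ["beta spindles", "normal alpha"]
        np.testing.assert_allclose(model.encode_text(texts).data,
                                   restored.encode_text(texts).data, atol=1e-6)
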