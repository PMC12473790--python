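"""Attention encoders, fusion, classifier, stage-2 training loop."""

import numpy as np
import pytest

from cate import nn
from cate.data import make_transfer_task
from cate.finetune import (
    AttentionParams,
    DualEncoderModel,
    EncoderParams,
    FinetuneConfig,
    classify,
    clip_gradients,
    cross_entropy,
    fuse,
    init_model,
    multi_head_attention,
    nerm_encode,
    predict,
    run_finetuning,
    wtrm_encode,
)
from cate.pretrain import init_extractor
from cate.synth import SynthConfig, generate_corpus


def attn(rng, d=8, h=2, identity=False):
    mk = (lambda: np.eye(d)) if identity else (lambda: rng.normal(size=(d, d)))
    return AttentionParams(W_Q=mk(), W_K=mk(), W_V=mk(), W_O=mk(), h=h)


def naive_mha(H, p):
    """Per-head loop oracle for multi-head attention."""
    B, L, D = H.shape
    dk = D // p.h
    out = np.zeros_like(H)
    for b in range(B):
        Q, K, V = H[b] @ p.W_Q, H[b] @ p.W_K, H[b] @ p.W_V
        heads = []
        for i in range(p.h):
            q, k, v = (m[:, i * dk : (i + 1) * dk] for m in (Q, K, V))
            s = q @ k.T / np.sqrt(dk)
            a = np.exp(s - s.max(axis=1, keepdims=True))
            a /= a.sum(axis=1, keepdims=True)
            heads.append(a @ v)
        out[b] = np.concatenate(heads, axis=1) @ p.W_O
    return out


class TestMultiHeadAttention:
    def test_single_token_degeneracy(self, rng):
        # softmax over one key is 1: output = H W_V W_O for any Q/K weights
        p = attn(rng)
        H = rng.normal(size=(5, 1, 8))
        out = multi_head_attention(H, p)
        assert np.abs(out - H @ p.W_V @ p.W_O).max() < 1e-6

    def test_identity_projections_single_token(self, rng):
        p = attn(rng, identity=True)
        H = rng.normal(size=(3, 1, 8))
        assert np.allclose(multi_head_attention(H, p), H)

    def test_matches_naive_loop_oracle(self, rng):
        p = attn(rng, h=4)
        H = rng.normal(size=(4, 3, 8))
        assert np.abs(multi_head_attention(H, p) - naive_mha(H, p)).max() < 1e-6

    def test_dim_mismatch(self, rng):
        with pytest.raises(ValueError):
            multi_head_attention(rng.normal(size=(2, 1, 6)), attn(rng, d=8))

    def test_head_divisibility_enforced(self, rng):
        with pytest.raises(ValueError):
            AttentionParams(
                W_Q=np.eye(6), W_K=np.eye(6), W_V=np.eye(6), W_O=np.eye(6), h=4
            )


def _encoder(rng, d=8, with_ffn=False, alpha=0.1, zero_ffn=False):
    enc = EncoderParams(
        backbone={}, attention=attn(rng, d=d), alpha=alpha, dropout_rate=0.0
    )
    if with_ffn:
        enc.ffn_W1 = np.zeros((d, 4 * d)) if zero_ffn else rng.normal(size=(d, 4 * d))
        enc.ffn_W2 = np.zeros((4 * d, d)) if zero_ffn else rng.normal(size=(4 * d, d))
    return enc


class TestEncoders:
    def test_nerm_alpha_zero_is_double_layernorm(self, rng):
        enc = _encoder(rng, alpha=0.0)
        H = rng.normal(size=(4, 1, 8))
        expected = nn.layer_norm(nn.tmean(nn.layer_norm(nn.as_tensor(H)), axis=1)).data
        assert np.allclose(nerm_encode(H, enc), expected)

    def test_layernorm_contract_on_output(self, rng):
        z = nerm_encode(rng.normal(size=(6, 1, 8)), _encoder(rng))
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-10)
        assert np.allclose(z.var(axis=1), 1.0, atol=1e-4)  # eps-damped unit variance

    def test_wtrm_zero_ffn_residual_identity(self, rng):
        # FFN with zero weights leaves H1 untouched; only the extra
        # LayerNorm stage separates the two encoder outputs
        enc = _encoder(rng, with_ffn=True, zero_ffn=True)
        H = rng.normal(size=(4, 1, 8))
        H1 = nn.layer_norm(nn.as_tensor(H) + nn.as_tensor(multi_head_attention(H, enc.attention)) * 0.1)
        expected = nn.layer_norm(nn.tmean(nn.layer_norm(H1), axis=1)).data
        assert np.allclose(wtrm_encode(H, enc), expected)

    def test_eval_mode_deterministic(self, rng):
        enc = _encoder(rng, with_ffn=True)
        H = rng.normal(size=(3, 1, 8))
        assert np.array_equal(wtrm_encode(H, enc), wtrm_encode(H, enc))


class TestFuseAndClassify:
    def test_fuse_cases(self):
        z = np.array([[1.0, 3.0]])
        assert np.array_equal(fuse(z, z), z)
        assert np.array_equal(fuse(z, -z), np.zeros((1, 2)))
        assert np.array_equal(fuse(np.array([[1.0, 3.0]]), np.array([[3.0, 1.0]])), [[2.0, 2.0]])
        with pytest.raises(ValueError):
            fuse(np.zeros((1, 2)), np.zeros((2, 1)))

    def test_zero_output_layer_gives_bias_logits(self, rng):
        model = DualEncoderModel(
            nerm_encoder=None,
            wtrm_encoder=None,
            cls_W1=rng.normal(size=(8, 4)),
            cls_b1=np.zeros(4),
            cls_W2=np.zeros((4, 3)),
            cls_b2=np.array([0.5, -1.0, 2.0]),
        )
        logits = classify(rng.normal(size=(6, 8)), model)
        assert np.allclose(logits, model.cls_b2[None, :])


class TestCrossEntropy:
    def test_uniform_logits(self):
        assert cross_entropy(np.zeros((4, 3)), np.zeros(4, int)) == pytest.approx(
            np.log(3), abs=1e-10
        )

    def test_confident_correct_limit(self):
        logits = np.array([[100.0, 0.0, 0.0]])
        assert cross_entropy(logits, np.array([0])) < 1e-10

    def test_out_of_range_label(self):
        with pytest.raises(ValueError):
            cross_entropy(np.zeros((1, 3)), np.array([5]))


class TestClipGradients:
    def test_closed_form(self):
        g = [np.full(4, 2.0)]  # global norm 4
        out = clip_gradients(g, 1.0)
        assert np.allclose(out[0], 0.5)
        g = [np.full(4, 0.25)]  # norm 0.5, untouched
        assert np.array_equal(clip_gradients(g, 1.0)[0], g[0])
        assert np.all(clip_gradients([np.zeros(3)], 1.0)[0] == 0.0)


@pytest.fixture(scope="module")
def target_corpus():
    return generate_corpus(
        SynthConfig(
            n_subjects=1,
            n_trials_per_subject=6,
            samples_per_trial=10,
            n_channels=6,
            noise_sd=0.4,
            seed=5,
        )
    )


TASK = make_transfer_task("src", "tgt", n_finetune=4, n_test=2, n_classes=3)
FCFG = FinetuneConfig(epochs=2, batch_size=16, learning_rate=1e-3, seed=11)


class TestRunFinetuning:
    def test_smoke_loss_and_accuracy(self, target_corpus):
        model, stats, history = run_finetuning(None, TASK, target_corpus, FCFG, d_model=8)
        assert len(history) == 2
        assert np.isfinite(history[-1]["loss"])
        assert history[-1]["train_acc"] >= 1 / 3 - 0.1

    def test_post_clip_norm_bounded_every_step(self, target_corpus):
        _, _, history = run_finetuning(None, TASK, target_corpus, FCFG, d_model=8)
        assert all(h["max_post_clip_grad_norm"] <= 1.0 + 1e-6 for h in history)

    def test_seed_determinism(self, target_corpus):
        _, _, h1 = run_finetuning(None, TASK, target_corpus, FCFG, d_model=8)
        _, _, h2 = run_finetuning(None, TASK, target_corpus, FCFG, d_model=8)
        assert h1 == h2

    def test_pretrained_initialisation_is_used(self, target_corpus, rng):
        pre = init_extractor(30, 8, rng)
        m1, _, _ = run_finetuning(pre, TASK, target_corpus, FCFG, d_model=8)
        m2, _, _ = run_finetuning(None, TASK, target_corpus, FCFG, d_model=8)
        X = target_corpus.flat()[:5]
        from cate.data import zscore_normalize

        Xn, _ = zscore_normalize(X)
        assert not np.array_equal(predict(m1, Xn), predict(m2, Xn)) or not np.array_equal(
            m1.cls_W1.data, m2.cls_W1.data
        )

    def test_class_count_mismatch_rejected(self, target_corpus):
        bad = make_transfer_task("s", "t", n_finetune=4, n_test=2, n_classes=2)
        with pytest.raises(ValueError):
            run_finetuning(None, bad, target_corpus, FCFG, d_model=8)

    def test_eval_forward_deterministic(self, target_corpus, rng):
        model, stats, _ = run_finetuning(None, TASK, target_corpus, FCFG, d_model=8)
        X = rng.normal(size=(7, 30))
        assert np.array_equal(predict(model, X), predict(model, X))

    def test_source_inclusion_enlarges_training_pool(self, target_corpus):
        source = generate_corpus(
            SynthConfig(
                n_subjects=1, n_trials_per_subject=6, samples_per_trial=10, n_channels=6, seed=77
            )
        )
        m_with, _, h_with = run_finetuning(
            None, TASK, target_corpus, FCFG, d_model=8, source_data=source
        )
        _, _, h_without = run_finetuning(None, TASK, target_corpus, FCFG, d_model=8)
        # more data, same batch size: different trajectory
        assert h_with != h_without
        assert np.isfinite(h_with[-1]["loss"])

    def test_augmented_finetuning_runs_and_differs(self, target_corpus):
        from dataclasses import replace

        aug_cfg = replace(FCFG, augment_inputs=True)
        _, _, h_aug = run_finetuning(None, TASK, target_corpus, aug_cfg, d_model=8)
        _, _, h_plain = run_finetuning(None, TASK, target_corpus, FCFG, d_model=8)
        assert np.isfinite(h_aug[-1]["loss"])
        assert h_aug != h_plain

    def test_ablation_variants_constructible(self):
        # random-init vs pre-trained backbones give different starting weights
        m_rand = init_model(None, 30, 8, 3, FinetuneConfig(seed=1, n_heads=2), np.random.default_rng(1))
        pre = init_extractor(30, 8, np.random.default_rng(2))
        m_pre = init_model(pre, 30, 8, 3, FinetuneConfig(seed=1, n_heads=2), np.random.default_rng(1))
        assert not np.array_equal(
            m_rand.nerm_encoder.backbone["W1"].data, m_pre.nerm_encoder.backbone["W1"].data
        )
        assert np.array_equal(m_pre.nerm_encoder.backbone["W1"].data, pre.W1)
        assert np.array_equal(m_pre.wtrm_encoder.backbone["W1"].data, pre.W1)
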