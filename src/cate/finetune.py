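"""Stage-2 supervised model: dual attention encoders, fusion, classifier.

The pre-trained backbone initialises two parallel encoders.  Each DE vector
is treated as a length-one token sequence, so the encoders are standard
transformer blocks whose pooling reduces to the identity: the noise-view
encoder applies one multi-head attention layer with a damped (alpha = 0.1)
residual, the wavelet-view encoder adds a position-wise feed-forward block
on top.  No augmentation is applied at fine-tune time; the two encoders
receive the same z-scored input and differentiate only through their
learned weights.  Their pooled embeddings are averaged and classified by a
small MLP head trained with cross-entropy, global-norm gradient clipping at
1.0 and a reduce-on-plateau learning-rate schedule (factor 0.5, patience 5)
monitoring the mean training loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .augment import nerm_view, wtrm_view
from .data import (
    DEFeatureSet,
    TransferTask,
    ZScoreStats,
    flatten,
    unflatten,
    zscore_normalize,
)
from .pretrain import SharedExtractorParams, _forward as _backbone_forward, init_extractor


# ----------------------------------------------------------------------
# Parameter containers (plain arrays or autodiff Tensors interchangeably)
# ----------------------------------------------------------------------
@dataclass
class AttentionParams:
    W_Q: object
    W_K: object
    W_V: object
    W_O: object
    h: int

    def __post_init__(self):
        d = np.shape(np.asarray(self.W_Q if not isinstance(self.W_Q, nn.Tensor) else self.W_Q.data))[0]
        if d % self.h != 0:
            raise ValueError(f"d_model={d} not divisible by h={self.h}")

    @property
    def d_model(self) -> int:
        w = self.W_Q.data if isinstance(self.W_Q, nn.Tensor) else self.W_Q
        return w.shape[0]

    @property
    def d_k(self) -> int:
        return self.d_model // self.h


@dataclass
class EncoderParams:
    """One view encoder: backbone copy + attention (+ FFN for the wavelet view)."""

    backbone: dict  # keys W1, b1, W2, b2
    attention: AttentionParams
    ffn_W1: object = None  # [d_model, 4*d_model] (input-major for x @ W1)
    ffn_W2: object = None
    alpha: float = 0.1
    dropout_rate: float = 0.1


@dataclass
class DualEncoderModel:
    nerm_encoder: EncoderParams
    wtrm_encoder: EncoderParams
    cls_W1: object = None  # [d_model, d_hidden]
    cls_b1: object = None
    cls_W2: object = None  # [d_hidden, K]
    cls_b2: object = None

    def parameters(self) -> list:
        ps = []
        for enc in (self.nerm_encoder, self.wtrm_encoder):
            ps.extend(enc.backbone[k] for k in ("W1", "b1", "W2", "b2"))
            ps.extend([enc.attention.W_Q, enc.attention.W_K, enc.attention.W_V, enc.attention.W_O])
            if enc.ffn_W1 is not None:
                ps.extend([enc.ffn_W1, enc.ffn_W2])
        ps.extend([self.cls_W1, self.cls_b1, self.cls_W2, self.cls_b2])
        return ps


@dataclass
class FinetuneConfig:
    epochs: int = 20
    batch_size: int = 128
    clip_norm: float = 1.0
    scheduler_factor: float = 0.5
    scheduler_patience: int = 5
    learning_rate: float = 1e-4
    seed: int = 0
    n_heads: int = 4
    d_hidden: int = 128
    dropout: float = 0.1
    alpha: float = 0.1
    augment_inputs: bool = False  # re-apply the two views to encoder inputs
    amp: bool = False  # accepted for interface parity; arithmetic stays float64

    def __post_init__(self):
        if self.clip_norm <= 0:
            raise ValueError("clip_norm must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


# ----------------------------------------------------------------------
# Forward blocks
# ----------------------------------------------------------------------
def _mha(H, p: AttentionParams) -> nn.Tensor:
    """softmax(Q K^T / sqrt(d_k)) V per head, concatenated, projected."""
    H = nn.as_tensor(H)
    B, L, D = H.shape
    h, dk = p.h, p.d_k

    def split(x):  # [B, L, D] -> [B, h, L, dk]
        return nn.transpose(nn.reshape(x, (B, L, h, dk)), (0, 2, 1, 3))

    Q = split(nn.matmul(H, p.W_Q))
    K = split(nn.matmul(H, p.W_K))
    V = split(nn.matmul(H, p.W_V))
    scores = nn.matmul(Q, nn.transpose(K, (0, 1, 3, 2))) * (1.0 / np.sqrt(dk))
    out = nn.matmul(nn.softmax(scores), V)  # [B, h, L, dk]
    out = nn.reshape(nn.transpose(out, (0, 2, 1, 3)), (B, L, D))
    return nn.matmul(out, p.W_O)


def multi_head_attention(H: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Multi-head self-attention on a ``[B, L, d_model]`` batch (eval path).

    At L = 1 the softmax over a single key is 1, so the block collapses to
    the fixed affine map ``H W_V W_O`` for any query/key weights.
    """
    H = np.asarray(H, dtype=np.float64)
    if H.ndim != 3 or H.shape[2] != params.d_model:
        raise ValueError(f"expected [B, L, {params.d_model}], got {H.shape}")
    return _mha(H, params).data


def _ffn(x, enc: EncoderParams, rng, training):
    h = nn.dropout(nn.matmul(nn.as_tensor(x), enc.ffn_W1), enc.dropout_rate, rng, training)
    h = nn.dropout(nn.matmul(nn.gelu(h), enc.ffn_W2), enc.dropout_rate, rng, training)
    return h


def _pool(H):  # mean over the sequence axis; identity at L = 1
    return nn.tmean(H, axis=1)


def _nerm_encode(H, enc: EncoderParams) -> nn.Tensor:
    H1 = nn.layer_norm(nn.as_tensor(H) + _mha(H, enc.attention) * enc.alpha)
    return nn.layer_norm(_pool(H1))


def _wtrm_encode(H, enc: EncoderParams, rng=None, training=False) -> nn.Tensor:
    H1 = nn.layer_norm(nn.as_tensor(H) + _mha(H, enc.attention) * enc.alpha)
    Hff = H1 + _ffn(H1, enc, rng, training) * enc.alpha
    return nn.layer_norm(_pool(nn.layer_norm(Hff)))


def nerm_encode(H: np.ndarray, enc: EncoderParams) -> np.ndarray:
    """Attention + damped residual + LayerNorm, pooled over the sequence."""
    return _nerm_encode(np.asarray(H, float), enc).data


def wtrm_encode(H: np.ndarray, enc: EncoderParams) -> np.ndarray:
    """As :func:`nerm_encode` plus a damped feed-forward refinement block."""
    return _wtrm_encode(np.asarray(H, float), enc).data


def fuse(z_nerm: np.ndarray, z_wtrm: np.ndarray) -> np.ndarray:
    """Simple elementwise average of the two view embeddings."""
    z_nerm, z_wtrm = np.asarray(z_nerm, float), np.asarray(z_wtrm, float)
    if z_nerm.shape != z_wtrm.shape:
        raise ValueError("fused embeddings must have the same shape")
    return 0.5 * (z_nerm + z_wtrm)


def _classify(z, model: DualEncoderModel, rng=None, training=False, dropout_rate=0.1):
    h = nn.gelu(nn.layer_norm(nn.matmul(nn.as_tensor(z), model.cls_W1) + model.cls_b1))
    h = nn.dropout(h, dropout_rate, rng, training)
    return nn.matmul(h, model.cls_W2) + model.cls_b2


def classify(z_fused: np.ndarray, model: DualEncoderModel) -> np.ndarray:
    """MLP head logits (eval mode: dropout inactive)."""
    return _classify(np.asarray(z_fused, float), model).data


def _model_forward(model, X_nerm, X_wtrm=None, rng=None, training=False):
    """Dual-encoder forward; both encoders see ``X_nerm`` unless a separate
    wavelet-view input is given (fine-tune-time augmentation)."""
    if X_wtrm is None:
        X_wtrm = X_nerm
    zs = []
    for enc, X_flat in ((model.nerm_encoder, X_nerm), (model.wtrm_encoder, X_wtrm)):
        H = _backbone_forward(X_flat, *(enc.backbone[k] for k in ("W1", "b1", "W2", "b2")))
        H = nn.reshape(H, (X_flat.shape[0], 1, -1))  # length-1 token sequence
        if enc is model.nerm_encoder:
            zs.append(_nerm_encode(H, enc))
        else:
            zs.append(_wtrm_encode(H, enc, rng, training))
    z = (zs[0] + zs[1]) * 0.5
    return _classify(z, model, rng, training, model.nerm_encoder.dropout_rate)


def predict(model: DualEncoderModel, X_flat: np.ndarray) -> np.ndarray:
    """Deterministic class predictions for normalised flat features."""
    logits = _model_forward(model, np.asarray(X_flat, float))
    return np.argmax(logits.data, axis=1)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-softmax of the true class."""
    return float(nn.cross_entropy_with_logits(np.asarray(logits, float), labels).data)


def clip_gradients(grads: list[np.ndarray], max_norm: float = 1.0) -> list[np.ndarray]:
    """Scale a gradient list by min(1, max_norm / global L2 norm)."""
    total = np.sqrt(sum(float((g**2).sum()) for g in grads))
    if total > max_norm and total > 0.0:
        scale = max_norm / total
        return [g * scale for g in grads]
    return [np.array(g, copy=True) for g in grads]


# ----------------------------------------------------------------------
# Model construction / training
# ----------------------------------------------------------------------
def init_model(
    pretrained: SharedExtractorParams | None,
    d_input: int,
    d_model: int,
    n_classes: int,
    cfg: FinetuneConfig,
    rng: np.random.Generator,
) -> DualEncoderModel:
    """Build the dual-encoder model; ``pretrained=None`` gives random backbones.

    Both encoders' backbones start from the *same* pre-trained weights and
    then train independently.
    """
    if d_model % cfg.n_heads != 0:
        raise ValueError("d_model must be divisible by the head count")

    def glorot(fan_in, fan_out):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return nn.parameter(rng.uniform(-lim, lim, size=(fan_in, fan_out)))

    def make_encoder(with_ffn: bool) -> EncoderParams:
        if pretrained is None:
            bb = init_extractor(d_input, d_model, rng)
        else:
            bb = pretrained
        backbone = {
            "W1": nn.parameter(bb.W1),
            "b1": nn.parameter(bb.b1),
            "W2": nn.parameter(bb.W2),
            "b2": nn.parameter(bb.b2),
        }
        att = AttentionParams(
            W_Q=glorot(d_model, d_model),
            W_K=glorot(d_model, d_model),
            W_V=glorot(d_model, d_model),
            W_O=glorot(d_model, d_model),
            h=cfg.n_heads,
        )
        enc = EncoderParams(
            backbone=backbone,
            attention=att,
            alpha=cfg.alpha,
            dropout_rate=cfg.dropout,
        )
        if with_ffn:
            enc.ffn_W1 = glorot(d_model, 4 * d_model)
            enc.ffn_W2 = glorot(4 * d_model, d_model)
        return enc

    return DualEncoderModel(
        nerm_encoder=make_encoder(with_ffn=False),
        wtrm_encoder=make_encoder(with_ffn=True),
        cls_W1=glorot(d_model, cfg.d_hidden),
        cls_b1=nn.parameter(np.zeros(cfg.d_hidden)),
        cls_W2=glorot(cfg.d_hidden, n_classes),
        cls_b2=nn.parameter(np.zeros(n_classes)),
    )


def run_finetuning(
    pretrained: SharedExtractorParams | None,
    task: TransferTask,
    data: DEFeatureSet,
    cfg: FinetuneConfig = FinetuneConfig(),
    d_model: int | None = None,
    source_data: DEFeatureSet | None = None,
) -> tuple[DualEncoderModel, ZScoreStats, list[dict]]:
    """Supervised stage 2 on the target fine-tune trials.

    Normalisation statistics are computed on the fine-tune split and
    returned for reuse on test data.  Every step applies global-norm
    gradient clipping; a plateau scheduler (factor/patience from ``cfg``)
    monitors the epoch-mean training loss.  ``source_data`` optionally adds
    labeled source-corpus samples to the training pool; with
    ``cfg.augment_inputs`` each encoder receives its own stochastic view of
    the batch instead of the shared clean input.  Returns the trained
    model, the z-score stats and a per-epoch history with loss, lr,
    training accuracy and the maximum post-clip gradient norm.
    """
    if data.n_classes > task.n_classes:
        raise ValueError(
            f"data has {data.n_classes} classes but the task declares {task.n_classes}"
        )
    if d_model is None:
        d_model = pretrained.d_model if pretrained is not None else 256
    ft_mask = np.isin(data.trial, sorted(task.target_finetune_trials))
    ft = data.subset(ft_mask)
    if ft.n_samples == 0:
        raise ValueError("no samples in the fine-tune trials")
    train_flat = ft.flat()
    y = ft.labels
    if source_data is not None:
        if source_data.n_classes > task.n_classes:
            raise ValueError("source corpus class count exceeds the task's")
        train_flat = np.concatenate([train_flat, source_data.flat()], axis=0)
        y = np.concatenate([y, source_data.labels])
    X, stats = zscore_normalize(train_flat)
    n_channels = data.n_channels
    rng = np.random.default_rng(cfg.seed)
    model = init_model(pretrained, X.shape[1], d_model, task.n_classes, cfg, rng)
    params = model.parameters()
    opt = nn.Adam(params, lr=cfg.learning_rate)
    sched = nn.ReduceLROnPlateau(opt, factor=cfg.scheduler_factor, patience=cfg.scheduler_patience)
    history: list[dict] = []
    n = X.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_loss, correct, max_norm, n_batches = 0.0, 0, 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb_wtrm = None
            xb = X[idx]
            if cfg.augment_inputs:
                cube = unflatten(xb, n_channels=n_channels, n_bands=5)
                xb = flatten(nerm_view(cube, rng=rng))
                xb_wtrm = flatten(wtrm_view(cube, rng=rng))
            logits = _model_forward(model, xb, xb_wtrm, rng=rng, training=True)
            loss = nn.cross_entropy_with_logits(logits, y[idx])
            opt.zero_grad()
            loss.backward()
            post = nn.clip_grad_norm(params, cfg.clip_norm)
            opt.step()
            ep_loss += loss.item()
            max_norm = max(max_norm, post)
            correct += int((np.argmax(logits.data, axis=1) == y[idx]).sum())
            n_batches += 1
        mean_loss = ep_loss / n_batches
        reduced = sched.step(mean_loss)
        history.append(
            {
                "epoch": epoch,
                "loss": mean_loss,
                "train_acc": correct / n,
                "lr": opt.lr,
                "max_post_clip_grad_norm": max_norm,
                "lr_reduced": reduced,
            }
        )
    return model, stats, history
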