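"""Shared feature extractor and the dual-view self-supervised objective.

Stage 1 trains a two-layer backbone ``LayerNorm(GELU(W1 x + b1)) W2 + b2``
on two stochastic views of each unlabeled batch (adaptive-noise and
wavelet-perturbation), with two loss components:

* an **alignment loss** ``2 - 2 * mean_i cos(z1_i, z2_i)`` that pulls the
  L2-normalised embeddings of the two views of the same sample together,
  and
* a **style-diversity loss** ``||Z1 Z1^T - I||_F^2 + ||Z2 Z2^T - I||_F^2``
  on (by default row-normalised) Gram matrices, which keeps different
  samples' embeddings spread out and prevents representation collapse.

Both views pass through the *same* parameter set, so the backbone learns a
single feature space consistent across perturbations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .augment import MaskConfig, NoiseConfig, WaveletConfig, identity_view, nerm_view, wtrm_view
from .data import DEFeatureSet, flatten


@dataclass
class SharedExtractorParams:
    """Parameters of the two-layer shared backbone.

    Shapes follow the convention W1: [d_model, d_input], W2: [d_model,
    d_model]; the forward pass multiplies with the transposes.
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray

    @property
    def d_input(self) -> int:
        return self.W1.shape[1]

    @property
    def d_model(self) -> int:
        return self.W1.shape[0]


def init_extractor(
    d_input: int, d_model: int, rng: np.random.Generator
) -> SharedExtractorParams:
    """Glorot-uniform weights, zero biases."""

    def glorot(fan_out, fan_in):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=(fan_out, fan_in))

    return SharedExtractorParams(
        W1=glorot(d_model, d_input),
        b1=np.zeros(d_model),
        W2=glorot(d_model, d_model),
        b2=np.zeros(d_model),
    )


def _forward(x, W1, b1, W2, b2):
    """Backbone forward in autodiff ops; works for Tensors or plain arrays."""
    h = nn.gelu(nn.matmul(nn.as_tensor(x), nn.transpose(nn.as_tensor(W1), (1, 0))) + b1)
    return nn.matmul(nn.layer_norm(h), nn.transpose(nn.as_tensor(W2), (1, 0))) + b2


def extract_features(X_flat: np.ndarray, params: SharedExtractorParams) -> np.ndarray:
    """Deterministic row-wise backbone map ``[B, d_input] -> [B, d_model]``."""
    X_flat = np.asarray(X_flat, dtype=np.float64)
    if X_flat.ndim != 2 or X_flat.shape[1] != params.d_input:
        raise ValueError(
            f"input shape {X_flat.shape} does not match d_input={params.d_input}"
        )
    return _forward(X_flat, params.W1, params.b1, params.W2, params.b2).data


# ----------------------------------------------------------------------
# Losses
# ----------------------------------------------------------------------
def _alignment(z1, z2) -> nn.Tensor:
    z1n = nn.l2_normalize_rows(z1)
    z2n = nn.l2_normalize_rows(z2)
    cos = nn.tsum(nn.mul(z1n, z2n), axis=-1)
    return 2.0 + nn.tmean(cos) * (-2.0)

def _style(z1, z2, normalize: bool) -> nn.Tensor:
    total = None
    for z in (z1, z2):
        zt = nn.l2_normalize_rows(z) if normalize else nn.as_tensor(z)
        B = zt.shape[0]
        g = nn.matmul(zt, nn.transpose(zt, (1, 0)))
        d = g - np.eye(B)
        term = nn.tsum(nn.mul(d, d))
        total = term if total is None else total + term
    return total


def alignment_loss(Z1: np.ndarray, Z2: np.ndarray) -> float:
    """2 - 2 * mean cosine similarity between paired rows; in [0, 4]."""
    if np.shape(Z1) != np.shape(Z2):
        raise ValueError("views must have identical shapes")
    return float(_alignment(np.asarray(Z1, float), np.asarray(Z2, float)).data)


def style_diversity_loss(Z1: np.ndarray, Z2: np.ndarray, normalize_gram: bool = True) -> float:
    """Frobenius distance of both views' Gram matrices from the identity.

    With ``normalize_gram`` (default) rows are L2-normalised first so the
    Gram diagonal is exactly 1 and only cross-sample similarity is
    penalised.
    """
    return float(_style(np.asarray(Z1, float), np.asarray(Z2, float), normalize_gram).data)


@dataclass
class PretrainConfig:
    """Stage-1 hyperparameters.

    ``lambda_align``/``lambda_style`` weight the two loss components; when
    ``normalize_gram`` is on the style term is additionally divided by B^2
    so its weight is batch-size stable.
    """

    lambda_align: float = 1.0
    lambda_style: float = 0.01
    epochs: int = 200
    batch_size: int = 256
    learning_rate: float = 1e-3
    seed: int = 0
    normalize_gram: bool = True
    d_model: int = 256

    def __post_init__(self):
        if self.lambda_align < 0 or self.lambda_style < 0 or self.epochs < 1:
            raise ValueError("require lambdas >= 0 and epochs >= 1")


def _total_loss(z1, z2, cfg: PretrainConfig):
    la = _alignment(z1, z2)
    ls = _style(z1, z2, cfg.normalize_gram)
    if cfg.normalize_gram:
        B = nn.as_tensor(z1).shape[0]
        ls = ls * (1.0 / B**2)
    total = la * cfg.lambda_align + ls * cfg.lambda_style
    return total, la, ls


def pretrain_total_loss(
    Z1: np.ndarray, Z2: np.ndarray, cfg: PretrainConfig
) -> tuple[float, dict]:
    """Weighted stage-1 objective and its components (for logging)."""
    total, la, ls = _total_loss(np.asarray(Z1, float), np.asarray(Z2, float), cfg)
    return float(total.data), {"align": float(la.data), "style": float(ls.data)}


# ----------------------------------------------------------------------
# Training loop
# ----------------------------------------------------------------------
def run_pretraining(
    data: DEFeatureSet | list[DEFeatureSet],
    cfg: PretrainConfig = PretrainConfig(),
    noise_cfg: NoiseConfig = NoiseConfig(),
    wavelet_cfg: WaveletConfig = WaveletConfig(),
    mask_cfg: MaskConfig = MaskConfig(),
    use_nerm: bool = True,
    use_wtrm: bool = True,
    init: SharedExtractorParams | None = None,
) -> tuple[SharedExtractorParams, list[dict]]:
    """Train the shared backbone on fresh dual views of each batch.

    ``use_nerm=False`` / ``use_wtrm=False`` replace the corresponding view
    with the clean input (the single-view ablations).  Returns the final
    parameters and one history record per epoch.  Fully seeded: the same
    config reproduces the same parameters bitwise.
    """
    sets = data if isinstance(data, list) else [data]
    X = np.concatenate([d.values for d in sets], axis=0)
    if X.shape[0] == 0:
        raise ValueError("empty pre-training corpus")
    rng = np.random.default_rng(cfg.seed)
    d_input = X.shape[1] * X.shape[2]
    params0 = init if init is not None else init_extractor(d_input, cfg.d_model, rng)
    W1, b1 = nn.parameter(params0.W1), nn.parameter(params0.b1)
    W2, b2 = nn.parameter(params0.W2), nn.parameter(params0.b2)
    opt = nn.Adam([W1, b1, W2, b2], lr=cfg.learning_rate)
    history: list[dict] = []
    n = X.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep = {"epoch": epoch, "total": 0.0, "align": 0.0, "style": 0.0}
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            xb = X[order[start : start + cfg.batch_size]]
            v1 = nerm_view(xb, noise_cfg, rng) if use_nerm else identity_view(xb)
            v2 = wtrm_view(xb, wavelet_cfg, mask_cfg, rng) if use_wtrm else identity_view(xb)
            z1 = _forward(flatten(v1), W1, b1, W2, b2)
            z2 = _forward(flatten(v2), W1, b1, W2, b2)
            total, la, ls = _total_loss(z1, z2, cfg)
            opt.zero_grad()
            total.backward()
            opt.step()
            ep["total"] += total.item()
            ep["align"] += la.item()
            ep["style"] += ls.item()
            n_batches += 1
        for k in ("total", "align", "style"):
            ep[k] /= n_batches
        history.append(ep)
    final = SharedExtractorParams(W1=W1.data, b1=b1.data, W2=W2.data, b2=b2.data)
    return final, history


# ----------------------------------------------------------------------
# Checkpointing
# ----------------------------------------------------------------------
def save_checkpoint(path: str | Path, params: SharedExtractorParams, cfg: PretrainConfig) -> None:
    """NPZ archive with parameter arrays plus the JSON-encoded config."""
    np.savez(
        Path(path),
        W1=params.W1,
        b1=params.b1,
        W2=params.W2,
        b2=params.b2,
        config=np.frombuffer(json.dumps(asdict(cfg)).encode(), dtype=np.uint8),
    )


def load_checkpoint(path: str | Path) -> tuple[SharedExtractorParams, PretrainConfig]:
    with np.load(Path(path)) as z:
        params = SharedExtractorParams(
            W1=z["W1"], b1=z["b1"], W2=z["W2"], b2=z["b2"]
        )
        cfg = PretrainConfig(**json.loads(bytes(z["config"]).decode()))
    return params, cfg
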