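"""The two self-supervised views of a DE feature batch.

NERM (noise-enhanced representation modelling) adds Gaussian noise whose
scale adapts to the batch magnitude and is capped, so the perturbation
regularises without corrupting the band structure.  WTRM (wavelet-transform
representation modelling) takes a level-1 Haar decomposition of each
channel's 5-band profile, randomly masks/perturbs the coefficients, and
inverts the transform — perturbing the overall activation level (via the
approximation coefficients) and the inter-band coordination (via the detail
coefficients) rather than raw values.

The band axis has odd length 5; it is padded to 6 by repeating the last
band before analysis and the synthesis output is truncated back to 5, which
makes the Haar round trip exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class NoiseConfig:
    """Adaptive-noise view: scale = min(cap, slope * mean|X| + eps)."""

    cap: float = 0.05
    slope: float = 0.1
    eps: float = 1e-8

    def __post_init__(self):
        if self.cap <= 0 or self.slope < 0 or self.eps <= 0:
            raise ValueError("require cap > 0, slope >= 0, eps > 0")


@dataclass(frozen=True)
class WaveletConfig:
    """Level-1 Haar over the band axis; the only supported basis/level."""

    basis: str = "haar"
    level: int = 1
    pad_mode: str = "symmetric-even"

    def __post_init__(self):
        if self.basis not in ("haar", "db1") or self.level != 1:
            raise ValueError("only level-1 Haar (db1) decomposition is supported")


@dataclass(frozen=True)
class MaskConfig:
    """Bernoulli mask rates for the wavelet view, all driven by ``mu``.

    The approximation mask fires with rate mu/2 and rescales coefficients by
    ``1 + amp_a * eps`` with standard-normal eps; detail coefficients are
    halved where the suppress mask (rate mu) fires and scaled by
    ``1 + eps * sigma`` where the enhance mask (rate mu/2) fires.  Where
    suppress and enhance coincide, suppress wins.  ``eq6_literal`` instead
    zeroes every detail coefficient that neither mask selects (the raw
    published multiplier), which destroys most of the view at small mu and
    is off by default.
    """

    mu: float = 0.05
    amp_a: float | None = None
    eq6_literal: bool = False

    def __post_init__(self):
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must be a probability")
        if self.amp_a is None:
            object.__setattr__(self, "amp_a", self.mu)

    @property
    def p_a(self) -> float:
        return self.mu * 0.5

    @property
    def p_suppress(self) -> float:
        return self.mu

    @property
    def p_enhance(self) -> float:
        return self.mu * 0.5


# ----------------------------------------------------------------------
# NERM
# ----------------------------------------------------------------------
def compute_noise_scale(X: np.ndarray, cfg: NoiseConfig = NoiseConfig()) -> float:
    """One noise scale for the whole batch: min(cap, slope * mean|X| + eps)."""
    return float(min(cfg.cap, cfg.slope * np.mean(np.abs(X)) + cfg.eps))


def nerm_view(
    X: np.ndarray, cfg: NoiseConfig = NoiseConfig(), rng: np.random.Generator | None = None
) -> np.ndarray:
    """X plus standard Gaussian noise scaled by the adaptive batch scale."""
    rng = np.random.default_rng() if rng is None else rng
    s = compute_noise_scale(X, cfg)
    return X + rng.standard_normal(X.shape) * s


# ----------------------------------------------------------------------
# Haar analysis / synthesis over the last axis (length 5)
# ----------------------------------------------------------------------
def dwt1(x: np.ndarray, cfg: WaveletConfig = WaveletConfig()) -> tuple[np.ndarray, np.ndarray]:
    """Level-1 Haar analysis of a 5-long band profile (any leading axes).

    Pads to length 6 by repeating the last value, then
    cA_k = (x_{2k} + x_{2k+1}) / sqrt(2), cD_k = (x_{2k} - x_{2k+1}) / sqrt(2).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] != 5:
        raise ValueError(f"band axis must have length 5, got {x.shape[-1]}")
    x6 = np.concatenate([x, x[..., -1:]], axis=-1)
    even, odd = x6[..., 0::2], x6[..., 1::2]
    return (even + odd) / SQRT2, (even - odd) / SQRT2


def idwt1(
    cA: np.ndarray, cD: np.ndarray, cfg: WaveletConfig = WaveletConfig()
) -> np.ndarray:
    """Haar synthesis to length 6, truncated to the 5 real bands."""
    cA = np.asarray(cA, dtype=np.float64)
    cD = np.asarray(cD, dtype=np.float64)
    if cA.shape != cD.shape or cA.shape[-1] != 3:
        raise ValueError(f"coefficient shapes must match with last axis 3, got {cA.shape}/{cD.shape}")
    out = np.empty(cA.shape[:-1] + (6,), dtype=np.float64)
    out[..., 0::2] = (cA + cD) / SQRT2
    out[..., 1::2] = (cA - cD) / SQRT2
    return out[..., :5]


# ----------------------------------------------------------------------
# Coefficient masking / perturbation
# ----------------------------------------------------------------------
def sample_masks(
    shape: tuple, cfg: MaskConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Independent Bernoulli masks (rates mu/2, mu, mu/2); suppress beats enhance."""
    m_a = rng.random(shape) < cfg.p_a
    m_sup = rng.random(shape) < cfg.p_suppress
    m_enh = (rng.random(shape) < cfg.p_enhance) & ~m_sup
    return m_a, m_sup, m_enh


@dataclass(frozen=True)
class PerturbationDraws:
    """Standard-normal draws and the per-channel detail spread sigma_d."""

    eps_a: np.ndarray
    eps_d: np.ndarray
    sigma_d: np.ndarray

    def __post_init__(self):
        if self.eps_a.shape != self.eps_d.shape:
            raise ValueError("draw shapes must match the coefficient arrays")


def perturb_coeffs(
    cA: np.ndarray,
    cD: np.ndarray,
    masks: tuple[np.ndarray, np.ndarray, np.ndarray],
    draws: PerturbationDraws,
    cfg: MaskConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the masked perturbations to the Haar coefficients.

    Approximation: cA * (1 + amp_a * M_A * eps_A).  Detail: multiplied by
    0.5 on suppress cells, by (1 + eps_D * sigma_D) on enhance cells, and by
    1 elsewhere (or 0 elsewhere under ``eq6_literal``).
    """
    m_a, m_sup, m_enh = masks
    cA_out = cA * (1.0 + cfg.amp_a * m_a * draws.eps_a)
    enhance = 1.0 + draws.eps_d * draws.sigma_d
    if cfg.eq6_literal:
        mult = 0.5 * m_sup + m_enh * enhance
    else:
        mult = np.where(m_sup, 0.5, np.where(m_enh, enhance, 1.0))
    return cA_out, cD * mult


def wtrm_view(
    X: np.ndarray,
    wcfg: WaveletConfig = WaveletConfig(),
    mcfg: MaskConfig = MaskConfig(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Wavelet-perturbation view of a ``[B, C, 5]`` batch.

    Per sample-channel: Haar analysis, masked coefficient perturbation with
    sigma_D the population std of that channel's 3 detail coefficients,
    Haar synthesis.  With mu = 0 this is the identity map.
    """
    rng = np.random.default_rng() if rng is None else rng
    X = np.asarray(X, dtype=np.float64)
    cA, cD = dwt1(X, wcfg)
    masks = sample_masks(cA.shape, mcfg, rng)
    draws = PerturbationDraws(
        eps_a=rng.standard_normal(cA.shape),
        eps_d=rng.standard_normal(cD.shape),
        sigma_d=cD.std(axis=-1, keepdims=True),  # population std over the 3 details
    )
    cA2, cD2 = perturb_coeffs(cA, cD, masks, draws, mcfg)
    return idwt1(cA2, cD2, wcfg)


def identity_view(X: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
    """Pass-through view used by the single-view ablations."""
    return np.array(X, dtype=np.float64, copy=True)
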