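"""Synthetic two-corpus DE feature generator with controllable domain shift.

Generates feature sets that mimic the *layout and statistical skeleton* of
multi-subject emotion-recognition corpora: class-conditional band-energy
means (the emotion signal lives in the 5-band profile, e.g. elevated
beta/gamma for high-arousal classes), random per-subject and per-channel
offsets, i.i.d. Gaussian sample noise, and trials as contiguous
single-label sample blocks.  A corpus-level affine transform per band
(gain + offset) plus a different noise level provides the domain shift
between a source and a target corpus that share the same class structure.

The default class/band means below are synthetic design values — chosen to
give a plausible band-profile separation between classes — not estimates
from any real EEG corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import DEFeatureSet, TransferTask, make_transfer_task

#: synthetic class-conditional DE means per band (rows: classes 0..2,
#: columns: delta, theta, alpha, beta, gamma)
DEFAULT_CLASS_BAND_MEANS = np.array(
    [
        [1.20, 1.00, 0.80, 0.55, 0.45],  # class 0: low-arousal, slow-band heavy
        [1.00, 0.90, 1.00, 0.80, 0.70],  # class 1: flat mid profile
        [0.90, 0.80, 0.95, 1.10, 1.00],  # class 2: beta/gamma elevated
    ]
)

#: default affine band shift applied to the target corpus of a pair
DEFAULT_TARGET_GAIN = np.array([1.15, 0.90, 1.05, 0.92, 1.12])
DEFAULT_TARGET_OFFSET = np.array([0.25, -0.15, 0.10, -0.20, 0.18])


@dataclass
class SynthConfig:
    """Generator settings; defaults give a small 3-class, 62-channel corpus."""

    n_subjects: int = 3
    n_trials_per_subject: int = 15
    samples_per_trial: int = 20
    n_classes: int = 3
    n_channels: int = 62
    n_bands: int = 5
    class_band_means: np.ndarray = field(
        default_factory=lambda: DEFAULT_CLASS_BAND_MEANS.copy()
    )
    subject_sd: float = 0.15
    channel_sd: float = 0.10
    corpus_gain: np.ndarray = field(default_factory=lambda: np.ones(5))
    corpus_offset: np.ndarray = field(default_factory=lambda: np.zeros(5))
    noise_sd: float = 0.80
    seed: int = 0

    def __post_init__(self):
        self.class_band_means = np.asarray(self.class_band_means, dtype=np.float64)
        self.corpus_gain = np.asarray(self.corpus_gain, dtype=np.float64)
        self.corpus_offset = np.asarray(self.corpus_offset, dtype=np.float64)
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.n_trials_per_subject < self.n_classes:
            raise ValueError("need at least one trial per class")
        if min(self.subject_sd, self.channel_sd, self.noise_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.class_band_means.shape != (self.n_classes, self.n_bands):
            raise ValueError("class_band_means must be [n_classes, n_bands]")
        if self.corpus_gain.shape != (self.n_bands,) or self.corpus_offset.shape != (
            self.n_bands,
        ):
            raise ValueError("corpus gain/offset must be per-band vectors")


def generate_corpus(cfg: SynthConfig) -> DEFeatureSet:
    """Draw one corpus.

    Sample value for class k, channel c, band f:
    ``gain_f * (class_mean[k, f] + subject_offset + channel_offset_c)
    + offset_f + N(0, noise_sd)``.  Trial labels cycle round-robin over the
    classes; each trial is a contiguous block of ``samples_per_trial``
    samples (single session, session id 0).
    """
    rng = np.random.default_rng(cfg.seed)
    values, labels, subject, session, trial = [], [], [], [], []
    for s in range(cfg.n_subjects):
        subj_off = rng.normal(0.0, cfg.subject_sd)
        chan_off = rng.normal(0.0, cfg.channel_sd, size=(cfg.n_channels, 1))
        for t in range(cfg.n_trials_per_subject):
            k = t % cfg.n_classes
            base = cfg.class_band_means[k][None, :] + subj_off + chan_off
            noise = rng.normal(
                0.0, cfg.noise_sd, size=(cfg.samples_per_trial, cfg.n_channels, cfg.n_bands)
            )
            x = cfg.corpus_gain * base[None, :, :] + cfg.corpus_offset + noise
            values.append(x)
            labels.extend([k] * cfg.samples_per_trial)
            subject.extend([s] * cfg.samples_per_trial)
            session.extend([0] * cfg.samples_per_trial)
            trial.extend([t] * cfg.samples_per_trial)
    return DEFeatureSet(
        values=np.concatenate(values, axis=0),
        labels=np.array(labels),
        subject=np.array(subject),
        session=np.array(session),
        trial=np.array(trial),
    )


def generate_transfer_pair(
    cfg_src: SynthConfig,
    cfg_tgt: SynthConfig,
    n_finetune: int | None = None,
    n_test: int | None = None,
) -> tuple[DEFeatureSet, DEFeatureSet, TransferTask]:
    """Source and target corpora sharing class structure, plus the trial split.

    The two configs must agree on classes/channels/bands; they are expected
    to differ in gain/offset/noise (the domain shift).  By default the
    target trials are split two-thirds fine-tune, one-third test.
    """
    if cfg_src.n_classes != cfg_tgt.n_classes:
        raise ValueError("source and target must have the same number of classes")
    if (cfg_src.n_channels, cfg_src.n_bands) != (cfg_tgt.n_channels, cfg_tgt.n_bands):
        raise ValueError("source and target must share channel/band dimensions")
    if not np.array_equal(cfg_src.class_band_means, cfg_tgt.class_band_means):
        raise ValueError("transfer pair must share class_band_means")
    source = generate_corpus(cfg_src)
    target = generate_corpus(cfg_tgt)
    if n_finetune is None:
        n_finetune = (2 * cfg_tgt.n_trials_per_subject) // 3
        n_test = cfg_tgt.n_trials_per_subject - n_finetune
    task = make_transfer_task(
        "synthetic-source",
        "synthetic-target",
        n_finetune=n_finetune,
        n_test=n_test,
        n_classes=cfg_src.n_classes,
    )
    return source, target, task


def default_transfer_pair(
    seed: int = 0, **overrides
) -> tuple[DEFeatureSet, DEFeatureSet, TransferTask]:
    """The package's default study pair: shared class structure, affine
    per-band shift plus a noisier target."""
    cfg_src = SynthConfig(seed=seed, **overrides)
    cfg_tgt = replace(
        cfg_src,
        corpus_gain=DEFAULT_TARGET_GAIN.copy(),
        corpus_offset=DEFAULT_TARGET_OFFSET.copy(),
        noise_sd=cfg_src.noise_sd * 1.2,
        seed=seed + 1,
    )
    return generate_transfer_pair(cfg_src, cfg_tgt)
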