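"""Feature tensors, on-disk layouts, normalisation and the trial-split protocol.

The in-memory container is :class:`DEFeatureSet`: a ``[N, C, F]`` array of
differential-entropy (DE) band-power features — ``C`` EEG channels by the
five canonical frequency bands (delta, theta, alpha, beta, gamma) — with one
integer emotion label, subject id, session id and trial id per sample.  A
trial is one stimulus presentation; all samples of a trial share its label
and trials are the unit of fine-tune/test splitting.

Flat ``N x (C*F)`` matrices (e.g. the 62*5 = 310-wide layout used for
SEED-family exports) are stored channel-major: the channel index varies
slowest, the band index fastest, so flat column ``c*F + f`` holds channel
``c``, band ``f``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")

#: target-side (fine-tune, test, n_classes) trial counts for the supported
#: cross-corpus protocols
PROTOCOL_SPLITS = {
    "SEED": (9, 6, 3),
    "SEED-IV3": (12, 6, 3),
    "SEED-V3": (6, 3, 3),
    "SEED-IV4": (16, 8, 4),
    "SEED-V4": (8, 4, 4),
}

SUPPORTED_TASKS = {
    ("SEED", "SEED-IV3"),
    ("SEED-IV3", "SEED"),
    ("SEED", "SEED-V3"),
    ("SEED-V3", "SEED"),
    ("SEED-IV4", "SEED-V4"),
    ("SEED-V4", "SEED-IV4"),
}


class FormatError(ValueError):
    """Raised when an on-disk file cannot be interpreted as DE features."""


class ConsistencyError(ValueError):
    """Raised when per-sample metadata do not agree with the feature tensor."""


@dataclass
class DEFeatureSet:
    """DE band features with per-sample labels and split metadata.

    Attributes
    ----------
    values : ndarray, shape (N, C, F)
        DE features (log-power units), finite.
    labels : ndarray of int, shape (N,)
        Emotion class per sample, in ``{0..K-1}``.
    subject, session, trial : ndarray of int, shape (N,)
        Per-sample indices; trial ids are 0-based per subject-session.
    band_names : tuple of str
        Always the five canonical bands, in fixed order.
    """

    values: np.ndarray
    labels: np.ndarray
    subject: np.ndarray
    session: np.ndarray
    trial: np.ndarray
    band_names: tuple = BAND_NAMES

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        for name in ("labels", "subject", "session", "trial"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        self.validate()

    def validate(self) -> None:
        if self.values.ndim != 3:
            raise FormatError(f"values must be [N, C, F], got shape {self.values.shape}")
        n, _, f = self.values.shape
        if f != len(self.band_names):
            raise FormatError(f"band axis has length {f}, expected {len(self.band_names)}")
        for name in ("labels", "subject", "session", "trial"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ConsistencyError(f"{name} has shape {arr.shape}, expected ({n},)")
        if not np.all(np.isfinite(self.values)):
            raise ConsistencyError("values contain non-finite entries")
        # one label per trial within each subject-session
        key = np.stack([self.subject, self.session, self.trial], axis=1)
        _, inv = np.unique(key, axis=0, return_inverse=True)
        for g in np.unique(inv):
            lab = self.labels[inv == g]
            if lab.size and np.any(lab != lab[0]):
                raise ConsistencyError("samples of one trial carry different labels")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def flat(self) -> np.ndarray:
        """The ``[N, C*F]`` channel-major view of the features."""
        return flatten(self.values)

    def subset(self, mask: np.ndarray) -> "DEFeatureSet":
        return replace(
            self,
            values=self.values[mask],
            labels=self.labels[mask],
            subject=self.subject[mask],
            session=self.session[mask],
            trial=self.trial[mask],
        )


@dataclass(frozen=True)
class TransferTask:
    """A (source corpus, target corpus) pair with the target trial split."""

    source_name: str
    target_name: str
    n_classes: int
    target_finetune_trials: frozenset
    target_test_trials: frozenset

    def __post_init__(self):
        if self.target_finetune_trials & self.target_test_trials:
            raise ValueError("fine-tune and test trial sets overlap")


def make_transfer_task(
    source: str,
    target: str,
    *,
    n_finetune: int | None = None,
    n_test: int | None = None,
    n_classes: int | None = None,
) -> TransferTask:
    """Build the target-side trial split for a cross-corpus task.

    For the six supported SEED-family tasks the split sizes are fixed by the
    protocol (target side): SEED 9/6, SEED-IV 3-class 12/6, SEED-V 3-class
    6/3, SEED-IV 4-class 16/8, SEED-V 4-class 8/4.  Synthetic pairs must
    give explicit counts.  Fine-tune trials are the first ``n_finetune``
    trial ids, test trials the following ``n_test``.
    """
    if n_finetune is None or n_test is None:
        if (source, target) not in SUPPORTED_TASKS:
            raise ValueError(
                f"unknown task {source!r} -> {target!r}; give explicit n_finetune/n_test"
            )
        n_finetune, n_test, n_classes = PROTOCOL_SPLITS[target]
    if n_classes is None:
        raise ValueError("n_classes required for custom tasks")
    ft = frozenset(range(n_finetune))
    te = frozenset(range(n_finetune, n_finetune + n_test))
    return TransferTask(source, target, n_classes, ft, te)


# ----------------------------------------------------------------------
# Shape plumbing
# ----------------------------------------------------------------------
def flatten(X: np.ndarray) -> np.ndarray:
    """``[B, C, F] -> [B, C*F]`` channel-major (band index fastest)."""
    X = np.asarray(X)
    if X.ndim != 3:
        raise ValueError(f"expected [B, C, F], got {X.shape}")
    return X.reshape(X.shape[0], -1)

def unflatten(M: np.ndarray, n_channels: int = 62, n_bands: int = 5) -> np.ndarray:
    """Inverse of :func:`flatten`; errors if the width is not C*F."""
    M = np.asarray(M)
    if M.ndim != 2 or M.shape[1] != n_channels * n_bands:
        raise FormatError(
            f"matrix of shape {M.shape} is not divisible into {n_channels}x{n_bands}"
        )
    return M.reshape(M.shape[0], n_channels, n_bands)


# ----------------------------------------------------------------------
# Normalisation
# ----------------------------------------------------------------------
@dataclass
class ZScoreStats:
    mean: np.ndarray
    std: np.ndarray
    clamped: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))


def zscore_normalize(
    X: np.ndarray, stats: ZScoreStats | None = None
) -> tuple[np.ndarray, ZScoreStats]:
    """Per-feature z-scoring with population (1/N) std.

    When ``stats`` is None they are computed from ``X`` and returned for
    reuse on held-out data.  Zero-variance columns get std clamped to 1 so
    the transform stays finite; the clamp is recorded and logged.
    """
    X = np.asarray(X, dtype=np.float64)
    if stats is None:
        mean = X.mean(axis=0)
        std = X.std(axis=0)  # population convention
        clamped = std == 0.0
        if clamped.any():
            logger.warning("zscore: %d zero-variance columns clamped to std=1", clamped.sum())
        std = np.where(clamped, 1.0, std)
        stats = ZScoreStats(mean=mean, std=std, clamped=clamped)
    elif stats.mean.shape[0] != X.shape[1]:
        raise ValueError("normalisation stats do not match feature width")
    return (X - stats.mean) / stats.std, stats


# ----------------------------------------------------------------------
# On-disk layouts
# ----------------------------------------------------------------------
def save_feature_set(ds: DEFeatureSet, path: str | Path, layout: str = "npz") -> None:
    """Write a feature set as NPZ, HDF5 or a CSV directory.

    All three layouts store the flat ``N x (C*F)`` matrix under ``values``
    plus ``labels``/``trial``/``subject``/``session`` vectors; the CSV
    directory splits ``values`` into one file per subject-session.
    """
    path = Path(path)
    flat = ds.flat()
    if layout == "npz":
        np.savez(
            path,
            values=flat,
            labels=ds.labels,
            trial=ds.trial,
            subject=ds.subject,
            session=ds.session,
            n_channels=np.int64(ds.n_channels),
        )
    elif layout == "hdf5":
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=flat)
            for name in ("labels", "trial", "subject", "session"):
                f.create_dataset(name, data=getattr(ds, name))
            f.attrs["n_channels"] = ds.n_channels
    elif layout == "csv-dir":
        path.mkdir(parents=True, exist_ok=True)
        import pandas as pd

        meta = pd.DataFrame(
            {
                "label": ds.labels,
                "trial": ds.trial,
                "subject": ds.subject,
                "session": ds.session,
            }
        )
        meta.to_csv(path / "labels.csv", index=False)
        for subj in np.unique(ds.subject):
            for sess in np.unique(ds.session[ds.subject == subj]):
                m = (ds.subject == subj) & (ds.session == sess)
                np.savetxt(
                    path / f"features_s{subj}_e{sess}.csv", flat[m], delimiter=","
                )
        (path / "meta.txt").write_text(f"n_channels={ds.n_channels}\n")
    else:
        raise ValueError(f"unknown layout {layout!r}")


def load_feature_set(path: str | Path, layout: str = "npz") -> DEFeatureSet:
    """Read a feature set written by :func:`save_feature_set`.

    Flat 310-wide matrices are reshaped to ``[N, 62, 5]`` (channel-major);
    other widths use the stored channel count.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if layout == "npz":
        try:
            with np.load(path) as z:
                flat = np.asarray(z["values"], dtype=np.float64)
                meta = {k: np.asarray(z[k]) for k in ("labels", "trial", "subject", "session")}
                n_channels = int(z["n_channels"]) if "n_channels" in z else 62
        except (OSError, KeyError, ValueError, EOFError) as e:
            raise FormatError(f"cannot read NPZ feature file {path}: {e}") from e
    elif layout == "hdf5":
        import h5py

        try:
            with h5py.File(path, "r") as f:
                flat = np.asarray(f["values"], dtype=np.float64)
                meta = {k: np.asarray(f[k]) for k in ("labels", "trial", "subject", "session")}
                n_channels = int(f.attrs.get("n_channels", 62))
        except (OSError, KeyError) as e:
            raise FormatError(f"cannot read HDF5 feature file {path}: {e}") from e
    elif layout == "csv-dir":
        import pandas as pd

        meta_df = pd.read_csv(path / "labels.csv")
        n_channels = 62
        meta_file = path / "meta.txt"
        if meta_file.exists():
            n_channels = int(meta_file.read_text().strip().split("=")[1])
        meta = {
            "labels": meta_df["label"].to_numpy(),
            "trial": meta_df["trial"].to_numpy(),
            "subject": meta_df["subject"].to_numpy(),
            "session": meta_df["session"].to_numpy(),
        }
        blocks = []
        for subj in np.unique(meta["subject"]):
            for sess in np.unique(meta["session"][meta["subject"] == subj]):
                blocks.append(
                    np.loadtxt(path / f"features_s{subj}_e{sess}.csv", delimiter=",", ndmin=2)
                )
        flat = np.concatenate(blocks, axis=0)
    else:
        raise ValueError(f"unknown layout {layout!r}")

    if flat.ndim != 2 or flat.shape[1] % 5 != 0:
        raise FormatError(f"feature matrix of shape {flat.shape} is not N x (C*5)")
    values = unflatten(flat, n_channels=n_channels, n_bands=5)
    if meta["labels"].shape[0] != flat.shape[0]:
        raise ConsistencyError("label length does not match sample count")
    return DEFeatureSet(values=values, **meta)
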