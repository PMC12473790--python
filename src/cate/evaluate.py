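"""Metrics, per-subject aggregation and the end-to-end experiment runner.

Accuracy is the fraction of correctly classified samples; corpus-level
results are reported as the mean and sample (n-1) standard deviation of
per-subject accuracies, in percent.  The experiment runner executes the
full two-stage protocol on a synthetic transfer pair — pre-train on the
unlabeled union of the source corpus and the target fine-tune trials,
fine-tune and test per target subject on the trial split — and supports
the ablation variants (no noise view, no wavelet view, no pre-training).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .data import DEFeatureSet, TransferTask, zscore_normalize
from .finetune import FinetuneConfig, predict, run_finetuning
from .pretrain import PretrainConfig, run_pretraining
from .synth import SynthConfig, default_transfer_pair, generate_transfer_pair

logger = logging.getLogger(__name__)

VARIANTS = ("full", "no-nerm", "no-wtrm", "no-pretrain")


def accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of samples classified correctly."""
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    if pred.size == 0:
        raise ValueError("accuracy of an empty prediction set is undefined")
    return float(np.mean(pred == truth))


def confusion_matrix(pred: np.ndarray, truth: np.ndarray, n_classes: int) -> np.ndarray:
    """K x K count matrix, rows = true class; trace/total equals accuracy."""
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.size and (max(pred.max(), truth.max()) >= n_classes or min(pred.min(), truth.min()) < 0):
        raise ValueError("label outside [0, n_classes)")
    return _sk_confusion(truth, pred, labels=np.arange(n_classes)).astype(np.int64)


def aggregate_subjects(per_subject_acc) -> tuple[float, float]:
    """(mean %, sample-sd %) across subjects; a single subject gives sd 0."""
    acc = np.asarray(per_subject_acc, dtype=np.float64)
    if acc.size == 0:
        raise ValueError("no per-subject accuracies to aggregate")
    if acc.size == 1:
        warnings.warn("single subject: standard deviation reported as 0", stacklevel=2)
        return float(acc[0] * 100.0), 0.0
    return float(acc.mean() * 100.0), float(acc.std(ddof=1) * 100.0)


@dataclass
class EvalReport:
    """Target-side evaluation summary of one experiment run."""

    accuracy: float
    per_subject_acc: list
    mean_acc: float  # percent
    std_acc: float  # percent
    confusion: np.ndarray

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_subject_acc": list(map(float, self.per_subject_acc)),
            "mean_acc": self.mean_acc,
            "std_acc": self.std_acc,
            "confusion": self.confusion.tolist(),
        }


@dataclass
class ExperimentConfig:
    """Everything needed to run the two-stage protocol on a synthetic pair."""

    variant: str = "full"
    seed: int = 0
    d_model: int = 64
    pretrain: PretrainConfig | None = None
    finetune: FinetuneConfig | None = None
    synth_source: SynthConfig | None = None
    synth_target: SynthConfig | None = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        # accept plain dicts (e.g. parsed from YAML) for the nested configs
        coerce = {
            "pretrain": PretrainConfig,
            "finetune": FinetuneConfig,
            "synth_source": SynthConfig,
            "synth_target": SynthConfig,
        }
        for name, cls in coerce.items():
            val = getattr(self, name)
            if isinstance(val, dict):
                setattr(self, name, cls(**val))


def run_experiment(cfg: ExperimentConfig) -> EvalReport:
    """synth -> pretrain -> per-subject finetune -> evaluate, fully seeded."""
    if cfg.synth_source is not None and cfg.synth_target is not None:
        source, target, task = generate_transfer_pair(cfg.synth_source, cfg.synth_target)
    else:
        source, target, task = default_transfer_pair(seed=cfg.seed)

    pcfg = cfg.pretrain or PretrainConfig(
        epochs=30, batch_size=128, d_model=cfg.d_model, seed=cfg.seed
    )
    pcfg = replace(pcfg, d_model=cfg.d_model, seed=cfg.seed)
    fcfg = cfg.finetune or FinetuneConfig(epochs=15, batch_size=64, learning_rate=1e-3)
    fcfg = replace(fcfg, seed=cfg.seed)

    pretrained = None
    if cfg.variant != "no-pretrain":
        ft_mask = np.isin(target.trial, sorted(task.target_finetune_trials))
        corpus = [source, target.subset(ft_mask)]
        pretrained, _ = run_pretraining(
            corpus,
            pcfg,
            use_nerm=cfg.variant != "no-nerm",
            use_wtrm=cfg.variant != "no-wtrm",
        )

    per_subject, confusions = [], []
    test_trials = sorted(task.target_test_trials)
    for subj in np.unique(target.subject):
        subj_data = target.subset(target.subject == subj)
        model, stats, _ = run_finetuning(
            pretrained, task, subj_data, fcfg, d_model=cfg.d_model
        )
        test = subj_data.subset(np.isin(subj_data.trial, test_trials))
        X_test, _ = zscore_normalize(test.flat(), stats)
        pred = predict(model, X_test)
        per_subject.append(accuracy(pred, test.labels))
        confusions.append(confusion_matrix(pred, test.labels, task.n_classes))

    conf = np.sum(confusions, axis=0)
    mean_pct, std_pct = aggregate_subjects(per_subject)
    return EvalReport(
        accuracy=float(np.trace(conf) / conf.sum()),
        per_subject_acc=per_subject,
        mean_acc=mean_pct,
        std_acc=std_pct,
        confusion=conf,
    )


def write_report(report: EvalReport, out_dir: str | Path, name: str = "report") -> None:
    """JSON summary plus the confusion matrix as CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / f"{name}.json").write_text(json.dumps(report.to_dict(), indent=2))
    np.savetxt(out_dir / f"{name}_confusion.csv", report.confusion, fmt="%d", delimiter=",")
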