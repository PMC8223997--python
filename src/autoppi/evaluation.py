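"""Confusion-matrix metrics, k-fold cross-validation, confidence intervals.

Metrics follow the usual confusion-matrix definitions with "positive" =
interacting.  The headline ranking metric is *balanced accuracy*,
(specificity + recall)/2, exposed as ``auc_balanced``; a conventional
rank-based ROC-AUC over the pr+ scores is available separately for
diagnostics (``rank_roc_auc``) but is never part of the report.

Cross-validation partitions each class independently into k seeded folds
(training is per-class by construction, so stratification is per class),
fits a fresh two-autoencoder model on the k-1 training folds and evaluates
on the held-out fold.  Per-metric means come with 95% Student-t confidence
interval half-widths.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from . import classifier as clf
from .autoencoders import TrainingConfig
from .descriptors import DescriptorConfig, featurize_proteins, pair_vector
from .sequence_io import LabeledPairSet, PairExample, ProteinRecord

logger = logging.getLogger("autoppi")

METRIC_NAMES = ("accuracy", "precision", "recall", "specificity", "f1", "auc_balanced")


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    auc_balanced: float


def confusion(preds: list[bool], truth: list[bool]) -> ConfusionMatrix:
    """Count TP/FP/TN/FN with True = interacting."""
    if len(preds) != len(truth):
        raise EvaluationError(
            f"length mismatch: {len(preds)} predictions vs {len(truth)} labels"
        )
    p = np.asarray(preds, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    return ConfusionMatrix(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        logger.warning("degenerate denominator for %s (0/0); reporting 0 by convention", name)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Standard confusion-matrix metrics; degenerate denominators yield 0."""
    precision = _ratio(cm.tp, cm.tp + cm.fp, "precision")
    recall = _ratio(cm.tp, cm.tp + cm.fn, "recall")
    specificity = _ratio(cm.tn, cm.tn + cm.fp, "specificity")
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    accuracy = _ratio(cm.tp + cm.tn, cm.total, "accuracy")
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1=f1,
        auc_balanced=(specificity + recall) / 2.0,
    )


def rank_roc_auc(scores: list[float], truth: list[bool]) -> float:
    """Conventional rank-based ROC-AUC over pr+ scores (diagnostic only)."""
    return float(roc_auc_score(np.asarray(truth, dtype=int), np.asarray(scores)))


def confidence_interval(values: list[float], level: float = 0.95) -> tuple[float, float]:
    """Student-t interval for the mean: returns (mean, half-width).

    Half-width = t_{(1+level)/2, n-1} * s / sqrt(n) with s the sample
    standard deviation (ddof=1).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise EvaluationError("confidence interval needs at least 2 values")
    mean = float(v.mean())
    s = float(v.std(ddof=1))
    tq = float(stats.t.ppf((1 + level) / 2.0, v.size - 1))
    return mean, tq * s / np.sqrt(v.size)


@dataclass
class CVReport:
    """Per-fold metric rows plus mean and 95% CI half-width per metric."""

    folds: list[MetricsReport]
    mean: dict[str, float]
    ci_halfwidth: dict[str, float]

    @property
    def k(self) -> int:
        return len(self.folds)

    def to_frame(self) -> pd.DataFrame:
        rows = [asdict(f) for f in self.folds]
        df = pd.DataFrame(rows, index=pd.Index(range(1, self.k + 1), name="fold"))
        return df

    def summary(self, decimals: int = 4) -> str:
        """One line per metric, formatted 'mean ± halfwidth'."""
        return "\n".join(
            f"{name}: {self.mean[name]:.{decimals}f} ± {self.ci_halfwidth[name]:.{decimals}f}"
            for name in METRIC_NAMES
        )

    def write(self, path: str | Path) -> None:
        """JSON + TSV export (path without extension gets both)."""
        path = Path(path)
        base = path.with_suffix("") if path.suffix in (".json", ".tsv") else path
        payload = {
            "folds": [asdict(f) for f in self.folds],
            "mean": self.mean,
            "ci_halfwidth": self.ci_halfwidth,
        }
        base.with_suffix(".json").write_text(json.dumps(payload, indent=2))
        df = self.to_frame()
        summary_row = {
            name: f"{self.mean[name]:.4f} ± {self.ci_halfwidth[name]:.4f}"
            for name in METRIC_NAMES
        }
        out = pd.concat([df.astype(object), pd.DataFrame([summary_row], index=["mean"])])
        out.to_csv(base.with_suffix(".tsv"), sep="\t")


def _fold_slices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffle indices 0..n-1 and split into k nearly equal folds."""
    perm = rng.permutation(n)
    return [np.array(f) for f in np.array_split(perm, k)]


def _pair_matrix(
    pairs: list[PairExample], features: dict, fingerprint: str
) -> np.ndarray:
    return np.vstack(
        [pair_vector(features[p.id_a], features[p.id_b]) for p in pairs]
    )


def cross_validate(
    proteins: list[ProteinRecord],
    pairs: LabeledPairSet,
    k: int,
    arch: str,
    tconfig: TrainingConfig,
    dconfig: DescriptorConfig,
    seed: int = 0,
    hidden: tuple[int, int] = (600, 600),
    bottleneck: int = 300,
    fit_fn=None,
    predict_fn=None,
) -> CVReport:
    """k-fold CV of the full pipeline with per-class fold assignment.

    Each class's pairs are shuffled with a seeded generator and split into k
    folds; fold i's test set is the union of the two classes' i-th folds and
    the model is fit on everything else with the shared hyperparameters.

    ``fit_fn``/``predict_fn`` default to the two-autoencoder pipeline and can
    be replaced by stubs to test the harness itself.
    """
    if k < 2:
        raise EvaluationError("k must be >= 2")
    if len(pairs.positives) < k or len(pairs.negatives) < k:
        raise EvaluationError(
            f"each class needs at least k={k} pairs "
            f"(have {len(pairs.positives)}+/{len(pairs.negatives)}-)"
        )

    features = featurize_proteins(proteins, dconfig)
    fp = dconfig.fingerprint()
    pos_mat = _pair_matrix(pairs.positives, features, fp)
    neg_mat = _pair_matrix(pairs.negatives, features, fp)

    rng = np.random.default_rng(seed)
    pos_folds = _fold_slices(pos_mat.shape[0], k, rng)
    neg_folds = _fold_slices(neg_mat.shape[0], k, rng)

    fold_reports: list[MetricsReport] = []
    for i in range(k):
        train_pos = np.vstack([pos_mat[f] for j, f in enumerate(pos_folds) if j != i])
        train_neg = np.vstack([neg_mat[f] for j, f in enumerate(neg_folds) if j != i])
        fold_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
        fold_cfg = TrainingConfig(**{**tconfig.__dict__, "seed": fold_seed})
        if fit_fn is None:
            model, _ = clf.fit(
                train_pos, train_neg, arch, fold_cfg,
                fingerprint=fp, hidden=hidden, bottleneck=bottleneck,
            )
        else:
            model = fit_fn(train_pos, train_neg, arch, fold_cfg)
        test = np.vstack([pos_mat[pos_folds[i]], neg_mat[neg_folds[i]]])
        truth = [True] * len(pos_folds[i]) + [False] * len(neg_folds[i])
        if predict_fn is None:
            preds = [r.label for r in clf.predict_batch(model, test)]
        else:
            preds = list(predict_fn(model, test))
        fold_reports.append(metrics(confusion(preds, truth)))

    mean: dict[str, float] = {}
    half: dict[str, float] = {}
    for name in METRIC_NAMES:
        vals = [getattr(f, name) for f in fold_reports]
        mean[name], half[name] = confidence_interval(vals)
    return CVReport(folds=fold_reports, mean=mean, ci_halfwidth=half)
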