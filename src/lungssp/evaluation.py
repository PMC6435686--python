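"""Scoring predictions and the iterated balanced train/test protocol.

Metrics: accuracy, balanced accuracy (mean per-class recall), macro
one-vs-rest AUC (rank-based, midrank ties), and per-class sensitivity,
specificity and precision.  Because a 2x2 concordance can be read with
either method as the reference, the per-class table carries both the
label-as-truth specificity and the precision (prediction-as-reference
agreement), explicitly labeled.

The feasibility protocol partitions a cohort into stratified train/test
splits of fixed size (class proportions preserved, remainder to train),
trains a fresh SSP per iteration, and summarizes per-iteration metrics as
mean and SD for both the reclassified training split and the held-out test
split.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .io_formats import ExpressionMatrix
from .ssp_core import MarkerPanel, Prediction, TrainConfig, predict_ssp, train_ssp


@dataclass
class EvaluationReport:
    """Confusion matrix plus summary metrics for one run or an iterated protocol."""

    confusion: pd.DataFrame                  # true class rows x predicted columns
    accuracy: float
    balanced_accuracy: float
    macro_auc: float | None
    per_class: pd.DataFrame                  # sensitivity / specificity / precision
    n_iterations: int = 1
    per_iteration: pd.DataFrame | None = None
    summary: pd.DataFrame | None = None      # mean/sd per metric, train & test

    def to_json(self) -> str:
        d = {
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "macro_auc": self.macro_auc,
            "n_iterations": self.n_iterations,
            "confusion": {c: self.confusion[c].to_dict() for c in self.confusion.columns},
            "per_class": self.per_class.to_dict(orient="index"),
        }
        if self.summary is not None:
            d["summary"] = self.summary.to_dict(orient="index")
        return json.dumps(d, indent=2)


def confusion_from_counts(
    counts: Mapping[tuple[str, str], int], classes: Sequence[str]
) -> pd.DataFrame:
    """Build a confusion DataFrame from (true, predicted) -> count entries."""
    df = pd.DataFrame(0, index=list(classes), columns=list(classes), dtype=int)
    for (t, p), n in counts.items():
        df.loc[t, p] = int(n)
    return df


def _metrics_from_confusion(conf: pd.DataFrame) -> tuple[float, float, pd.DataFrame]:
    n = conf.to_numpy().sum()
    acc = float(np.trace(conf.to_numpy()) / n)
    rows = {}
    recalls = []
    for c in conf.index:
        tp = conf.loc[c, c]
        fn = conf.loc[c].sum() - tp
        fp = conf[c].sum() - tp
        tn = n - tp - fn - fp
        sens = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        prec = tp / (tp + fp) if tp + fp else np.nan
        rows[c] = {"sensitivity": sens, "specificity": spec, "precision": prec}
        if tp + fn:
            recalls.append(sens)
    bal = float(np.mean(recalls))
    return acc, bal, pd.DataFrame(rows).T


def score_confusion(conf: pd.DataFrame) -> EvaluationReport:
    """Score a pre-tabulated confusion matrix (e.g. a printed concordance table)."""
    acc, bal, per_class = _metrics_from_confusion(conf)
    return EvaluationReport(conf, acc, bal, None, per_class)


def score_predictions(
    predictions: Sequence[Prediction],
    labels: pd.Series,
    classes: Sequence[str] | None = None,
) -> EvaluationReport:
    """Score a set of single-sample predictions against true labels.

    Accuracy is trace/n, balanced accuracy the mean per-class recall;
    macro AUC is computed from the posteriors when every prediction carries
    them.  Unlabeled predictions are a hard error.
    """
    missing = [p.sample_id for p in predictions if p.sample_id not in labels.index]
    if missing:
        raise ValueError(f"no label for predicted samples: {missing}")
    y_true = [str(labels[p.sample_id]) for p in predictions]
    y_pred = [p.predicted_class for p in predictions]
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    conf = pd.DataFrame(0, index=list(classes), columns=list(classes), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf.loc[t, p] += 1
    acc, bal, per_class = _metrics_from_confusion(conf)
    post = pd.DataFrame({c: [p.posterior.get(c, np.nan) for p in predictions]
                         for c in predictions[0].posterior}, index=[p.sample_id for p in predictions])
    auc = macro_ovr_auc(post, pd.Series(y_true, index=post.index)) if not post.isna().any().any() else None
    return EvaluationReport(conf, acc, bal, auc, per_class)


def macro_ovr_auc(posteriors: pd.DataFrame, labels: pd.Series) -> float:
    """Macro-averaged one-vs-rest AUC with midrank tie handling.

    For every class with at least one positive and one negative sample in
    ``labels``, the class's posterior column is scored against the binary
    one-vs-rest labels; classes that cannot be scored are skipped with a
    warning.  Invariant to strictly increasing transforms of the scores.
    """
    labels = labels.loc[posteriors.index]
    aucs = []
    for c in sorted(set(labels)):
        if c not in posteriors.columns:
            warnings.warn(f"no posterior column for class {c!r}; skipped in macro AUC")
            continue
        y = (labels == c).to_numpy().astype(int)
        if y.sum() == 0 or y.sum() == len(y):
            warnings.warn(f"class {c!r} lacks positives or negatives; skipped in macro AUC")
            continue
        aucs.append(roc_auc_score(y, posteriors[c].to_numpy()))
    if not aucs:
        raise ValueError("no class could be scored for AUC")
    return float(np.mean(aucs))


def iterated_holdout(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    panel: MarkerPanel | None = None,
    n_iter: int = 10,
    train_n: int = 48,
    test_n: int = 20,
    seed: int = 0,
    train_config: TrainConfig | None = None,
) -> EvaluationReport:
    """Iterated stratified train/test protocol.

    Each iteration draws a fresh class-proportion-preserving partition of
    ``train_n``/``test_n`` samples (remainder to train), trains an SSP on the
    training split and scores both the reclassified training split and the
    held-out test split.  The report carries the per-iteration table, the
    mean/SD summary (SD only when ``n_iter > 1``), and the test confusion
    pooled over iterations.
    """
    common = [s for s in matrix.sample_ids if s in labels.index]
    matrix = matrix.subset_samples(common)
    y = labels.loc[common].astype(str)
    if train_n + test_n != len(common):
        raise ValueError(
            f"train_n + test_n = {train_n + test_n} but cohort has {len(common)} labeled samples"
        )
    base_config = train_config or TrainConfig()
    rows = []
    pooled: pd.DataFrame | None = None
    classes = sorted(set(y))
    for it in range(n_iter):
        it_seed = seed + it
        train_ids, test_ids = train_test_split(
            common, test_size=test_n, random_state=it_seed, stratify=y.loc[common]
        )
        cfg = TrainConfig(
            alpha=base_config.alpha, k_grid=base_config.k_grid,
            folds=base_config.folds, seed=it_seed, priors_mode=base_config.priors_mode,
        )
        model = train_ssp(matrix.subset_samples(train_ids), y.loc[train_ids], panel, cfg)
        rep_train = score_predictions(
            predict_ssp(model, matrix.subset_samples(train_ids)), y, classes
        )
        rep_test = score_predictions(
            predict_ssp(model, matrix.subset_samples(test_ids)), y, classes
        )
        rows.append(
            {
                "iteration": it, "seed": it_seed, "n_rules": model.n_rules,
                "train_accuracy": rep_train.accuracy,
                "train_balanced_accuracy": rep_train.balanced_accuracy,
                "train_auc": rep_train.macro_auc,
                "test_accuracy": rep_test.accuracy,
                "test_balanced_accuracy": rep_test.balanced_accuracy,
                "test_auc": rep_test.macro_auc,
            }
        )
        pooled = rep_test.confusion if pooled is None else pooled + rep_test.confusion
    per_iter = pd.DataFrame(rows)
    metric_cols = [c for c in per_iter.columns if c not in ("iteration", "seed", "n_rules")]
    summary = pd.DataFrame({"mean": per_iter[metric_cols].mean()})
    if n_iter > 1:
        summary["sd"] = per_iter[metric_cols].std(ddof=1)
    acc, bal, per_class = _metrics_from_confusion(pooled)
    return EvaluationReport(
        confusion=pooled,
        accuracy=float(per_iter["test_accuracy"].mean()),
        balanced_accuracy=float(per_iter["test_balanced_accuracy"].mean()),
        macro_auc=float(per_iter["test_auc"].mean()),
        per_class=per_class,
        n_iterations=n_iter,
        per_iteration=per_iter,
        summary=summary,
    )
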