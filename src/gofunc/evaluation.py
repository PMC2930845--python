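"""Evaluation: confusion statistics, ROC scores, cross-validation, Wilcoxon.

Per (term, method) the harness reports sensitivity, specificity,
precision, recall, F1 (the harmonic mean of precision and recall — robust
to the heavy class imbalance of one-vs-rest GO datasets) and the ROC
score (area under the ROC curve, equal to the probability that a random
positive outscores a random negative, ties counted 1/2).

The cross-validation protocol: stratified folds; per fold the three
methods are trained on the other folds, then every test-fold sample is
calibrated leave-one-out against the rest of its fold (the *helper set*),
which is also what supplies the per-method ROC scores behind the
weighted-mean combiner.  Helper samples are never used for training or
for the reported statistics.  Statistics are averaged over folds.
Zero-denominator rates are reported as 0 (not NaN) so averages over many
terms stay defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .calibration import HelperSet, calibrate
from .datasets import TermDataset
from .ensemble import (
    addition_combine,
    mean_combine,
    vote,
    weighted_mean_combine,
    weights_from_roc,
)
from .errors import GofuncError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(predicted, truth) -> ConfusionCounts:
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if predicted.shape != truth.shape:
        raise ValueError(
            f"length mismatch: {predicted.shape} predictions vs {truth.shape} truths"
        )
    return ConfusionCounts(
        tp=int((predicted & truth).sum()),
        fp=int((predicted & ~truth).sum()),
        tn=int((~predicted & ~truth).sum()),
        fn=int((~predicted & truth).sum()),
    )


def f1_stats(c: ConfusionCounts) -> dict[str, float]:
    """Precision, recall (= sensitivity), specificity and F1.

    Zero denominators yield 0 by convention.
    """
    precision = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    recall = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    specificity = c.tn / (c.tn + c.fp) if c.tn + c.fp else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if precision + recall else 0.0
    return {
        "precision": precision,
        "recall": recall,
        "sensitivity": recall,
        "specificity": specificity,
        "f1": f1,
    }


def roc_score(scores, truth) -> float:
    """AUC as the rank statistic P(score+ > score-), ties counted 1/2."""
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise GofuncError("ROC score undefined: only one class present")
    return float(roc_auc_score(truth.astype(int), np.asarray(scores, dtype=float)))


def wilcoxon_signed_rank(paired_a, paired_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test (normal approximation).

    Zero differences are dropped; midranks for ties; continuity
    correction applied.  All-zero differences are degenerate:
    (statistic 0, p = 1).
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if np.all(a == b):
        return 0.0, 1.0
    res = scipy.stats.wilcoxon(
        a, b, zero_method="wilcox", correction=True, method="approx"
    )
    return float(res.statistic), float(res.pvalue)


def _helper_roc(raws: np.ndarray, truths: np.ndarray, hold_out: int) -> float:
    """ROC of one method on the helper set (fold minus one sample)."""
    mask = np.ones(len(raws), dtype=bool)
    mask[hold_out] = False
    t = truths[mask]
    if t.all() or not t.any():
        return 0.5  # degenerate helper set: no discrimination measurable
    return roc_score(raws[mask], t)


def cross_validate(
    dataset: TermDataset,
    sequences: Mapping[str, str],
    method_factories: Mapping[str, Callable[[], object]],
    folds: int = 5,
    seed: int = 0,
    exponent: float = 10.0,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Stratified k-fold evaluation of the methods and their combiners.

    Returns one row per evaluated method/combiner with fold-averaged
    statistics.  Rows named ``<method>`` use threshold-relaxed labels;
    rows named ``<method>_natural`` use the raw output at its natural
    threshold 0, quantifying what relaxation buys.  Combiner rows
    (``vote``, ``mean``, ``wmean``, ``add``) appear when all three base
    methods are evaluated.
    """
    if folds < 2:
        raise ValueError(f"folds must be >= 2, got {folds}")
    ids = sorted(dataset.positives) + sorted(dataset.negatives)
    truth = np.array([pid in dataset.positives for pid in ids])
    if truth.sum() < folds or (~truth).sum() < folds:
        raise GofuncError(
            f"{dataset.term_id}: each class needs at least {folds} members"
        )
    missing = [pid for pid in ids if pid not in sequences]
    if missing:
        raise GofuncError(f"no sequence for protein(s) {missing[:5]}")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_stats: dict[str, list[dict[str, float]]] = {}

    for train_idx, test_idx in skf.split(ids, truth.astype(int)):
        train_ids = [ids[i] for i in train_idx]
        test_ids = [ids[i] for i in test_idx]
        y_train, y_test = truth[train_idx], truth[test_idx]
        train_seqs = [sequences[p] for p in train_ids]
        test_seqs = [sequences[p] for p in test_ids]

        raws: dict[str, np.ndarray] = {}
        for name, factory in method_factories.items():
            method = factory()
            method.fit(train_ids, train_seqs, y_train)
            raws[name] = np.asarray(method.decision_values(test_seqs), dtype=float)

        n_test = len(test_ids)
        per_sample: dict[str, dict[str, list]] = {
            name: {"p": [], "label": []} for name in raws
        }
        comb: dict[str, dict[str, list]] = {
            name: {"p": [], "label": []} for name in ("vote", "mean", "wmean", "add")
        }
        trio = {"knn", "spmap", "pepstats"} <= set(raws)
        summed = sum(raws[m] for m in raws)

        for i in range(n_test):
            mask = np.ones(n_test, dtype=bool)
            mask[i] = False
            ps: dict[str, float] = {}
            labels: dict[str, bool] = {}
            for name, r in raws.items():
                helper = HelperSet(
                    positive_outputs=list(r[mask & y_test]),
                    negative_outputs=list(r[mask & ~y_test]),
                )
                pred = calibrate(float(r[i]), helper, threshold=threshold)
                ps[name], labels[name] = pred.p, pred.label
                per_sample[name]["p"].append(pred.p)
                per_sample[name]["label"].append(pred.label)
            if trio:
                trio_names = ("knn", "spmap", "pepstats")
                comb["vote"]["label"].append(vote([labels[m] for m in trio_names]))
                comb["vote"]["p"].append(np.mean([ps[m] for m in trio_names]))
                mp = mean_combine([ps[m] for m in trio_names], threshold=threshold)
                comb["mean"]["p"].append(mp.p)
                comb["mean"]["label"].append(mp.label)
                rocs = {
                    m: _helper_roc(raws[m], y_test, i) for m in trio_names
                }
                wp = weighted_mean_combine(
                    {m: ps[m] for m in trio_names},
                    weights_from_roc(rocs, exponent),
                    threshold=threshold,
                )
                comb["wmean"]["p"].append(wp.p)
                comb["wmean"]["label"].append(wp.label)
                helper_sum = HelperSet(
                    positive_outputs=list(summed[mask & y_test]),
                    negative_outputs=list(summed[mask & ~y_test]),
                )
                ap = addition_combine(
                    [raws[m][i] for m in trio_names], helper_sum,
                    threshold=threshold,
                )
                comb["add"]["p"].append(ap.p)
                comb["add"]["label"].append(ap.label)

        def record(row_name: str, labels_arr, scores_arr) -> None:
            c = confusion(labels_arr, y_test)
            stats = f1_stats(c)
            both = y_test.any() and not y_test.all()
            stats["roc_score"] = roc_score(scores_arr, y_test) if both else 0.5
            stats.update(tp=c.tp, fp=c.fp, tn=c.tn, fn=c.fn)
            fold_stats.setdefault(row_name, []).append(stats)

        for name, r in raws.items():
            record(name, np.array(per_sample[name]["label"]), np.array(per_sample[name]["p"]))
            record(f"{name}_natural", r > 0.0, r)
        if trio:
            for cname, d in comb.items():
                record(cname, np.array(d["label"]), np.array(d["p"]))

    rows = []
    for name, stats_list in fold_stats.items():
        avg = {k: float(np.mean([s[k] for s in stats_list])) for k in stats_list[0]}
        avg["method"] = name
        avg["term_id"] = dataset.term_id
        avg["n_pos"] = int(truth.sum())
        avg["n_neg"] = int((~truth).sum())
        rows.append(avg)
    cols = [
        "term_id", "method", "n_pos", "n_neg", "tp", "fp", "tn", "fn",
        "sensitivity", "specificity", "precision", "recall", "f1", "roc_score",
    ]
    return pd.DataFrame(rows)[cols].set_index("method")
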