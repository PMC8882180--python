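"""Cross-validated evaluation: stratified (optionally participant-grouped)
repeated k-fold, confusion-matrix metrics, model selection by FPR/TNR, the
one-tailed binomial test against the null-information rate, the
two-proportion z-test, and hold-out evaluation with a leakage guard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from statsmodels.stats.proportion import proportions_ztest

from .classifiers import EnsembleConfig, ModelBundle, predict_bundle, train_ensemble
from .errors import LeakageError, ValidationError

__all__ = [
    "ConfusionCounts",
    "CvResult",
    "stratified_repeated_kfold",
    "confusion_from_predictions",
    "compute_metrics",
    "rank_auc",
    "select_model",
    "binomial_test_vs_nir",
    "null_information_rate",
    "two_proportion_test",
    "cross_validate_ensemble",
    "evaluate_holdout",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def validate(self) -> "ConfusionCounts":
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValidationError("confusion counts are all zero")
        return self


def stratified_repeated_kfold(keys, labels, k: int = 5, repeats: int = 5,
                              seed: int = 0, groups=None,
                              ) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    """Fold assignments: ``repeats`` independent stratified k-fold splits.

    Returns one list of (train_idx, test_idx) pairs per repeat.  Without
    ``groups``, per-fold class counts differ from proportional by at most
    one sample.  With ``groups`` (participant ids), all scans of one
    participant stay in the same fold and stratification is approximate.
    """
    y = np.asarray(labels)
    keys = np.asarray(keys, dtype=object)
    counts = pd.Series(y).value_counts()
    if counts.min() < k:
        raise ValidationError(
            f"smallest class has {counts.min()} members < k={k}")
    out = []
    for r in range(repeats):
        if groups is None:
            cv = StratifiedKFold(n_splits=k, shuffle=True,
                                 random_state=seed + r)
            splits = cv.split(keys.reshape(-1, 1), y)
        else:
            cv = StratifiedGroupKFold(n_splits=k, shuffle=True,
                                      random_state=seed + r)
            splits = cv.split(keys.reshape(-1, 1), y, np.asarray(groups))
        out.append([(tr.copy(), te.copy()) for tr, te in splits])
    return out


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    ).validate()


def rank_auc(y_true, scores) -> float:
    """AUC as the tie-averaged rank statistic (Mann-Whitney form)."""
    y = np.asarray(y_true, int)
    s = np.asarray(scores, float)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("AUC needs both classes present")
    order = pd.Series(s).rank(method="average").to_numpy()
    return float((order[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def compute_metrics(cc: ConfusionCounts, probabilities=None,
                    y_true=None) -> dict:
    """Accuracy, PPV, FPR, sensitivity, specificity and (given scores) AUC.

    Metrics with a zero denominator are returned as None and listed under
    ``"undefined"`` rather than silently yielding NaN.  On an all-negative
    set, accuracy + FPR = 1 exactly.
    """
    cc.validate()
    metrics: dict = {"counts": cc, "undefined": []}

    def ratio(name, num, den):
        if den == 0:
            metrics[name] = None
            metrics["undefined"].append(name)
        else:
            metrics[name] = num / den

    ratio("accuracy", cc.tp + cc.tn, cc.total)
    ratio("ppv", cc.tp, cc.tp + cc.fp)
    ratio("fpr", cc.fp, cc.fp + cc.tn)
    ratio("sensitivity", cc.tp, cc.tp + cc.fn)
    ratio("specificity", cc.tn, cc.tn + cc.fp)
    metrics["tnr"] = metrics["specificity"]
    if probabilities is not None and y_true is not None:
        y = np.asarray(y_true, int)
        if 0 < y.sum() < len(y):
            metrics["auc"] = rank_auc(y, probabilities)
        else:
            metrics["auc"] = None
            metrics["undefined"].append("auc")
    return metrics


def select_model(candidates: list[dict]) -> dict:
    """Pick the candidate minimising mean FPR/TNR over folds.

    Each candidate carries ``fold_fpr``/``fold_tnr`` sequences, an
    ``accuracy`` and a ``config_id``.  Ties break by higher accuracy, then
    lexicographically smaller config id.
    """
    scored = []
    for cand in candidates:
        fpr = np.asarray(cand["fold_fpr"], float)
        tnr = np.asarray(cand["fold_tnr"], float)
        if np.any(tnr == 0):
            continue
        scored.append((float(np.mean(fpr / tnr)), -float(cand["accuracy"]),
                       str(cand["config_id"]), cand))
    if not scored:
        raise ValidationError("no candidate has nonzero TNR in every fold")
    return min(scored)[3]


def null_information_rate(labels) -> float:
    """Majority-class proportion: the chance accuracy benchmark."""
    y = np.asarray(labels)
    return float(pd.Series(y).value_counts(normalize=True).max())


def binomial_test_vs_nir(n_correct: int, n_total: int, nir: float) -> float:
    """Exact one-tailed tail mass P(X >= n_correct), X ~ Binomial(n, nir)."""
    if not (0 <= n_correct <= n_total) or n_total <= 0:
        raise ValidationError("need 0 <= n_correct <= n_total, n_total > 0")
    if not (0 < nir < 1):
        raise ValidationError("nir must lie in (0, 1)")
    return float(binom.sf(n_correct - 1, n_total, nir))


def two_proportion_test(x1: int, n1: int, x2: int, n2: int,
                        alternative: str = "larger") -> tuple[float, float]:
    """Pooled-variance two-sample proportion z-test.

    ``alternative``: "larger" tests p1 > p2 one-sided; "two-sided" is the
    symmetric version.  Returns (z, p).
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0 or not (0 <= x <= n):
            raise ValidationError("counts out of range")
    z, p = proportions_ztest([x1, x2], [n1, n2], alternative=alternative)
    return float(z), float(p)


@dataclass
class CvResult:
    """Pooled and per-fold cross-validation outcome."""

    fold_counts: list[ConfusionCounts]
    fold_metrics: list[dict]
    pooled: dict
    nir: float
    binomial_p: float
    seed: int
    k: int
    repeats: int
    probabilities: np.ndarray = field(default_factory=lambda: np.zeros(0))
    y_true: np.ndarray = field(default_factory=lambda: np.zeros(0, int))

    @property
    def pooled_counts(self) -> ConfusionCounts:
        return sum(self.fold_counts, ConfusionCounts())


def cross_validate_ensemble(features: pd.DataFrame, sequences: dict,
                            config: EnsembleConfig | None = None,
                            k: int = 5, repeats: int = 5, seed: int = 0,
                            threshold: float = 0.5,
                            group_by_participant: bool = True) -> CvResult:
    """Repeated stratified k-fold evaluation of the stacked ensemble.

    Folds are grouped by participant by default so no participant's scans
    straddle train and test.  Metrics are pooled over all test folds
    (micro-average); per-fold metrics ride along.  Significance is the
    exact binomial tail of pooled accuracy against the majority-class
    null-information rate.
    """
    y = features["label"].to_numpy(int)
    keys = np.arange(len(features))
    groups = (features["participant_id"].to_numpy(str)
              if group_by_participant else None)
    assignments = stratified_repeated_kfold(keys, y, k=k, repeats=repeats,
                                            seed=seed, groups=groups)
    fold_counts, fold_metrics = [], []
    probs_by_repeat = []
    for r, splits in enumerate(assignments):
        probs_r = np.full(len(y), np.nan)
        for f, (tr, te) in enumerate(splits):
            bundle = train_ensemble(features.iloc[tr], sequences, config,
                                    seed=seed + 1000 * r + f)
            probs = predict_bundle(bundle, features.iloc[te], sequences)
            probs_r[te] = probs
            pred = (probs >= threshold).astype(int)
            cc = confusion_from_predictions(y[te], pred)
            fold_counts.append(cc)
            fold_metrics.append(compute_metrics(cc, probs, y[te]))
        probs_by_repeat.append(probs_r)
    probs_flat = np.concatenate(probs_by_repeat)
    y_flat = np.tile(y, repeats)
    pooled_cc = sum(fold_counts, ConfusionCounts())
    pooled = compute_metrics(pooled_cc, probs_flat, y_flat)
    nir = null_information_rate(y)
    p = binomial_test_vs_nir(pooled_cc.tp + pooled_cc.tn, pooled_cc.total, nir)
    return CvResult(
        fold_counts=fold_counts, fold_metrics=fold_metrics, pooled=pooled,
        nir=nir, binomial_p=p, seed=seed, k=k, repeats=repeats,
        probabilities=probs_flat, y_true=y_flat,
    )


def evaluate_holdout(bundle: ModelBundle, features: pd.DataFrame,
                     sequences: dict, threshold: float = 0.5) -> dict:
    """Score a hold-out set; on an all-negative set accuracy + FPR = 1.

    Raises :class:`LeakageError` if any hold-out participant was seen in
    training.
    """
    overlap = bundle.train_participants & set(
        features["participant_id"].astype(str))
    if overlap:
        raise LeakageError(
            f"participants in both training and hold-out: {sorted(overlap)[:5]}")
    y = features["label"].to_numpy(int)
    probs = predict_bundle(bundle, features, sequences)
    pred = (probs >= threshold).astype(int)
    cc = confusion_from_predictions(y, pred)
    metrics = compute_metrics(cc, probs, y)
    if y.sum() == 0 and metrics["accuracy"] is not None:
        assert abs(metrics["accuracy"] + metrics["fpr"] - 1) < 1e-12
    metrics["probabilities"] = probs
    return metrics
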