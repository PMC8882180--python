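"""Predictive models: boosted trees on temporal features, the connectivity
RNN, and their stacked ensemble.

The ensemble follows a stacked design: within each training set, the RNN is
fitted on internal splits so that every training scan receives an
out-of-split connectivity probability, which is appended to the 95 temporal
features as a 96th predictor for the gradient-boosted tree model.  At
prediction time the RNN (refitted on the full training set) scores the
connectivity sequence first and the boosted trees consume the augmented
feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from xgboost import XGBClassifier

from .errors import ValidationError
from .features import feature_names
from .rnn import ConnectivityRNN, RnnConfig, train_rnn

__all__ = [
    "DEFAULT_GBT_PARAMS",
    "EnsembleConfig",
    "ModelBundle",
    "train_gbt",
    "train_ensemble",
    "predict_bundle",
]

DEFAULT_GBT_PARAMS = dict(
    n_estimators=200, max_depth=3, learning_rate=0.1,
    objective="binary:logistic", tree_method="hist", n_jobs=1,
    eval_metric="logloss",
)

RNN_PROB_COL = "rnn_prob"


def train_gbt(X, y, hyperparams: dict | None = None, seed: int = 0,
              sample_weight=None) -> XGBClassifier:
    """Gradient-boosted decision trees with predict_proba; deterministic for
    a fixed seed in single-threaded mode."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValidationError("training labels contain a single class")
    params = {**DEFAULT_GBT_PARAMS, **(hyperparams or {})}
    model = XGBClassifier(random_state=seed, **params)
    model.fit(np.asarray(X, float), y, sample_weight=sample_weight)
    return model


@dataclass
class EnsembleConfig:
    rnn: RnnConfig = field(default_factory=RnnConfig)
    gbt_params: dict = field(default_factory=dict)
    internal_splits: int = 2        # splits used for out-of-split RNN probs
    n_rounds: int = 1               # >1: AdaBoost-style GBT reweighting


@dataclass
class ModelBundle:
    """A fitted ensemble plus the metadata needed to apply it safely."""

    gbt: XGBClassifier
    rnn: ConnectivityRNN
    feature_manifest: tuple[str, ...]
    config: EnsembleConfig
    seed: int
    train_participants: frozenset[str]

    def validate(self) -> "ModelBundle":
        if len(self.feature_manifest) not in (95, 96):
            raise ValidationError(
                f"feature manifest has {len(self.feature_manifest)} entries")
        return self


def _split_frame(features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray,
                                                  np.ndarray, list[str]]:
    cols = feature_names()
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise ValidationError(f"feature table missing columns {missing[:3]}...")
    X = features[cols].to_numpy(float)
    y = features["label"].to_numpy(int)
    groups = features["participant_id"].to_numpy(str)
    return X, y, groups, cols


def _sequence_array(features: pd.DataFrame, sequences: dict) -> np.ndarray:
    keys = [(r.participant_id, r.visit_arm, int(r.scan_index))
            for r in features.itertuples()]
    missing = [k for k in keys if k not in sequences]
    if missing:
        raise ValidationError(
            f"connectivity sequences missing for scans {missing[:3]}...")
    return np.stack([np.asarray(sequences[k], float) for k in keys])


def _oof_rnn_probs(seqs: np.ndarray, y: np.ndarray, groups: np.ndarray,
                   config: EnsembleConfig, seed: int) -> np.ndarray:
    """Out-of-split RNN probabilities for every training scan.

    Splits are grouped by participant when possible; if the grouping forces
    a single-class split (tiny cohorts), the internal split falls back to
    plain stratification, and with fewer than two members per class the
    stacked column degenerates to an uninformative constant 0.5.
    """
    n_splits = min(config.internal_splits, int(np.min(np.bincount(y))))
    if n_splits < 2:
        return np.full(len(y), 0.5)
    for cv in (StratifiedGroupKFold(n_splits=n_splits, shuffle=True,
                                    random_state=seed),
               StratifiedKFold(n_splits=n_splits, shuffle=True,
                               random_state=seed)):
        oof = np.full(len(y), np.nan)
        try:
            splits = (cv.split(seqs, y, groups)
                      if isinstance(cv, StratifiedGroupKFold)
                      else cv.split(seqs, y))
            for i, (tr, te) in enumerate(splits):
                if len(np.unique(y[tr])) < 2:
                    raise ValidationError("single-class internal split")
                rnn = train_rnn(seqs[tr], y[tr], config.rnn, seed=seed + i)
                oof[te] = rnn.predict_proba(seqs[te])
        except ValidationError:
            continue
        if not np.any(np.isnan(oof)):
            return oof
    raise ValidationError("internal stacking splits failed for both "
                          "grouped and ungrouped stratification")


def train_ensemble(features: pd.DataFrame, sequences: dict,
                   config: EnsembleConfig | None = None,
                   seed: int = 0) -> ModelBundle:
    """Fit the stacked RNN + boosted-trees ensemble.

    ``features`` is the design matrix from
    :func:`nirsimpair.features.feature_matrix`; ``sequences`` maps each scan
    key to its (n_windows, 190) connectivity-vector sequence.  With
    ``n_rounds`` > 1, boosted-tree sample weights are raised on
    misclassified scans between rounds (a declared reconstruction of
    iterative ensemble boosting; off by default).
    """
    config = config or EnsembleConfig()
    X, y, groups, cols = _split_frame(features)
    seqs = _sequence_array(features, sequences)
    oof = _oof_rnn_probs(seqs, y, groups, config, seed)
    X_aug = np.column_stack([X, oof])
    weights = np.ones(len(y))
    gbt = train_gbt(X_aug, y, config.gbt_params, seed=seed,
                    sample_weight=weights)
    for _round in range(1, config.n_rounds):
        pred = gbt.predict_proba(X_aug)[:, 1] >= 0.5
        wrong = pred.astype(int) != y
        err = max(weights[wrong].sum() / weights.sum(), 1e-12)
        alpha = 0.5 * np.log((1 - err) / err)
        weights *= np.exp(np.where(wrong, alpha, -alpha))
        weights *= len(y) / weights.sum()
        gbt = train_gbt(X_aug, y, config.gbt_params, seed=seed,
                        sample_weight=weights)
    final_rnn = train_rnn(seqs, y, config.rnn, seed=seed)
    return ModelBundle(
        gbt=gbt, rnn=final_rnn,
        feature_manifest=tuple(cols) + (RNN_PROB_COL,),
        config=config, seed=seed,
        train_participants=frozenset(groups),
    ).validate()


def predict_bundle(bundle: ModelBundle, features: pd.DataFrame,
                   sequences: dict) -> np.ndarray:
    """Ensemble probabilities: RNN scores the sequence, trees take over."""
    bundle.validate()
    X, _y, _groups, _cols = _split_frame(features)
    seqs = _sequence_array(features, sequences)
    rnn_prob = bundle.rnn.predict_proba(seqs)
    X_aug = np.column_stack([X, rnn_prob])
    return bundle.gbt.predict_proba(X_aug)[:, 1]
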