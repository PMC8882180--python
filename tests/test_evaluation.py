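import numpy as np
import pytest
from scipy.stats import binom
from sklearn.metrics import roc_auc_score

from nirsimpair.errors import LeakageError, ValidationError
from nirsimpair.evaluation import (
    ConfusionCounts, binomial_test_vs_nir, compute_metrics,
    confusion_from_predictions, null_information_rate, rank_auc,
    select_model, stratified_repeated_kfold, two_proportion_test,
)


# ----------------------------------------------------------------- folds

def test_balanced_divisible_folds_exact():
    y = np.repeat([0, 1], 50)
    reps = stratified_repeated_kfold(np.arange(100), y, k=5, repeats=2, seed=0)
    for splits in reps:
        for _tr, te in splits:
            assert (y[te] == 1).sum() == 10
            assert (y[te] == 0).sum() == 10


def test_folds_partition_each_repeat():
    y = np.repeat([0, 1], [63, 37])
    reps = stratified_repeated_kfold(np.arange(100), y, k=5, repeats=3, seed=1)
    for splits in reps:
        tests = [set(te.tolist()) for _tr, te in splits]
        assert set().union(*tests) == set(range(100))
        for i in range(5):
            for j in range(i + 1, 5):
                assert not tests[i] & tests[j]


def test_unbalanced_positives_within_one_of_proportional():
    y = np.repeat([1, 0], [37, 63])
    reps = stratified_repeated_kfold(np.arange(100), y, k=5, repeats=2, seed=3)
    for splits in reps:
        per_fold = sorted(int((y[te] == 1).sum()) for _tr, te in splits)
        assert set(per_fold) <= {7, 8}
        assert sum(per_fold) == 37


def test_grouped_folds_keep_participants_together():
    y = np.tile([0, 0, 1, 1], 10)
    groups = np.repeat([f"P{i}" for i in range(20)], 2)
    reps = stratified_repeated_kfold(np.arange(40), y, k=4, repeats=2,
                                     seed=0, groups=groups)
    for splits in reps:
        for tr, te in splits:
            assert not set(groups[tr]) & set(groups[te])


def test_class_smaller_than_k_rejected():
    with pytest.raises(ValidationError, match="< k"):
        stratified_repeated_kfold(np.arange(10), [1, 1, 0, 0, 0, 0, 0, 0, 0, 0],
                                  k=5)


# ----------------------------------------------------------------- metrics

def test_metrics_hand_arithmetic():
    m = compute_metrics(ConfusionCounts(tp=3, fp=1, tn=9, fn=2))
    assert m["accuracy"] == pytest.approx(0.8)
    assert m["ppv"] == pytest.approx(0.75)
    assert m["fpr"] == pytest.approx(0.1)
    assert m["sensitivity"] == pytest.approx(0.6)
    assert m["specificity"] == pytest.approx(0.9)


def test_perfect_predictor():
    y = np.array([0, 0, 1, 1])
    p = np.array([0.1, 0.2, 0.8, 0.9])
    cc = confusion_from_predictions(y, p >= 0.5)
    m = compute_metrics(cc, p, y)
    assert m["accuracy"] == 1.0 and m["fpr"] == 0.0 and m["auc"] == 1.0


def test_all_negative_identity_accuracy_plus_fpr():
    cc = ConfusionCounts(tp=0, fp=154, tn=846, fn=0)
    m = compute_metrics(cc)
    assert m["accuracy"] + m["fpr"] == pytest.approx(1.0)
    assert m["accuracy"] == pytest.approx(0.846)
    assert m["ppv"] == 0.0
    assert "sensitivity" in m["undefined"]


def test_undefined_metrics_flagged_not_nan():
    m = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
    assert m["ppv"] is None and "ppv" in m["undefined"]


def test_rank_auc_matches_sklearn(rng):
    y = rng.integers(0, 2, 200)
    y[:2] = [0, 1]
    s = np.round(rng.standard_normal(200), 1)     # force ties
    assert rank_auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


def test_auc_invariant_under_monotone_transform(rng):
    y = rng.integers(0, 2, 100)
    y[:2] = [0, 1]
    s = rng.random(100)
    assert rank_auc(y, s) == pytest.approx(rank_auc(y, np.exp(3 * s)),
                                           abs=1e-12)


# ----------------------------------------------------------- model selection

def test_select_model_trivial_cases():
    a = {"fold_fpr": [0.2], "fold_tnr": [0.8], "accuracy": 0.7,
         "config_id": "a"}
    b = {"fold_fpr": [0.1], "fold_tnr": [0.9], "accuracy": 0.7,
         "config_id": "b"}
    assert select_model([a, b]) is b
    c = dict(a, accuracy=0.8, config_id="c")
    assert select_model([a, c]) is c


def test_selection_equals_argmin_fpr(rng):
    """FPR/TNR = FPR/(1-FPR) is increasing in FPR, so selection reduces to
    the smallest FPR."""
    for _ in range(100):
        n = int(rng.integers(2, 8))
        cands = []
        for i in range(n):
            fpr = float(rng.uniform(0.01, 0.8))
            cands.append({"fold_fpr": [fpr], "fold_tnr": [1 - fpr],
                          "accuracy": 0.5, "config_id": str(i)})
        best = select_model(cands)
        assert best["fold_fpr"][0] == min(c["fold_fpr"][0] for c in cands)


def test_all_zero_tnr_rejected():
    with pytest.raises(ValidationError):
        select_model([{"fold_fpr": [1.0], "fold_tnr": [0.0],
                       "accuracy": 0.5, "config_id": "x"}])


# ------------------------------------------------------------ binomial test

def test_binomial_perfect_ten():
    assert binomial_test_vs_nir(10, 10, 0.5) == pytest.approx(0.5 ** 10,
                                                              rel=1e-12)


def test_binomial_at_mean_large_p():
    assert binomial_test_vs_nir(10, 20, 0.5) > 0.4


@pytest.mark.parametrize("n", [1, 5, 12, 20])
def test_binomial_matches_pmf_enumeration(n, rng):
    nir = float(rng.uniform(0.1, 0.9))
    for k in range(n + 1):
        brute = sum(binom.pmf(j, n, nir) for j in range(k, n + 1))
        assert binomial_test_vs_nir(k, n, nir) == pytest.approx(brute,
                                                                rel=1e-9)


def test_binomial_invalid_inputs():
    with pytest.raises(ValidationError):
        binomial_test_vs_nir(5, 4, 0.5)
    with pytest.raises(ValidationError):
        binomial_test_vs_nir(1, 4, 1.0)


def test_nir_is_majority_class():
    assert null_information_rate([0, 0, 0, 1]) == 0.75


# -------------------------------------------------------- proportion z-test

def test_identical_proportions_z_zero():
    z, p = two_proportion_test(10, 100, 10, 100, alternative="two-sided")
    assert z == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_large_difference_significant():
    _z, p = two_proportion_test(36, 100, 10, 100, alternative="larger")
    assert p < 0.001


def test_z_matches_permutation(rng):
    x1, n1, x2, n2 = 8, 20, 3, 20
    z, p = two_proportion_test(x1, n1, x2, n2, alternative="larger")
    pool = np.array([1] * (x1 + x2) + [0] * (n1 + n2 - x1 - x2))
    obs = x1 / n1 - x2 / n2
    hits = 0
    n_perm = 4000
    for _ in range(n_perm):
        rng.shuffle(pool)
        hits += (pool[:n1].mean() - pool[n1:].mean()) >= obs - 1e-12
    # normal approximation vs exact resampling: agree within a few percent
    assert p == pytest.approx(hits / n_perm, abs=0.05)


def test_counts_out_of_range():
    with pytest.raises(ValidationError):
        two_proportion_test(5, 4, 1, 10)


# --------------------------------------------------------------- aggregation

def test_pooled_counts_equal_sum_of_folds():
    folds = [ConfusionCounts(1, 2, 3, 4), ConfusionCounts(5, 0, 1, 2)]
    total = sum(folds, ConfusionCounts())
    assert (total.tp, total.fp, total.tn, total.fn) == (6, 2, 4, 6)
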