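import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nirsimpair.core import GroundTruth, ScanLabel
from nirsimpair.errors import ValidationError
from nirsimpair.features import (
    ROI_FEATURE_NAMES, FeatureVector, build_feature_vector,
    extract_roi_features, feature_matrix, feature_names,
)
from nirsimpair.preprocess import RoiTimecourse
from nirsimpair.simulate import canonical_hrf

FS = 7.81
N = round(40 * FS) + 1


def make_tc(y, roi="MPFC", fs=FS):
    y = np.asarray(y, float)
    return RoiTimecourse(roi=roi, hbo=y, hbr=-y / 3, fs=fs,
                         n_blocks_averaged=1).validate()


def hrf_tc(amp=1.0):
    t = np.arange(N) / FS
    return make_tc(amp * canonical_hrf(t))


def test_constant_signal_closed_forms():
    c = 1.7
    f = extract_roi_features(make_tc(np.full(N, c)))
    for a in range(0, 40, 5):
        assert f[f"seg_mean_{a}_{a + 5}"] == pytest.approx(c)
    assert f["slope_5_15"] == pytest.approx(0.0, abs=1e-12)
    assert f["auc_0_15"] == pytest.approx(15 * c, rel=1e-12)
    assert f["auc_15_40"] == pytest.approx(25 * c, rel=1e-12)
    assert f["sd_after_ext1"] == pytest.approx(0.0, abs=1e-12)


def test_linear_signal_slope_exact():
    t = np.arange(N) / FS
    a, b = 0.3, -0.05
    f = extract_roi_features(make_tc(a + b * t))
    assert f["slope_5_15"] == pytest.approx(b, rel=1e-10)


def test_hrf_extrema_match_brute_force():
    tc = hrf_tc()
    f = extract_roi_features(tc)
    y = tc.hbo
    # noise-free response: first extremum is the global peak, second the
    # undershoot trough
    assert f["t_ext1"] == pytest.approx(np.argmax(y) / FS)
    assert f["mag_ext1"] == pytest.approx(y.max())
    assert f["mag_ext2"] == pytest.approx(y.min())
    # moments vs direct formulas over [0, 15) s
    idx = np.arange(0, int(np.floor(15 * FS)))
    seg = y[idx]
    mu, sd = seg.mean(), seg.std(ddof=0)
    skew = np.mean((seg - mu) ** 3) / sd ** 3
    kurt = np.mean((seg - mu) ** 4) / sd ** 4
    assert f["skew_0_15"] == pytest.approx(skew, abs=1e-10)
    assert f["kurt_0_15"] == pytest.approx(kurt, abs=1e-10)


def test_segment_means_match_brute_force(rng):
    y = rng.standard_normal(N)
    f = extract_roi_features(make_tc(y))
    for a in range(0, 40, 5):
        idx = np.arange(int(np.floor(a * FS)), int(np.floor((a + 5) * FS)))
        assert f[f"seg_mean_{a}_{a + 5}"] == pytest.approx(y[idx].mean(),
                                                           abs=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(c=st.floats(-5, 5), seed=st.integers(0, 1000))
def test_shift_covariance(c, seed):
    """Adding a constant shifts means/magnitudes/AUCs predictably and leaves
    shape features (slope, moments, times, post-peak SD) unchanged."""
    y = np.random.default_rng(seed).standard_normal(N)
    f0 = extract_roi_features(make_tc(y))
    f1 = extract_roi_features(make_tc(y + c))
    for a in range(0, 40, 5):
        k = f"seg_mean_{a}_{a + 5}"
        assert f1[k] == pytest.approx(f0[k] + c, abs=1e-9)
    assert f1["auc_0_15"] == pytest.approx(f0["auc_0_15"] + 15 * c, abs=1e-8)
    assert f1["auc_15_40"] == pytest.approx(f0["auc_15_40"] + 25 * c, abs=1e-8)
    assert f1["mag_ext1"] == pytest.approx(f0["mag_ext1"] + c, abs=1e-9)
    for k in ("slope_5_15", "skew_0_15", "kurt_0_15", "t_ext1", "t_ext2",
              "sd_after_ext1"):
        assert f1[k] == pytest.approx(f0[k], abs=1e-8)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(k=st.floats(0.1, 10), seed=st.integers(0, 1000))
def test_scale_covariance(k, seed):
    y = np.random.default_rng(seed).standard_normal(N)
    f0 = extract_roi_features(make_tc(y))
    f1 = extract_roi_features(make_tc(k * y))
    for name in ("seg_mean_0_5", "auc_0_15", "auc_15_40", "mag_ext1",
                 "mag_ext2", "mean_after_ext1", "sd_after_ext1",
                 "slope_5_15"):
        assert f1[name] == pytest.approx(k * f0[name], rel=1e-8, abs=1e-10)
    for name in ("skew_0_15", "kurt_0_15", "t_ext1", "t_ext2"):
        assert f1[name] == pytest.approx(f0[name], rel=1e-8, abs=1e-10)


def test_vector_is_95_with_19_per_roi():
    tcs = [make_tc(np.arange(N, dtype=float) / N + i, roi=roi)
           for i, roi in enumerate(("MPFC", "RDLPFC", "RVLPFC",
                                    "LDLPFC", "LVLPFC"))]
    fv = build_feature_vector(tcs, scan_key=("P", "THC", 2))
    assert len(fv.values) == 95
    assert len(ROI_FEATURE_NAMES) == 19
    per_roi = {}
    for name in fv.names:
        roi = name.split("__")[0]
        per_roi[roi] = per_roi.get(roi, 0) + 1
    assert set(per_roi.values()) == {19}
    # determinism: same input, same vector
    fv2 = build_feature_vector(tcs, scan_key=("P", "THC", 2))
    np.testing.assert_array_equal(fv.values, fv2.values)


def test_missing_roi_named():
    tcs = [make_tc(np.zeros(N) + 1, roi="MPFC")]
    with pytest.raises(ValidationError, match="RDLPFC"):
        build_feature_vector(tcs)


def test_short_timecourse_rejected():
    with pytest.raises(ValidationError):
        extract_roi_features(
            RoiTimecourse("MPFC", np.zeros(50), np.zeros(50), FS, 1,
                          window_s=(0.0, 50 / FS)))


def _fv(key, fill=0.0):
    return FeatureVector(key, tuple(feature_names()),
                         np.full(95, fill) + np.arange(95) * 1e-3)


def _lab(pid, arm, sidx, gt):
    ccr = "impaired" if gt is GroundTruth.IMPAIRED else "not"
    algo = gt is GroundTruth.IMPAIRED
    if gt is GroundTruth.DISCORDANT:
        ccr, algo = "impaired", False
    return ScanLabel(pid, arm, sidx, ccr, algo, gt)


def test_feature_matrix_row_counts_and_classes():
    vectors, labels = [], []
    for i in range(4):
        vectors.append(_fv((f"A{i}", "THC", 2)))
        labels.append(_lab(f"A{i}", "THC", 2, GroundTruth.IMPAIRED))
    for i in range(3):
        vectors.append(_fv((f"B{i}", "placebo", 2)))
        labels.append(_lab(f"B{i}", "placebo", 2, GroundTruth.PLACEBO_NEGATIVE))
    vectors.append(_fv(("C0", "THC", 3)))
    labels.append(_lab("C0", "THC", 3, GroundTruth.DISCORDANT))
    df = feature_matrix(vectors, labels)
    assert len(df) == 7                       # discordant excluded
    assert df.label.sum() == 4
    assert len([c for c in df.columns if "__" in c]) == 95


def test_holdout_matrix_is_all_negative():
    vectors = [_fv((f"H{i}", "THC", 2)) for i in range(5)]
    labels = [_lab(f"H{i}", "THC", 2, GroundTruth.NOT_CLEARLY_IMPAIRED)
              for i in range(5)]
    df = feature_matrix(vectors, labels,
                        include={GroundTruth.NOT_CLEARLY_IMPAIRED})
    assert (df.label == 0).all()
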