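"""The 19-per-ROI temporal feature map (95 values per scan).

For each ROI's block-averaged 0-40 s HbO response: eight 5-s segment means,
the 5-15 s slope, skewness and kurtosis over 0-15 s, areas under the curve
over 0-15 and 15-40 s, times and magnitudes of the first two extrema, and
the mean and standard deviation of the signal after the first extremum.
Feature names are a stable public contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GroundTruth, ROI_ORDER, ScanLabel
from .errors import ValidationError
from .preprocess import RoiTimecourse

__all__ = [
    "ROI_FEATURE_NAMES",
    "feature_names",
    "FeatureVector",
    "extract_roi_features",
    "build_feature_vector",
    "feature_matrix",
]

_SEGMENTS = [(a, a + 5) for a in range(0, 40, 5)]

ROI_FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"seg_mean_{a}_{b}" for a, b in _SEGMENTS]
    + ["slope_5_15", "skew_0_15", "kurt_0_15", "auc_0_15", "auc_15_40",
       "t_ext1", "t_ext2", "mag_ext1", "mag_ext2",
       "mean_after_ext1", "sd_after_ext1"]
)
assert len(ROI_FEATURE_NAMES) == 19


def feature_names(rois: tuple[str, ...] = ROI_ORDER) -> list[str]:
    """The 95 feature column names, ROI-major in fixed ROI order."""
    return [f"{roi}__{name}" for roi in rois for name in ROI_FEATURE_NAMES]


def _window_idx(a: float, b: float, fs: float, n: int) -> np.ndarray:
    """Sample indices of the half-open window [a, b) seconds."""
    idx = np.arange(int(np.floor(a * fs)), int(np.floor(b * fs)))
    idx = idx[(idx >= 0) & (idx < n)]
    if len(idx) < 3:
        raise ValidationError(f"window [{a}, {b}) s has fewer than 3 samples")
    return idx


def _auc(t: np.ndarray, y: np.ndarray, a: float, b: float) -> float:
    """Integral over [a, b] of the piecewise-linear interpolant of (t, y).

    The interpolant holds edge values beyond the sampled range, so a
    constant signal c integrates to exactly (b - a) * c even when the last
    sample falls a fraction of a sample short of b.
    """
    inner = t[(t > a) & (t < b)]
    nodes = np.concatenate([[a], inner, [b]])
    vals = np.interp(nodes, t, y)
    return float(np.trapezoid(vals, nodes))


def _turning_points(y: np.ndarray, eps: float) -> list[int]:
    d = np.diff(y)
    signs = np.sign(d)
    # carry the last nonzero sign across plateaus
    last = 0.0
    filled = np.empty_like(signs)
    for i, s in enumerate(signs):
        if s != 0:
            last = s
        filled[i] = last
    turns = [i for i in range(1, len(filled))
             if filled[i - 1] != 0 and filled[i] != 0 and filled[i - 1] != filled[i]]
    if eps > 0:
        kept: list[int] = []
        ref = y[0]
        for i in turns:
            if abs(y[i] - ref) >= eps:
                kept.append(i)
                ref = y[i]
        turns = kept
    return turns


def extract_roi_features(tc: RoiTimecourse, fs: float | None = None,
                         extremum_eps: float = 0.0) -> dict[str, float]:
    """The 19 named temporal features of one ROI's HbO timecourse.

    Segment means use half-open windows mapped to samples by
    floor(a*fs)..floor(b*fs)-1; the slope is the least-squares line over
    [5, 15) s; moments are plain sample moments over [0, 15) s (kurtosis
    non-excess); AUCs are trapezoidal over [0, 15] and [15, 40] s; extrema
    are the first two turning points of the signal (global max then global
    min as fallback when fewer than two exist).
    """
    fs = fs or tc.fs
    y = np.asarray(tc.hbo, float)
    t = tc.times - tc.window_s[0]
    n = len(y)
    if t[-1] < 39.0:
        raise ValidationError(f"ROI {tc.roi}: timecourse spans less than 40 s")
    out: dict[str, float] = {}
    for a, b in _SEGMENTS:
        out[f"seg_mean_{a}_{b}"] = float(y[_window_idx(a, b, fs, n)].mean())
    idx = _window_idx(5, 15, fs, n)
    out["slope_5_15"] = float(np.polyfit(t[idx], y[idx], 1)[0])
    idx = _window_idx(0, 15, fs, n)
    seg = y[idx]
    sd = seg.std(ddof=0)
    if sd <= 1e-12 * max(np.abs(seg).max(), 1.0):
        # degenerate (constant) segment: moments are undefined, report 0
        out["skew_0_15"] = 0.0
        out["kurt_0_15"] = 0.0
    else:
        out["skew_0_15"] = float(stats.skew(seg, bias=True))
        out["kurt_0_15"] = float(stats.kurtosis(seg, fisher=False, bias=True))
    out["auc_0_15"] = _auc(t, y, 0.0, 15.0)
    out["auc_15_40"] = _auc(t, y, 15.0, 40.0)

    turns = _turning_points(y, extremum_eps)
    if len(turns) >= 2:
        e1, e2 = turns[0], turns[1]
    else:
        e1, e2 = int(np.argmax(y)), int(np.argmin(y))
    out["t_ext1"], out["t_ext2"] = e1 / fs, e2 / fs
    out["mag_ext1"], out["mag_ext2"] = float(y[e1]), float(y[e2])
    after = y[e1 + 1:]
    if len(after) == 0:
        after = y[e1:]
    out["mean_after_ext1"] = float(after.mean())
    out["sd_after_ext1"] = float(after.std(ddof=0))
    assert list(out) == list(ROI_FEATURE_NAMES)
    return out


@dataclass(frozen=True)
class FeatureVector:
    """The ordered 95-value temporal feature map of one scan."""

    scan_key: tuple[str, str, int]
    names: tuple[str, ...]
    values: np.ndarray

    def validate(self) -> "FeatureVector":
        if len(self.names) != 95 or len(self.values) != 95:
            raise ValidationError(
                f"feature vector must have 95 values, got {len(self.values)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite feature values")
        return self


def build_feature_vector(timecourses: list[RoiTimecourse],
                         scan_key: tuple[str, str, int] = ("", "", 1),
                         extremum_eps: float = 0.0) -> FeatureVector:
    """Concatenate the 19 per-ROI features over the 5 ROIs in fixed order."""
    by_roi = {tc.roi: tc for tc in timecourses}
    missing = [r for r in ROI_ORDER if r not in by_roi]
    if missing:
        raise ValidationError(f"missing ROI timecourses: {missing}")
    names, values = [], []
    for roi in ROI_ORDER:
        feats = extract_roi_features(by_roi[roi], extremum_eps=extremum_eps)
        for k, v in feats.items():
            names.append(f"{roi}__{k}")
            values.append(v)
    return FeatureVector(scan_key, tuple(names), np.array(values)).validate()


def feature_matrix(vectors: list[FeatureVector],
                   labels: list[ScanLabel],
                   include: set[GroundTruth] | None = None,
                   include_pre_dose: bool = False) -> pd.DataFrame:
    """Assemble the classifier design matrix.

    Rows are scans whose ground truth is in ``include`` (default: impaired
    as the positive class, placebo-negative as the negative class); the
    binary ``label`` column is 1 for impaired, 0 otherwise.  With
    ``include_pre_dose`` the pre-dose (scan 1) feature vectors enter as
    additional negatives.  Metadata columns (participant_id, visit_arm,
    scan_index, ground_truth, label) precede the 95 feature columns.
    """
    include = include or {GroundTruth.IMPAIRED, GroundTruth.PLACEBO_NEGATIVE}
    by_key = {(l.participant_id, l.visit_arm, l.scan_index): l for l in labels}
    rows = []
    for fv in vectors:
        fv.validate()
        pid, arm, sidx = fv.scan_key
        lab = by_key.get(fv.scan_key)
        if lab is not None and lab.ground_truth in include:
            gt = lab.ground_truth.value
            y = int(lab.ground_truth is GroundTruth.IMPAIRED)
        elif include_pre_dose and sidx == 1:
            gt, y = "pre_dose", 0
        else:
            continue
        row = {"participant_id": pid, "visit_arm": arm, "scan_index": sidx,
               "ground_truth": gt, "label": y}
        row.update(zip(fv.names, fv.values))
        rows.append(row)
    if not rows:
        raise ValidationError("no scans left after class filtering")
    df = pd.DataFrame(rows)
    expected = feature_names()
    if list(df.columns[5:]) != expected:
        raise ValidationError("inconsistent feature columns across scans")
    return df
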