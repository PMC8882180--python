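"""Group-level HbO comparisons.

For each participant the peak-dose scan (scan 2 or 3, whichever carries the
higher DEQ "high" rating near the scan) is paired with the pre-dose scan;
at every block-relative timepoint a paired t-test compares peak vs pre
across participants, with Benjamini-Hochberg FDR correction applied across
timepoints within each ROI (q = 0.05 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import DEFAULT_SCAN_TIMES_MIN, VitalsSeries
from .errors import ValidationError
from .preprocess import RoiTimecourse

__all__ = [
    "select_peak_scan",
    "matched_pairs",
    "TimepointTestResult",
    "timepoint_paired_tests",
]


def _deq_at(vitals: VitalsSeries, minute: float) -> float:
    """DEQ-high at the vitals sample nearest the given minute."""
    idx = int(np.argmin(np.abs(np.asarray(vitals.minutes, float) - minute)))
    return float(vitals.deq_high[idx])


def select_peak_scan(available_scans: set[int], vitals: VitalsSeries,
                     scan_times_min: dict[int, float] | None = None) -> int:
    """The post-dose scan with the larger matched DEQ rating; ties -> scan 2.

    With only one post-dose scan available that one is returned.
    """
    times = scan_times_min or DEFAULT_SCAN_TIMES_MIN
    post = sorted(s for s in available_scans if s in (2, 3))
    if not post:
        raise ValidationError("participant has no post-dose scans")
    if len(post) == 1:
        return post[0]
    d2, d3 = _deq_at(vitals, times[2]), _deq_at(vitals, times[3])
    return 3 if d3 > d2 else 2


def matched_pairs(timecourses: dict[tuple[str, str, int], RoiTimecourse],
                  participants: list[str], visit_arm: str,
                  vitals_by_participant: dict[str, VitalsSeries],
                  roi: str,
                  scan_times_min: dict[int, float] | None = None,
                  ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Pre-dose / peak-dose HbO pairs for one ROI and group.

    ``timecourses`` is keyed by (participant, arm, scan_index) and holds the
    requested ROI's block-averaged timecourse.  Participants lacking a
    pre-dose scan, any post-dose scan, or vitals are excluded and counted.
    Returns (pre, peak) arrays of shape (n_pairs, n_timepoints) and an
    exclusion report.
    """
    pre_rows, peak_rows = [], []
    excluded = {"no_pre": 0, "no_post": 0, "no_vitals": 0}
    for pid in participants:
        pre_key = (pid, visit_arm, 1)
        if pre_key not in timecourses:
            excluded["no_pre"] += 1
            continue
        avail = {s for s in (2, 3) if (pid, visit_arm, s) in timecourses}
        if not avail:
            excluded["no_post"] += 1
            continue
        vit = vitals_by_participant.get(pid)
        if vit is None:
            excluded["no_vitals"] += 1
            continue
        peak = select_peak_scan(avail, vit, scan_times_min)
        tc_pre = timecourses[pre_key]
        tc_peak = timecourses[(pid, visit_arm, peak)]
        if tc_pre.roi != roi or tc_peak.roi != roi:
            raise ValidationError(
                f"{pid}: timecourse ROI mismatch, expected {roi}")
        pre_rows.append(tc_pre.hbo)
        peak_rows.append(tc_peak.hbo)
    if not pre_rows:
        raise ValidationError(
            f"no matched pre/peak pairs for {visit_arm}/{roi}")
    report = {"n_pairs": len(pre_rows), **excluded}
    return np.asarray(pre_rows), np.asarray(peak_rows), report


@dataclass
class TimepointTestResult:
    roi: str
    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray          # BH mask at level q
    q: float
    n_pairs: int
    zero_variance: np.ndarray        # timepoints where all differences tie

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


def timepoint_paired_tests(pre: np.ndarray, peak: np.ndarray,
                           roi: str = "", q: float = 0.05,
                           ) -> TimepointTestResult:
    """Per-timepoint paired t (peak - pre) with BH-FDR across timepoints.

    Timepoints whose paired differences have zero variance get p = 1 and a
    flag (no evidence either way from a degenerate test).
    """
    pre = np.asarray(pre, float)
    peak = np.asarray(peak, float)
    if pre.shape != peak.shape:
        raise ValidationError("pre and peak arrays must share a shape")
    n, L = pre.shape
    if n < 3:
        raise ValidationError(f"need >= 3 pairs, got {n}")
    diffs = peak - pre
    sd = diffs.std(axis=0, ddof=1)
    zero_var = sd == 0
    t = np.zeros(L)
    p = np.ones(L)
    ok = ~zero_var
    if np.any(ok):
        res = stats.ttest_rel(peak[:, ok], pre[:, ok], axis=0)
        t[ok] = res.statistic
        p[ok] = res.pvalue
    rejected, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")[0:4]
    return TimepointTestResult(
        roi=roi, t=t, p=p, significant=rejected, q=q, n_pairs=n,
        zero_variance=zero_var)
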