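"""Ground-truth operationalisation.

A post-dose scan counts as impaired only when two independent routes agree:
the clinical consensus rating (CCR, supplied externally or simulated) and a
physiologic/psychologic algorithm requiring both a DEQ self-rated "high"
above the cut (default >50 of 100) and a post-dose heart-rate rise over the
pre-dose baseline (default >=10 bpm) near the scan.  Discordant scans are
excluded from classifier building; placebo scans are negatives by design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DEFAULT_SCAN_TIMES_MIN, GroundTruth, ScanLabel, VitalsSeries
from .errors import ValidationError

__all__ = [
    "AlgoThresholds",
    "AlgoEvidence",
    "algorithmic_intoxication",
    "concordant_ground_truth",
    "label_cohort",
    "assemble_label_table",
]


@dataclass(frozen=True)
class AlgoThresholds:
    """Thresholds of the heart-rate / DEQ intoxication algorithm."""

    deq_high_cut: float = 50.0       # exclusive: positive requires DEQ > cut
    hr_delta_cut_bpm: float = 10.0   # inclusive: rise over pre-dose baseline
    scan_window_min: float = 30.0    # half-width around the scan midpoint

    def validate(self) -> "AlgoThresholds":
        if not 0 < self.deq_high_cut < 100:
            raise ValidationError("deq_high_cut must lie in (0, 100)")
        if self.hr_delta_cut_bpm < 0:
            raise ValidationError("hr_delta_cut_bpm must be >= 0")
        if self.scan_window_min <= 0:
            raise ValidationError("scan_window_min must be positive")
        return self


@dataclass(frozen=True)
class AlgoEvidence:
    """Margins behind one algorithmic determination."""

    intoxicated: bool
    deq_max: float
    deq_margin: float          # deq_max - cut
    hr_baseline: float
    hr_delta: float            # max in-window HR - pre-dose mean
    hr_margin: float           # hr_delta - cut
    n_window_samples: int


def algorithmic_intoxication(vitals: VitalsSeries, scan_time_min: float,
                             thresholds: AlgoThresholds | None = None,
                             ) -> AlgoEvidence:
    """Apply the conjunctive DEQ/tachycardia rule to one scan.

    Positive iff the maximum DEQ-high within +/- ``scan_window_min`` of the
    scan midpoint exceeds ``deq_high_cut`` AND the maximum in-window heart
    rate exceeds the pre-dose mean by at least ``hr_delta_cut_bpm``.
    """
    th = (thresholds or AlgoThresholds()).validate()
    vitals.validate()
    m = np.asarray(vitals.minutes, float)
    pre = m <= 0
    if not np.any(pre):
        raise ValidationError(
            f"{vitals.participant_id}/{vitals.visit_arm}: no pre-dose vitals")
    win = np.abs(m - scan_time_min) <= th.scan_window_min
    if not np.any(win):
        raise ValidationError(
            f"{vitals.participant_id}/{vitals.visit_arm}: no vitals within "
            f"{th.scan_window_min} min of scan at {scan_time_min} min")
    hr_base = float(np.mean(vitals.heart_rate[pre]))
    hr_delta = float(np.max(vitals.heart_rate[win]) - hr_base)
    deq_max = float(np.max(vitals.deq_high[win]))
    positive = (deq_max > th.deq_high_cut) and (hr_delta >= th.hr_delta_cut_bpm)
    return AlgoEvidence(
        intoxicated=positive, deq_max=deq_max,
        deq_margin=deq_max - th.deq_high_cut, hr_baseline=hr_base,
        hr_delta=hr_delta, hr_margin=hr_delta - th.hr_delta_cut_bpm,
        n_window_samples=int(win.sum()))


def concordant_ground_truth(ccr_impaired: str, algo_intoxicated: bool,
                            visit_arm: str) -> GroundTruth:
    """Combine the CCR and algorithm routes into the scan's ground truth.

    Placebo scans are placebo-negative; on the THC arm, (impaired, True) ->
    impaired, (not, False) -> not clearly impaired, any disagreement or an
    unavailable CCR -> discordant (excluded downstream).
    """
    if visit_arm == "placebo":
        return GroundTruth.PLACEBO_NEGATIVE
    if ccr_impaired not in ("impaired", "not", "unavailable"):
        raise ValidationError(f"unknown CCR value {ccr_impaired!r}")
    if ccr_impaired == "impaired" and algo_intoxicated:
        return GroundTruth.IMPAIRED
    if ccr_impaired == "not" and not algo_intoxicated:
        return GroundTruth.NOT_CLEARLY_IMPAIRED
    return GroundTruth.DISCORDANT


def label_cohort(vitals: list[VitalsSeries], ccr: pd.DataFrame,
                 thresholds: AlgoThresholds | None = None,
                 scan_times_min: dict[int, float] | None = None,
                 ) -> list[ScanLabel]:
    """Label every post-dose scan of a cohort.

    ``ccr`` needs columns participant_id, visit_arm, scan_index,
    ccr_impaired (THC arm only; placebo scans need no rating).
    """
    times = scan_times_min or DEFAULT_SCAN_TIMES_MIN
    ccr_map = {(str(r.participant_id), str(r.visit_arm), int(r.scan_index)):
               str(r.ccr_impaired) for r in ccr.itertuples()}
    labels = []
    for v in vitals:
        for sidx in (2, 3):
            ev = algorithmic_intoxication(v, times[sidx], thresholds)
            rating = ccr_map.get((v.participant_id, v.visit_arm, sidx),
                                 "unavailable")
            gt = concordant_ground_truth(rating, ev.intoxicated, v.visit_arm)
            labels.append(ScanLabel(
                participant_id=v.participant_id, visit_arm=v.visit_arm,
                scan_index=sidx, ccr_impaired=rating,
                algo_intoxicated=ev.intoxicated, ground_truth=gt,
            ).validate())
    return labels


def assemble_label_table(labels: list[ScanLabel],
                         ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-scan label table plus per-participant THC-visit summary counts.

    Counts bucket each THC-arm participant by where their impaired scans
    fall: scan 2 only, scan 3 only, both, or neither; buckets sum to the
    number of THC-arm participants.
    """
    keys = [(l.participant_id, l.visit_arm, l.scan_index) for l in labels]
    if len(keys) != len(set(keys)):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValidationError(f"duplicate scan labels for {dupes[:3]}")
    table = pd.DataFrame([{
        "participant_id": l.participant_id, "visit_arm": l.visit_arm,
        "scan_index": l.scan_index, "ccr_impaired": l.ccr_impaired,
        "algo_intoxicated": l.algo_intoxicated,
        "ground_truth": l.ground_truth.value,
    } for l in labels])
    counts = {"scan2_only": 0, "scan3_only": 0, "both": 0, "neither": 0}
    thc = table[table.visit_arm == "THC"]
    for _pid, g in thc.groupby("participant_id"):
        imp = set(g.loc[g.ground_truth == GroundTruth.IMPAIRED.value,
                        "scan_index"])
        if imp == {2}:
            counts["scan2_only"] += 1
        elif imp == {3}:
            counts["scan3_only"] += 1
        elif imp == {2, 3}:
            counts["both"] += 1
        else:
            counts["neither"] += 1
    counts["n_thc_participants"] = thc.participant_id.nunique()
    counts["n_impaired_scans"] = int(
        (table.ground_truth == GroundTruth.IMPAIRED.value).sum())
    return table, counts
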