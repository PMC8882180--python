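"""End-to-end helpers wiring the stages together.

These functions take in-memory cohorts (from the generator or from disk)
through preprocessing, labeling, feature extraction and connectivity into
the design matrices consumed by the classifiers and the group analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .connectivity import sliding_window_correlations, vectorize_windows
from .core import GroundTruth, ProbeLayout, Scan, ScanLabel, VitalsSeries
from .features import build_feature_vector, feature_matrix
from .labeling import AlgoThresholds, label_cohort
from .preprocess import MBLLParams, RoiTimecourse, preprocess_scan, bandpass_and_detrend
from .errors import ValidationError

__all__ = ["ScanDerivatives", "derive_scan", "derive_cohort", "build_design"]


@dataclass
class ScanDerivatives:
    """Everything downstream needs from one scan."""

    key: tuple[str, str, int]
    timecourses: dict[str, RoiTimecourse]     # roi -> block average
    feature_vector: object
    sequence: object                          # (n_windows, 190) array


def derive_scan(scan: Scan, layout: ProbeLayout,
                mbll: MBLLParams | None = None,
                band: tuple[float, float] | None = (0.01, 0.5),
                window: int = 300, skip: int = 100) -> ScanDerivatives:
    """Preprocess one scan into ROI timecourses, the 95-feature vector and
    the connectivity-vector sequence.

    The connectivity correlations run on the band-passed continuous HbO
    (each window is a small segment of the scan), while features come from
    the block-averaged response.
    """
    tcs = preprocess_scan(scan, layout, mbll=mbll, band=band)
    fv = build_feature_vector(tcs, scan_key=scan.key)
    if scan.data_kind == "raw_intensity":
        from .preprocess import intensity_to_od, od_to_hemoglobin
        hbo = od_to_hemoglobin(
            {k: intensity_to_od(v) for k, v in scan.series.items()}, mbll)["hbo"]
    else:
        hbo = scan.series["hbo"]
    if band is not None:
        hbo = bandpass_and_detrend(hbo, scan.sampling_rate_hz, *band)
    seq = vectorize_windows(
        sliding_window_correlations(hbo, window, skip, scan_key=scan.key))
    return ScanDerivatives(key=scan.key, timecourses={t.roi: t for t in tcs},
                           feature_vector=fv, sequence=seq)


def derive_cohort(scans: list[Scan], layout: ProbeLayout,
                  mbll: MBLLParams | None = None,
                  band: tuple[float, float] | None = (0.01, 0.5),
                  window: int = 300, skip: int = 100,
                  ) -> dict[tuple[str, str, int], ScanDerivatives]:
    out = {}
    for scan in scans:
        if scan.key in out:
            raise ValidationError(f"duplicate scan key {scan.key}")
        out[scan.key] = derive_scan(scan, layout, mbll, band, window, skip)
    return out


def build_design(derived: dict, labels: list[ScanLabel],
                 include: set[GroundTruth] | None = None,
                 include_pre_dose: bool = False,
                 ) -> tuple[pd.DataFrame, dict]:
    """Design matrix + matching sequence map for the classifiers."""
    vectors = [d.feature_vector for d in derived.values()]
    df = feature_matrix(vectors, labels, include=include,
                        include_pre_dose=include_pre_dose)
    sequences = {k: d.sequence for k, d in derived.items()}
    return df, sequences


def label_and_design(derived: dict, vitals: list[VitalsSeries],
                     ccr: pd.DataFrame,
                     thresholds: AlgoThresholds | None = None,
                     include: set[GroundTruth] | None = None,
                     include_pre_dose: bool = False):
    """Convenience: label the cohort then build the design matrix."""
    labels = label_cohort(vitals, ccr, thresholds)
    df, sequences = build_design(derived, labels, include, include_pre_dose)
    return labels, df, sequences
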