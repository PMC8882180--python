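"""Raw-intensity to hemoglobin conversion and block averaging.

The chain is the standard continuous-wave one: optical density from the
temporal-mean-referenced intensity ratio, the modified Beer-Lambert law
(MBLL) to convert dual-wavelength optical density into oxy-/deoxy-hemoglobin
concentration changes (micromolar), a zero-phase Butterworth band-pass, and
per-condition epoching with baseline subtraction and block averaging into
one 0-40 s region-of-interest (ROI) timecourse per scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .core import ProbeLayout, ROI_ORDER, Scan
from .errors import ConfigurationError, ValidationError

__all__ = [
    "MBLLParams",
    "RoiTimecourse",
    "intensity_to_od",
    "od_to_hemoglobin",
    "hemoglobin_to_od",
    "bandpass_and_detrend",
    "epoch_and_block_average",
    "preprocess_scan",
]

log = logging.getLogger(__name__)

# Molar extinction coefficients (cm^-1 / M), HbO and HbR at 760 and 850 nm
# (standard tabulated values for adult hemoglobin).
_DEFAULT_EXTINCTION = np.array([
    [586.0, 1548.52],   # 760 nm: [HbO, HbR]
    [1058.0, 691.32],   # 850 nm
])


@dataclass
class MBLLParams:
    """Parameters of the modified Beer-Lambert inversion.

    ``extinction`` rows follow ``wavelengths`` order, columns are (HbO, HbR)
    in cm^-1/M.  ``dpf`` is the differential pathlength factor per wavelength;
    ``distance_cm`` the source-detector separation, scalar or per channel.
    """

    wavelengths: tuple[float, float] = (760.0, 850.0)
    extinction: np.ndarray = field(default_factory=lambda: _DEFAULT_EXTINCTION.copy())
    dpf: tuple[float, float] = (6.0, 6.0)
    distance_cm: float | np.ndarray = 3.0

    def validate(self) -> "MBLLParams":
        E = np.asarray(self.extinction, float)
        if E.shape != (2, 2):
            raise ConfigurationError("extinction matrix must be 2x2")
        if abs(np.linalg.det(E)) < 1e-9 * np.abs(E).max() ** 2:
            raise ConfigurationError("extinction matrix is singular")
        if np.any(np.asarray(self.dpf) <= 0):
            raise ConfigurationError("DPF must be positive")
        if np.any(np.asarray(self.distance_cm) <= 0):
            raise ConfigurationError("source-detector distance must be positive")
        return self


def intensity_to_od(intensity: np.ndarray) -> np.ndarray:
    """Optical density: OD(t) = -ln(I(t) / mean_t I), per channel column."""
    I = np.asarray(intensity, float)
    if np.any(I <= 0):
        t, c = np.argwhere(I <= 0)[0]
        raise ValidationError(
            f"non-positive intensity at sample {t}, channel column {c}"
        )
    return -np.log(I / I.mean(axis=0, keepdims=True))


def _pathlengths(params: MBLLParams, n_channels: int) -> np.ndarray:
    """Effective pathlength d * DPF per (wavelength, channel), cm."""
    d = np.broadcast_to(np.asarray(params.distance_cm, float), (n_channels,))
    dpf = np.asarray(params.dpf, float)[:, None]
    return d[None, :] * dpf


def od_to_hemoglobin(od: dict[str, np.ndarray],
                     params: MBLLParams | None = None) -> dict[str, np.ndarray]:
    """Invert the MBLL: per channel, [dHbO, dHbR] = E^-1 . OD_lambda/(d.DPF).

    ``od`` maps ``"wl760"``/``"wl850"`` to (T, C) matrices.  Returns
    ``{"hbo": ..., "hbr": ...}`` in micromolar.  Linear in the OD input.
    """
    params = (params or MBLLParams()).validate()
    od760, od850 = np.asarray(od["wl760"], float), np.asarray(od["wl850"], float)
    pl = _pathlengths(params, od760.shape[1])
    A = np.stack([od760 / pl[0], od850 / pl[1]], axis=-1)     # (T, C, 2)
    conc = A @ np.linalg.inv(np.asarray(params.extinction, float)).T
    return {"hbo": conc[..., 0] * 1e6, "hbr": conc[..., 1] * 1e6}


def hemoglobin_to_od(hemo: dict[str, np.ndarray],
                     params: MBLLParams | None = None) -> dict[str, np.ndarray]:
    """Forward MBLL (inverse of :func:`od_to_hemoglobin`); input micromolar."""
    params = (params or MBLLParams()).validate()
    C = np.stack([np.asarray(hemo["hbo"], float),
                  np.asarray(hemo["hbr"], float)], axis=-1) * 1e-6
    od = C @ np.asarray(params.extinction, float).T           # (T, C, 2)
    pl = _pathlengths(params, C.shape[1])
    return {"wl760": od[..., 0] * pl[0], "wl850": od[..., 1] * pl[1]}


def bandpass_and_detrend(x: np.ndarray, fs: float,
                         low_hz: float = 0.01, high_hz: float = 0.5,
                         order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass after DC removal.

    ``low_hz`` may be 0, in which case only the low-pass edge applies.
    Output length equals input length (forward-backward filtering).
    """
    if not (0 <= low_hz < high_hz < fs / 2):
        raise ValidationError(
            f"invalid band [{low_hz}, {high_hz}] Hz for fs={fs} Hz"
        )
    x = np.asarray(x, float)
    x = x - x.mean(axis=0, keepdims=True)
    if low_hz > 0:
        sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=fs,
                     output="sos")
    else:
        sos = butter(order, high_hz, btype="lowpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x, axis=0)


@dataclass
class RoiTimecourse:
    """Block-averaged hemodynamic response of one ROI over 0-40 s."""

    roi: str
    hbo: np.ndarray
    hbr: np.ndarray
    fs: float
    n_blocks_averaged: int
    n_blocks_dropped: int = 0
    baseline_s: tuple[float, float] = (-2.0, 0.0)
    window_s: tuple[float, float] = (0.0, 40.0)

    def validate(self) -> "RoiTimecourse":
        n_expected = round((self.window_s[1] - self.window_s[0]) * self.fs) + 1
        if len(self.hbo) != n_expected or len(self.hbr) != n_expected:
            raise ValidationError(
                f"ROI {self.roi}: timecourse length {len(self.hbo)}, "
                f"expected {n_expected}"
            )
        if not (np.all(np.isfinite(self.hbo)) and np.all(np.isfinite(self.hbr))):
            raise ValidationError(f"ROI {self.roi}: non-finite values")
        return self

    @property
    def times(self) -> np.ndarray:
        n = len(self.hbo)
        return self.window_s[0] + np.arange(n) / self.fs


def epoch_and_block_average(scan: Scan, layout: ProbeLayout,
                            window: tuple[float, float] = (0.0, 40.0),
                            baseline: tuple[float, float] = (-2.0, 0.0),
                            condition: str = "2-back") -> list[RoiTimecourse]:
    """Average channels within each ROI, epoch per *condition* onset, subtract
    the pre-onset baseline mean and average across blocks.

    The epoch runs over ``window`` seconds relative to block onset (inclusive
    endpoint sample); blocks whose window or baseline falls outside the
    record are dropped and counted.  Raises if no usable block remains.
    """
    scan.validate()
    if scan.data_kind != "hemoglobin":
        raise ValidationError(
            f"scan {scan.key}: epoching needs hemoglobin data, run MBLL first"
        )
    fs = scan.sampling_rate_hz
    onsets = [e.onset_sample for e in scan.events if e.condition == condition]
    if not onsets:
        raise ValidationError(f"scan {scan.key}: no {condition!r} events")
    i0, i1 = round(window[0] * fs), round(window[1] * fs)
    b0, b1 = round(baseline[0] * fs), round(baseline[1] * fs)
    n = scan.n_samples
    usable = [o for o in onsets
              if o + b0 >= 0 and o + i0 >= 0 and o + i1 < n]
    dropped = len(onsets) - len(usable)
    if dropped:
        log.info("scan %s: dropped %d/%d %s blocks with incomplete windows",
                 scan.key, dropped, len(onsets), condition)
    if not usable:
        raise ValidationError(
            f"scan {scan.key}: zero usable {condition!r} blocks within the record"
        )
    out = []
    for roi in ROI_ORDER:
        if roi not in layout.roi_map:
            continue
        cols = layout.roi_channel_indices(roi)
        tcs = {}
        for name in ("hbo", "hbr"):
            roi_series = scan.series[name][:, cols].mean(axis=1)
            epochs = []
            for o in usable:
                ep = roi_series[o + i0: o + i1 + 1].copy()
                base = roi_series[o + b0: o + b1] if b1 > b0 else np.array([0.0])
                ep -= base.mean()
                epochs.append(ep)
            tcs[name] = np.mean(epochs, axis=0)
        out.append(RoiTimecourse(
            roi=roi, hbo=tcs["hbo"], hbr=tcs["hbr"], fs=fs,
            n_blocks_averaged=len(usable), n_blocks_dropped=dropped,
            baseline_s=baseline, window_s=window,
        ).validate())
    return out


def preprocess_scan(scan: Scan, layout: ProbeLayout,
                    mbll: MBLLParams | None = None,
                    band: tuple[float, float] | None = (0.01, 0.5),
                    window: tuple[float, float] = (0.0, 40.0),
                    baseline: tuple[float, float] = (-2.0, 0.0),
                    condition: str = "2-back") -> list[RoiTimecourse]:
    """Full chain: (MBLL if raw) -> band-pass -> epoch and block-average."""
    if scan.data_kind == "raw_intensity":
        od = {k: intensity_to_od(v) for k, v in scan.series.items()}
        hemo = od_to_hemoglobin(od, mbll)
        scan = Scan(
            participant_id=scan.participant_id, visit_arm=scan.visit_arm,
            scan_index=scan.scan_index, sampling_rate_hz=scan.sampling_rate_hz,
            data_kind="hemoglobin", series=hemo, events=scan.events,
            meta=scan.meta,
        )
    if band is not None:
        scan = Scan(
            participant_id=scan.participant_id, visit_arm=scan.visit_arm,
            scan_index=scan.scan_index, sampling_rate_hz=scan.sampling_rate_hz,
            data_kind="hemoglobin",
            series={k: bandpass_and_detrend(v, scan.sampling_rate_hz, *band)
                    for k, v in scan.series.items()},
            events=scan.events, meta=scan.meta,
        )
    return epoch_and_block_average(scan, layout, window, baseline, condition)
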