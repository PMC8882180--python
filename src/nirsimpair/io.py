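"""Scan, vitals and label I/O.

Two scan formats are supported:

* ``csv`` -- a wide table whose first column is time in seconds (sample k at
  k/fs) followed by one column per channel and series (``hbo_ch01`` ... or
  ``wl760_ch01`` ...), with a JSON sidecar (same stem, ``.json``) carrying
  metadata and task events.
* ``snirf`` -- the SNIRF HDF5 layout (``/nirs/data1`` time series with a
  measurement list, ``/nirs/stim*`` blocks, ``/nirs/metaDataTags``), written
  with h5py.

Vitals and labels travel as plain CSV with documented headers.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import BlockEvent, GroundTruth, Scan, ScanLabel, VitalsSeries
from .errors import FormatError

__all__ = [
    "write_scan",
    "read_scan",
    "write_vitals_csv",
    "read_vitals_csv",
    "write_labels_csv",
    "read_labels_csv",
]

_SERIES_ORDER = {"hemoglobin": ("hbo", "hbr"), "raw_intensity": ("wl760", "wl850")}


def _col(series: str, ch: int) -> str:
    return f"{series}_ch{ch:02d}"


# ---------------------------------------------------------------- CSV + JSON

def _write_csv(scan: Scan, path: Path) -> None:
    t = np.arange(scan.n_samples) / scan.sampling_rate_hz
    data = {"time_s": t}
    for name in _SERIES_ORDER[scan.data_kind]:
        mat = scan.series[name]
        for j in range(scan.n_channels):
            data[_col(name, j + 1)] = mat[:, j]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "participant_id": scan.participant_id,
        "visit_arm": scan.visit_arm,
        "scan_index": scan.scan_index,
        "sampling_rate_hz": scan.sampling_rate_hz,
        "data_kind": scan.data_kind,
        "n_channels": scan.n_channels,
        "events": [
            {"onset_sample": e.onset_sample, "condition": e.condition,
             "duration_s": e.duration_s}
            for e in scan.events
        ],
        "meta": scan.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def _read_csv(path: Path, n_channels_expected: int | None) -> Scan:
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing JSON sidecar for {path}")
    sidecar = json.loads(sidecar_path.read_text())
    df = pd.read_csv(path)
    if df.columns[0] != "time_s":
        raise FormatError(f"{path}: first column must be time_s")
    t = df["time_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: time column is not strictly increasing")
    kind = sidecar["data_kind"]
    n_ch = int(sidecar["n_channels"])
    if n_channels_expected is not None and n_ch != n_channels_expected:
        raise FormatError(
            f"{path}: {n_ch} channels, layout expects {n_channels_expected}"
        )
    series = {}
    for name in _SERIES_ORDER[kind]:
        cols = [_col(name, j + 1) for j in range(n_ch)]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing columns {missing[:3]}...")
        series[name] = df[cols].to_numpy(dtype=float)
    scan = Scan(
        participant_id=sidecar["participant_id"],
        visit_arm=sidecar["visit_arm"],
        scan_index=int(sidecar["scan_index"]),
        sampling_rate_hz=float(sidecar["sampling_rate_hz"]),
        data_kind=kind,
        series=series,
        events=[BlockEvent(int(e["onset_sample"]), e["condition"],
                           float(e["duration_s"])) for e in sidecar["events"]],
        meta=sidecar.get("meta", {}),
    )
    return scan.validate()


# -------------------------------------------------------------------- SNIRF

def _write_snirf(scan: Scan, path: Path) -> None:
    names = _SERIES_ORDER[scan.data_kind]
    fs = scan.sampling_rate_hz
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=scan.participant_id)
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="cm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        meta.create_dataset("VisitArm", data=scan.visit_arm)
        meta.create_dataset("ScanIndex", data=str(scan.scan_index))
        meta.create_dataset("ExtraMeta", data=json.dumps(scan.meta))
        data1 = nirs.create_group("data1")
        stacked = np.hstack([scan.series[n] for n in names])
        data1.create_dataset("dataTimeSeries", data=stacked)
        data1.create_dataset("time", data=np.arange(scan.n_samples) / fs)
        idx = 1
        for s_i, name in enumerate(names):
            for ch in range(scan.n_channels):
                ml = data1.create_group(f"measurementList{idx}")
                ml.create_dataset("sourceIndex", data=ch + 1)
                ml.create_dataset("detectorIndex", data=ch + 1)
                ml.create_dataset("wavelengthIndex", data=s_i + 1)
                if scan.data_kind == "hemoglobin":
                    ml.create_dataset("dataType", data=99999)
                    ml.create_dataset("dataTypeLabel",
                                      data="HbO" if name == "hbo" else "HbR")
                else:
                    ml.create_dataset("dataType", data=1)
                idx += 1
        for i, e in enumerate(scan.events, start=1):
            stim = nirs.create_group(f"stim{i}")
            stim.create_dataset("name", data=e.condition)
            stim.create_dataset(
                "data",
                data=np.array([[e.onset_sample / fs, e.duration_s, 1.0]]),
            )
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.array([760.0, 850.0]))


def _read_str(ds) -> str:
    v = ds[()]
    return v.decode() if isinstance(v, bytes) else str(v)


def _read_snirf(path: Path, n_channels_expected: int | None) -> Scan:
    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        meta = nirs["metaDataTags"]
        data1 = nirs["data1"]
        stacked = data1["dataTimeSeries"][()]
        t = data1["time"][()]
        if np.any(np.diff(t) <= 0):
            raise FormatError(f"{path}: non-monotone time vector")
        fs = 1.0 / float(np.median(np.diff(t)))
        labels = []
        idx = 1
        while f"measurementList{idx}" in data1:
            ml = data1[f"measurementList{idx}"]
            if "dataTypeLabel" in ml:
                labels.append(_read_str(ml["dataTypeLabel"]).lower())
            else:
                labels.append(f"wl{int(ml['wavelengthIndex'][()])}")
            idx += 1
        if stacked.shape[1] != len(labels):
            raise FormatError(f"{path}: measurement list does not match columns")
        if labels and labels[0] in ("hbo", "hbr"):
            kind = "hemoglobin"
            names = ("hbo", "hbr")
        else:
            kind = "raw_intensity"
            names = ("wl760", "wl850")
            labels = ["wl760" if l == "wl1" else "wl850" for l in labels]
        series = {}
        for name in names:
            cols = [j for j, l in enumerate(labels) if l == name]
            series[name] = stacked[:, cols]
        n_ch = series[names[0]].shape[1]
        if n_channels_expected is not None and n_ch != n_channels_expected:
            raise FormatError(
                f"{path}: {n_ch} channels, layout expects {n_channels_expected}"
            )
        events = []
        i = 1
        while f"stim{i}" in nirs:
            stim = nirs[f"stim{i}"]
            cond = _read_str(stim["name"])
            for onset_s, dur, _amp in np.atleast_2d(stim["data"][()]):
                events.append(BlockEvent(int(round(onset_s * fs)), cond, float(dur)))
            i += 1
        events.sort(key=lambda e: e.onset_sample)
        scan = Scan(
            participant_id=_read_str(meta["SubjectID"]),
            visit_arm=_read_str(meta["VisitArm"]),
            scan_index=int(_read_str(meta["ScanIndex"])),
            sampling_rate_hz=float(round(fs, 6)),
            data_kind=kind,
            series=series,
            events=events,
            meta=json.loads(_read_str(meta["ExtraMeta"])) if "ExtraMeta" in meta else {},
        )
    return scan.validate()


def write_scan(scan: Scan, path: str | Path, format: str | None = None) -> Path:
    """Write *scan* to *path* as ``csv`` or ``snirf`` (inferred from suffix)."""
    path = Path(path)
    fmt = format or ("snirf" if path.suffix == ".snirf" else "csv")
    if fmt == "csv":
        _write_csv(scan, path)
    elif fmt == "snirf":
        _write_snirf(scan, path)
    else:
        raise FormatError(f"unknown scan format {fmt!r}")
    return path


def read_scan(path: str | Path, format: str | None = None,
              n_channels_expected: int | None = None) -> Scan:
    """Read a scan written by :func:`write_scan`."""
    path = Path(path)
    fmt = format or ("snirf" if path.suffix == ".snirf" else "csv")
    if fmt == "csv":
        return _read_csv(path, n_channels_expected)
    if fmt == "snirf":
        return _read_snirf(path, n_channels_expected)
    raise FormatError(f"unknown scan format {fmt!r}")


# ----------------------------------------------------------- vitals / labels

def write_vitals_csv(vitals: list[VitalsSeries], path: str | Path) -> Path:
    rows = []
    for v in vitals:
        for m, hr, dq in zip(v.minutes, v.heart_rate, v.deq_high):
            rows.append({
                "participant_id": v.participant_id, "visit_arm": v.visit_arm,
                "minutes": m, "heart_rate": hr, "deq_high": dq,
            })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")
    return Path(path)


def read_vitals_csv(path: str | Path) -> list[VitalsSeries]:
    df = pd.read_csv(path)
    out = []
    for (pid, arm), g in df.groupby(["participant_id", "visit_arm"], sort=True):
        g = g.sort_values("minutes")
        out.append(VitalsSeries(
            participant_id=str(pid), visit_arm=str(arm),
            minutes=g["minutes"].to_numpy(float),
            heart_rate=g["heart_rate"].to_numpy(float),
            deq_high=g["deq_high"].to_numpy(float),
        ).validate())
    return out


def write_labels_csv(labels: list[ScanLabel], path: str | Path) -> Path:
    pd.DataFrame([{
        "participant_id": l.participant_id, "visit_arm": l.visit_arm,
        "scan_index": l.scan_index, "ccr_impaired": l.ccr_impaired,
        "algo_intoxicated": l.algo_intoxicated,
        "ground_truth": l.ground_truth.value,
    } for l in labels]).to_csv(path, index=False)
    return Path(path)


def read_labels_csv(path: str | Path) -> list[ScanLabel]:
    df = pd.read_csv(path)
    return [ScanLabel(
        participant_id=str(r.participant_id), visit_arm=str(r.visit_arm),
        scan_index=int(r.scan_index), ccr_impaired=str(r.ccr_impaired),
        algo_intoxicated=bool(r.algo_intoxicated),
        ground_truth=GroundTruth(r.ground_truth),
    ).validate() for r in df.itertuples()]
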