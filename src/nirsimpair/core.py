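"""Core data model: probe geometry, scans, vitals and scan labels.

The probe is a 20-channel prefrontal montage: 8 sources and 7 detectors
whose pairings define channels 1-20, grouped into five regions of interest
(middle, left/right dorsolateral and left/right ventrolateral prefrontal
cortex).  Geometry is metadata only -- the analysis uses optode identity and
ROI membership, never coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "ROI_ORDER",
    "DEFAULT_ROI_MAP",
    "DEFAULT_SCAN_TIMES_MIN",
    "Channel",
    "ProbeLayout",
    "build_probe_layout",
    "default_probe_config",
    "BlockEvent",
    "Scan",
    "VitalsSeries",
    "GroundTruth",
    "ScanLabel",
]

#: Fixed ROI order used everywhere a per-ROI quantity is serialised.
ROI_ORDER = ("MPFC", "RDLPFC", "RVLPFC", "LDLPFC", "LVLPFC")

DEFAULT_ROI_MAP: dict[str, frozenset[int]] = {
    "MPFC": frozenset(range(7, 15)),
    "RDLPFC": frozenset({15, 17, 18}),
    "RVLPFC": frozenset({16, 19, 20}),
    "LDLPFC": frozenset({1, 2, 5}),
    "LVLPFC": frozenset({3, 4, 6}),
}

#: Nominal scan midpoints in minutes from dosing (scan 1 pre-dose, 2 and 3 post).
DEFAULT_SCAN_TIMES_MIN = {1: -30.0, 2: 100.0, 3: 200.0}


@dataclass(frozen=True)
class Channel:
    channel_id: int
    source_id: str
    detector_id: str
    position_label: str = ""
    distance_cm: float = 3.0


@dataclass(frozen=True)
class ProbeLayout:
    """Validated optode/channel/ROI geometry."""

    sources: Mapping[str, str]          # source id -> 10-20 position label
    detectors: Mapping[str, str]        # detector id -> 10-20 position label
    channels: Sequence[Channel]
    roi_map: Mapping[str, frozenset[int]]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def channel_ids(self) -> tuple[int, ...]:
        return tuple(ch.channel_id for ch in self.channels)

    def roi_channel_indices(self, roi: str) -> np.ndarray:
        """0-based column indices (channel order) of the channels in *roi*."""
        ids = self.roi_map[roi]
        return np.array(
            [i for i, ch in enumerate(self.channels) if ch.channel_id in ids],
            dtype=int,
        )

    def validate(self) -> "ProbeLayout":
        ids = [ch.channel_id for ch in self.channels]
        dupes = {c for c in ids if ids.count(c) > 1}
        if dupes:
            raise ValidationError(f"duplicate channel ids: {sorted(dupes)}")
        for ch in self.channels:
            if ch.source_id not in self.sources:
                raise ValidationError(
                    f"channel {ch.channel_id} references unknown source {ch.source_id!r}"
                )
            if ch.detector_id not in self.detectors:
                raise ValidationError(
                    f"channel {ch.channel_id} references unknown detector {ch.detector_id!r}"
                )
            if ch.distance_cm <= 0:
                raise ValidationError(
                    f"channel {ch.channel_id} has non-positive distance"
                )
        id_set = set(ids)
        covered: set[int] = set()
        for roi, members in self.roi_map.items():
            unknown = set(members) - id_set
            if unknown:
                raise ValidationError(
                    f"ROI {roi!r} references unknown channels {sorted(unknown)}"
                )
            overlap = covered & set(members)
            if overlap:
                raise ValidationError(
                    f"ROI {roi!r} overlaps previously assigned channels {sorted(overlap)}"
                )
            covered |= set(members)
        if covered != id_set:
            raise ValidationError(
                f"ROIs do not cover channels {sorted(id_set - covered)}"
            )
        return self


def default_probe_config() -> dict:
    """The stock 8-source / 7-detector frontal montage as a plain config record.

    Sources sit on the upper two probe rows, detectors interleaved below;
    the exact source-detector pairing reproduces 20 channels whose midpoints
    are the numbered channel locations.  Inter-optode distance defaults to
    3 cm for every pair (the montage spans 2.5-3 cm; per-pair values may be
    supplied in the config).
    """
    sources = {f"S{i}": lbl for i, lbl in enumerate(
        ["F5", "Fp1", "AFz", "Fp2", "F6", "AF7", "Fpz", "AF8"], start=1)}
    detectors = {f"D{i}": lbl for i, lbl in enumerate(
        ["AF5", "AF1", "AF2", "AF6", "F3", "Fz", "F4"], start=1)}
    # channel id -> (source, detector); midpoints run left to right, 1-20
    pairs = {
        1: ("S1", "D5"), 2: ("S1", "D1"), 3: ("S6", "D5"), 4: ("S6", "D1"),
        5: ("S2", "D1"), 6: ("S2", "D5"), 7: ("S2", "D2"), 8: ("S7", "D2"),
        9: ("S3", "D2"), 10: ("S3", "D6"), 11: ("S7", "D6"), 12: ("S3", "D3"),
        13: ("S7", "D3"), 14: ("S4", "D3"), 15: ("S4", "D7"), 16: ("S4", "D4"),
        17: ("S8", "D7"), 18: ("S5", "D7"), 19: ("S8", "D4"), 20: ("S5", "D4"),
    }
    return {
        "sources": sources,
        "detectors": detectors,
        "channels": [
            {"channel_id": cid, "source_id": s, "detector_id": d,
             "distance_cm": 3.0}
            for cid, (s, d) in sorted(pairs.items())
        ],
        "roi_map": {roi: sorted(chs) for roi, chs in DEFAULT_ROI_MAP.items()},
    }


def build_probe_layout(config: dict | None = None) -> ProbeLayout:
    """Build and validate a :class:`ProbeLayout` from a probe-spec record.

    ``config`` defaults to :func:`default_probe_config`.  Raises
    :class:`~nirsimpair.errors.ValidationError` naming the offending channel
    or ROI on any inconsistency.
    """
    if config is None:
        config = default_probe_config()
    channels = [
        Channel(
            channel_id=int(c["channel_id"]),
            source_id=str(c["source_id"]),
            detector_id=str(c["detector_id"]),
            position_label=str(c.get("position_label", "")),
            distance_cm=float(c.get("distance_cm", 3.0)),
        )
        for c in config["channels"]
    ]
    layout = ProbeLayout(
        sources=dict(config["sources"]),
        detectors=dict(config["detectors"]),
        channels=tuple(sorted(channels, key=lambda c: c.channel_id)),
        roi_map={k: frozenset(v) for k, v in config["roi_map"].items()},
    )
    return layout.validate()


@dataclass(frozen=True)
class BlockEvent:
    """A task block: onset sample, condition name, duration in seconds.

    The block occupies the half-open interval [onset, onset + duration).
    """

    onset_sample: int
    condition: str
    duration_s: float


@dataclass
class Scan:
    """One fNIRS run: a time x channel matrix per wavelength or chromophore.

    ``series`` keys are ``"hbo"``/``"hbr"`` (micromolar) when ``data_kind`` is
    ``"hemoglobin"``, or ``"wl760"``/``"wl850"`` (raw intensities) when it is
    ``"raw_intensity"``.
    """

    participant_id: str
    visit_arm: str                       # "THC" | "placebo"
    scan_index: int                      # 1 pre-dose, 2 ~100 min, 3 ~200 min
    sampling_rate_hz: float
    data_kind: str                       # "raw_intensity" | "hemoglobin"
    series: dict[str, np.ndarray]
    events: list[BlockEvent] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return next(iter(self.series.values())).shape[0]

    @property
    def n_channels(self) -> int:
        return next(iter(self.series.values())).shape[1]

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.participant_id, self.visit_arm, self.scan_index)

    def validate(self) -> "Scan":
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be positive")
        if self.scan_index not in (1, 2, 3):
            raise ValidationError(f"scan_index must be 1, 2 or 3, got {self.scan_index}")
        if self.visit_arm not in ("THC", "placebo"):
            raise ValidationError(f"unknown visit_arm {self.visit_arm!r}")
        if self.data_kind not in ("raw_intensity", "hemoglobin"):
            raise ValidationError(f"unknown data_kind {self.data_kind!r}")
        if not self.series:
            raise ValidationError("scan has no series")
        shapes = {k: v.shape for k, v in self.series.items()}
        if len({s for s in shapes.values()}) != 1:
            raise ValidationError(f"series shapes differ: {shapes}")
        n = self.n_samples
        onsets = [e.onset_sample for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValidationError("event onsets must be strictly increasing")
        if any(o < 0 or o >= n for o in onsets):
            raise ValidationError("event onset outside the record")
        return self


@dataclass
class VitalsSeries:
    """Heart rate and DEQ self-rated 'high' sampled across one visit."""

    participant_id: str
    visit_arm: str
    minutes: np.ndarray        # minutes from dose; pre-dose samples are <= 0
    heart_rate: np.ndarray     # bpm
    deq_high: np.ndarray       # 0-100 self rating

    def validate(self) -> "VitalsSeries":
        if not (len(self.minutes) == len(self.heart_rate) == len(self.deq_high)):
            raise ValidationError("vitals arrays have unequal lengths")
        if not np.any(np.asarray(self.minutes) <= 0):
            raise ValidationError("vitals need at least one pre-dose sample")
        if np.any(np.asarray(self.heart_rate) <= 0):
            raise ValidationError("heart rate must be positive")
        d = np.asarray(self.deq_high)
        if np.any((d < 0) | (d > 100)):
            raise ValidationError("DEQ-high outside [0, 100]")
        return self


class GroundTruth(str, Enum):
    IMPAIRED = "impaired"
    NOT_CLEARLY_IMPAIRED = "not_clearly_impaired"
    DISCORDANT = "discordant"
    PLACEBO_NEGATIVE = "placebo_negative"


@dataclass(frozen=True)
class ScanLabel:
    """Ground-truth status of one post-dose scan.

    ``ccr_impaired`` is the clinical consensus rating ("impaired" | "not" |
    "unavailable"); ``algo_intoxicated`` the heart-rate/DEQ algorithm output.
    """

    participant_id: str
    visit_arm: str
    scan_index: int
    ccr_impaired: str
    algo_intoxicated: bool
    ground_truth: GroundTruth

    def validate(self) -> "ScanLabel":
        if (self.ground_truth is GroundTruth.PLACEBO_NEGATIVE) != (
            self.visit_arm == "placebo"
        ):
            raise ValidationError(
                "placebo_negative label iff placebo arm "
                f"({self.participant_id}, {self.visit_arm}, scan {self.scan_index})"
            )
        if self.ground_truth is GroundTruth.IMPAIRED and not (
            self.ccr_impaired == "impaired" and self.algo_intoxicated
        ):
            raise ValidationError(
                "impaired label requires concordant CCR and algorithm positivity"
            )
        return self
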