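"""Synthetic cross-over study generator.

Emulates the study design end to end: each participant completes a THC and
a placebo visit; each visit holds three 6-minute, 20-channel fNIRS scans at
7.81 Hz (one pre-dose, two post-dose at ~100 and ~200 min) during an
alternating 0-back/2-back block task, plus heart-rate and DEQ self-rated
"high" series sampled every ~20 min from -20 to 240 min.  A latent
impairment status (Bernoulli per participant, given THC) raises the 2-back
HbO response amplitude, produces post-dose tachycardia and drives the DEQ
"high" trajectory above the 50/100 mark; a noisy clinical consensus rating
(CCR) is simulated by flipping the latent scan status with a configurable
error rate.

HbO is built as amplitude x (canonical double-gamma HRF convolved with the
block boxcar, normalised to unit single-block peak) plus linear drift,
shared sinusoidal physiological components (cardiac ~1.1 Hz, respiratory
~0.25 Hz, Mayer waves ~0.1 Hz) and white noise; HbR is an anti-correlated,
scaled copy with independent noise.  Separate named RNG substreams
(assignment / fNIRS / vitals / CCR) derive from the master seed, so e.g.
changing heart-rate parameters never perturbs the fNIRS series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from scipy.stats import gamma as gamma_dist

from .core import BlockEvent, DEFAULT_SCAN_TIMES_MIN, Scan, VitalsSeries
from .errors import ValidationError

__all__ = [
    "CohortSpec",
    "LatentTruth",
    "canonical_hrf",
    "block_schedule",
    "synth_scan_timeseries",
    "synth_vitals",
    "generate_cohort",
    "cohort_tables",
]


@dataclass
class CohortSpec:
    """Free parameters of the synthetic study.

    Amplitudes are micromolar HbO at the channel level; vitals are bpm and
    0-100 DEQ units.  ``scan_pattern_probs`` gives the probability that an
    impaired participant is impaired at scan 2 only, scan 3 only, or both
    (study proportions 39:20:24).
    """

    n_participants: int = 20
    p_impaired_given_thc: float = 80 / 137
    scan_pattern_probs: tuple[float, float, float] = (39 / 83, 20 / 83, 24 / 83)
    seed: int = 0
    # task / acquisition
    sampling_rate_hz: float = 7.81
    scan_duration_s: float = 360.0
    block_duration_s: float = 30.0
    n_blocks: int = 12
    first_condition: str = "0-back"
    scan_times_min: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SCAN_TIMES_MIN))
    # hemodynamic forward model
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    hrf_undershoot_ratio: float = 6.0
    beta_base_um: float = 0.2
    beta_sd_um: float = 0.05
    beta_0back_frac: float = 0.25
    delta_beta_um: float = 0.3
    hbr_ratio: float = 1 / 3
    # noise
    white_sd_um: float = 0.3
    drift_sd_um: float = 0.1
    cardiac_hz: float = 1.1
    cardiac_amp_um: float = 0.15
    resp_hz: float = 0.25
    resp_amp_um: float = 0.10
    mayer_hz: float = 0.1
    mayer_amp_um: float = 0.10
    shared_noise_frac: float = 0.5
    # vitals
    vitals_step_min: float = 20.0
    vitals_span_min: tuple[float, float] = (-20.0, 240.0)
    hr_baseline_mean_bpm: float = 70.0
    hr_baseline_sd_bpm: float = 8.0
    hr_delta_bpm: float = 25.0
    hr_delta_nonimpaired_bpm: float = 5.0
    effect_bump_sd_min: float = 50.0
    hr_noise_sd_bpm: float = 3.0
    deq_peak_impaired: float = 75.0
    deq_peak_nonimpaired: float = 20.0
    deq_noise_sd: float = 5.0
    # clinical consensus rating emulation
    ccr_error_rate: float = 0.10

    def validate(self) -> "CohortSpec":
        for p in (self.p_impaired_given_thc, self.ccr_error_rate,
                  *self.scan_pattern_probs):
            if not 0 <= p <= 1:
                raise ValidationError(f"probability {p} outside [0, 1]")
        if abs(sum(self.scan_pattern_probs) - 1) > 1e-9:
            raise ValidationError("scan_pattern_probs must sum to 1")
        amps = (self.beta_base_um, self.delta_beta_um, self.white_sd_um,
                self.drift_sd_um, self.cardiac_amp_um, self.resp_amp_um,
                self.mayer_amp_um, self.hr_delta_bpm, self.hr_noise_sd_bpm,
                self.deq_noise_sd)
        if any(a < 0 for a in amps):
            raise ValidationError("amplitudes must be non-negative")
        if self.deq_peak_impaired <= self.deq_peak_nonimpaired:
            raise ValidationError(
                "impaired DEQ peak must exceed not-impaired DEQ peak")
        if self.scan_duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValidationError("duration and sampling rate must be positive")
        return self


@dataclass
class LatentTruth:
    """Ground truth behind one synthetic participant."""

    participant_id: str
    impaired_if_thc: bool
    impaired_scans: tuple[int, ...]          # subset of (2, 3), THC visit
    beta_um: float                            # participant 2-back amplitude
    realized_beta: dict[tuple[str, int], float]
    hr_baseline_bpm: dict[str, float]
    ccr: dict[int, str]                       # scan index -> impaired | not


def canonical_hrf(t: np.ndarray, peak_s: float = 6.0,
                  undershoot_s: float = 16.0, ratio: float = 6.0) -> np.ndarray:
    """Double-gamma hemodynamic response (unit-free shape, mode at *peak_s*)."""
    pos = gamma_dist.pdf(t, a=peak_s + 1, scale=1.0)
    neg = gamma_dist.pdf(t, a=undershoot_s + 1, scale=1.0)
    return pos - neg / ratio


def block_schedule(spec: CohortSpec) -> list[BlockEvent]:
    """Alternating 30-s blocks filling the 6-minute run (default 0-back first)."""
    fs = spec.sampling_rate_hz
    other = "2-back" if spec.first_condition == "0-back" else "0-back"
    events = []
    for i in range(spec.n_blocks):
        onset = int(round(i * spec.block_duration_s * fs))
        cond = spec.first_condition if i % 2 == 0 else other
        events.append(BlockEvent(onset, cond, spec.block_duration_s))
    return events


def _task_regressors(spec: CohortSpec, n: int) -> dict[str, np.ndarray]:
    """Unit-amplitude HRF-convolved block regressors per condition.

    Normalised so that an isolated block reaches peak 1; the amplitude
    parameter is therefore the peak evoked response in micromolar.
    """
    fs = spec.sampling_rate_hz
    t_hrf = np.arange(0, 40.0, 1 / fs)
    hrf = canonical_hrf(t_hrf, spec.hrf_peak_s, spec.hrf_undershoot_s,
                        spec.hrf_undershoot_ratio)
    dur = int(round(spec.block_duration_s * fs))
    single = fftconvolve(np.ones(dur), hrf)
    scale = 1.0 / single.max()
    out = {}
    for cond in ("0-back", "2-back"):
        box = np.zeros(n)
        for e in block_schedule(spec):
            if e.condition == cond:
                box[e.onset_sample: e.onset_sample + dur] = 1.0
        out[cond] = fftconvolve(box, hrf)[:n] * scale
    return out


def synth_scan_timeseries(spec: CohortSpec, beta_2back_um: float,
                          rng: np.random.Generator,
                          participant_id: str = "P000",
                          visit_arm: str = "THC",
                          scan_index: int = 1) -> Scan:
    """One 20-channel hemoglobin scan given the 2-back response amplitude."""
    spec.validate()
    fs = spec.sampling_rate_hz
    n = int(np.floor(spec.scan_duration_s * fs))
    t = np.arange(n) / fs
    reg = _task_regressors(spec, n)
    task = (beta_2back_um * reg["2-back"]
            + spec.beta_0back_frac * beta_2back_um * reg["0-back"])
    n_ch = 20

    # sinusoidal physiological components with a shared and a private part
    comps = [(spec.cardiac_hz, spec.cardiac_amp_um),
             (spec.resp_hz, spec.resp_amp_um),
             (spec.mayer_hz, spec.mayer_amp_um)]
    physio = np.zeros((n, n_ch))
    for f_hz, amp in comps:
        ph_shared = rng.uniform(0, 2 * np.pi)
        ph_priv = rng.uniform(0, 2 * np.pi, size=n_ch)
        shared = np.sin(2 * np.pi * f_hz * t + ph_shared)[:, None]
        private = np.sin(2 * np.pi * f_hz * t[:, None] + ph_priv[None, :])
        physio += amp * (spec.shared_noise_frac * shared
                         + (1 - spec.shared_noise_frac) * private)
    slopes = rng.standard_normal(n_ch) * spec.drift_sd_um
    drift = slopes[None, :] * (2 * t[:, None] / t[-1] - 1 if n > 1 else 0)
    clean = task[:, None] + physio + drift
    hbo = clean + rng.standard_normal((n, n_ch)) * spec.white_sd_um
    hbr = -spec.hbr_ratio * clean + rng.standard_normal((n, n_ch)) * (
        spec.hbr_ratio * spec.white_sd_um)
    return Scan(
        participant_id=participant_id, visit_arm=visit_arm,
        scan_index=scan_index, sampling_rate_hz=fs, data_kind="hemoglobin",
        series={"hbo": hbo, "hbr": hbr}, events=block_schedule(spec),
        meta={"beta_2back_um": beta_2back_um},
    ).validate()


def _effect_curve(minutes: np.ndarray, centers: list[float],
                  sd_min: float) -> np.ndarray:
    """Post-dose effect envelope in [0, 1]: max of Gaussian bumps at the
    impaired scan times, zero at and before dosing.  Reaches exactly 1 at a
    bump centre lying on the sampling grid."""
    if not centers:
        return np.zeros_like(minutes, dtype=float)
    g = np.max([np.exp(-0.5 * ((minutes - c) / sd_min) ** 2) for c in centers],
               axis=0)
    return np.where(minutes > 0, g, 0.0)


def synth_vitals(impaired, visit_arm: str, spec: CohortSpec,
                 rng: np.random.Generator, participant_id: str = "P000",
                 hr_baseline_bpm: float | None = None) -> VitalsSeries:
    """Heart-rate and DEQ-high series for one visit.

    ``impaired`` is the set of impaired scan indices for this participant's
    THC visit (a bare ``True`` means both post-dose scans).  On the placebo
    arm, or when the set is empty, trajectories are flat apart from noise
    (a small non-impaired THC effect is configurable).
    """
    spec.validate()
    if impaired is True:
        impaired = {2, 3}
    impaired = set(impaired or ())
    lo, hi = spec.vitals_span_min
    minutes = np.arange(lo, hi + 1e-9, spec.vitals_step_min)
    base = (hr_baseline_bpm if hr_baseline_bpm is not None
            else spec.hr_baseline_mean_bpm
            + spec.hr_baseline_sd_bpm * rng.standard_normal())
    centers = [spec.scan_times_min[s] for s in sorted(impaired)
               if visit_arm == "THC"]
    g = _effect_curve(minutes, centers, spec.effect_bump_sd_min)
    if visit_arm == "THC" and not impaired:
        g_mild = _effect_curve(minutes, [spec.scan_times_min[2]],
                               spec.effect_bump_sd_min)
        hr = base + spec.hr_delta_nonimpaired_bpm * g_mild
        deq = spec.deq_peak_nonimpaired * g_mild
    else:
        hr = base + spec.hr_delta_bpm * g
        deq = spec.deq_peak_impaired * g if visit_arm == "THC" else np.zeros_like(g)
    hr = hr + spec.hr_noise_sd_bpm * rng.standard_normal(len(minutes))
    deq = deq + spec.deq_noise_sd * rng.standard_normal(len(minutes))
    return VitalsSeries(
        participant_id=participant_id, visit_arm=visit_arm, minutes=minutes,
        heart_rate=np.maximum(hr, 30.0), deq_high=np.clip(deq, 0.0, 100.0),
    ).validate()


_PATTERNS = ((2,), (3,), (2, 3))


def generate_cohort(spec: CohortSpec,
                    ) -> tuple[list[Scan], list[VitalsSeries], list[LatentTruth]]:
    """The full synthetic study: 2 visits x 3 scans per participant.

    Returns scans, vitals (one series per visit) and the latent truth
    including the simulated CCR for post-dose THC scans.  Regeneration with
    the same spec (and seed) is bit-identical.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_assign, rng_fnirs, rng_vitals, rng_ccr = (
        np.random.default_rng(s) for s in ss.spawn(4))
    scans, vitals, truths = [], [], []
    for i in range(spec.n_participants):
        pid = f"P{i + 1:03d}"
        impaired = bool(rng_assign.random() < spec.p_impaired_given_thc)
        pattern = _PATTERNS[rng_assign.choice(3, p=spec.scan_pattern_probs)]
        impaired_scans = tuple(pattern) if impaired else ()
        beta = max(0.0, spec.beta_base_um
                   + spec.beta_sd_um * rng_fnirs.standard_normal())
        realized: dict[tuple[str, int], float] = {}
        hr_base: dict[str, float] = {}
        for arm in ("THC", "placebo"):
            for sidx in (1, 2, 3):
                b = beta + (spec.delta_beta_um
                            if arm == "THC" and sidx in impaired_scans else 0.0)
                realized[(arm, sidx)] = b
                scans.append(synth_scan_timeseries(
                    spec, b, rng_fnirs, participant_id=pid,
                    visit_arm=arm, scan_index=sidx))
            hr_base[arm] = (spec.hr_baseline_mean_bpm
                            + spec.hr_baseline_sd_bpm
                            * rng_vitals.standard_normal())
            vitals.append(synth_vitals(
                set(impaired_scans) if arm == "THC" else set(), arm, spec,
                rng_vitals, participant_id=pid, hr_baseline_bpm=hr_base[arm]))
        ccr = {}
        for sidx in (2, 3):
            truly = sidx in impaired_scans
            flip = rng_ccr.random() < spec.ccr_error_rate
            # rating = latent scan status XOR rater error
            ccr[sidx] = "impaired" if (truly != flip) else "not"
        truths.append(LatentTruth(
            participant_id=pid, impaired_if_thc=impaired,
            impaired_scans=impaired_scans, beta_um=beta,
            realized_beta=realized, hr_baseline_bpm=hr_base, ccr=ccr))
    return scans, vitals, truths


def cohort_tables(truths: list[LatentTruth]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Truth and CCR tables (one row per participant / per post-dose scan)."""
    truth_df = pd.DataFrame([{
        "participant_id": t.participant_id,
        "impaired_if_thc": t.impaired_if_thc,
        "impaired_scans": "+".join(map(str, t.impaired_scans)),
        "beta_um": t.beta_um,
    } for t in truths])
    ccr_df = pd.DataFrame([{
        "participant_id": t.participant_id, "visit_arm": "THC",
        "scan_index": sidx, "ccr_impaired": t.ccr[sidx],
    } for t in truths for sidx in (2, 3)])
    return truth_df, ccr_df


def null_spec(spec: CohortSpec) -> CohortSpec:
    """The same study with the fNIRS impairment effect switched off."""
    return replace(spec, delta_beta_um=0.0)


def noise_free(spec: CohortSpec) -> CohortSpec:
    """The same study with every noise source silenced (forward model only)."""
    return replace(spec, white_sd_um=0.0, drift_sd_um=0.0, cardiac_amp_um=0.0,
                   resp_amp_um=0.0, mayer_amp_um=0.0, beta_sd_um=0.0,
                   hr_baseline_sd_bpm=0.0, hr_noise_sd_bpm=0.0,
                   deq_noise_sd=0.0)
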