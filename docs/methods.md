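# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `nirsimpair`. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## Probe and data model

The probe is an 8-source / 7-detector prefrontal montage defining 20
channels, grouped into five ROIs that partition channels 1–20: MPFC
{7–14}, RDLPFC {15,17,18}, RVLPFC {16,19,20}, LDLPFC {1,2,5}, LVLPFC
{3,4,6}. Optode positions are stored as 10-20 labels only; geometry is
metadata, since the analysis never uses coordinates beyond ROI membership.
The exact source–detector pairing behind each numbered channel is not fully
specified by the montage description, so the default config ships a
plausible 20-pair assignment; it is fully configurable and nothing
downstream depends on it beyond channel identity. Inter-optode distance
defaults to 3 cm for every pair (the montage spans 2.5–3 cm; per-channel
values can be configured).

Scans carry a time × channel matrix per wavelength (raw) or per chromophore
(µM), task block events as half-open intervals `[onset, onset+duration)`,
and visit metadata. CSV files use a seconds-from-start time column with
samples at k/fs (0-based) plus a JSON sidecar; SNIRF files follow the
public HDF5 layout and round-trip exactly.

## Preprocessing

* **MBLL.** Extinction coefficients default to the standard tabulated
  values for HbO/HbR at 760/850 nm (cm⁻¹/M); the differential pathlength
  factor defaults to 6.0 at both wavelengths. Both are configurable and
  recorded in run manifests. The inversion is linear; a forward–inverse
  round trip is exact to numerical precision.
* **Filtering.** 3rd-order Butterworth, 0.01–0.5 Hz, applied
  forward–backward as second-order sections (`sosfiltfilt`): zero phase
  preserves feature timing, and the SOS form is numerically necessary
  because the 0.01 Hz edge sits at 0.26% of Nyquist. The 0.01 Hz edge has a
  ~100 s transient, negligible over a 6-minute scan but dominant on short
  test signals.
* **Epoching.** 2-back blocks only. Epochs span 0–40 s from onset
  (inclusive endpoint sample, `round(40·fs)+1` samples), with the mean over
  a [−2, 0) s pre-onset baseline subtracted, then averaged across blocks;
  incomplete blocks are dropped and counted. The 40-s window deliberately
  extends ~10 s into the following 0-back block, because the 35–40 s
  feature segment requires it. Features are computed on the block average
  (whether the original analysis averaged before or after feature
  extraction is unstated; block-averaged is this package's default).

## Temporal features

Nineteen per ROI, 95 per scan, in a fixed ROI-major order that is part of
the public contract. Conventions the source description leaves open:

* Segment means use half-open windows [a, b) mapped to samples
  `floor(a·fs) … floor(b·fs)−1`, partitioning 0–40 s without overlap.
* The slope is the least-squares line over [5, 15) s; skewness and
  kurtosis are plain biased sample moments over [0, 15) s, kurtosis
  **non-excess**; a constant segment reports both as 0 rather than NaN.
* AUCs integrate the piecewise-linear interpolant over exactly [0, 15] and
  [15, 40] s with edge-hold at the boundary, so a constant c yields 15c and
  25c exactly even though the sample grid ends at 39.95 s.
* An *extremum* is a sign change of the first difference (any turning
  point; a configurable prominence ε is available). If fewer than two
  turning points exist the fallback is global max then global min, which
  guarantees totality on monotone signals.

Shift/scale covariance of every feature is property-tested.

## Dynamic connectivity

Pearson correlations of all C(20,2)=190 channel pairs over windows of 300
samples slid by 100, on the band-passed continuous HbO (each window is a
small segment of the scan, not a block average). Window starts are
0-indexed with no partial final window: `n = floor((T−300)/100)+1`, giving
26 windows for a 2811-sample scan. Zero-variance channels yield
correlation 0 plus a degeneracy flag (detected with a relative tolerance,
since a constant channel's floating-point SD is ~1e-16·|value|) rather
than an error, so degenerate synthetic edge cases cannot abort a pipeline.
Correlations are not Fisher-transformed.

## Classifiers

* **Boosted trees**: XGBoost, 200 trees, depth 3, learning rate 0.1,
  logistic objective, single-threaded and seeded for determinism. The
  hyperparameters are conventional defaults; the original work names the
  library but no settings.
* **Recurrent network**: the architecture description ("5 hidden layers
  and 128, 64, 32, and 16 nodes" plus a 64-dim recurrent output) lists
  four encoder sizes; it is reconciled as four affine+tanh encoder layers
  plus the 64-unit tanh recurrent layer — five hidden layers in total.
  Per-window probability is a logistic readout of the hidden state;
  the scan-level probability aggregates per-window probabilities (mean by
  default; last/max switchable). Training minimizes the cross-entropy of
  the mean-aggregated scan probability with full-batch Adam (lr 1e-3,
  60 epochs default), Glorot-uniform init from a seeded generator. The
  implementation is NumPy with hand-derived backprop-through-time,
  validated against central finite differences; the network is small
  enough that this is fast and exactly reproducible.
* **Ensemble**: a stacked design. Within each training set the RNN is
  fitted on internal stratified (participant-grouped where possible)
  splits so every training scan gets an out-of-split connectivity
  probability; that probability joins the 95 features as a 96th predictor
  for the trees. At prediction time an RNN refitted on the full training
  set scores the sequence first. "Iteratively fitting" the two models is
  under-specified in the source; the single-pass stack is the primary
  behavior, with an optional AdaBoost-style reweighting loop
  (`n_rounds > 1`, off by default) as a declared reconstruction. On tiny
  cohorts where grouped internal splits degenerate to one class, the
  stacking falls back to ungrouped stratification, and finally to an
  uninformative constant column.

## Ground-truth labeling

The intoxication algorithm is a conjunction: DEQ self-rated "high"
strictly above 50 (the in-text >50/100 split) **and** a heart-rate rise of
at least 10 bpm over the pre-dose mean, both evaluated on vitals within
±30 min of the scan midpoint. The exact published rule (thresholds,
window, combination) lives in an unavailable supplement; the conjunction
and the 10 bpm tachycardia-change criterion are declared reconstructions,
configurable and recorded in manifests. Scan-level ground truth requires
CCR/algorithm concordance; disagreement (or a missing CCR) is *discordant*
and excluded from classifier building; placebo scans are negatives by
design. Raising either threshold is monotone non-increasing in positives
(property-tested).

## Evaluation

Folds are stratified by scan label and grouped by participant, so no
participant's scans straddle train and test — the source does not state
this, but without it within-subject signal leaks across folds. Ungrouped
stratified folds guarantee per-fold class counts within ±1 of
proportional; grouping makes stratification approximate (group sizes
forbid an exact guarantee). Metrics are pooled over test folds
(micro-average) with per-fold values alongside; AUC is the tie-averaged
rank statistic. The null-information rate is the majority-class
proportion, and significance is the exact binomial tail
P(X ≥ n_correct | n, NIR). Model selection minimizes mean FPR/TNR (ties:
higher accuracy, then config id); since FPR/(1−FPR) is increasing, this
equals argmin FPR. Hold-out evaluation refuses participant overlap with
training and, on all-negative sets, satisfies accuracy + FPR = 1 exactly.

## Group analysis

For each participant the peak-dose scan is the post-dose scan whose
DEQ-"high" at the nearest vitals sample is larger (ties → scan 2);
matched pre/peak pairs feed per-timepoint paired t-tests, with BH-FDR at
q = 0.05 applied **within each ROI across timepoints** (the correction
family is ambiguous in the source; per-ROI is the default and it is
switchable). Zero-variance timepoints get p = 1 with a flag.

## Synthetic-data generator

The generator emulates the study conditions: per participant, a THC and a
placebo visit; three scans per visit (pre-dose, ~100, ~200 min); each scan
6 minutes of 20-channel HbO/HbR at 7.81 Hz with twelve alternating 30-s
blocks (six 2-back + six 0-back — the run-length reading of the task
description, which is ambiguous between six total and six per condition;
the 0-back-first order gives every 2-back block a pre-onset baseline, and
the last 2-back block's 40-s window is dropped, leaving five usable
blocks); vitals every 20 min over [−20, 240] min.

Forward model: HbO = β·(double-gamma HRF ⊛ block boxcar, normalized to
unit isolated-block peak) + linear drift + shared+private sinusoidal
physiological components (cardiac 1.1 Hz, respiratory 0.25 Hz, Mayer
0.1 Hz) + white noise; HbR is −⅓·(clean HbO) plus independent noise. The
HRF peaks at 6 s with a 16-s undershoot (the canonical default; the source
never states an HRF, only that impairment raises HbO). Key defaults:
baseline 2-back amplitude 0.2 µM (SD 0.05 between participants), 0-back
amplitude 25% of 2-back, impairment increment Δβ = 0.3 µM, white noise SD
0.3 µM — i.e. a single-sample SNR of about one for the impairment effect,
with averaging across blocks and ROI channels doing the rest, which is
what makes the recovery analyses non-trivial but feasible at n = 40.

Impairment is Bernoulli per participant with p = 80/137 (the study's
impaired fraction among concordant participants); impaired participants
are impaired at scan 2 only / scan 3 only / both with probabilities
39:20:24 (the study's printed pattern). Vitals follow Gaussian bumps
(SD 50 min) centered on the impaired scan times: heart rate +25 bpm and
DEQ peak 75 when impaired, a mild +5 bpm / DEQ 20 on non-impaired THC
visits, flat on placebo; noise SDs 3 bpm and 5 DEQ units; DEQ clipped to
[0, 100]. The clinical consensus rating is simulated as the latent
scan status flipped with a 10% error rate, which produces discordant
cases. Separate named RNG substreams (assignment / fNIRS / vitals / CCR)
derive from the master seed, so changing vitals parameters never perturbs
the fNIRS series.

What the generator does **not** emulate: motion artifacts, optode-coupling
dropouts, non-sinusoidal physiology, spatially structured (ROI-specific)
activation differences, behavioral performance, or any relationship
between dose and impairment. Passing recovery tests therefore shows the
pipeline is correct and well-calibrated under its own assumptions, not
that the headline classification numbers transfer to real recordings —
on this cleanly separable synthetic signal the cross-validated ensemble
scores far higher than any real-data expectation.

## Problem sizes and numerical choices

The acceptance computations use: a 40-participant all-impaired cohort
(40 matched pairs per ROI) for group-level recovery; a 70-participant
cohort (~190 classifier scans) with 5-fold × 2-repeat CV (RNN at 40
epochs) for ensemble performance; and a 40-participant null cohort
(Δβ = 0) with 5-fold CV for type-I control. These sizes were chosen as
the smallest at which the group and classifier analyses are comfortably
powered under the default effect size. Tolerances: oracle equivalences at
1e-10–1e-12; the noise-free amplitude recovery at 1% relative;
distributional checks at 95% binomial bands.

## Known limitations

* The labeling algorithm and the ensemble's "iterative" coupling are
  reconstructions of procedures whose exact published form is unavailable;
  both are isolated behind configuration.
* HbR is generated and converted but never analyzed, matching the
  HbO-only outcome scope.
* The recurrent model is intentionally small and CPU-bound; there is no
  GPU path and no hyperparameter search.
* Connectivity windows use raw correlations (no tapering, no Fisher z);
  graph-theoretic summaries are out of scope.
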