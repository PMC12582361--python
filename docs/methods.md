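# Methods

This note documents the models, estimators and numerical choices behind
`ecog_biomarkers`, and what the synthetic cohorts can and cannot establish
about real intracranial recordings.

## Setting and data model

The package analyses intraoperative electrocorticography (ECoG) / intracranial
EEG recorded at 1000 Hz during a stepwise anaesthetic protocol: an isoflurane
baseline (1 vol%), sevoflurane raised from 2 to 3 to 4 vol% in 5-min stages,
and, in patients who also underwent extraoperative monitoring, an
anaesthesia-free slow-wave-sleep (SWS) block. Each stage is subdivided into
1-min epochs; the first three artifact-free minutes of each sevoflurane stage
are the analysis epochs, while control stages contribute their full span as
z-score baselines. Channels are classified from surgical outcome: *normative*
sites were retained, lie outside the seizure-onset zone and MRI lesions, and
are free of interictal discharges; *epileptogenic* sites were resected in
patients who became seizure-free.

Signals are referenced to a bipolar montage (consecutive contact differences)
before any biomarker computation; metadata flags of a derived channel are the
OR of its members', so a pair touching pathological tissue is never counted
as normative.

## Preprocessing

* **Band-pass 0.016–300 Hz.** The upper edge is a 4th-order zero-phase
  Butterworth low-pass (forward–backward, so the effective attenuation one
  octave above the edge exceeds 50 dB and the passband stays flat to well
  under 1 dB). The nominal 0.016 Hz lower edge matches the acquisition
  hardware filter; re-applying it digitally is numerically unusable (the
  poles sit within 1e-4 of the unit circle and their transients span
  minutes), so any configured lower edge below 0.5 Hz is implemented as
  linear detrending — over recordings of minutes, content below such an edge
  is indistinguishable from drift. Lower edges ≥ 0.5 Hz use a true
  Butterworth high-pass.
* **60 Hz notch.** 3rd-order Butterworth band-stop at 60 ± 1.5 Hz, zero
  phase; ≥ 30 dB within ±0.5 Hz of the line frequency, < 1 dB at ±5 Hz.
* **Artifact screening.** Visual review is replaced by a deterministic rule:
  samples beyond 6 robust SDs (median/MAD) of their channel are masked and
  dilated by 0.5 s; channels that are flat (MAD = 0) or > 50 % masked are
  rejected. Masking annotates, never alters, samples. Parameters live in the
  run configuration (`artifact_z_amp`, `artifact_min_gap_s`).

## Spectral amplitude

Band amplitude is the mean over a frequency grid of per-frequency Morlet
amplitudes (square root of wavelet power), computed in the frequency domain:
a 7-cycle Morlet at centre f is a Gaussian transfer function of width
f/7 Hz, applied to the signal FFT on positive frequencies and inverted. The
grids are 3/3.5/4 Hz for the delta band and 80–300 Hz in 10 Hz steps for the
HFO band (step configurable; reduced runs use 20 Hz). The transform is
validated against `mne.time_frequency.tfr_array_morlet` in the test suite.
Amplitude series stay at the native 1000 Hz; masked samples propagate as
missing values, widened by half the longest wavelet so estimates leaking
across an artifact boundary are discarded too.

Amplitude is z-scored per channel against the mean and SD of its unmasked
control-period samples (isoflurane, or SWS in two-stage patients), which
cancels electrode gain. Channels with under 60 s of usable control data, or
zero control SD, are excluded with a warning.

## Phase–amplitude coupling

Delta–HFO coupling is rated by the normalized mean-vector modulation index on
the raw (preprocessed, bipolar) trace: phi(t) is the analytic-signal phase of
the 3–4 Hz FIR-band-passed trace, A(t) the analytic envelope of the
80–300 Hz band, and

    MI = | mean_t A(t) e^{i phi(t)} | / mean_t A(t).

MI is scale-free, lies in [0, 1], and for an envelope A = 1 + k cos(phi − phi0)
converges to k/2 with preferred phase phi0 — the closed form the tests pin to
±0.02 on 120-s signals. Zero-phase FIR filters (~3 cycles of the low band
edge) avoid group delay. Per-epoch MI values are averaged across a stage's
three analysis minutes when a single stage-level map value is needed.

An optional surrogate z-score compares MI against circular time-shifts
(≥ 1 s) of the envelope. Shifts only destroy coupling when the slow rhythm is
aperiodic; a strictly sinusoidal delta phase is invariant under rotation, so
the synthetic delta rhythm carries Brownian phase wander (see below) and the
null calibration is run on such quasi-periodic signals.

## Burst binarization and transfer entropy

The z-scored amplitude is reduced to a binary burst train. The wave-cycle
reference is the band's lower edge (3 Hz and 80 Hz — the conservative reading
of "at least six cycles per bin"), giving 2-s delta bins and 75-ms HFO bins.
A bin is 1 iff it contains an excursion above z = 2 sustained for at least
three cycles; excursions spanning a bin boundary credit every bin they touch;
bins overlapping masked samples are missing, not zero.

Directed coupling between trains is the plug-in transfer entropy with history
length k = 1 and one-bin lag,

    TE(x→y) = Σ p(y⁺, y, x) log2 [ p(y⁺ | y, x) / p(y⁺ | y) ],

estimated from joint counts over jointly non-missing triplets (0·log 0 = 0).
No bias correction is applied; the estimator's O(1/N) positive bias is
instead quantified in the tests (≈ 2/(2N ln 2) bits on null binary pairs) and
respected in the design choices below. A channel's effective connectivity
(EC) is the mean of its efferent, afferent, or all 2(n−1) pairwise values;
bipolar pairs sharing a physical contact are excluded to guard against
montage-induced spurious coupling.

Two granularity choices follow from the bin arithmetic. HFO EC is computed
per 1-min epoch (~800 bins). Delta EC cannot be: a 1-min epoch holds only
~29 two-second triplets, below any usable sample size, so delta trains of a
stage's analysis epochs are concatenated into one stage-level estimate whose
channel summaries are replicated across that stage's epoch rows; the
`min_triplets` floor is 50 for per-epoch HFO TE and 25 for stage-level delta
TE (both configurable).

## Synthetic cohorts

The generator emulates the statistical structure of such a cohort, not its
biophysics:

* **Background**: Brownian (1/f²) noise, detrended, SD 15 µV, plus a 2 µV
  60 Hz line component.
* **Delta rhythm**: one frequency per patient drawn from 3–4 Hz with shared
  Brownian phase wander (0.2 rad²/s) and per-channel phase offsets,
  amplitude 30 µV with stage gains 1.0/1.05/1.1/1.15 (Iso→Sev4). A global
  rhythm is both physiologically sensible (anaesthetic delta is a
  thalamocortical phenomenon) and necessary: independent per-channel
  frequencies beat in bipolar derivations and flood the burst binarization
  with spurious crossings, while a perfectly periodic phase would defeat
  circular-shift surrogates.
* **Slow-wave excursions**: Poisson events (0.1/s normative) raising delta
  amplitude 2.5-fold for 2.5 s — long enough to survive 7-cycle wavelet
  smoothing and the 3-cycle excursion rule. These events propagate along
  planted directed edges with per-(stage, class) probabilities.
* **HFO bursts**: 50–150 ms of 80–300 Hz band-limited noise, envelope peak
  20 µV over a 1.5 µV tonic in-band floor, at per-(stage, class) Poisson
  rates; each burst's amplitude is scaled by 1 + κ·cos(phi_delta − phi0)
  with the channel's preferred phase phi0 and the per-(stage, class)
  coupling depth κ. Bursts propagate one hop along the planted edges at a
  one-bin lag.
* **Class structure** (the double dissociation): epileptogenic channels have
  higher κ (up to 0.7 vs 0.35 at 4 vol%), higher HFO transmission (0.65 vs
  0.20), *lower* delta transmission (0.04 vs 0.80), fewer slow-wave
  excursions (factor 0.3), and a denser epi→epi edge sub-network (density
  ×3) emulating a hyperconnected focus. An edge transmits with the geometric
  mean of its endpoint classes' probabilities so the class effect appears in
  both efferent and afferent summaries. These magnitudes are free parameters
  of the simulation — no published consensus pins their quantitative magnitudes — fixed
  once from detectability diagnostics of the generator itself and not tuned
  thereafter.

Default cohort structure mirrors a realistic paediatric surgical series: 19 patients, ~30 % epileptogenic
sites, 11/19 two-stage (SWS block present), 5-min stages at 1000 Hz.

**What passing tests do and do not show.** The synthetic cohorts share the
target design's *statistical* skeleton (stage gains, class contrasts, patient random
effects, missingness via artifact masking) but not real ECoG's
nonstationarity, spatially correlated noise, volume conduction beyond the
shared-rhythm term, or electrode-geometry effects. Recovery of planted
effects therefore validates the estimator chain and the statistical
machinery, not clinical performance on patient data.

## Mixed-effects statistics

Biomarker tables are long format: one row per (patient, channel, stage,
epoch, biomarker). The anaesthetic stage enters as a single ordinal covariate
(control = 0, the nine sevoflurane minutes = 1..9), matching an
origin-anchored linear trend; epoch-level rows (not stage means) are the
default modelling unit.

* **Stage trend (normative channels)**: linear mixed model by REML
  (`statsmodels` MixedLM), fixed effects age, sex, hemisphere, MRI lesion,
  daily seizures, anti-seizure medication count, surgical staging, and the
  stage code, with a random intercept per patient (random stage slope
  optional). Wald t-tests use residual degrees of freedom — an approximation
  to a Satterthwaite correction, adequate at electrode-level sample sizes.
  Bonferroni m = 6. Covariates that are constant, or collinear with the
  patient structure in a given subset, are dropped by a rank-checked greedy
  selection; if the optimizer's convergence flag is false but the final
  iterate carries finite curvature, Wald statistics are reported from it
  with a flag. The implementation is cross-checked against lme4's `lmer` in
  the test suite. Sorted residual quantiles are exported for Q–Q
  diagnostics.
* **Epileptogenicity / SOZ characterization (all channels)**: binary
  logistic mixed model (variational-Bayes binomial mixed GLM) of site status
  on the same covariates plus the biomarker value, random intercept per
  patient, Bonferroni m = 40. The biomarker value is standardized by
  default, so odds ratios read "per SD of the biomarker": raw transfer
  entropies live on a millibit scale where per-unit log-odds are in the
  hundreds, which a shrinkage posterior cannot represent (and which produce
  the astronomically large per-unit odds ratios familiar from unpenalized
  fits). Raw-scale estimation is available (`standardize_value=False`) and
  used in the recovery benchmarks (coefficient bias < 15 % at ~1500
  channels). Quasi-complete separation is flagged, not "fixed".
* **Effect sizes**: per patient and 1-min epoch, Cohen's d is
  |mean(pathological) − mean(others)| / SD(all sites), averaged over patients
  and epochs per stage. The subtraction predictor is each patient's
  mean(resected) − mean(retained) biomarker value, a resection-completeness
  proxy for outcome models.
* **Log variant**: per biomarker, values map to log(value + ε), ε = half the
  smallest positive value and only applied when zeros are present;
  downstream models are unchanged.

## Hotspots

A channel is a hotspot at a stage when its stage-averaged biomarker value is
at least 3 SD above the SWS reference mean ("at least": the boundary is
included), with the reference mean/SD pooled across normative channels
(per-channel referencing available). All unordered hotspot pairs are exported
as a CSV edge list (with coordinates when supplied) for external tractography
software; streamline tracking is out of scope.

## Reduced evaluation cohorts and problem sizes

Full cohort scale (19 patients × ~100 contacts × 25 min at 1 kHz) is far
beyond a desk run, so the verification suite uses reduced cohorts chosen as
the smallest sizes at which the planted effects are reliably detectable:
5 patients × 8 contacts, schedule Iso 90 s / Sev2 60 s / Sev3 180 s /
Sev4 180 s (the longer 3–4 vol% stages supply the delta-band TE sample), HFO
grid step 20 Hz. Calibration studies use 200 table-level replicates (Wald
coverage, type-I rate), 20 cohorts of 1500 channels (logistic recovery), 200
null TE pairs and 100 surrogate runs. The full-pipeline determinism check
runs 2 patients × 6 contacts twice and compares outputs byte for byte.

## Known limitations

* Per-epoch delta EC is fundamentally sample-starved at 2-s bins; the
  stage-level estimate trades within-stage temporal resolution for usable
  variance.
* The Wald df approximation is anti-conservative relative to Satterthwaite
  at small patient counts; measured CI coverage is ≈ 0.93–0.95.
* The variational logistic posterior shrinks extreme coefficients; per-SD
  standardization is the supported scale.
* EDF files are ingested (via MNE) but not written; the package's HDF5
  container is the native signal format.
* The generator's class contrasts are stylized: single-hop propagation, hard
  class dichotomy, and stationary within-stage statistics.
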