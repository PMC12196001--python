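# Methods

`dyadsync` analyses dyadic ("hyperscanning") fNIRS recordings of two people
sharing an experience — here, couples co-viewing a fixed set of emotive
videos — and asks how similar their prefrontal haemodynamics are, and
whether that similarity relates to how differently the two partners rate
their relationship.

## Paradigm and data model

A session is seven repetitions of a 60 s fixation cross followed by a 114 s
video (total 1218 s). The seven videos target happiness, love, pride
(positive), sadness, fear, disgust (negative) and a neutral ocean clip
(baseline); three fixed orders (sequences A, B, C) are assigned across
dyads. Recordings are two-wavelength (760/850 nm) optical-density series at
7.81 Hz from eight ventral-prefrontal channels per subject — channels
4/19 (left/right VLPFC), 7/14 (left/right VMPFC), 6/11 (left OFC) and
13/16 (right OFC) — grouped into a frontal-left {4, 6, 7, 11} and a
frontal-right {13, 14, 16, 19} region of interest. Each subject also
answers the 7-item Relationship Assessment Scale (7-point Likert); items 4
and 7 are reverse-scored (`8 − x`, the instrument's standard key — the key
is an explicit argument because published analyses do not always state
theirs), the score is the item mean, and the dyad predictor is the absolute
score difference Δs.

## Preprocessing

Per subject, in a fixed order:

1. **Channel quality.** A channel is dropped when its amplifier gain
   exceeds 8 or the coefficient of variation of either wavelength exceeds
   7.5 (strict inequalities: boundary values pass). Every exclusion is
   logged once with a machine-readable reason; a channel enters the
   synchrony stage only if retained in *both* subjects.
2. **Despiking.** A sample is flagged when it deviates from the moving
   median (window 1 s, truncated at the edges) by more than
   `k = 5` × 1.4826 × the moving MAD, and is replaced by linear
   interpolation between clean neighbours (endpoints take the nearest clean
   value). This removes impulsive motion artifacts; a clean level shift is
   deliberately *not* flagged (each sample sides with the majority of its
   own window) — baseline shifts are left to the band-pass stage.
3. **Band-pass.** Zero-phase (forward–backward) 3rd-order Butterworth,
   0.01–0.2 Hz. Zero phase matters because the downstream synchrony measure
   is sensitive to relative timing between subjects. The signal is extended
   by mirror ("even") padding over ~3 time constants of the low edge before
   filtering: the default odd extension reflects about the endpoint *value*,
   which offsets the pad's local mean and drives an O(signal) transient
   through the very narrow band. Measured contract at 7.81 Hz: DC residual
   < 1e−12 relative, 1.0 Hz attenuated by ~45 dB, 0.05 Hz retained at
   99.9 % RMS.
4. **Beer–Lambert conversion.** Per sample the 2×2 system
   ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR]·d·DPF(λ) is solved exactly for
   (ΔHbO, ΔHbR), with d = 3 cm, DPF = 6.0 at both wavelengths and the
   standard Gratzer/Prahl extinction coefficients at 760/850 nm (in
   µM⁻¹cm⁻¹: ε_HbO = 5.86e−4, ε_HbR = 1.54852e−3 at 760 nm;
   ε_HbO = 1.058e−3, ε_HbR = 6.9132e−4 at 850 nm). The simulator uses the
   same constants for its forward map, so the conversion round-trips to
   machine precision.

## Synchrony index

For each dyad, retained channel and video block, the two subjects' ΔHbO
segments (890 samples = floor(114 s × 7.81 Hz); fixation periods are not
scored) are aligned with Dynamic Time Warping under the symmetric step
pattern with double-weighted diagonal ("symmetric2"):

    D(0,0) = c(0,0),
    D(i,j) = min( D(i−1,j−1) + 2c(i,j), D(i−1,j) + c(i,j), D(i,j−1) + c(i,j) ),

with local cost c(i,j) = |xᵢ − yⱼ|. The **normalized distance index** is
D(N,M)/(N+M) — N+M is precisely the normalization constant of the
symmetric2 pattern. Larger index = worse warping alignment = lower
interpersonal synchrony. The recursion is validated against an exhaustive
enumeration of all monotone warping paths on short series; path
backtracking prefers diagonal steps on ties. The DTW input signal is ΔHbO
by default (configurable to ΔHbR or the species mean); segments are not
z-normalized (raw concentration changes), both configurable. No global
window constraint is applied by default; a Sakoe–Chiba band is available.

Channel indexes are averaged (unweighted) into the two ROIs per block, then
block indexes into the three conditions (positive, negative, baseline) —
mean of means, so a missing channel affects only its own ROI. A (dyad, ROI)
cell with no surviving channel is missing, never zero-filled.

## Statistics

Three analyses on the dyad × ROI × condition table (right cluster by
default, switchable):

- **Kruskal–Wallis** across the positive/negative/baseline per-dyad
  indexes (df = 2), and the two-group variant comparing each dyad's
  emotion index (mean of positive and negative) with its baseline index
  (df = 1) — the same tie-corrected H statistic with a chi-square tail.
  *Caveat:* the condition samples are repeated measures on the same dyads
  but are treated as independent groups; this replicates the original
  analytic plan rather than a statistically optimal one (a Friedman test
  would respect the pairing).
- **OLS per ROI** of index on Δs and an emotion dummy (positive = 1),
  baseline excluded: 2 rows per complete dyad, so 15 dyads give 30 rows
  and residual df 27. The same caveat applies: the two rows of a dyad are
  correlated, so printed standard errors are mildly anti-conservative; on
  the synthetic conditions below the 2·SE null coverage measures ~93–96 %
  against the ~94.5 % nominal ceiling of a t(27).
- **Pearson correlation** between Δs and the right-cluster index averaged
  over the two emotion conditions (n = dyads, df = n − 2); at n = 15 this
  is the analysis with the printed df of the study design. The r→p
  conversion (two-tailed t) is exposed as `pearson_p_from_r`.

No multiple-testing correction; all tests two-tailed.

## Synthetic cohorts

The generator produces the full measurement chain so every stage is
testable without the original deposit. Per dyad:

- **Responses.** Each video block contributes a boxcar scaled by its
  condition amplitude (defaults 0.5 µM ΔHbO for positive and negative,
  0.2 µM for the neutral clip — free parameters; the study reports no
  per-condition magnitudes), convolved with a canonical double-gamma HRF
  (peak 6 s, undershoot 16 s, ratio 1/6). Channels carry a log-normal
  sensitivity factor (σ = 0.2) shared by both subjects.
- **Coupling.** The subject's true ΔHbO is
  κ·shared + (1−κ)·individual, where the individual component re-uses the
  shared response with per-channel, per-block amplitude jitter
  (σ = 0.3, emulating fluctuating attention/habituation) plus a slow
  individual wander (0.3 µM RMS, low-passed below 0.05 Hz). Coupling
  follows κ = clip(β₀ + β₁·Δs + N(0, σ_κ), 0, 1) with defaults β₀ = 0.2,
  β₁ = 0.35, σ_κ = 0.05, so mismatched couples are *more* coupled — the
  direction the downstream regression should recover as a negative
  coefficient of the distance index on Δs. β₁ is sized so the slope is
  detectable from 15 dyads (30 regression rows); the jitter/wander split
  deliberately keeps most index noise at the block/channel level so the
  independence-assuming OLS stays approximately calibrated (a large
  dyad-level component would make its printed SEs anti-conservative — the
  same caveat as for real data).
- **Noise.** Cardiac (1.1 Hz) and respiratory (0.25 Hz) sinusoids with
  random phases, a stochastic narrowband Mayer-wave component around
  0.1 Hz (power-matched to a 0.25 µM sinusoid), white noise (0.05 µM),
  linear drift (±0.5 µM over the session) and Poisson motion spikes
  (0.2/min, 5–15 µM, 1–3 samples). ΔHbR = −ΔHbO_true/3 plus its own small
  white noise. Concentrations map to optical densities via the forward
  Beer–Lambert model above. Channel quality metadata marks a channel bad
  with probability 0.05 (high gain or high CV), emulating realistic
  attrition.
- **Questionnaires.** Satisfaction scores are drawn per subject from
  truncated Gaussians (means 4.3 and 4.4, SD 0.5, the study's printed
  descriptives; the resulting |Δs| has mean ≈ 0.57, SD ≈ 0.43). Integer
  item responses are constructed so the keyed mean lands within 1/14 of
  the drawn score.
- **Reproducibility.** Per-dyad seeds derive from the master seed via
  `SeedSequence(master, spawn_key=(dyad_index,))`; sequence labels are
  assigned round-robin A, B, C and shuffled with a seeded permutation.
  Identical seed and configuration give byte-identical output tables.

What the generator does **not** emulate: scalp/systemic physiology layers
and short-channel content, optode-position errors, heteroscedastic or
serially correlated questionnaire error, wavelength-dependent spike
topography, and any true anti-phase or lagged coupling structure beyond
what DTW warping absorbs. Passing tests therefore show the pipeline
recovers the planted link under plausible signal/noise conditions — not
that the original study's effect is real.

## Problem sizes and numerical choices

The Monte-Carlo claims use 200 replicate cohorts (15 dyads each) for link
recovery and 100 for null calibration; the Kruskal–Wallis size check uses
1000 replicates of 3 × 15 samples. Each replicate runs the full pipeline
(840 alignments of 890-sample segments per cohort); the DTW hot path is a
numba kernel that processes all channel × block pairs of a dyad in one
lane-parallel pass. Degenerate inputs are handled explicitly: all-identical
Kruskal–Wallis samples return H = 0 with a warning; constant series are an
error for Pearson; an all-flagged channel is an error for despiking; a DTW
window tighter than |N − M| is an error; channels missing in one subject
propagate as missing rows, and a cohort losing every dyad to quality
filtering aborts with an empty-cohort error.

## Replicating on real data

The original study's statistics (H(2) = 5.26; H(1) = 3.88; the Table-4
regressions; r = −0.47) require its OSF deposit, which this package does
not download. `dyadsync run-all --input-dir <dir> --out <dir>` reproduces
the full analysis on any cohort stored in the documented long-format CSV
dialect (or SNIRF); the reader makes no assumption about whether deposited
series are raw or preprocessed — preprocessing parameters can be relaxed
(e.g. wider band, no despiking) through the YAML config if the input is
already clean.
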