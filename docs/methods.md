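# Methods

`dircuff` implements a complete analysis chain for directionally sensitive
nerve-cuff electroneurography (ENG): a generative simulator of four-contact
cuff recordings with afferent/efferent ground truth, the tetrapolar signal
algebra, a threshold-based spike-extraction pipeline, a 20-feature window
descriptor, direction classifiers, and obstruction-response statistics.
This note records the model, the defaults and why they were chosen, and the
numerical decisions that were genuinely open.

## The tetrapolar recording model

Four contacts at longitudinal positions 0, 2.5, 5.0 and 7.5 mm inside a
12-mm cuff yield voltages V1..V4 sampled at 40 kHz. The derivations are

    Bipolar1   = V1 − V4              Bipolar2  = V3 − V2
    Tripolar1  = V2 − (V3 + V1)/2     Tripolar2 = V3 − (V2 + V4)/2
    Tetrapolar = Tripolar1 − Tripolar2
               = −1/2·V1 + 3/2·V2 − 3/2·V3 + 1/2·V4
               = −1/2·Bipolar1 − 3/2·Bipolar2

The tripolar-difference composition is the package's canonical sign
convention; the coefficient expansion and the bipolar combination are
algebraically forced by it, and the three are tested to agree to machine
precision. The coefficients sum to zero (common-mode rejection) and, with
equal spacing, have zero first moment (a field varying linearly along the
cuff cancels exactly): this is the "low-noise" property of the geometry.

Direction sensitivity follows from antisymmetry: reversing the contact
order negates the coefficient vector, so a spike passing the contacts in
the 4→1 (efferent) order produces exactly the negative of the 1→4
(afferent) waveform of the same fibre. The classifier therefore has a real
physical signal to learn — waveform polarity and the shape features that
encode it.

## Synthetic recordings

The simulator emulates an anesthetized-rodent upper-airway-obstruction
preparation. Unstated physiological parameters are package choices, exposed
in `ScenarioConfig` and fixed once:

| parameter | default | rationale |
|---|---|---|
| conduction velocity | 25 m/s | mid-range myelinated fibre; gives a 4-sample adjacent-contact delay at 40 kHz |
| AP template | biphasic, 0.8 ms, second lobe 0.45 of the first | extracellular convention; dominant initial phase |
| template peak | 8 µV | physiological cuff ENG is a few µV |
| afferent / efferent rate | 300 / 200 events/s | dense multi-unit compound traffic; corpus-scale window counts on desk-scale durations |
| respiration | 1.5 Hz raised-cosine gain (1 − cos 2πft) on the afferent rate | rat respiratory rhythm; time-average equals the base rate |
| obstruction suppression | 0.05 | afferent lung-stretch traffic almost silenced during occlusion |
| target SNR | 6.05 dB | the reported mean operating point (range 4.3–7.3 dB) |
| protocol | 60 s baseline, 5 × 15-s obstructions, 60-s gaps, 60 s post | the published protocol timing |

Firing is an inhomogeneous Poisson process (thinning); spike collisions
superpose with no refractory enforcement. Per-spike amplitudes jitter
uniformly ±20%.

**Noise calibration.** SNR is defined as `20·log10(Vpp_signal/Vpp_noise)`.
The estimators the definition leaves open are fixed as: signal Vpp =
peak-to-peak of one clean spike at the tetrapolar output; noise Vpp = mean
peak-to-peak of the tetrapolar noise over consecutive 1-ms windows. White
Gaussian noise is added per contact and rescaled against the realised
estimate, so the achieved SNR matches the target essentially exactly
(tested to ±0.5 dB over 20 seeds). At the 6.05-dB default this places the
3σ detection threshold near 2.6 µV, consistent with the few-µV thresholds
such preparations report.

**Artifacts.** Far-field ECG (150 µV, 360 beats/min), respiration-locked
EMG bursts (10 µV, in-band) and sparse large "movement/flush" events
(2 mV, 0.1 /s, 4 ms) couple into the contacts with a common + linear
gradient + small random per-contact asymmetry (2%, the impedance-mismatch
residual). The gradient part cancels exactly in the tetrapolar output — the
point of the geometry — while the asymmetry leaves the realistic residual
that motivates artifact blanking. These couplings were sized from a noise
budget: the artifact residual must sit below the calibrated noise floor
(as it does in a foil-shielded cuff), otherwise the noise reference no
longer reflects the white-noise operating point that the SNR calibration
defines.

**What the simulator does not model:** biophysical volume conduction,
fibre-diameter (velocity) dispersion, electrode drift, breathing-rate
variability, anesthetic depth. Passing tests therefore demonstrate the
pipeline's correctness and the direction-classification principle under the
stated generative model, not in vivo performance.

## Spike pipeline

Blocks, in order: (1) hard blanking of the two bipolar derivations at
700 µV with a ±1-ms guard — the mask is the union over both derivations,
because an artifact event corrupts the whole cuff and one-sided blanking
leaves a large imbalance residual in the tetrapolar combination; replaced
samples take the trace mean to avoid step edges into the filter; (2)
8th-order Butterworth band-pass 250 Hz–10 kHz, applied zero-phase
(forward-backward, so peak times are unshifted; the effective order
doubles); (3) tetrapolar construction from the filtered bipolars; (4)
thresholds `mean(data) ± 3·std(noise)` where the noise reference is a
signal-free (complete-transection) recording run through blocks 1–3; (5)
peak detection: supra-threshold local extrema of either polarity, a
≥20-sample minimum separation resolved greedily in favour of the larger
magnitude, 20-sample edge guard; (6) 41-sample (1.025 ms) windows centred
on each peak — windows whose centre is not their absolute maximum (a larger
neighbour intrudes) are dropped so the centred-peak invariant always holds;
(7) paradigm labels: proximal transection → afferent, distal → efferent,
complete → noise, intact → unknown mixture.

At the 6-dB operating point the detector's false peaks on pure noise
(≈80 /s, the Rice rate of 3σ excursions for this bandwidth) and its losses
to burst-overlap merging (≈15%) roughly cancel, so detected counts track
the true spike count to within about ±15%. Both error components are
measured separately in the test suite.

## Window features

Twenty descriptors per 41-sample window, in a fixed canonical order. Names
alone underdetermine several of them; the conventions are documented in
`dircuff.features` and summarised here: unbiased variance; standardised
third/fourth moments (kurtosis not excess; zero for flat windows); Shannon
entropy (bits) of a 10-bin amplitude histogram; max |DFT|; RMS of the raw
window vs RMS of the mean-removed window (the two near-duplicate names are
deliberately split this way); Hjorth mobility `sqrt(var(Δx)/var(x))`;
range; mean power; mean first difference × fs (µV/s); strict zero
crossings with zeros inheriting the previous sign; sign of the largest-|.|
sample (ties → earliest, zero → +1); geometric and harmonic means of
|x| + 1e−12; mean |x|; mean periodogram PSD; mean Welch PSD (16-sample
Hann segments, 50% overlap — a declared choice, the window being only 41
samples); first-slope sign; sign changes of Δ|x|. No definition can emit
NaN. Negating a window flips exactly the two polarity-coded features and
preserves the amplitude-symmetric ones — this is where the direction
signal lives. (Entropy's mirror symmetry holds except when samples sit
exactly on interior histogram edges, a measure-zero layout.)

## Classification

Class 0 = efferent, class 1 = afferent. Model 1: pooled 60/40
train-pool/test split, then 85/15 train/validation inside the pool; Model
2: one whole experiment held out as test, the rest split 85/15. Splits are
stratified per class with floor rounding (remainder to the test/validation
side) and seeded. Features are z-scored on training statistics only.

Four families: Gaussian-kernel SVM (primary), k-NN with the "coarse"
k = 100 preset, AdaBoost over 30 depth-1 trees, and a one-hidden-layer
10-unit logistic MLP with early stopping. SVM kernel width uses the median
pairwise-distance heuristic on a 400-row subsample; the box constraint
defaults to C = 30 — the C = 1 convention underfits the polarity boundary
in this standardized 20-feature space. The per-class misclassification
penalty is tuned on the validation set: each candidate afferent:efferent
ratio is trained and the one minimising |recall₀ − recall₁| wins (ties to
the smaller ratio). ROC curves are built from decision scores (SVM margin,
k-NN vote fraction, AdaBoost margin, MLP probability) and AUC by the
trapezoidal rule; a single-class test set yields a flagged null AUC.

## Obstruction analysis

HR (R-peaks at 50% of the global maximum with a 100-ms refractory → 60 /
mean RR), mean BP, GGEMG activity (rectify → normalised 300-ms Bartlett
moving average → peaks above 0.2 mV → trapezoidal area of the smoothed
signal over each contiguous supra-threshold extent, counted once), and the
RnP (band-pass 250 Hz–10 kHz, square, 2-Hz 4th-order zero-phase Butterworth
low-pass, negative ripple clamped) are reduced to 15-s bins starting at
epoch boundaries (partial trailing bins dropped; inter-obstruction gaps are
tagged `recovery` and excluded from the baseline-vs-obstruction contrast).
Percent change is computed on epoch means with SE across the supplied
replicates.

The Wilcoxon rank-sum p is exact (full enumeration, midranks) for combined
n ≤ 12 and otherwise uses a continuity-corrected normal approximation with
tie-corrected variance plus an Edgeworth kurtosis term,
γ₂ = −(6/5)(m² + n² + mn + m + n)/(mn(N+1)): the rank-sum null is
platykurtic at small n, and the plain normal tail is off by up to ~0.017 at
N = 12 while the corrected form stays within ~0.003 of exact.

**Suppression recovery.** For a superposition of independent spike trains
the mean ENG power is linear in firing rate plus a constant noise floor
(Campbell's theorem), so
`(RnP_obstruction − floor)/(RnP_baseline − floor)` estimates the fraction
of afferent firing retained during obstruction; the floor comes from
signal-free recordings processed identically, and 1.5-s margins keep the
2-Hz filter transition out of the epoch averages. The recovery test runs
this estimator with the artifact channels disabled, isolating the neural
estimator; artifact robustness is exercised separately by the
detection-count test, which runs with all artifacts on.

## Problem sizes used in the tests

The validation suite scales the study down to desk size as its own design:
integration protocols use a 30-s baseline with three 15-s obstructions and
20-s gaps; classification experiments use 4,000 training and 1,000 test
windows per class per condition, 20 seeds per SNR level in
{12, 9, 6, 3} dB; recovery experiments use 10 seeds; the obstruction
hypothesis test uses 6 synthetic animals per condition. Published worked
examples (split accounting on the 380,800-row corpus, the 2.8-µV threshold,
the 6.05-dB SNR, the 41-sample window) are checked at full stated size.

## Known limitations

* The in vivo headline effect sizes (RnP decreases of ~92%/78%, ~85%
  classification accuracy) are properties of recordings that were never
  deposited; the package reproduces the phenomena (direction separability,
  suppression-driven RnP and afferent-fraction decreases) on synthetic data
  with known ground truth, not those specific magnitudes.
* The simulator's single conduction velocity makes the efferent waveform an
  exact mirror of the afferent one; velocity dispersion would soften the
  polarity cue and lower accuracy at a given SNR.
* Sub-sample spike alignment is quantised to whole samples at 40 kHz.
* k-NN has no native per-class penalty; the tuned weights are echoed in its
  metadata but do not alter its vote.
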