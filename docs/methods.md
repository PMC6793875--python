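# Methods

`affectlab` re-implements, as a tested library, a psychophysiological
emotion-recognition analysis for experiments that compare a real environment
with its immersive-virtual twin: ECG and 9-channel EEG are recorded while
subjects pass through calibration stages (2D affective picture blocks,
360-degree emotional rooms) and a museum stage experienced either physically
or in VR; per-stimulus features feed leave-one-subject-out (LOSO) classifiers
of arousal, valence, and real-vs-virtual condition.

## Analysis chain

1. **ECG → RR series.** Pan–Tompkins QRS detection (band-pass 5–15 Hz,
   five-point derivative, squaring, 150 ms moving-window integration,
   adaptive dual thresholds with 200 ms refractory and RR-based search-back),
   refined to the raw-signal maximum within ±75 ms. Ectopic/artifact beats
   are intervals deviating > 25% from an 11-beat local median, replaced by
   cubic-spline interpolation (> 20% flagged warns, > 50% errors). Slow
   trends are removed by the smoothness-priors method (second-difference
   ridge penalty, λ = 500 by default) *after* time-domain features are
   computed and with the mean level restored, so mean-RR information is not
   destroyed.
2. **HRV features (26).** Time domain: mean RR, SDNN (n−1 denominator),
   RMSSD, pNN50 (percentage; the raw count is exposed as NN50), triangular
   index and TINN with 1/128 s histogram bins (TINN by a least-squares
   triangle fit searched over bin edges). Frequency domain: tachogram
   cubic-resampled to 4 Hz, Welch PSD (150 s Hann segments or full length,
   50% overlap); VLF < 0.04, LF 0.04–0.15, HF 0.12–0.4 Hz. The HF band
   deliberately overlaps LF as printed in the protocol this package follows;
   a conventional 0.15–0.4 Hz switch exists (`hf_band`). **Total power is
   defined as the sum of the three band powers**, so normalized units
   (band/(total−VLF)·100) satisfy lf_nu + hf_nu = 100 exactly despite the
   overlap. Nonlinear: Poincaré SD1/SD2, ApEn/SampEn (m = 2, r = 0.2·SD,
   Chebyshev distance, ≥ 100 beats), DFA α1 (boxes 4–16) and α2 (16–64,
   ≥ 130 beats), Grassberger–Procaccia correlation dimension (embedding 10,
   delay 1, slope of log C(r) between the 5th and 50th distance percentiles,
   ≥ 200 beats). SD1 is computed as RMSSD/√2 (mean-square of successive
   differences), making the SD1 ≡ RMSSD/√2 identity exact for every input;
   SD2 uses the population variance so an alternating series gives exactly 0.
   Features that cannot be estimated (short windows, degenerate series) are
   NaN markers, never silent zeros; imputation is the classifier's decision.
3. **EEG cleaning.** Corrupted channels: robust z of excess kurtosis across
   channels > 5, or flat (successive difference < 0.01 µV) for > 10% of the
   recording; exactly one corrupted channel is interpolated as the unweighted
   mean of fixed montage neighbours, more than one rejects the subject.
   Mean subtraction, zero-phase 4th-order 0.5–40 Hz band-pass, segmentation
   into 1-s epochs. An epoch is invalid when more than 2 channels violate
   the artifact rule (|sample| > 100 µV **or** gradient > 70 µV; an
   and-semantics switch exists); subjects with > 1/3 invalid epochs are
   rejected. ICA (FastICA; see substitutions) removes components that look
   like blinks (frontal topography dominance and < 4 Hz power fraction
   > 0.5) or muscle (γ fraction > 0.5 and excess kurtosis > 5), with a
   manual component list as override.
4. **EEG features (36 + 144).** Band powers per epoch via Welch (0.5 s Hann
   segments, 50% overlap) for θ(4–8), α(8–12), β(13–25), γ(25–40 Hz), δ
   excluded; band power is the sum of PSD bins whose centre lies in the band
   times the bin width (a trapezoid over the 2 Hz grid would truncate the
   narrow bands). Mean phase coherence (MPC) per channel pair and band:
   R = |E[exp(iΔϕ)]| with instantaneous phases from a frequency-domain
   band-limited analytic signal per epoch (positive-frequency bins in the
   band kept and doubled), 10% of samples trimmed at each epoch edge.
   The per-epoch complex phase-difference means are averaged across epochs
   before taking the magnitude: unsynchronized pairs then average toward 0
   as epochs accumulate, while any constant phase lag still yields R = 1.
   (Averaging per-epoch scalar R values instead — available as
   `epoch_aggregate="magnitude"` — is positively biased to ≈ 0.5 under the
   null for 4-Hz-wide bands on 1-s epochs and cannot meet the null
   behaviour this statistic is used for.) Per-stimulus values are means over
   the valid epochs in the stimulus window.
5. **Fusion and psychometrics.** Each stimulus record carries 26 HRV + 36
   band + 144 MPC = 206 features with block tags. Self-assessment scores in
   [−4, 4] are bipolarized at > 0 (high) vs ≤ 0 (low); subjects whose
   picture-norm z-scores fall strictly outside ±2.58 are screened out.
   Real-vs-virtual rating comparisons: Shapiro–Wilk per group, two-sided
   Mann–Whitney U per stimulus and dimension, flags at α = 0.05 and 0.1,
   plus bipolarized high-proportions per condition. Analysis cases: (1)
   museum only, (2) museum + picture blocks, (3) museum + 360° rooms;
   validation rows are always museum stimuli.
6. **Classification.** One LOSO fold per museum subject; training rows are
   all other subjects' records including calibration-stage extras.
   Everything is refit per fold: train-median imputation of undefined
   features, median/MAD normalization (raw MAD, zero-MAD features dropped
   and logged), then one PCA per block retaining the smallest leading set
   with ≥ 95% cumulative explained variance. A C-SVM with sigmoid kernel is
   searched jointly over 15 log-spaced values from 0.1 to 1000 for both cost
   and gamma (225 pairs), maximizing pooled validation accuracy subject to
   the balance rule (both per-class recalls > 60%); ties break to the
   smaller recall gap, then smaller cost, then smaller gamma; if no pair is
   balanced the best unbalanced model is reported and flagged. Feature
   relevance: nonlinear SVM-RFE per fold using the margin-objective
   sensitivity criterion (drop in W² = Σ αᵢαⱼyᵢyⱼK(xᵢ,xⱼ) when a component
   is removed, support vectors fixed), with correlation-bias reduction:
   components correlated above |r| = 0.85 form a group and each member's
   criterion is evaluated with its group-mates temporarily excluded, so
   near-duplicates cannot mask each other. Per-fold rankings are aggregated
   by median rank; the final component subset is the median-rank prefix
   maximizing pooled accuracy under the balance constraint (ties to the
   smaller subset). The real-vs-virtual ("nature") model runs the same
   machinery on museum rows of both phases with the condition as label and
   "virtual" as the positive class; emotion models use "high".

## Synthetic study generator

The generator is first-class, tested code: it produces the world every
end-to-end test assumes, with two cohorts (default 30 subjects per phase,
configurable), 9-channel EEG + 1-lead ECG at a nominal 256 Hz, and three
stages (picture blocks of 10 s; four 360° rooms of 90 s, fixed by design;
eight museum stimuli — five rooms and three artworks — of 60 s by default,
a free choice since exploration times are not prescribed anywhere).

* **RR series**: RR(t) = mean + a_LF sin(2π·0.10t) + a_HF sin(2π·0.25t) +
  white per-beat noise; a_LF²/a_HF² equals the requested LF/HF and the
  sinusoids carry 90% of the requested SDNN² (a larger broadband share
  dilutes the spectral ratio toward 1, breaking the generator's contract
  that the estimated LF/HF tracks the requested one).
* **ECG**: stylized Gaussian-bump PQRST template with R peaks at the beat
  times; morphology claims are explicitly out of scope.
* **EEG**: per band, each channel is √(1−c²)·independent + c·shared
  band-limited Gaussian noise scaled to a dB target. Band limiting uses the
  same frequency-domain brick wall as the feature extractor. Expected MPC
  increases monotonically with c.
* **Effects** (`EffectModel`, per label unit): arousal → mean RR −15 ms,
  LF/HF +0.15, β/γ power +0.75 dB, phase coupling +0.06; valence → frontal
  α asymmetry (F4 vs F3) ±0.3 dB each; condition → +0.15 coupling in the
  virtual phase (the condition enters *only* through coupling by default).
  Effect sizes are a stated stand-in — the real ones are unknowable from the
  source material — chosen once so that strong effects are clearly
  recoverable and the zero model is provably at chance; they were not
  adjusted against test outcomes. Subject SAM ratings scatter around the
  stimulus design labels (SD 0.8) with a +0.3 offset in VR, and the
  physiology is driven by the *reported* labels, so labels and signals share
  exactly the injected structure.

What a green end-to-end test establishes: the chain recovers label-linked
structure of the kinds injected (autonomic chronotropy, spectral balance,
band power, phase coupling) from realistic-bandwidth signals, without
leaking validation information. What it does not establish: performance on
real recordings — no volume conduction, no 1/f background, no movement
artifacts beyond the simple transients used to exercise the rejection rules,
and no subject-level idiosyncrasies beyond baseline shifts.

## Numerical choices and degenerate inputs

* Tachogram span < 60 s → all spectral features undefined; < 100 beats → no
  entropies; < 130 → no α2; < 200 → no D2. Constant series → entropies,
  DFA, D2 undefined (NaN), SD = RMSSD = pNN50 = 0.
* MPC of a zero-variance (in-band) channel is NaN for its pairs, 1 on the
  diagonal. Values are clipped to [0, 1] against rounding.
* The FFT brick-wall analytic signal is exact for in-band bin-frequency
  sinusoids, which an IIR band-pass on 1-s epochs is not (edge ringing
  leaves ~10⁻³ phase ripple). Known limitation: truncating a continuous
  band-limited signal to 1-s epochs spreads energy across band edges, so
  with adjacent bands present a fully coupled band reads R ≈ 0.85–0.9
  rather than 1; monotonicity in the coupling is unaffected.
* ICA: FastICA frequently reports formal non-convergence on signals whose
  decomposition is nevertheless clean; the iteration-limit flag is logged
  (`ica_converged`) and the decomposition used, while a degenerate
  (non-finite) result passes the data through unchanged with a warning.
* LOSO folds whose training rows hold a single class are skipped and
  logged; at least 3 usable folds are required.
* All stochastic steps are seeded; a fixed seed reproduces every output
  byte-identically.

## Scaled-down test world

The default test and acceptance runs use 128 Hz sampling, museum-only
studies with 24-s windows, and ICA off, purely for runtime; the dose-response
and augmentation property tests use 2–3 seeds and coarse hyperparameter
grids. Nothing about thresholds, tolerances, or effect sizes differs from
the defaults documented above.

## Substitutions and limitations

* Signals are read and written as long-format CSV (plus events/SAM tables);
  EDF support would require a reader not available in the target
  environment.
* ICA uses FastICA rather than infomax (no infomax implementation
  available); component selection is deterministic heuristics with a manual
  override, replacing expert visual review for reproducibility.
* The 206-feature count follows the block arithmetic (26 + 36 + 144); the
  protocol text's "209" is not reconstructible from its own feature lists.
* The RFE subset-size rule (median-rank prefix maximizing pooled accuracy
  under balance) is this package's design choice; the source protocol does
  not state how its final feature counts were selected.
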