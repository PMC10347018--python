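# Methods

This note records the scientific and numerical choices behind
`pcg_lstf`: what each stage assumes, which parameters matter, what the
synthetic data does and does not emulate, and the decisions taken where
the design was genuinely open.

## Signal model and pre-processing

A phonocardiogram is modeled as a train of two fundamental heart sounds
per cardiac cycle — S1 opening systole, S2 opening diastole — embedded
in broadband noise, with possible extra acoustic activity (murmurs)
between them. Fundamental heart sounds and murmurs occupy low audio
frequencies, so recordings are resampled to the corpus convention of
2000 Hz (polyphase, anti-aliased) and low-pass filtered with a 4th-order
Butterworth at 400 Hz, applied forward–backward so that event times are
not shifted. The 400 Hz cutoff keeps the murmur band while removing most
lung/ambient noise; it is configurable (`lowpass_cutoff_hz`).

Amplitudes are not normalized at read time: the segmentation threshold
is defined relative to each recording's own envelope maximum, so the
chain is scale-invariant where it needs to be. A `normalize_amplitude`
flag (default off) enables per-recording max-abs normalization for
callers who want scale-free amplitude features too.

## Envelope and segmentation

The envelope is the normalized average Shannon energy: the signal is
scaled to unit peak, cut into 20 ms frames hopped by 10 ms, and each
frame contributes −mean(x² log x²). Shannon energy compresses large
excursions and suppresses tiny ones, which keeps the weaker S2
comparable to S1 — the standard choice for PCG envelopes. Envelope
samples are timestamped at frame centers, so peak times are accurate to
about half a hop (5 ms).

Candidate peaks are all local envelope maxima at or above 30 % of the
envelope maximum (`threshold_frac`). Extra-peak rejection then applies,
until stable:

- **minimum gap** — two peaks closer than 50 ms cannot both be heart
  sounds; the smaller is dropped (ties drop the later one);
- **cycle capacity** — a cardiac cycle spans 400–1500 ms (40–150 bpm)
  and contains exactly one S1 and one S2, so whenever three peaks fall
  inside a 400 ms span the smallest is dropped. A literal "reject the
  smaller of any pair 50–400 ms apart" rule would delete every
  legitimate S1–S2 pair (systole ≈ 300 ms), so the constraint is
  applied to triples, which preserves pairs and removes within-cycle
  clutter;
- **gap refinement** — a gap above 1500 ms implies a heart sound was
  missed below the threshold; the threshold is lowered by ×0.8 per
  iteration over that gap only (floor 5 % of the envelope maximum) and
  detection re-run there. If the floor is reached with the gap intact,
  segmentation fails for that recording; the pipeline logs and excludes
  it rather than aborting, since real corpora contain unsegmentable
  records.

The result is idempotent under re-application and guarantees all
retained peaks ≥ 50 ms apart. S1/S2 labels are then assigned by parity:
of the two alternating assignments, the one whose S1→S2 intervals have
the smaller mean is chosen (systole is shorter than diastole at these
heart rates). An exact tie takes the first peak as S1 and warns.

Fragments are contiguous non-overlapping 5 s windows from t = 0; a
trailing remainder is discarded (a sub-window fragment would bias
length-dependent features), and each fragment inherits its recording's
label.

## Features

Short-term statistics use population conventions throughout (divide by
N): population standard deviation, skewness and non-excess kurtosis
(≈ 3 for a normal signal), mean absolute deviation, and quartiles by the
(n+1)/4 rank rule with linear interpolation — deliberately not numpy's
default quantile scheme. Shannon entropy is the entropy (nats) of
pᵢ = |xᵢ|/Σ|x|, spectral entropy likewise on the normalized one-sided
power spectrum; both are scale-invariant by construction. The three
spectral-peak features (argmax frequency, its magnitude, its energy
fraction) are read off the one-sided FFT of the whole fragment.

MFCCs: 25 ms Hamming frames, 10 ms hop, 512-point periodogram
(|FFT|²/512), 26 triangular mel filters (HTK scale, edges snapped to
FFT bins), natural-log energies floored at machine epsilon, orthonormal
DCT-II, coefficients 1–13 *including* the 0th-order coefficient, and the
fragment value is the mean over frames. Whether the 0th coefficient is
included and whether coefficients are frame-averaged were open choices;
both are configurable (`n_coeffs`, frame/hop), and the defaults are the
common speech-processing ones. A constant or all-zero fragment produces
finite values via the log floor, with a warning.

Long-term features take interval statistics directly from the labeled
events — systolic mean T12 over N pairs, diastolic mean T21 over N−1
gaps, and the population standard deviations of each interval set — in
milliseconds, plus the two rejection ratios (retained/total peak count;
retained/total mean envelope amplitude). The ratios use the retained
quantities in the numerator: rejecting spurious small peaks drives the
count ratio below 1 and the amplitude ratio above 1, so both respond to
the extra acoustic activity that murmurs add.

## NCA feature weighting

Feature informativeness is scored with diagonal (per-feature) NCA:
weights wᵣ scale an L1 distance d(xᵢ,xⱼ) = Σᵣ wᵣ²|xᵢᵣ−xⱼᵣ|, and the
objective F(w) = (1/n)Σᵢ Σ_{j≠i, yⱼ=yᵢ} p_ij − λΣᵣwᵣ², with
p_ij ∝ exp(−d(xᵢ,xⱼ)), is maximized by L-BFGS from w = 1 (all features
equal). Reported weights are wᵣ² ≥ 0. The default regularization
λ = 1/n shrinks label-independent features to ≈ 0. Features are z-scored
inside the optimizer only; classifier scaling is a separate, train-split
concern. Tables beyond `nca_max_rows` (500) rows are seed-stratified
subsampled first — the optimization is O(n²d) per iteration, and weight
rankings stabilize well below that size.

Selection defaults to the mean-weight threshold. Because NCA weights are
sparse in practice (often only the dominant features stay non-zero),
the mean threshold can select *no* short-term features; the canonical
configuration for the reduced sets is therefore
`SelectionResult.top_k_short(16)`, which re-thresholds so exactly the 16
best short-term features survive — giving SSTF 16 columns and SLSTF
16 + 6 = 22 (all six long-term features are always kept in SLSTF by
definition). The pipeline uses `select_k = 16` by default.

## Classification protocol

The 22 presets map the MATLAB Machine Learning Toolbox variants onto
scikit-learn with the documented hyperparameters (fine/medium/coarse
trees = 100/20/4 splits; fine…coarse Gaussian SVM kernel scales
√P/4, √P, 4√P; fine/medium/coarse KNN k = 1/10/100; weighted KNN with
inverse-squared-distance weights; 30-learner ensembles, subspace
dimension ⌈P/2⌉). Kernel naive Bayes (per-feature Gaussian KDE) and
RUSBoost (AdaBoost.M1 on class-balanced random undersamples) have no
scikit-learn equivalent and are implemented in-package. Splits are
stratified 70/30 at the fragment level by default — the paper-faithful
protocol, which lets fragments of one recording appear on both sides;
`mode="recording"` is the leakage-safe alternative and keeps each
recording intact. On the synthetic datasets used here, a murmur-free
control with arbitrary recording labels shows fragment-mode STF accuracy
≈ 0.5, i.e. recording-fingerprint leakage does not drive the short-term
results. Features are z-scored with training-split statistics only;
constant training columns are dropped with a warning. Sensitivity,
specificity and F1 take "abnormal" as the positive class.

## Synthetic data: what it emulates, and what it does not

Each synthetic recording is a pulse train: S1 (60 Hz carrier, 60 ms
Gaussian width, unit amplitude) at each cycle start, S2 (90 Hz, 40 ms,
0.7) one systolic interval later, per-event Gaussian timing jitter, and
white noise at a stated SNR. Abnormal recordings add a systolic murmur:
150–400 Hz band-passed noise, half-cosine-gated into the systolic
intervals, at a stated RMS relative to the S1 peak. Because clinical
murmurs wax and wane with respiration and stethoscope position, the
murmur is active over a contiguous fraction of the recording
(`murmur_duty`): a 5 s fragment of an abnormal recording may contain no
murmur at all while the recording clearly does. This is the two-
timescale information asymmetry the method targets, and without it a
continuous murmur is trivially separable from every fragment and the
feature-set comparison degenerates to ties at 100 % accuracy.

Dataset-level study conditions (fixed once, used by tests and the
acceptance script): 20 s recordings; heart rate U(60, 110) bpm; systole
U(0.34, 0.40) of the cycle; jitter U(5, 10) ms; SNR U(15, 25) dB;
abnormal murmur RMS U(0.15, 0.35) of S1 peak, active over a contiguous
U(0.35, 0.65) of the recording. Segmentation-recovery checks use 50
recordings spanning 60–120 bpm at SNR 20–25 dB with 5 ms jitter; the
classifier ablation uses 200 recordings (100 per class), three split
seeds, and the five family-best presets.

What the generator does **not** model: split S2, S3/S4 sounds, clicks,
diastolic murmurs, respiration and sensor artifacts, heart-rate drift
within a recording, or the heterogeneous recording hardware of real
corpora. Passing tests therefore demonstrate the pipeline's correctness
and the direction of the two-timescale effect under controlled
conditions — not clinical-grade accuracy on real phonocardiograms,
which can only be measured on real data (`pcg-lstf
benchmark-physionet`).

## Numerical details and edge cases

- Event times are in ms from recording start; sample indices 0-based;
  windows half-open [t, t + 5 s).
- Quartiles clamp the (n+1)/4 rank into [1, n] for tiny fragments.
- Constant fragments return skewness = kurtosis = 0 with a warning
  (σ = 0 makes them undefined).
- Degenerate envelopes (all zero) and recordings shorter than one
  5 s window are reported as errors/warnings, not silently dropped.
- Resampling uses `scipy.signal.resample_poly` with the rate ratio as a
  limited-denominator fraction.
- The corpus sampling rate is taken as 2000 Hz (the figure "2000 kHz"
  sometimes quoted for this corpus is physically implausible for audio
  and inconsistent with the distributed files).
- All stochastic components (generator, splits, subsampling, ensemble
  seeds) are driven by explicit integer seeds; identical seeds give
  bit-identical recordings and reports.

## Known limitations

- The S1/S2 parity rule assumes systole < diastole, which fails at very
  high heart rates (> ~150 bpm, outside the supported cycle range).
- Rejection-rule refinement only fires when the envelope is available;
  peak lists manipulated directly (without an envelope) leave long gaps
  untouched.
- The WFDB reader supports format-16 single-signal records (the
  PhysioNet 2016 layout); other WFDB formats are rejected with a clear
  error.
- NCA weights are sparse; rank order below the leading features is not
  meaningful when their weights are ≈ 0.
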