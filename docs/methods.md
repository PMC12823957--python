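# Methods

## Model and procedure

Four linear software sensors estimate one epoch-level physiological
quantity from features of another sensor's signal.  All operate on
non-overlapping 60-s epochs.  With epoch slice x₀..x_{N−1}, the one-sided
magnitude spectrum of the unnormalized forward DFT, |X_k| for
k = 0..⌊N/2⌋, is computed without detrending, windowing or zero-padding.
Two spectral summaries are used:

* **band mean magnitude** — the arithmetic mean of |X_k| over bins whose
  center frequency k·Δf (Δf = fs/N; 1/60 Hz for 60-s epochs) lies in the
  half-open interval [low, high).  Half-open membership means a bin sitting
  exactly on a shared band edge (e.g. 0.3 Hz between the HR model's low and
  mid bands) is counted once, in the upper band.
* **mean spectral magnitude** — the mean of |X_k| over all non-DC bins
  (k ≥ 1).  The DC bin is excluded everywhere: belt units and offsets are
  arbitrary, and excluding DC makes every magnitude feature invariant to a
  constant signal offset.

The HR model regresses the epoch-average pulse on the abdominal belt's
band means in 0.07–0.3, 0.3–1.7 and 1.7–5 Hz, its RMS, and its population
skewness (m₃/m₂^{3/2}, no small-sample correction — at N ≥ 12,000 the
distinction from the corrected estimator is far below measurement noise).
The NPF and P2es models regress the nasal-flow / esophageal-pressure mean
spectral magnitude on the two belts' mean spectral magnitudes; P1es uses
the nasal and oral flow magnitudes instead.  For the flow and pressure
sensors the targets are themselves spectral magnitudes: these sensors
estimate breathing *intensity* in the frequency domain, not the waveform.

Coefficients are estimated by ordinary least squares on raw feature scales
(no standardization, no regularization), solved by QR decomposition.  Rank
deficiency raises an error naming the dependent columns rather than
silently dropping them — with at most five predictors, collinearity means
a degenerate feature table, not an over-parameterized model.  The
statistics panel is classical and homoskedastic: coefficient covariance
σ̂²(XᵀX)⁻¹ with σ̂² = SSE/(n−p), two-sided t p-values with n−p degrees of
freedom, R², adjusted R², the F test against the intercept-only model with
(p−1, n−p) degrees of freedom, and residual RMSE = √(SSE/n).  Error
degrees of freedom are always the number of valid epochs minus the number
of estimated parameters.

## Preprocessing

Epoch screening rules, with defaults in `CleaningConfig`:

* **Pulse plausibility** — any 1-s pulse sample < 40 or > 180 bpm rejects
  the epoch; so does any absolute difference > 40 bpm between consecutive
  1-s samples.  Comparisons are strict inequalities, applied to the 1 Hz
  pulse series (the pulse channel is defined as a 1-s averaged bpm series).
  A jump spanning an epoch boundary belongs to neither epoch's slice and is
  therefore not detectable by per-epoch differencing; this is documented
  behaviour.
* **Flat signal** — an epoch is rejected when the fraction of samples with
  |x| ≤ ε is at least `flat_fraction` (0.9, boundary inclusive).  ε
  defaults to 10⁻³ times the channel's median absolute deviation, making
  the rule scale-free across belt gains; an explicit ε can be supplied.
* **Esophageal pressure cleaning** — samples with |x| > 2 cmH₂O are
  replaced by linear interpolation between the nearest surviving
  neighbours (edge runs extended from the nearest survivor), followed by a
  5-sample running median (edge-replicated).  The median pass runs only
  when spikes were actually replaced, so cleaning a clean signal is the
  identity and the operation is idempotent once its output is spike-free.
  The 5-sample kernel is the shortest that removes isolated residual
  spikes without flattening breath morphology at 250 Hz.  A signal whose
  every sample exceeds the threshold is unusable and raises an error.
* **Per-epoch Pes corruption** — epochs where more than
  `pes_corrupt_fraction` (5%) of samples had to be replaced are rejected
  outright; interpolating through long spike bursts would manufacture
  data, not repair it.
* **Missing data** — NaN samples are an explicit missing-data sentinel;
  they invalidate the epoch and are never silently interpolated (the Pes
  spike repair above is the one deliberate, documented exception, and it
  leaves NaNs in place).

Epoch i covers [i·60, (i+1)·60) seconds on every channel regardless of
sampling rate; the trailing partial window is discarded.  A recording
enters fitting only when its valid epochs total at least 4 h (boundary
inclusive).  The ±2 cmH₂O spike threshold presumes a baseline-free Pes
signal whose ordinary breathing excursions stay inside the threshold; both
the threshold and the corruption fraction are configuration values.

## Evaluation

Ten-fold cross-validation partitions epochs by a seeded uniform shuffle
into near-equal folds; each fold is predicted by a model fit on the other
nine, scored by Pearson correlation and RMSE on the held-out epochs.  A
`blocked` option uses contiguous time blocks instead, to probe sensitivity
to temporal leakage; random assignment is the default.  Two scopes mirror
the two ways such sensors would be deployed: **pooled** (one
one-fits-them-all model over all subjects' epochs; fold mean ± SD
reported) and **per-subject** (each subject cross-validated and fit
individually; the cohort report averages per-subject values and also
carries each subject's full-fit n_obs, error dof, R², adjusted R², F and
p).  Subjects can be stratified by apnea-hypopnea index at the standard
clinical cut points (5/15/30 events/h).  Whether per-subject CV uses one
fixed partition or repeated partitions is a free choice; a single seeded
partition is the default and the seed is part of every report's
provenance.

## Synthetic polysomnography generator

Real overnight cohorts with esophageal catheters are rare and closed, so
the generator produces labelled recordings embodying the couplings the
sensors exploit.  All latent processes live on a 10 Hz grid and are
interpolated to each channel's rate; a single seeded generator drives
every draw, so identical configs give bit-identical recordings.

* **Respiratory drive** — instantaneous breathing frequency is a clipped
  Ornstein–Uhlenbeck process (0.25 ± 0.03 Hz, τ = 60 s) plus fast
  breath-to-breath jitter (SD 0.035 Hz, τ = 3 s); effort amplitude a(t) is
  log-normal OU (SD 0.3, τ = 120 s, clipped to [0.3, 3]).  The drive is
  r(t) = a(t)·sin φ(t) with φ the integrated instantaneous frequency.
* **Shared motion texture** — a broadband OU component (τ = 0.2 s) scaled
  by effort is added to the drive seen by the belts and the esophageal
  pressure, and its time derivative feeds the flow channels.  Physically,
  the same thoracoabdominal motion drives all three sensor families.
  Numerically it is what makes the full-band l1 magnitude feature
  well-behaved: a finite-window pure tone's mean |X_k| is dominated by
  spectral-leakage tails set by the window-edge discontinuity, which
  differs between a waveform and its quadrature-phase derivative and would
  artificially decorrelate channels that real physiology couples tightly.
  Broadband content self-averages across thousands of bins and restores
  the coupling the feature is meant to measure.
* **Channels** — AB = gain·(drive+texture) with a 2% cardiac-frequency
  ballistocardiographic component and white noise; TH likewise with a
  0.15-s lag and smaller gain.  NPF follows the drive's derivative through
  a flow gate; OPF is a 15% fraction of it.  Pes tracks −(drive+texture)
  through a slowly wandering coupling gain and a soft saturation at
  1.8 cmH₂O (catheter excursions are bounded, and ordinary breathing must
  stay below the ±2 cmH₂O spike-cleaning threshold).  Pulse is the 1-s
  average of instantaneous heart rate at 1 Hz.
* **Heart rate** — HR(t) = 65 − 4·r(t) − 5·(a(t)·gate − 1) + 0.5·z_f(t)
  bpm: within-breath respiratory sinus arrhythmia (slower while the drive
  is high) plus two slow autonomic couplings — deeper breathing lowers,
  faster breathing slightly raises, the epoch-scale rate.  The slow terms
  are what give epoch-average pulse genuine variance that spectral
  magnitude features can track; pure within-breath RSA averages to nearly
  zero over a 60-s epoch and would leave the HR sensor nothing to predict
  at the epoch level.
* **Events and artifacts** — obstructive events close the flow gate over
  2-s cosine ramps while effort is maintained (ramped to 1.2×); central
  events suppress flow and effort together.  The scheduled event count per
  hour defines the recording's AHI.  Scripted artifacts overwrite their
  intervals (FLAT → zeros; SPIKE → alternating ±5 cmH₂O excursions;
  PULSE_JUMP → a +50 bpm step), and the ground truth records exactly which
  epochs each artifact invalidates under matching cleaning thresholds, so
  screening can be scored with precision and recall.

Default noise SDs (AB/TH 0.02, NPF 0.002, OPF 0.001, PES 0.02 in channel
units, pulse 0.2 bpm) describe clean, well-attached sensors.  Because the
full-band mean magnitude integrates noise over thousands of bins, even
these levels put the broadband noise floor on the order of the respiratory
peak in the feature domain — the moderate-noise regime the defaults are
meant to represent.

`make_linear_cohort` is a separate, deliberately non-mechanistic harness:
it draws feature tables directly (log-normal magnitudes and RMS, Gaussian
skewness) and builds targets from known per-subject coefficients plus
Gaussian noise.  It isolates "is the least-squares machinery correct"
(exact recovery, SE calibration) from "can the pipeline find structure in
signals" (the mechanistic generator).

### What the generator does and does not emulate

It reproduces the couplings, sampling rates, event dissociations and
artifact classes the pipeline must handle, but not real waveform
morphology (no inspiratory/expiratory asymmetry, no body-position or
sleep-stage structure, no pink noise, no hypopneas, no real Pes waveform
shape).  Passing tests therefore demonstrate that the pipeline correctly
extracts and models the couplings when they are present — not that any
particular correlation level would be attained on clinical recordings,
where coupling strengths, artifact budgets and between-subject variability
are materially harsher.

## Numerical choices

* Unnormalized forward DFT (no 1/N), one-sided; normalization affects only
  coefficient scale, not correlations.
* Band membership uses exact comparisons on bin-center frequencies; with
  60-s epochs the band edges at 0.3 and 1.7 Hz fall on bins 18 and 102,
  which belong to the upper band.
* QR-based rank test with threshold max(n,p)·eps·max|R_jj|; an exact fit
  (SSE = 0) reports infinite t statistics with p = 0 rather than NaN.
* A constant target (SST = 0) reports R² = 0 and an undefined (NaN) F.
* Fold splitting uses a seeded `numpy` permutation and `array_split`, so
  fold sizes differ by at most one.
* EDF export quantizes to 16-bit over a declared or data-derived physical
  range; worst-case error is (max−min)/2¹⁶ per sample.  One-second data
  records require integer sampling rates and whole-second channels.
* Cohort standard deviations use the n−1 (sample) convention; a
  single-subject cohort reports NaN spread.

## Limitations

Linear models only; magnitude-domain targets for three of the four
sensors; no waveform reconstruction; per-epoch screening cannot see pulse
jumps that straddle epoch boundaries; the "abrupt transition" notion for
Pes has no numeric definition and only the amplitude rule is implemented;
the synthetic generator is a mechanistic caricature whose defaults are
chosen for internal consistency, not fit to any cohort.
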