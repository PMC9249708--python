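# Methods

This note documents the models and procedures the package implements, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions a maintainer would want
written down.

## Preprocessing

Recordings are channels × samples arrays in μV. Re-referencing follows the
contralateral-mastoid convention: scalp channels with an odd 10-20 index
are referenced to A2, even to A1; midline ("z") channels, which carry no
hemisphere, are referenced to the mean of both mastoids — an arbitrary but
inert choice, since only lateral frontal/central channels enter any
analysis. Mastoids and non-scalp channels pass through unchanged, which
makes the operation idempotent once the mastoids are zeroed.

The analysis band-pass is 0.3–35 Hz, applied as a zero-phase order-5
Butterworth (maximally flat passband; forward–backward filtering doubles
the effective order). Attenuation at 0.05 Hz and at 45 Hz exceeds 20 dB;
the tests measure this on pure tones.

Artifact rejection is deliberately coarse: a whole 30-s epoch is discarded
iff any scalp-EEG sample of its 0.5-Hz high-passed version exceeds
±200 μV. The high-pass ensures large slow waves (which legitimately reach
−120 μV and beyond) never trigger the bound. Epochs are 0-based and
half-open, `[i·30, (i+1)·30)` s; an event belongs to the epoch containing
its anchor (spindle peak, SO trough).

Sleep architecture is computed over the lights-out→lights-on window:
stage minutes = epoch counts × 0.5; sleep latency = minutes from lights
out to the first epoch of any sleep stage (NaN if none); WASO = wake
minutes after that onset; SE = 100·TST/time-in-bed. These identities are
asserted property-style on random hypnograms.

## Spectral analysis

Per artifact-free 30-s epoch the PSD uses Welch's method with 4-s Hann
windows at 50 % overlap (14 segments per epoch), no detrending; epoch PSDs
are averaged within a stage *before* band integration, so each subject
contributes one spectrum per stage. Band power integrates the linearly
interpolated PSD between band edges (trapezoid with fractional end bins).
Because that integral is exactly additive over contiguous sub-intervals,
relative powers over the five bands (SWA 0.3–1, delta 1–4, theta 4–7,
slow sigma 9–11, fast sigma 12–15 Hz) plus the explicit complement
(7–9, 11–12, 15–35 Hz) always sum to 100 % of broadband power to machine
precision — the partition identity the tests assert at 1e-6.

The relative-power denominator is total 0.3–35 Hz power (the analysis
band). This is a documented choice: "relative power" admits other
denominators (e.g. the sum of the named bands), but percent-of-broadband
yields SWA values near 60 % and sigma values near 1 % in stage-2 sleep,
the magnitudes this literature reports. It is configurable via
`total_band`.

Channel-average rows "F" (F3/F4) and "C" (C3/C4) average the member PSDs;
by linearity their band powers equal the mean of the members' band powers,
which a test verifies directly.

## Spindle detection

The sigma-band transform is a single-scale complex Morlet CWT
(PyWavelets `cmor1.0-1.0`) at the scale whose center frequency is the
middle of the 9–15 Hz band (12 Hz); its half-amplitude points fall near
the band edges, so the kernel itself defines the detection band. The
magnitude is normalized so a unit tone at the center frequency yields a
unit trace (the gain is measured once per sampling rate on a synthetic
tone, cached).

The detection trace is the 100-ms moving average of the **squared**
magnitude, and the threshold is 4× the mean of that trace over
artifact-free S2+S3 samples, per channel per night. Squaring matters: for
a narrowband Gaussian background with envelope RMS σ, the mean envelope is
≈1.25σ, so an amplitude-domain 4×-mean threshold sits at ≈5σ — precisely
the amplitude of a realistic high-SNR spindle, making detection a coin
flip. On the squared trace the threshold sits at ≈8σ² while the same burst
reaches ≈25σ², giving clean separation. This squared form is also how the
classic moving-average wavelet detectors are written. Reported
`peak_amplitude` is the square root of the trace peak (μV-equivalent
envelope units).

One event = one contiguous supra-threshold excursion with duration within
0.3–3.0 s (bounds are a package choice — without them single-sample
crossings would count as events) whose peak lies in an artifact-free
S2/S3 epoch. Raising the threshold factor can only remove excursions,
never create them, so spindle counts are non-increasing in the factor
(asserted over factors 2–6).

The "mean of the moving window" baseline is the per-channel NREM mean of
the whole night, not the local window mean: a local baseline would make
the threshold self-normalizing (every excursion ≈ its own baseline) and no
stable event definition survives. The interpretation is configurable
through `threshold_factor` and the trace function.

## Slow-oscillation detection

The SO band-pass is 0.1–4 Hz (zero-phase Butterworth order 3). The
detector scans consecutive (down, up, down) zero-crossing triples —
crossing times linearly interpolated between bracketing samples, a sample
exactly at zero counting as non-positive — and keeps a triple iff

1. the crossing pattern is down → up → down,
2. the down-state duration (first down to up) is 0.3–1.0 s,
3. the total length (down to second down) is < 10 s,
4. the down-state minimum is ≤ −80 μV,
5. the up-state maximum is < +140 μV.

A deliberately naive brute-force implementation of the same five criteria
(explicit loop over every crossing triple) serves as the oracle; the
detector must agree with it event-for-event on 100 random 2-minute
signals. Note a 0.3–1.0 s down state requires spectral content well above
0.4 Hz, which is why the band's upper edge is 4 Hz; the low edge at
0.1 Hz removes drift. Both edges are configurable.

## SO–spindle coupling

A spindle couples to an SO when its envelope peak lies within ±1.25 s of
the SO trough, same channel. The spindle's anchor is its detection-trace
peak — the detector's most robust single landmark; anchoring at spindle
onset instead would shift all offsets by roughly half a spindle duration
and is available by post-processing the event lists. Pairing is per-SO:
one spindle may appear in two pairs if two troughs fall within its window.
Coupling density divides the count of stage-matched coupled events by the
minutes spent in that stage, separately for S2 and S3 and per channel.

## Synthetic EEG

Background noise is Gaussian with a 1/f^α amplitude-shaped spectrum
(α = 1 by default, flattened below 0.1 Hz to keep total power finite),
scaled to 20 μV RMS on scalp channels and 30 % of that on mastoids.
Spindles are Gaussian-windowed sinusoids (default 13 Hz, 1 s, 25 μV); the
envelope SD is dur/4, so sigma power spans most of the nominal duration,
as it does in real spindles whose durations are measured at envelope
threshold crossings. Slow oscillations are one-cycle asymmetric waves:
a 0.5-s positive lead bump, the down lobe, a 2-s up lobe, and a shallow
4-s tail that zeroes the waveform's mean. The lead bump pins the initial
down zero-crossing at the lobe onset (zero-phase filtering otherwise
pre-rings the crossing seconds earlier), and the lobe amplitudes are
iterated until the *filtered* trough and peak equal the configured values
to ~1e-9 relative — which is what lets the boundary tests place events
exactly on or off each amplitude criterion.

Events are placed uniformly within eligible stage epochs (S2 and S3),
with a 2-s minimum separation between same-type events and event counts of
round(density × stage minutes); a configurable fraction of spindles is
instead placed at a fixed offset from an SO trough to create known coupled
pairs. Densities default to 2 spindles/min and 3 SOs/min — conventional
NREM values, chosen once; no published values constrain them here.
Identical seeds reproduce signals bit-for-bit.

What the generator does *not* emulate: EMG/EOG/ECG, arousals, stage
transitions within epochs, spatially varying topography beyond
frontal/central injection, spindle frequency drift, or any drug effect on
the EEG. Passing detector tests therefore demonstrate correctness of the
algorithms against their own definitions and robustness at realistic SNR —
not performance on clinical recordings.

## Recognition-memory model and scoring

Trials follow the task structure: per condition, an encoding list of 20
negative and 28 neutral pictures with the 8 extra neutrals as primacy/
recency buffers (serial positions 1–4 and 45–48); two recognition tests,
each with 10 old + 10 novel pictures per valence, novel pictures never
reused. Latent familiarity is equal-variance Gaussian: new ~ N(0, 1),
old ~ N(d′, 1) with the cell's true d′. A response is "present" when
familiarity exceeds the decision criterion c; confidence discretizes
familiarity at five cut-points c + δ·{2, 1, 0, −1, −2} (δ = 0.5), whose
midpoint is c itself, so collapsing 1–3 vs 4–6 reproduces the binary
decision exactly — which is why only the midpoint is consequential for
scoring.

Defaults are the study conditions: 25 subjects; per-cell true d′ between
1.84 and 2.43 with mild overnight forgetting concentrated in the
placebo/negative cell; c = 1.1, which yields hit rates near 0.8 and
false-alarm rates near 0.13 at these d′ levels; body weight ~ N(75, 12²) kg
as the covariate.

Scoring excludes buffers, computes hit = P(present | old) and
fa = P(present | new), accuracy over all scored trials, and
d′ = Φ⁻¹(hit) − Φ⁻¹(fa) with 0 → 1/(2N), 1 → 1 − 1/(2N) correction
(configurable; with only 10 targets per cell, perfect rates are common and
must be handled). The correction introduces a small positive bias at high
d′ (≈ +0.06 averaged over the default cells, < 0.1, verified by
simulation); group-mean d′ therefore does not equal the d′ of group-mean
rates. Outlier handling (drop scores beyond ±2.5 SD of the cell mean) is
applied at the group-analysis stage via `exclude_outliers`, not at
scoring.

## Inference

All within factors are 2-level, so every ANOVA effect has one numerator
df and sphericity is moot. Each within effect is tested on its
per-subject contrast (product-coded cell means); with the mean-centered
covariate the contrast is regressed on [1, w]: the intercept F(1, n−2)
tests the effect, the slope F its covariate interaction, and the
between-subject covariate effect is the slope test on subject means. With
no covariate (or a constant one) this reduces exactly to the standard
univariate RM-ANOVA, and the tests verify F and p agree with
statsmodels' AnovaRM to 1e-8 on random data and with an explicit
sums-of-squares decomposition on a 4-subject example. Subjects with any
missing cell are removed listwise and the per-analysis n is reported with
every effect.

Paired t-tests are two-sided with df = n−1; zero-variance differences are
flagged degenerate rather than erroring. Holm–Bonferroni is the standard
step-down: reject the i-th smallest p iff every p(j), j ≤ i, satisfies
p(j) ≤ α/(m−j); equivalence with a brute-force prefix implementation and
with statsmodels is asserted on 1000 random vectors. Correlation screens
compute Pearson r per (sleep feature, memory variable) pair separately per
condition, flagged significant against the supplied corrected alpha
(0.0025 for the spectral screen, 0.004 for the event screen); constant
vectors or n < 3 are flagged invalid rather than scored. The a-priori
directional sigma hypothesis is reported two-sided like everything else;
a one-sided reading halves the p-value and is left to the reader.

Calibration is checked by simulation at the study size: under a null
cohort (all cells d′ = 2.0, no effects), the drug × test × emotion
interaction rejects at the nominal 5 % (±2 % over 500 replicates), and an
injected three-way interaction of 0.6 between-subject SDs of the null
contrast is detected in a clear majority of replicates (~78 % observed,
consistent with the ~0.8 theoretical power of a 1-df test at n = 25).

## Pipeline and reproducibility

Stages are file-based (EDF, CSV, JSON) so each can be re-run from the CLI.
The manifest records package versions, the master seed, a SHA-256 of the
resolved configuration and of every output; per-record seeds derive from
(master seed, subject, condition) via `numpy.random.SeedSequence`, so runs
are byte-identical under a fixed seed and robust to reordering. `run-all`
skips work when an existing manifest's configuration hash and output
hashes all match (`--force` overrides); the cache key is the whole run,
not per-stage input hashes — simpler, and detection (the only expensive
stage) is cheap at the default problem sizes.

Default problem sizes — 30-minute recordings at 256 Hz, 6 EEG subjects,
25 behavioral subjects, 500-replicate calibration studies — are desk-scale
choices that keep a full validation run under a minute while leaving every
statistical check adequately powered; all are configurable upward (the
EDF writer and detectors handle 1000 Hz recordings unchanged).

## Known limitations

- The EDF writer emits a minimal but standard-compliant subset (1-s
  records, 16-bit, per-channel symmetric physical ranges); annotations and
  EDF+ discontinuous records are out of scope.
- Spindle detection reports envelope-domain amplitudes, not raw-signal
  peak-to-peak; slow/fast spindle classes are separated spectrally (slow
  vs fast sigma bands), not by the event detector.
- Coupling is coincidence-based; preferred-phase/circular statistics are
  not computed.
- The artifact mask cannot reproduce manual artifact scoring; it is a
  deterministic amplitude rule.
- With 10 targets/foils per cell, d′ is quantized and ceiling-corrected;
  comparisons across packages must use the same extreme-rate correction.
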