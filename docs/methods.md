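# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the places where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Session representation

A session is a continuous 16-channel recording (10-20 montage, right-ear
reference, 256 Hz, microvolts) plus a scored trial table. Sample indices are
0-based; all epochs are half-open `[start, end)` in samples. Each trial
shows one photograph for 10 s with a 1-5 s inter-trial gap; the response is
scored into ten categories (keypad values 0-9 assigned in schema row order,
since the source never lists them): no response, correct, and
fragment / semantic / phonological-neologistic errors each in plain and
self-corrected form, plus circumlocution and perseveration. A trial has a
response onset exactly when its category is not "no response", and the
onset must fall inside the 10-s display window.

On disk a session is an EDF file plus a TSV event table. The 16 channel
labels are a package choice (F7 F3 Fz F4 F8 T3 C3 Cz C4 T4 T5 P3 Pz P4 T6
Oz): the original recordings used 16 unspecified 10-20 sites, and this
symmetric grid covers the nine channels the analysis requires. EDF is
written by a minimal writer in this package (one-second records, per-channel
16-bit scaling) and read back through `mne`, which acts as an independent
check on the files; signals round-trip to within one quantization step,
events exactly. The exact sample count is stored in a TSV header comment so
EDF's whole-second padding can be trimmed.

## Spectral features

Per channel and trial, the epoch runs from stimulus onset up to (but not
including) the response onset; no-response trials use the full 10-s display
window, since "just before the response" is undefined for them. Windows of
1000 ms (256 samples), stepped 62.5 ms (16 samples), are anchored at the
epoch start; only fully contained windows are analyzed, so a 10-s epoch
yields `floor((2560-256)/16)+1 = 145` windows and an epoch under 1 s yields
none (the trial is excluded and logged — response latencies under one
second do occur in the generator, which mirrors the unexplained small
trial-count deficits in the published degrees of freedom).

Each window is demeaned (no detrending, no filtering) and fit with a
40th-order AR model by Burg's method. Burg was chosen because its
reflection coefficients are guaranteed inside (-1, 1) — every fitted model
is stable — and because Yule-Walker estimates of order 40 are badly biased
on 256-sample windows. The recursion is implemented batched over windows
(one vectorized pass fits all windows of a trial across channels), which is
what makes 900-trial participants tractable. A constant window yields a
flagged degenerate model with an identically zero spectrum.

"Amplitude" is defined as the square root of the AR power spectrum
`sigma^2 / fs / |1 - sum_k a_k e^(-2 pi i f k / fs)|^2`, averaged over an
inclusive 0.25-Hz grid inside each band (6-9, 10-13, 14-17, 18-21, 22-25,
26-29 Hz). The source says only "amplitudes"; this convention is fixed here
and verified against Welch-periodogram amplitudes on long stationary
simulations. The feature vector of a trial is the per-(channel, band) mean
over its windows; columns are ordered channel-major (`Fz_6-9 ... Pz_26-29`),
18 columns for the Fz/Cz/Pz set and 54 for the 9-channel set.

## Elastic net

The objective is used literally as printed in the source —
`||y - X b||^2 + lam2 ||b||^2 + lam1 ||b||_1` with no 1/(2n) factor — on
standardized columns (population SD) and centered y. Cyclic coordinate
descent uses the update `b_j <- S(x_j' r_j, lam1/2) / (x_j' x_j + lam2)`,
tolerance 1e-7 on the largest coefficient change, at most 10,000 sweeps,
with warm starts down each penalty ladder. The solution is identically zero
once `lam1 >= 2 max|X'y|`. Coefficients are reported on the original
feature scale with a matching intercept, zero-variance columns are dropped
before standardization and restored as zeros afterward, and a debug mode
asserts the objective never increases across sweeps. The mapping to the
common per-observation parameterization,
`alpha * l1_ratio = lam1 / (2n)` and `alpha * (1 - l1_ratio) = lam2 / n`,
is used only to cross-check against scikit-learn in tests.

Penalty selection: 10-fold cross-validation of the training set, stratified
by outcome (sorted outcomes dealt into folds in shuffled blocks), over a
grid of 10 mixing ratios (0.1 to 1.0) times a 50-point lam1 ladder
log-spaced from the kill threshold down four decades, with
`lam2 = lam1 (1-m)/m`. The source names neither fold count nor grid; these
are package choices. The chosen cell minimizes mean held-out squared error;
ties within 1e-12 resolve to the largest lam1 then largest lam2 (sparsest,
then smoothest). A known consequence of minimum-CV selection is that under
pure noise a minority of runs still admits a moderate number of features;
a one-standard-error rule would be more conservative but is not what the
protocol describes.

## Experiment driver

Accuracy coding is binary and total (correct first attempt = 1). Error
correction is ordinal 0/1/2 (uncorrected error / self-corrected / correct)
and drops no-response, circumlocution and perseveration trials from both
fitting and evaluation; the source is explicit only about the model, and
symmetry is assumed for evaluation. Since evaluation is a Pearson
correlation, any increasing affine recoding of equally spaced codes gives
the identical r; unequal spacings would not, and the original coding is
unstated — this is flagged rather than resolved.

Sessions 1-2 train, session 3 tests. Evaluation reports r, the df pair
(k, n-k-1) with k the number of selected features, and a two-sided p from
`t = r sqrt(df/(1-r^2))`. The reported training r is in-sample and labeled
as such (whether the published training correlations were in-sample is
unstated). Significance stars (* .05, ** .01, *** .001, **** .0001) are a
reporting convention of this package; the source uses up to four stars
without defining them. No multiple-testing correction is applied across
participants or modes, mirroring the protocol.

Topographies are point-biserial Pearson correlations between single-trial
band amplitude and the binary accuracy coding for every (channel, band)
cell, positive when amplitude is higher on correct trials; constant feature
columns are recorded as r = 0 and flagged.

The published per-participant three-channel coefficient sets are embedded
(`published_models`) so the package can apply them; their "8 Hz / 12 Hz /
..." feature labels are mapped onto the 6-9 / 10-13 / ... bands in
ascending positional order, which the source never states explicitly. Some
printed coefficient counts disagree with the printed df numerators, and
some df denominators imply undocumented trial exclusions; both are stored
as printed and treated as caveats, not reproduced.

## Behavioral statistics

Tabulation reports per-category counts and percentages per session and
overall; headline accuracy counts only first-attempt correct responses
(no-response and self-corrections count as incorrect). The one-way
within-subject ANOVA uses the standard decomposition
(SS_subjects + SS_conditions + SS_error), F on (c-1, (c-1)(s-1)) df;
Mauchly's W is computed on an orthonormal contrast basis with the usual
chi-square approximation, and the Greenhouse-Geisser epsilon
(`tr(S)^2 / ((c-1) tr(S^2))`, clamped to [1/(c-1), 1]) deflates both df
when sphericity is rejected at alpha = 0.05 — the same reporting pattern
the source follows. The published ANOVAs operate on per-session counts that
were never released, so exact reproduction of their F values is impossible
and not claimed; the module is validated against pingouin on random
instances instead.

## Synthetic data generator

Defaults are the study conditions: 3 sessions x 300 trials (900 per
participant), 256 Hz, 10-s displays, inter-trial gaps uniform on (1 s, 5 s]
(the protocol states only the 5-s maximum; 1 s is a package choice), 2-s
pre/post rolls.

Background EEG per channel is an AR(2) resonance (default peak 10 Hz,
bandwidth 4 Hz, RMS 10 uV) plus a white noise floor (5 uV) — a stationary
alpha-like spectrum, chosen so the analysis bands sit on a realistic 1/f-ish
slope with an alpha peak. Each trial draws a latent state
`s_t ~ N(0, 1)`; at each of the signature's effect (channel, band) cells,
band-limited Gaussian noise (4th-order Butterworth bandpass) is added over
the 10-s display epoch with RMS `effect_rms * w * (1 + g * s_t)` (floored
at zero), keeping the planted mechanism strictly inside the analysis bands
with a controllable effect size. The same state drives behavior:
`P(correct) = logistic(a + b * sum(w) * s_t)`. Incorrect trials draw from a
six-way error mixture (no response, fragment, semantic, circumlocution,
phonological-neologistic, perseveration); fragment/semantic/phonological
draws are promoted to their self-corrected categories with per-family
probabilities. Mixtures and baseline accuracy can be instantiated from the
study's published per-participant response-frequency rows, so synthetic
cohorts reproduce the study's behavioral heterogeneity (the default profile
is the mean row, baseline accuracy about 61%).

Response latency is lognormal (median 2.5 s, log-sd 0.5) truncated to
(0.25 s, 10 s]; the study reports no latencies, so this is an invention of
the package. One RNG stream per session, seeded by (config seed, session
index), makes event tables and signals byte-reproducible.

What the generator does *not* emulate: evoked-response morphology, eye/EMG
artifacts, non-stationary drift, volume-conduction correlations between
channels, and any claim about which EEG pattern actually distinguishes
correct from error trials in aphasia (the study shows it varies per
person). Passing tests therefore demonstrate that the pipeline recovers the
kind of band-amplitude/behavior linkage it assumes, not that such linkage
takes this form in real patients.

## Benchmark conditions and problem sizes

The detectability benchmarks (`eegnaming.benchmarks`) use one strong
planted cell (weight 1, link slope 2, amplitude gain 0.6, effect RMS 6 uV)
drawn per run from the midline channels and six bands — the "clearly
detectable" regime those checks are about — and null runs with all weights
zero. Benchmark cohorts run 100-trial sessions rather than 300: the
quantities of interest are hit *rates* over 20-50 independent participants,
and the planted effects are strong enough that each run remains
comfortably powered at that size; the generator's defaults are unchanged.

## Known limitations

- The EDF writer covers only this package's needs (uniform rate,
  one-second records); it is not a general EDF library.
- Whether the original epochs ended at scored response time or voice onset
  is unstated; the event table's response onset is taken as the epoch end,
  and windows overlapping the response are dropped rather than truncated.
- Minimum-CV penalty selection occasionally keeps moderate-size models on
  pure noise (see above).
- The error-correction coding's 0/1/2 spacing is immaterial for Pearson
  evaluation only up to affine transforms; a different monotone spacing
  would change r.
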