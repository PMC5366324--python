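# eegnaming

Single-trial EEG prediction of picture-naming accuracy and error
self-correction in aphasia.

## The problem

People with aphasia make frequent and heterogeneous errors when naming
pictured objects. Two competing therapy philosophies exist: *errorless
learning* (prevent errors with maximal cueing) and *retrieval practice*
(force effortful naming attempts, errors included). If an upcoming error
could be predicted from the client's brain state before the naming attempt,
a clinician could switch to errorless support only when needed and keep the
long-term benefits of retrieval practice otherwise.

This package implements, as a tested offline pipeline, the analysis behind
that idea: within-participant statistical models that predict single-trial
naming outcomes from EEG spectral features, trained on two sessions and
evaluated on a held-out third. Because no patient EEG was deposited with the
original study, a first-class synthetic-data module emulates the study
design (3 sessions x 300 trials, 16-channel 10-20 montage at 256 Hz, 10-s
stimulus displays, ten-way response scoring) with a controllable link
between band amplitudes and behavior, so every stage is verifiable end to
end.

## The method

For each trial, each channel's signal between stimulus onset and the moment
just before the response is cut into 1000-ms windows stepped every 62.5 ms.
Each window is fit with a 40th-order autoregressive model by Burg's method,
and the model's amplitude spectrum is averaged inside six 4-Hz bands
(6–9, 10–13, 14–17, 18–21, 22–25, 26–29 Hz). Averaging over windows gives
one feature per (channel, band): 18 features for the midline Fz/Cz/Pz
analysis, 54 for the 9-channel variant.

Outcomes are regressed on these features with an elastic net,

    beta = argmin ||y − X beta||² + λ₂||beta||² + λ₁||beta||₁ ,

with both penalties chosen simultaneously by embedded cross-validation of
the training set (sessions 1–2). Generalization is the Pearson correlation
r between predicted and observed outcomes in session 3, with a t-based
p-value on n − k − 1 degrees of freedom (k = number of selected features).
Two outcome codings are supported: binary accuracy (correct on first
attempt vs. everything else) and a three-level error-correction coding
(correct / self-corrected / uncorrected error, with no-response,
circumlocution and perseveration trials excluded). Channel-by-band
correlation topographies and the behavioral analyses (response-type
tabulation; repeated-measures ANOVA across sessions with Mauchly's
sphericity test and Greenhouse–Geisser correction) round out the pipeline.

## Worked example

```sh
eegnaming run-all --out-dir runs/demo --participant demo \
    --channels 9 --mode accuracy --seed 7 --trials 100
```

simulates a participant whose accuracy is linked to band amplitudes at
three (channel, band) cells (for seed 7: P3 6–9 Hz, P4 10–13 Hz,
C4 18–21 Hz) and prints:

```
participant demo  mode=accuracy  channels=9
penalties: lam1=19.3868 lam2=0  selected k=10

feature            coefficient
F3_14-17           +0.0432
F3_26-29           +0.0520
Fz_18-21           -0.3961
F4_6-9             +0.0164
F4_26-29           -0.0291
C4_10-13           +0.0017
C4_26-29           +1.0016
Pz_26-29           +0.0250
P4_14-17           +0.0297
P4_26-29           +0.3988
intercept          +0.0037
train: r=0.5338****  df=10/182  p=6.044e-15  n=193
test: r=0.5130****  df=10/88  p=2.343e-07  n=99
```

Read it like the study's reporting: the elastic net kept 10 of 54 features
(k = 10), the in-sample training correlation is 0.53, and the model
generalized to the held-out third session with r = 0.51 (p ≈ 2e-7 on 88
residual df) — a participant whose naming accuracy is genuinely predictable
from pre-response EEG. (A few of the 2 x 100 training and 100 test trials are
missing because responses faster than one second leave no complete
analysis window.) Null participants (simulate with `--null`) instead give empty
models and test correlations centered on zero.

The same steps are available separately (`simulate`, `extract-features`,
`fit`, `evaluate`, `topomap`) and as library calls; see
`eegnaming.prediction_pipeline.run_experiment`.

## Layout

- `eegnaming.session_model` — domain types, ten-category scoring schema, EDF+TSV session I/O
- `eegnaming.synthetic_data` — study-design generator, stimulus filtering/partition
- `eegnaming.spectral_features` — Burg AR spectra, band amplitudes, sliding windows, feature tables
- `eegnaming.elastic_net` — coordinate-descent solver, embedded CV over both penalties
- `eegnaming.prediction_pipeline` — outcome coding, session split, evaluation, topographies
- `eegnaming.behavioral_stats` — tabulation, repeated-measures ANOVA (Mauchly, Greenhouse–Geisser)
- `eegnaming.published_models` — the published per-participant coefficient sets and correlations
- `eegnaming.benchmarks` — planted-effect recovery and null-calibration cohort runs

See `docs/methods.md` for the modeling assumptions, parameter choices and
known limitations.
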