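# rhythmeg

Syllabic-rhythm periodicity, theta-band auditory–motor coupling, and speech
comprehension — as a tested, reusable analysis pipeline on synthetic data
with known ground truth.

## Who this is for

Auditory/speech neuroscientists who want to quantify how regular the
syllable timing of a sentence is, estimate phase coupling between auditory
(pSTG) and speech-motor (iPCG, IFG, SMA) source time series, and relate both
to single-trial comprehension — without committing to any particular MEG
preprocessing stack. Parcel time series are taken as input; everything
upstream (beamforming, atlases, artifact rejection) is out of scope.

## What it computes

**Periodicity.** For each sentence, the median absolute deviation (MAD) of
the inter-syllable-nuclei intervals,
`MAD = c · median(|d − median(d)|)` (scale `c = 1.4826` by default); and the
**residual MAD** — MAD with its within-rate-condition linear dependence on
the empirical syllabic rate regressed out — as a rate-decorrelated
periodicity measure (larger = less periodic). Nuclei come from CSV, Praat
TextGrid point tiers, or a simple intensity-peak detector on a WAV envelope.

**Coupling.** Gaussian-copula mutual information (GCMI) between two regions'
band-limited phases: per trial, each region's voxel series is reduced to its
top 3 principal components, band-passed (4–8 Hz in 1 Hz steps, 2 Hz
bandwidth), Hilbert-transformed and unit-normalised; MI is computed from the
copula-normalised (cos, sin) pairs,

    I(X;Y) = 1/2 · log2 [ det Σx · det Σy / det Σxy ]   (bits, bias-corrected)

with motor-to-auditory delays scanned over 0–300 ms (headline value at
50 ms). The observed GCMI is standardised against N = 500 segment-shuffle
surrogates (segments = 80% of the syllabic cycle of the trial's rate
condition; 160.0 ms at 5 Syl/s, 72.72 ms at 11 Syl/s):

    z = (GCMI_obs − mean(GCMI_surr)) / sd(GCMI_surr),

and averaged over 4–8 Hz at the extraction delay (`theta_mean_z`).

**Comprehension.** Verbal-recall accuracy as the Ratcliff–Obershelp
word-overlap ratio `2M/T` between reference and response token lists.

**Modelling.** Beta regression (logit mean link, constant precision φ) for
scores and min-max-normalised coupling, with boundary adjustment
±(median/n), orthogonal polynomial rate terms up to degree 3, cluster
bootstrap over subjects for clustered uncertainty, simple-slope contrasts,
and Benjamini–Hochberg FDR. `BetaRegression` is a scikit-learn compatible
estimator.

A synthetic-data module generates syllable trains with controllable interval
jitter, two-region 100 Hz signals with 1/f background plus a theta component
coupled at a known lag and strength, and beta-distributed comprehension
scores from a logit-linear model — so every stage is testable against ground
truth. See `docs/methods.md` for models, defaults and limitations.

## Worked example

```python
import numpy as np
from rhythmeg import (CoupledSignalSpec, PipelineConfig, SyllableTrainSpec,
                      gen_coupled_trial, gen_syllable_train, intervals, mad,
                      run_trial_coupling, sequence_similarity, tokenize)

# periodicity of a jittered 11 Syl/s syllable train
train = gen_syllable_train(SyllableTrainSpec(rate=11, jitter_sd=0.02,
                                             n_syllables=25, seed=1))
print(f"MAD = {mad(intervals(train)) * 1000:.1f} ms")

# theta coupling of one synthetic 10-s trial, coupled at 50 ms lag
trial = gen_coupled_trial(CoupledSignalSpec(coupling_strength=0.9, lag=0.05,
                                            duration=10.0, seed=1))
cfg = PipelineConfig(n_surrogates=200, seed=0)
res = run_trial_coupling(trial, 11.0, cfg)
print(f"theta_mean_z = {res.theta_mean_z:.2f}")
print(f"peak delay = {res.delays_ms[np.argmax(res.gcmi.mean(axis=0))]:.0f} ms")

# word-overlap comprehension score
ref, resp = tokenize("Der Hund lief schnell weg."), tokenize("der Hund lief weg")
print(f"overlap = {sequence_similarity(ref, resp):.3f}")
```

prints

```
MAD = 12.7 ms
theta_mean_z = 5.81
peak delay = 50 ms
overlap = 0.889
```

The train's intervals scatter around 91 ms (11 Syl/s), and the scaled MAD of
this particular 24-interval draw lands at 12.7 ms. The coupled trial's theta
z-GCMI sits ~6 null standard deviations above its segment-shuffle
surrogates, and the delay-resolved GCMI peaks at the injected 50 ms lag. The
recall missed one of the five reference words: 2·4/(5+4) ≈ 0.889.

A command-line front end exposes the same pipeline
(`rhythmeg simulate`, `rhythmeg coupling run`, `rhythmeg coupling join`,
`rhythmeg score`).

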