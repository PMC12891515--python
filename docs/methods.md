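# Methods

This note documents the models, estimators and design choices behind
`rhythmeg`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, with which
defaults, and what the synthetic validation does and does not establish.

## Scientific setting

Speech carries a quasi-periodic rhythm at the syllabic time scale
(roughly 4–8 syllables per second in comfortable speech, the same range as
cortical theta oscillations). The analysis implemented here links three
quantities per sentence/trial:

1. **Syllabic periodicity** — how regular the syllable timing is;
2. **Theta-band auditory–motor coupling** — statistical dependence between
   band-limited phase in auditory association cortex (pSTG) and speech-motor
   regions (iPCG, IFG, SMA), measured as Gaussian-copula mutual information
   (GCMI) standardised against segment-shuffle surrogates;
3. **Comprehension** — word-overlap accuracy of verbal recall, modelled with
   beta regression on rate, periodicity and their interaction.

The package ships its own synthetic-data generators so the entire chain can
be validated against known ground truth without any external recordings.

## Periodicity: MAD and residual MAD

For a sentence with syllable-nuclei times `t_1 < ... < t_k`, the intervals
are `d_i = t_{i+1} - t_i` and periodicity is quantified as the median
absolute deviation,

    MAD = c * median(|d - median(d)|),

with scale constant `c = 1.4826` by default (the Gaussian-consistency
constant used by default in mainstream statistical environments; `c = 1`
is available since the convention is not universal). Larger MAD = less
periodic.

MAD is naturally confounded with syllabic rate (faster speech has shorter,
less variable intervals). The decorrelated measure, **residual MAD**,
regresses MAD on the empirical per-sentence rate (nuclei per second of
spanned time) by OLS *within each rate condition* and keeps the residuals.
The regressor is the empirical rate rather than the condition label: the
label is constant within a group, which would reduce the regression to
demeaning (that fallback is available as `mode="demean"`). Residuals have
exactly zero mean and zero rate-correlation per group; on synthetic cohorts
with rate-dependent jitter the pooled |corr(periodicity, rate)| drops
relative to raw MAD, which is the point of the construction.

Nuclei can be supplied from CSV or a Praat TextGrid point tier, or detected
from an amplitude envelope with a deliberately simple intensity-peak
detector (30 ms smoothing, 2 dB prominence, 40 ms refractory interval). This
detector is a stand-in for full voicedness-based syllable-nuclei scripts; on
rendered envelopes with 20 dB SNR it recovers ≥ 95% of true nuclei within
20 ms, which is sufficient for interval statistics at rates up to ~20 Syl/s.

## Comprehension scoring

Responses are scored against references with the Ratcliff–Obershelp ratio on
word tokens: recursively find the longest common contiguous block (ties
broken by earliest start in the reference, then in the response), recurse on
both flanks, and report `2M/T` (`M` matched tokens, `T` total tokens). No
junk/autojunk heuristics are applied — sentences are short and heuristics
silently change scores. Tokenisation lowercases, strips punctuation and
splits on whitespace; these normalisation choices are declared defaults, not
claims about any particular transcription pipeline. The implementation
matches the stdlib `difflib.SequenceMatcher` ratio exactly on random token
lists and never exceeds the `2·LCS/T` dynamic-programming bound.

## GCMI coupling estimator

**Copula step.** Each column is rank-transformed (stable ties: earlier
sample → lower rank) and mapped through `Φ⁻¹((r+1)/(n+1))`. This makes the
estimator exactly invariant to strictly monotone marginal transforms, at the
cost of estimating a lower bound to the true MI.

**Gaussian MI.** On the normal scores,
`I = ½ log2[det Σx · det Σy / det Σxy]`. With bias correction the analytic
digamma-based small-sample bias of the three Gaussian entropy estimates is
subtracted; the corrected estimate can go slightly negative (within the bias
term's magnitude), the uncorrected one is non-negative. Covariance blocks
are checked for rank deficiency via their eigenvalues (relative tolerance
1e-12) and the offending block is named in the error.

**Spectral front end.** Per region, voxel series are reduced to the top 3
principal components per trial (≈ 90% of variance on data of this kind),
then band-passed with a 4th-order zero-phase Butterworth filter (centre
frequencies 4–8 Hz in 1 Hz steps, 2 Hz bandwidth) and Hilbert-transformed.
The default representation is phase-only: per-sample unit-normalised
(cos, sin) pairs, giving 6 dimensions per region. An amplitude-retaining
mode is available (`phase_only=False`); whether the original analyses used
phase-only or complex inputs is not determinable, so both are provided.
200 ms at each epoch edge are excluded from estimation (filter transients).

**Delay scan.** The motor series is shifted against the auditory series by
0–300 ms in 10 ms steps (integer samples at 100 Hz); the overhang is
truncated, never wrapped — circular wrapping creates a seam that biases MI.
All delays use the same effective sample count (truncated to the largest
delay) so values are comparable across the grid. The headline value is
extracted at 50 ms.

**Surrogate normalisation.** The null distribution is built by cutting the
motor region's *raw component series* into contiguous segments of 80% of
the syllabic cycle of the trial's rate condition (160.0 ms at 5 Syl/s,
72.72 ms at 11 Syl/s), permuting the segments uniformly (N = 500 by
default), and re-running the identical filter → Hilbert → copula → MI path
on each permuted copy. Shuffling *before* filtering matters: permuting
band-limited phases directly truncates the surrogate autocorrelation
relative to the observed series and overdisperses the z statistic (~8.5%
tail rate beyond |1.96| instead of 5% in pilot simulations); refiltering
after the shuffle restores the autocorrelation structure and calibrates the
null (sd(z) ≈ 0.99, 5.3% tail rate). Observed and surrogate estimates use
the identical sample window, so the estimator's small-sample bias cancels in

    z = (GCMI_observed − mean(GCMI_surrogate)) / sd(GCMI_surrogate).

The sign convention is such that stronger-than-chance coupling gives larger
z (the convention under which normalised coupling is positive and increases
with coupling strength). Only the motor region is shuffled by default —
one-sided shuffling suffices to destroy cross-regional dependence — with a
symmetric mode behind `shuffle_both`. The surrogate mean/sd are estimated at
the extraction delay and applied to the whole delay row (the null does not
depend on the delay; a per-delay surrogate ensemble would multiply cost by
the grid size). Surrogate RNG streams are derived per
(seed, subject, trial, ROI pair, hemisphere, frequency), so results are
bit-reproducible and independent of execution order. The theta summary
`theta_mean_z` averages z over 4–8 Hz at the extraction delay. Trials too
short to hold two segments at their rate's segment length are skipped with a
logged reason, never padded.

## Statistical models

Bounded responses are modelled with a beta likelihood,
`y ~ Beta(μφ, (1−μ)φ)`, `logit(μ) = x'β`, constant precision `φ`. Boundary
values are moved into the open interval by `ε = median(y)/n` (full-vector
median by default; a per-group flag exists because the original rule's
grouping is ambiguous). Coupling values are min-max normalised onto [0, 1]
before beta modelling (globally by default; per-participant behind a flag).
Rate can enter as an orthonormal polynomial basis of degree ≤ 3.

The likelihood is maximised through the beta-regression machinery of
statsmodels (logit mean link, log-precision parameterisation, quasi-Newton
optimisation) wrapped in a scikit-learn style estimator (`BetaRegression`)
exposing coefficients, SEs, covariance, log-likelihood, convergence flag,
and two pseudo-R² variants (squared correlation of logit(y) with logit(μ̂),
and a likelihood-ratio R²). Neither pseudo-R² is comparable to marginal/
conditional R² of a mixed model.

**No random effects are estimated.** Crossed-random-effect beta GLMMs need
Laplace/AGQ machinery out of proportion to this artifact, and on the logit
scale random intercepts change the interpretation of coefficients
(conditional vs marginal). The supported inference path for clustered data
is fixed-effects ML plus a cluster bootstrap over subjects (resample
clusters with replacement, refit, report SD and percentile CIs). Recovery
simulations therefore default to zero subject heterogeneity; with
heterogeneity the bootstrap SEs correctly exceed the naive model SEs, and
fixed-effect estimates are attenuated relative to conditional GLMM
coefficients. Post-hoc trend comparisons are linear-combination contrasts of
fitted coefficients (simple slopes at chosen moderator levels) with
bootstrap CIs; no estimated-marginal-means reference-grid machinery is
provided. Multiple comparisons use Benjamini–Hochberg FDR.

## Synthetic generators: what they emulate

**Syllable trains.** Intervals are `1/rate` plus Gaussian jitter truncated
so each interval stays above 10% of the nominal interval (keeping times
strictly increasing at high jitter). The five rate conditions are 5, 11, 14,
16, 17.5 Syl/s. Real speech adds structure the generator omits: pauses,
word- and phrase-level prosody, correlated interval sequences.

**Coupled neural trials.** Two regions × 6 channels at 100 Hz. Each channel
is independent 1/f^α background (α = 1 by default, synthesised by spectral
amplitude shaping for exact exponent control) plus a shared region-level
theta component: band-limited Gaussian noise centred on 6 Hz (bandwidth
5 Hz). The motor region's theta component is the auditory region's delayed
by the coupling lag and scaled by the coupling strength, mixed with
independent narrow-band noise to keep unit variance. Coupling is injected
only in the theta band (a broadband mode exists behind a flag) — this
isolates the band the analysis targets. Not emulated: cross-frequency
structure, nonstationarity, sensor noise topographies, volume conduction.

**Comprehension scores.** Beta-distributed with a logit-linear mean in
centred rate, residual MAD and their interaction. The default generating
coefficients take the reported effect directions and magnitudes
(−0.16 per Syl/s for rate, +3.41 per second of residual MAD, −0.21 for the
interaction, on the logit scale) with an intercept of 0.9 on centred rate
(mean accuracy ≈ 0.85 at 5 Syl/s falling to ≈ 0.5 at 17.5 Syl/s) and
precision φ = 20, typical of single-trial accuracy data. Optional Gaussian
subject intercepts add cohort heterogeneity.

**Cohorts.** The desk-scale cohort uses 12 subjects × 300 sentences
(mirroring the 300-sentence session structure) with jitter SD drawn
uniformly from 5–60 ms independent of rate — chosen for coverage of the
periodicity range, since the empirical per-condition MAD distributions are
only available graphically. Ground-truth coupling strength increases
affinely in rate and jitter (clipped to [0.15, 0.9]), matching the reported
directions (stronger coupling at faster rates and lower periodicity). The
neural arm of the sign-structure study uses 160 trials per replicate with 60
surrogates and a {0, 50} ms delay grid: the z statistic there only needs the
extraction delay, and the study sizes keep a 20-replicate end-to-end run in
a few CPU-minutes while retaining adequate power for the four scored effect
directions (rate and residual MAD on comprehension; rate and residual MAD on
theta z-GCMI). The rate×MAD interaction is an order of magnitude weaker on
the logit scale (per-replicate sign-recovery probability only ≈ 0.9 at 3600
trials); its recovery is validated in a separate behavioral-only study at
the full 57-subject × 300-sentence size, where the fit is cheap and the
interaction well powered (t ≈ 3.9).

## Validation studies and their problem sizes

The `studies` module (used by both the test suite and
`scripts/acceptance.py`) runs:

- Gaussian closed form: 50 000 samples, r = 0.1…0.9; max error < 0.01 bits.
- Copula invariance: exact equality under monotone marginal transforms.
- Surrogate-z calibration: 200 uncoupled 4-s trials, 200 surrogates each,
  cycling all five rate conditions; |mean z| < 0.15 and 3–7% beyond |1.96|.
- Lag recovery: 50 trials at coupling 0.9, lag 50 ms, 10-s epochs (phase
  series carry roughly bandwidth-many effective samples per second, so
  per-trial delay localisation needs the longer window); argmax of the
  theta-averaged delay profile within ±10 ms in ≥ 90% of trials.
- Beta recovery: n = 3000, φ = 30, coefficients within 3 SEs; 300 null
  replicates at n = 600 with Wald type-I rate in 3–7%.
- Sign structure: 20 end-to-end cohort replicates; ≥ 90% must recover the
  four scored effect directions. The interaction-inclusive three-sign
  behavioral recovery runs at the 57 × 300 cohort size (20 replicates,
  ≥ 90%).

Passing these establishes that the estimators and models are implemented
correctly and calibrated *under the generators' assumptions* (stationary
narrow-band coupling, beta-distributed scores, exchangeable trials). It does
not establish that real MEG data meet those assumptions, nor reproduce any
empirical coefficient estimated on real recordings.

## Numerical notes and limitations

- Ranks use stable tie-breaking, so the estimator is deterministic on
  discretised data.
- `ortho_poly` uses a QR factorisation of the centred Vandermonde matrix
  with a positive-leading-coefficient sign convention; columns are
  orthonormal (R's convention differs by column scale only).
- PCA components of rank-deficient parcels are truncated to the effective
  rank with a warning.
- The minimum epoch for phase extraction is 3 cycles of the centre
  frequency; delays must be integer sample shifts.
- `segment_shuffle` drops a sub-segment tail (documented; in the pipeline
  the tail sits inside the trimmed filter edge).
- The z statistic uses the n−1 SD of a finite surrogate ensemble and is
  therefore slightly t-like; with N = 200 surrogates the |z| > 1.96 rate
  under the null is ≈ 5.2% before any ensemble mismatch.
- Known limitation: with very short epochs or very slow rates the segment
  count is small and the permutation ensemble coarse; the pipeline refuses
  (< 2 segments) rather than degrade silently.
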