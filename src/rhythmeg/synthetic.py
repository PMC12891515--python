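"""Synthetic generators with known ground truth.

Three families of generators emulate the ingredients of a syllabic-rhythm /
auditory-motor coupling experiment:

* syllable-nuclei trains at a controlled syllabic rate with controllable
  inter-nucleus interval jitter (the substrate of all periodicity measures),
* two-region multichannel neural signals at 100 Hz consisting of 1/f
  background plus a shared theta-band oscillation coupled across regions at a
  known lag and strength,
* beta-distributed comprehension scores in [0, 1] produced by a logit-linear
  model in rate, periodicity and their interaction, with optional subject
  intercept heterogeneity.

Every generator is bit-reproducible given its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal
from scipy.special import expit

__all__ = [
    "SyllableTrainSpec",
    "CoupledSignalSpec",
    "BehaviorGenSpec",
    "SyllableTrain",
    "TrialData",
    "gen_syllable_train",
    "gen_coupled_trial",
    "gen_behavior",
    "one_over_f_noise",
    "render_envelope",
    "write_trains_csv",
    "write_behavior_csv",
    "write_trial",
    "read_trial",
    "DEFAULT_RATE_CONDITIONS",
]

#: The five syllabic-rate conditions (syllables per second) of the study design.
DEFAULT_RATE_CONDITIONS = (5.0, 11.0, 14.0, 16.0, 17.5)


@dataclass(frozen=True)
class SyllableTrainSpec:
    """Specification for one synthetic syllable-nuclei train.

    Parameters
    ----------
    rate : float
        Nominal syllabic rate in syllables per second (Syl/s); the nominal
        inter-nucleus interval is ``1 / rate``.
    jitter_sd : float
        Standard deviation (s) of the Gaussian noise added to each interval.
    n_syllables : int
        Number of nuclei in the train (>= 2).
    seed : int
        RNG seed.
    """

    rate: float
    jitter_sd: float = 0.0
    n_syllables: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if self.jitter_sd < 0:
            raise ValueError(f"jitter_sd must be >= 0, got {self.jitter_sd}")
        if self.n_syllables < 2:
            raise ValueError(f"n_syllables must be >= 2, got {self.n_syllables}")


@dataclass(frozen=True)
class CoupledSignalSpec:
    """Specification for one two-region coupled multichannel trial.

    The second region's theta component equals the first region's delayed by
    ``lag`` seconds and scaled by ``coupling_strength``, mixed with independent
    narrow-band noise so that the theta component keeps unit variance.
    """

    fs: float = 100.0
    duration: float = 4.0
    theta_freq: float = 6.0
    coupling_strength: float = 0.5
    lag: float = 0.05
    noise_exponent: float = 1.0
    n_components: int = 6
    seed: int = 0
    #: full bandwidth (Hz) of the stochastic theta component
    theta_bw: float = 5.0
    #: std of the theta component relative to the 1/f background (per channel)
    theta_snr: float = 1.0
    #: also couple a delayed broadband component (off by default; the analysis
    #: band is theta, so coupling is injected there unless requested)
    broadband_coupling: bool = False

    def __post_init__(self) -> None:
        if not self.fs > 2 * self.theta_freq:
            raise ValueError("fs must exceed twice the theta frequency")
        if not 0 <= self.coupling_strength <= 1:
            raise ValueError("coupling_strength must lie in [0, 1]")
        if not 0 <= self.lag < self.duration:
            raise ValueError("lag must lie in [0, duration)")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


@dataclass(frozen=True)
class BehaviorGenSpec:
    """Specification of the comprehension-score generator.

    ``fixed_coefficients`` is a mapping from design-column names to logit-scale
    coefficients; the key ``"intercept"`` is implicit (no column required).
    Scores are drawn from Beta(mu*phi, (1-mu)*phi) with
    logit(mu) = x'beta + subject intercept.
    """

    fixed_coefficients: Mapping[str, float]
    precision: float = 20.0
    subject_sd: float = 0.0
    n_subjects: int = 12
    trials_per_subject: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.precision > 0:
            raise ValueError("precision must be positive")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")


@dataclass
class SyllableTrain:
    """Nuclei times for one sentence plus stimulus covariates."""

    sentence_id: str
    nuclei_times: np.ndarray
    rate_condition: float
    compression_factor: float = 1.0
    n_syllables: int | None = None
    mean_word_frequency: float = 0.0

    def __post_init__(self) -> None:
        self.nuclei_times = np.asarray(self.nuclei_times, dtype=float)
        if np.any(np.diff(self.nuclei_times) <= 0):
            raise ValueError("nuclei_times must be strictly increasing")
        if self.n_syllables is None:
            self.n_syllables = len(self.nuclei_times)
        elif self.n_syllables != len(self.nuclei_times):
            raise ValueError("n_syllables does not match len(nuclei_times)")


@dataclass
class TrialData:
    """Per-trial multichannel time series for two or more regions.

    ``regions`` maps ``(region_label, hemisphere)`` to a samples x channels
    array sampled at ``fs`` Hz.
    """

    fs: float
    regions: dict
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return next(iter(self.regions.values())).shape[0]


def gen_syllable_train(
    spec: SyllableTrainSpec,
    sentence_id: str = "s0",
    compression_factor: float = 1.0,
    mean_word_frequency: float = 0.0,
) -> SyllableTrain:
    """Draw a syllable-nuclei train with jittered inter-nucleus intervals.

    Intervals are ``1/rate`` plus Gaussian noise with SD ``jitter_sd``,
    truncated so that every interval stays above 10% of the nominal interval
    (keeping nuclei times strictly increasing even at high jitter).
    """
    rng = np.random.default_rng(spec.seed)
    nominal = 1.0 / spec.rate
    n_int = spec.n_syllables - 1
    if spec.jitter_sd == 0:
        intervals = np.full(n_int, nominal)
    else:
        # truncated Gaussian via rejection: exact and much faster than the
        # generic truncnorm sampler for the mild truncation used here
        lo = 0.1 * nominal - nominal
        noise = rng.normal(0.0, spec.jitter_sd, size=n_int)
        bad = noise < lo
        while bad.any():
            noise[bad] = rng.normal(0.0, spec.jitter_sd, size=int(bad.sum()))
            bad = noise < lo
        intervals = nominal + noise
    times = np.concatenate([[0.0], np.cumsum(intervals)])
    return SyllableTrain(
        sentence_id=sentence_id,
        nuclei_times=times,
        rate_condition=spec.rate,
        compression_factor=compression_factor,
        mean_word_frequency=mean_word_frequency,
    )


def one_over_f_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f**exponent, unit variance.

    Synthesised by spectral amplitude shaping of white Gaussian noise, which
    gives exact exponent control in O(n log n).
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # avoid the DC singularity
    spec *= f ** (-exponent / 2.0)
    out = np.fft.irfft(spec, n)
    sd = out.std()
    if sd > 0:
        out /= sd
    return out


def _narrowband(n: int, fs: float, f0: float, bw: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise centred on f0."""
    lo = max(f0 - bw / 2.0, 0.1)
    hi = min(f0 + bw / 2.0, 0.49 * fs)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n + 4 * int(fs)))
    x = x[2 * int(fs): 2 * int(fs) + n]
    return x / x.std()


def gen_coupled_trial(
    spec: CoupledSignalSpec,
    region_labels: tuple[str, str] = ("pSTG", "iPCG"),
    hemisphere: str = "L",
) -> TrialData:
    """Generate one two-region trial with theta coupling at a known lag.

    Each channel is an independent 1/f background plus the region's shared
    theta component; region 2's theta component is region 1's delayed by
    ``lag`` and scaled by ``coupling_strength``, plus independent narrow-band
    noise restoring unit variance.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs
    n = int(round(spec.duration * fs))
    k = int(round(spec.lag * fs))
    if k >= n:
        raise ValueError("lag must be shorter than the epoch")

    z = _narrowband(n + k, fs, spec.theta_freq, spec.theta_bw, rng)
    c = spec.coupling_strength
    s1 = z[k:k + n]
    indep = _narrowband(n, fs, spec.theta_freq, spec.theta_bw, rng)
    s2 = c * z[:n] + np.sqrt(max(1.0 - c ** 2, 0.0)) * indep

    shared_bb = None
    if spec.broadband_coupling:
        bb = rng.standard_normal(n + k)
        bb /= bb.std()
        shared_bb = (bb[k:k + n], c * bb[:n])

    regions = {}
    for r, s in enumerate((s1, s2)):
        gains = spec.theta_snr * rng.uniform(0.5, 1.5, size=spec.n_components)
        chans = np.empty((n, spec.n_components))
        for j in range(spec.n_components):
            chans[:, j] = gains[j] * s + one_over_f_noise(n, spec.noise_exponent, rng)
            if shared_bb is not None:
                chans[:, j] += 0.5 * shared_bb[r]
        regions[(region_labels[r], hemisphere)] = chans

    meta = {"seed": spec.seed, "lag": spec.lag,
            "coupling_strength": spec.coupling_strength,
            "theta_freq": spec.theta_freq}
    return TrialData(fs=fs, regions=regions, meta=meta)


def gen_behavior(design: pd.DataFrame, spec: BehaviorGenSpec) -> pd.DataFrame:
    """Draw beta-distributed comprehension scores for a covariate design.

    Every coefficient name (except ``"intercept"``) must be a column of
    ``design``; a missing column raises ``KeyError``. If ``subject_sd > 0``
    and a ``subject`` column is present, per-subject Gaussian intercepts are
    added on the logit scale. Returns a copy of ``design`` with a ``score``
    column.
    """
    rng = np.random.default_rng(spec.seed)
    eta = np.full(len(design), float(spec.fixed_coefficients.get("intercept", 0.0)))
    for name, beta in spec.fixed_coefficients.items():
        if name == "intercept":
            continue
        if name not in design.columns:
            raise KeyError(f"design has no column for coefficient {name!r}")
        eta = eta + beta * design[name].to_numpy(dtype=float)
    if spec.subject_sd > 0:
        if "subject" not in design.columns:
            raise KeyError("subject_sd > 0 requires a 'subject' column")
        subjects, inverse = np.unique(design["subject"].to_numpy(), return_inverse=True)
        intercepts = rng.normal(0.0, spec.subject_sd, size=len(subjects))
        eta = eta + intercepts[inverse]
    mu = expit(eta)
    score = rng.beta(mu * spec.precision, (1.0 - mu) * spec.precision)
    out = design.copy()
    out["score"] = score
    return out


def render_envelope(
    train: SyllableTrain,
    fs: float = 1000.0,
    bump_sd: float = 0.02,
    snr_db: float = np.inf,
    pad: float = 0.2,
    seed: int = 0,
) -> np.ndarray:
    """Render a nonnegative amplitude envelope with a Gaussian bump per nucleus.

    Used to exercise envelope-based nuclei detection against known timing;
    ``snr_db`` sets the ratio of envelope RMS to additive white noise RMS.
    """
    t_end = train.nuclei_times[-1] + pad
    t = np.arange(0.0, t_end + pad, 1.0 / fs)
    env = np.zeros_like(t)
    for t0 in train.nuclei_times + pad:
        env += np.exp(-0.5 * ((t - t0) / bump_sd) ** 2)
    if np.isfinite(snr_db):
        rng = np.random.default_rng(seed)
        noise_sd = np.sqrt(np.mean(env ** 2)) / (10 ** (snr_db / 20.0))
        env = env + rng.normal(0.0, noise_sd, size=env.shape)
    return np.clip(env, 0.0, None)


# ---------------------------------------------------------------------------
# persistence

def write_trains_csv(trains: list[SyllableTrain], path) -> None:
    rows = []
    for tr in trains:
        rows.append({
            "sentence_id": tr.sentence_id,
            "rate_condition": tr.rate_condition,
            "compression_factor": tr.compression_factor,
            "n_syllables": tr.n_syllables,
            "mean_word_frequency": tr.mean_word_frequency,
            "nuclei_times": ";".join(f"{t:.6f}" for t in tr.nuclei_times),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trains_csv(path) -> list[SyllableTrain]:
    df = pd.read_csv(path)
    trains = []
    for _, row in df.iterrows():
        times = np.array([float(v) for v in str(row["nuclei_times"]).split(";")])
        trains.append(SyllableTrain(
            sentence_id=str(row["sentence_id"]),
            nuclei_times=times,
            rate_condition=float(row["rate_condition"]),
            compression_factor=float(row["compression_factor"]),
            mean_word_frequency=float(row["mean_word_frequency"]),
        ))
    return trains


def write_behavior_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def write_trial(trial: TrialData, directory) -> None:
    """Write a trial as one CSV per region plus a JSON sidecar.

    Layout: ``<dir>/<region>_<hemisphere>.csv`` (samples x channels, no
    header) and ``<dir>/trial.json`` holding fs, region keys and metadata.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    labels = []
    for (label, hemi), data in trial.regions.items():
        fname = f"{label}_{hemi}.csv"
        np.savetxt(directory / fname, data, delimiter=",")
        labels.append([label, hemi])
    sidecar = {"fs": trial.fs, "regions": labels, "meta": trial.meta}
    (directory / "trial.json").write_text(json.dumps(sidecar, indent=1))


def read_trial(directory) -> TrialData:
    directory = Path(directory)
    sidecar = json.loads((directory / "trial.json").read_text())
    regions = {}
    for label, hemi in sidecar["regions"]:
        data = np.loadtxt(directory / f"{label}_{hemi}.csv", delimiter=",")
        regions[(label, hemi)] = np.atleast_2d(data.T).T
    return TrialData(fs=sidecar["fs"], regions=regions, meta=sidecar.get("meta", {}))
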