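"""Syllabic-level periodicity measures.

Periodicity of a sentence is quantified as the median absolute deviation
(MAD) of its inter-syllable-nuclei intervals: perfectly periodic speech has
identical intervals and MAD 0; larger MAD means less periodic timing. Because
MAD and syllabic rate are naturally correlated, the MAD is decorrelated from
rate by regressing it, within each rate condition, on the empirical
per-sentence rate and keeping the residuals ("residual MAD").
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .synthetic import SyllableTrain

__all__ = [
    "intervals",
    "mad",
    "empirical_rate",
    "periodicity_records",
    "residualize_mad",
    "detect_nuclei",
    "envelope_from_wav",
    "read_nuclei_csv",
    "write_records_csv",
    "GroupTooSmallError",
]

#: consistency constant of the classical scaled MAD (normal-consistent)
MAD_SCALE = 1.4826


class GroupTooSmallError(ValueError):
    """A rate group has too few sentences to fit a residualising model."""


def intervals(train) -> np.ndarray:
    """Inter-nuclei intervals (first differences of nuclei times, in s)."""
    times = train.nuclei_times if isinstance(train, SyllableTrain) else np.asarray(train, float)
    if len(times) < 2:
        raise ValueError("need at least 2 nuclei to form intervals")
    out = np.diff(times)
    if np.any(out <= 0):
        raise ValueError("nuclei times must be strictly increasing")
    return out


def mad(values, scale_constant: float = MAD_SCALE) -> float:
    """Median absolute deviation: scale * median(|x - median(x)|).

    The default scale 1.4826 makes the estimate consistent for a Gaussian SD;
    pass ``scale_constant=1.0`` for the unscaled convention.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("mad of empty input")
    return float(scale_constant * np.median(np.abs(x - np.median(x))))


def empirical_rate(train) -> float:
    """Per-sentence syllabic rate: nuclei events per second of spanned time."""
    times = train.nuclei_times if isinstance(train, SyllableTrain) else np.asarray(train, float)
    if len(times) < 2:
        raise ValueError("need at least 2 nuclei")
    return (len(times) - 1) / (times[-1] - times[0])


def periodicity_records(trains: list, scale_constant: float = MAD_SCALE) -> pd.DataFrame:
    """One periodicity record per sentence: intervals' MAD and empirical rate."""
    rows = []
    for tr in trains:
        ivals = intervals(tr)
        rows.append({
            "sentence_id": tr.sentence_id,
            "rate_condition": tr.rate_condition,
            "n_intervals": len(ivals),
            "mad": mad(ivals, scale_constant),
            "empirical_rate": empirical_rate(tr),
            "compression_factor": tr.compression_factor,
            "n_syllables": tr.n_syllables,
            "mean_word_frequency": tr.mean_word_frequency,
        })
    return pd.DataFrame(rows)


def residualize_mad(records: pd.DataFrame, mode: str = "ols_on_rate") -> pd.DataFrame:
    """Decorrelate MAD from syllabic rate within each rate condition.

    ``ols_on_rate`` (default) regresses MAD on the empirical per-sentence rate
    by OLS within each ``rate_condition`` group and keeps the residuals;
    ``demean`` simply centres MAD within each group. Residuals have zero group
    mean either way. Groups with fewer than 3 sentences raise
    :class:`GroupTooSmallError`.
    """
    if mode not in ("ols_on_rate", "demean"):
        raise ValueError(f"unknown mode {mode!r}")
    out = records.copy()
    out["residual_mad"] = np.nan
    for cond, idx in records.groupby("rate_condition").groups.items():
        grp = records.loc[idx]
        if len(grp) < 3:
            raise GroupTooSmallError(
                f"rate condition {cond} has only {len(grp)} sentences (need >= 3)")
        y = grp["mad"].to_numpy(dtype=float)
        if mode == "demean" or np.ptp(grp["empirical_rate"].to_numpy()) == 0:
            resid = y - y.mean()
        else:
            x = grp["empirical_rate"].to_numpy(dtype=float)
            slope, icept = np.polyfit(x, y, 1)
            resid = y - (slope * x + icept)
        out.loc[idx, "residual_mad"] = resid
    return out


def detect_nuclei(
    envelope,
    fs: float,
    min_dip_db: float = 2.0,
    min_peak_interval: float = 0.04,
    smooth_ms: float = 30.0,
) -> np.ndarray:
    """Detect syllable nuclei as intensity peaks of an amplitude envelope.

    A simplified intensity-peak detector: the envelope is smoothed
    (``smooth_ms`` moving average), converted to dB, and local maxima are kept
    if they are separated by at least ``min_peak_interval`` seconds and rise at
    least ``min_dip_db`` dB above their flanking dips (peak prominence in dB).
    Returns nucleus times in seconds; a constant or empty envelope yields an
    empty array.
    """
    if not fs > 0:
        raise ValueError("fs must be positive")
    env = np.asarray(envelope, dtype=float)
    if env.size < int(fs * 0.1):
        raise ValueError("envelope shorter than 100 ms")
    win = max(int(round(smooth_ms / 1000.0 * fs)), 1)
    if win > 1:
        from scipy.ndimage import uniform_filter1d

        env = uniform_filter1d(env, win, mode="nearest")
    if np.ptp(env) == 0:
        return np.array([])
    floor = env.max() * 1e-6 + 1e-12
    db = 20.0 * np.log10(np.maximum(env, floor))
    peaks, _ = signal.find_peaks(
        db,
        distance=max(int(round(min_peak_interval * fs)), 1),
        prominence=min_dip_db,
    )
    return peaks / fs


def envelope_from_wav(path, smooth_ms: float = 30.0) -> tuple[np.ndarray, float]:
    """Amplitude envelope of a PCM WAV file (rectified + smoothed), with fs."""
    from scipy.io import wavfile

    fs, data = wavfile.read(path)
    data = np.asarray(data, dtype=float)
    if data.ndim > 1:
        data = data.mean(axis=1)
    env = np.abs(data)
    win = max(int(round(smooth_ms / 1000.0 * fs)), 1)
    if win > 1:
        env = np.convolve(env, np.ones(win) / win, mode="same")
    return env, float(fs)


def read_nuclei_csv(path) -> dict:
    """Read nuclei times from CSV with columns ``sentence_id, time_s``."""
    df = pd.read_csv(path)
    if not {"sentence_id", "time_s"} <= set(df.columns):
        raise ValueError("nuclei CSV needs columns 'sentence_id' and 'time_s'")
    out = {}
    for sid, grp in df.groupby("sentence_id"):
        out[str(sid)] = np.sort(grp["time_s"].to_numpy(dtype=float))
    return out


def write_records_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)
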