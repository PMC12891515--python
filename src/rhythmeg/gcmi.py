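"""Gaussian-copula mutual information (GCMI) between multivariate signals.

The estimator rank-transforms each marginal to Gaussian scores (the copula
step, which makes the estimate invariant to any strictly monotone marginal
transform of the raw data) and then computes the parametric Gaussian mutual
information from covariance determinants,

    I = 1/2 * log2 [ det(Sx) det(Sy) / det(Sxy) ],

optionally subtracting the analytic digamma-based small-sample bias of the
Gaussian entropy estimates. The spectral front-end extracts band-limited
phase as per-sample unit-normalised (cos, sin) pairs from a zero-phase
band-pass filter followed by the analytic signal, and the delay scan shifts
one region against the other by integer sample lags (truncating the overhang,
never wrapping). Segment shuffling and surrogate z-scoring provide the
surrogate-normalisation used to express coupling in null standard deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, special
from scipy.stats import norm
from sklearn.decomposition import PCA

__all__ = [
    "MIEstimate",
    "SpectralPhase",
    "RankDeficiencyError",
    "copula_normalize",
    "mi_gg",
    "pca_reduce",
    "band_phase",
    "delay_gcmi",
    "segment_shuffle",
    "surrogate_z",
]

_LN2 = np.log(2.0)


class RankDeficiencyError(ValueError):
    """A covariance block required by the Gaussian MI is singular."""


@dataclass(frozen=True)
class MIEstimate:
    """A mutual-information estimate in bits."""

    value: float
    bias_corrected: bool
    n_samples: int
    dims: tuple[int, int]


@dataclass
class SpectralPhase:
    """Band-limited phase of a multichannel signal at one centre frequency.

    ``phase_pairs`` holds, per retained channel, the per-sample
    unit-normalised (cos, sin) of the analytic-signal phase, interleaved as
    columns (samples x 2k). ``valid`` flags samples outside the filter edge
    region. In amplitude-retaining mode the pairs are the unnormalised
    (real, imag) parts instead.
    """

    freq: float
    fs: float
    phase_pairs: np.ndarray
    valid: np.ndarray
    phase_only: bool = True

    def trimmed(self) -> np.ndarray:
        return self.phase_pairs[self.valid]


def _as_columns(data) -> np.ndarray:
    x = np.asarray(data, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x


def copula_normalize(data) -> np.ndarray:
    """Map each column to Gaussian scores of its ranks.

    Ranks are assigned with stable tie-breaking (the earlier sample gets the
    lower rank) and mapped through the standard-normal quantile function at
    ``(rank + 1) / (n + 1)``. The output depends on the input only through
    the column-wise rank order.
    """
    x = _as_columns(data)
    n, d = x.shape
    if n < 3:
        raise ValueError("copula normalization needs at least 3 samples")
    if np.any(~np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    if np.any(x.max(axis=0) == x.min(axis=0)):
        bad = np.nonzero(x.max(axis=0) == x.min(axis=0))[0]
        raise ValueError(f"degenerate (constant) column(s): {bad.tolist()}")
    order = np.argsort(x, axis=0, kind="stable")
    ranks = np.empty((n, d), dtype=np.intp)
    np.put_along_axis(ranks, order, np.arange(n, dtype=np.intp)[:, None], axis=0)
    return norm.ppf((ranks + 1.0) / (n + 1.0))


def _mi_bias_nats(n: int, dx: int, dy: int) -> float:
    """Analytic small-sample bias of the Gaussian MI estimate (nats).

    Derived from the digamma expansions of the three Gaussian entropy
    estimates; the sample-size terms common to the entropies cancel in MI.
    """
    psi = special.psi((n - np.arange(1, dx + dy + 1)) / 2.0) / 2.0
    return float(psi[:dx].sum() + psi[:dy].sum() - psi.sum())


def _gauss_mi_bits(x: np.ndarray, y: np.ndarray, bias_correct: bool) -> float:
    """Gaussian MI in bits from (already copula-normalised) score matrices."""
    n, dx = x.shape
    dy = y.shape[1]
    xy = np.concatenate([x, y], axis=1)
    xy = xy - xy.mean(axis=0)
    c = (xy.T @ xy) / (n - 1)

    def logdet(block, name):
        w = np.linalg.eigvalsh(block)
        if w[0] <= w[-1] * 1e-12:
            raise RankDeficiencyError(f"covariance block '{name}' is singular")
        return np.log(w).sum()

    mi = 0.5 * (logdet(c[:dx, :dx], "x") + logdet(c[dx:, dx:], "y")
                - logdet(c, "joint"))
    if bias_correct:
        mi -= _mi_bias_nats(n, dx, dy)
    return mi / _LN2


def mi_gg(x, y, bias_correct: bool = True) -> MIEstimate:
    """Mutual information (bits) between two sets of Gaussian-score columns.

    ``x`` and ``y`` are samples x d matrices that have typically been passed
    through :func:`copula_normalize`. With ``bias_correct`` the analytic
    digamma-based bias of the parametric Gaussian entropy estimates is
    subtracted (so small negative values can occur within the bias term's
    magnitude; without it the estimate is non-negative).
    """
    xm = _as_columns(x)
    ym = _as_columns(y)
    if xm.shape[0] != ym.shape[0]:
        raise ValueError("x and y must have the same number of samples")
    n, dx = xm.shape
    dy = ym.shape[1]
    if not n > dx + dy + 3:
        raise ValueError(f"need n > dx + dy + 3 samples, got n={n}, dims=({dx},{dy})")
    if np.any(~np.isfinite(xm)) or np.any(~np.isfinite(ym)):
        raise ValueError("inputs must be jointly finite")
    value = _gauss_mi_bits(xm, ym, bias_correct)
    return MIEstimate(value=value, bias_corrected=bias_correct,
                      n_samples=n, dims=(dx, dy))


def pca_reduce(parcel_data, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Scores of the top-k principal components of a samples x voxels array.

    Fitted per trial per parcel. If the data rank is below ``k`` the result is
    truncated to the effective rank (with a warning); the returned
    ``variance_explained`` ratios are non-increasing.
    """
    x = _as_columns(parcel_data)
    n, v = x.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > v:
        raise ValueError(f"k={k} exceeds the number of voxels ({v})")
    pca = PCA(n_components=min(k, n, v))
    scores = pca.fit_transform(x)
    var = pca.explained_variance_
    tol = var[0] * 1e-10 if var[0] > 0 else 0.0
    rank = int(np.sum(var > tol))
    if rank < scores.shape[1]:
        warnings.warn(
            f"data rank {rank} below requested {k} components; truncating",
            RuntimeWarning, stacklevel=2)
        scores = scores[:, :rank]
    return scores, pca.explained_variance_ratio_[:scores.shape[1]]


def _band_sos(fs: float, f0: float, bw: float):
    lo, hi = f0 - bw / 2.0, f0 + bw / 2.0
    if lo <= 0 or not fs > 2 * hi:
        raise ValueError(f"band {lo}-{hi} Hz not representable at fs={fs}")
    return signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")


def band_phase(
    data,
    fs: float,
    f0: float,
    bw: float = 2.0,
    edge_trim: float = 0.2,
    phase_only: bool = True,
) -> SpectralPhase:
    """Band-limited analytic-signal phase of each channel at centre f0.

    A 4th-order Butterworth band-pass at ``f0 +/- bw/2`` is applied forward
    and backward (zero net phase shift), the analytic signal is taken, and
    each sample is unit-normalised so only phase is retained (set
    ``phase_only=False`` to keep amplitude). The first and last ``edge_trim``
    seconds are flagged invalid. Requires at least 3 cycles of f0.
    """
    x = _as_columns(data)
    n = x.shape[0]
    min_n = int(np.ceil(3.0 * fs / f0))
    if n < min_n:
        raise ValueError(f"epoch of {n} samples below the minimum {min_n} "
                         f"(3 cycles of {f0} Hz at fs={fs})")
    sos = _band_sos(fs, f0, bw)
    filt = signal.sosfiltfilt(sos, x, axis=0)
    analytic = signal.hilbert(filt, axis=0)
    re, im = analytic.real, analytic.imag
    if phase_only:
        amp = np.maximum(np.abs(analytic), np.finfo(float).tiny)
        re, im = re / amp, im / amp
    pairs = np.empty((n, 2 * x.shape[1]))
    pairs[:, 0::2] = re
    pairs[:, 1::2] = im
    valid = np.zeros(n, dtype=bool)
    k = int(round(edge_trim * fs))
    valid[k:n - k if k > 0 else n] = True
    return SpectralPhase(freq=f0, fs=fs, phase_pairs=pairs, valid=valid,
                         phase_only=phase_only)


def _delay_samples(delays, fs: float) -> np.ndarray:
    d = np.asarray(delays, dtype=float)
    shifts = d * fs
    rounded = np.round(shifts)
    if np.any(np.abs(shifts - rounded) > 1e-6):
        raise ValueError("delays must be integer multiples of the sample period")
    if np.any(rounded < 0):
        raise ValueError("delays must be non-negative")
    return rounded.astype(int)


def delay_gcmi(
    x_region,
    y_region,
    delays,
    fs: float | None = None,
    bias_correct: bool = True,
    window: int | None = None,
) -> np.ndarray:
    """GCMI (bits) between x and y with y shifted by each delay (seconds).

    ``x_region``/``y_region`` are :class:`SpectralPhase` objects (their valid
    samples are used) or plain samples x d matrices with ``fs`` given. For a
    delay ``d`` the pairing is ``x[t]`` with ``y[t + d]``; the trailing
    overhang is dropped (no wrap-around) and every delay uses the same
    effective sample count, truncated to the largest delay. ``window`` forces
    a specific effective sample count (further truncation), which keeps the
    estimator bias identical between observed and surrogate computations.
    """
    if isinstance(x_region, SpectralPhase):
        fs = x_region.fs
        xm = x_region.trimmed()
    else:
        xm = _as_columns(x_region)
    ym = y_region.trimmed() if isinstance(y_region, SpectralPhase) else _as_columns(y_region)
    if fs is None:
        raise ValueError("fs is required with plain-array inputs")
    shifts = _delay_samples(delays, fs)
    n = min(xm.shape[0], ym.shape[0])
    kmax = int(shifts.max()) if len(shifts) else 0
    n_eff = n - kmax if window is None else int(window)
    if n_eff > n - kmax:
        raise ValueError("window exceeds the available overlap")
    if n_eff <= xm.shape[1] + ym.shape[1] + 3:
        raise ValueError("largest delay leaves too few overlapping samples")
    xw = copula_normalize(xm[:n_eff])
    out = np.empty(len(shifts))
    for i, k in enumerate(shifts):
        yw = copula_normalize(ym[k:k + n_eff])
        out[i] = _gauss_mi_bits(xw, yw, bias_correct)
    return out


def segment_shuffle(ts, segment_length: float, fs: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Shuffle non-overlapping contiguous segments of a time series.

    The series is cut into segments of ``segment_length`` seconds (in
    original order); a uniformly random permutation of the segments is
    concatenated and returned. A trailing remainder shorter than one segment
    is dropped, so the marginal sample multiset is preserved up to that tail.
    """
    x = _as_columns(np.asarray(ts, dtype=float))
    seg = int(round(segment_length * fs))
    if seg < 1:
        raise ValueError("segment shorter than one sample")
    n_seg = x.shape[0] // seg
    if n_seg < 2:
        raise ValueError(f"epoch holds {n_seg} segment(s); need at least 2")
    blocks = x[:n_seg * seg].reshape(n_seg, seg, x.shape[1])
    perm = rng.permutation(n_seg)
    out = blocks[perm].reshape(n_seg * seg, x.shape[1])
    return out[:, 0] if np.asarray(ts).ndim == 1 else out


def surrogate_z(observed: float, surrogate_values) -> float:
    """Standardise an observed GCMI against its surrogate distribution.

    ``z = (observed - mean(surrogates)) / sd(surrogates)`` with the n-1
    denominator, i.e. the sign convention under which stronger-than-chance
    coupling yields a larger z.
    """
    s = np.asarray(surrogate_values, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 surrogate values")
    sd = s.std(ddof=1)
    if sd == 0:
        raise ValueError("surrogate distribution has zero spread")
    return float((observed - s.mean()) / sd)
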