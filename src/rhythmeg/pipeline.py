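"""Per-trial coupling estimation across ROI pairs, with surrogate z-scoring.

For each trial the pipeline reduces each region's voxel series to its leading
principal components, extracts band-limited phase on a frequency grid, scans
auditory-to-motor delays, and standardises the observed GCMI against a
surrogate distribution obtained by shuffling contiguous segments of the motor
region's component series. The segment length follows the syllabic rate of
the trial: a fixed fraction (default 80%) of the syllabic cycle, so that
segments are comparable across rate conditions relative to the stimulus
rhythm. The theta-band summary is the mean z over 4-8 Hz at the extraction
delay (default 50 ms).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gcmi import (_mi_bias_nats, band_phase, copula_normalize, delay_gcmi,
                   pca_reduce)

__all__ = [
    "PipelineConfig",
    "CouplingResult",
    "TrialTooShortError",
    "segment_length",
    "run_trial_coupling",
    "run_cohort_coupling",
    "results_frame",
    "theta_table",
    "assemble_dataset",
]

_LN2 = np.log(2.0)

#: the ROI pairs of interest: each speech-motor region against auditory pSTG
ROI_PAIRS = ("iPCG", "IFG", "SMA")


class TrialTooShortError(ValueError):
    """The epoch is too short for two surrogate segments at the trial's rate."""


def segment_length(rate: float, fraction: float = 0.8) -> float:
    """Surrogate segment length in seconds: ``fraction`` of the syllabic cycle.

    E.g. at 5 Syl/s the cycle is 200 ms and the default 0.8 fraction gives
    160.0 ms; at 11 Syl/s it gives 72.72 ms.
    """
    if not rate > 0:
        raise ValueError("rate must be positive")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    return fraction / rate


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the coupling pipeline.

    Defaults reproduce the study conditions: theta frequencies 4-8 Hz (1 Hz
    steps, 2 Hz bandwidth), delays 0-300 ms in 10 ms steps with extraction at
    50 ms, 500 segment-shuffle surrogates with segments of 80% of the
    syllabic cycle, and 3 principal components per region.
    """

    freqs: tuple = tuple(range(4, 9))
    delays_ms: tuple = tuple(range(0, 310, 10))
    extraction_delay_ms: float = 50.0
    theta_band: tuple = (4.0, 8.0)
    n_surrogates: int = 500
    surrogate_fraction: float = 0.8
    n_components: int = 3
    bandwidth: float = 2.0
    edge_trim: float = 0.2
    phase_only: bool = True
    shuffle_both: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extraction_delay_ms not in self.delays_ms:
            raise ValueError("extraction_delay_ms must be on the delay grid")
        if not 0 < self.surrogate_fraction <= 1:
            raise ValueError("surrogate_fraction must lie in (0, 1]")
        if self.n_surrogates < 2:
            raise ValueError("need at least 2 surrogates")


@dataclass
class CouplingResult:
    """Raw and z-normalised GCMI on a frequency x delay grid for one trial."""

    subject: object
    trial: object
    roi_pair: str
    hemisphere: str
    freqs: np.ndarray
    delays_ms: np.ndarray
    gcmi: np.ndarray
    z_gcmi: np.ndarray
    surrogate_mean: np.ndarray
    surrogate_sd: np.ndarray
    theta_mean_z: float

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: one row per frequency x delay."""
        f, d = np.meshgrid(self.freqs, self.delays_ms, indexing="ij")
        return pd.DataFrame({
            "subject": self.subject,
            "trial": self.trial,
            "roi_pair": self.roi_pair,
            "hemisphere": self.hemisphere,
            "freq_hz": f.ravel(),
            "delay_ms": d.ravel(),
            "gcmi_bits": self.gcmi.ravel(),
            "z_gcmi": self.z_gcmi.ravel(),
        })


def _child_rng(*keys) -> np.random.Generator:
    """Deterministic RNG stream keyed by (seed, subject, trial, pair, freq)."""
    ints = []
    for key in keys:
        if isinstance(key, str):
            ints.append(zlib.crc32(key.encode()))
        elif isinstance(key, (int, np.integer)):
            ints.append(int(key) & 0x7FFFFFFF)
        else:
            ints.append(int(round(float(key) * 1000.0)) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(ints))


def _shuffled_stack(series: np.ndarray, seg: int, n_surr: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Stack ``n_surr`` segment-shuffled copies of a samples x k series.

    Shuffling permutes whole segments of the raw component series; the
    sub-segment tail is left in place so that all copies keep the original
    length (the tail sits in the filter edge region downstream). Columns are
    ordered surrogate-major: (samples, n_surr * k).
    """
    n, k = series.shape
    n_seg = n // seg
    blocks = series[:n_seg * seg].reshape(n_seg, seg, k)
    perms = np.stack([rng.permutation(n_seg) for _ in range(n_surr)])
    shuffled = blocks[perms].reshape(n_surr, n_seg * seg, k)
    out = np.empty((n_surr, n, k))
    out[:, :n_seg * seg] = shuffled
    out[:, n_seg * seg:] = series[n_seg * seg:]
    return np.moveaxis(out, 0, 1).reshape(n, n_surr * k)


def _surrogate_mi(
    xs: np.ndarray,
    ys: np.ndarray,
    fs: float,
    f0: float,
    config: PipelineConfig,
    seg: int,
    ke: int,
    n_eff: int,
    xn: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bias-corrected GCMI (bits) for segment-shuffle surrogates at one freq.

    The motor region's component series ``ys`` is segment-shuffled
    ``n_surrogates`` times; every copy runs through the identical spectral and
    copula path and the identical sample window as the observed estimate, so
    the estimator's small-sample bias cancels exactly in the z-score. ``xn``
    is the observed region's centred copula scores on the window (recomputed
    per surrogate only in ``shuffle_both`` mode).
    """
    n_surr = config.n_surrogates
    k = ys.shape[1]
    stack = _shuffled_stack(ys, seg, n_surr, rng)
    sp = band_phase(stack, fs, f0, config.bandwidth, config.edge_trim,
                    config.phase_only)
    yw = sp.trimmed()[ke:ke + n_eff]
    yn = copula_normalize(yw).reshape(n_eff, n_surr, 2 * k)
    yn = yn - yn.mean(axis=0)

    if config.shuffle_both:
        kx = xs.shape[1]
        xstack = _shuffled_stack(xs, seg, n_surr, rng)
        spx = band_phase(xstack, fs, f0, config.bandwidth, config.edge_trim,
                         config.phase_only)
        xw = spx.trimmed()[:n_eff]
        xb = copula_normalize(xw).reshape(n_eff, n_surr, 2 * kx)
        xb = xb - xb.mean(axis=0)
    else:
        xb = None

    dx = xn.shape[1]
    dy = 2 * k
    denom = n_eff - 1
    if xb is None:
        cx = (xn.T @ xn) / denom
        _, ldx = np.linalg.slogdet(cx)
        cxy = np.einsum("na,nrb->rab", xn, yn) / denom
    else:
        cxx = np.einsum("nra,nrb->rab", xb, xb) / denom
        _, ldx_r = np.linalg.slogdet(cxx)
        cxy = np.einsum("nra,nrb->rab", xb, yn) / denom
    cyy = np.einsum("nra,nrb->rab", yn, yn) / denom
    _, ldy = np.linalg.slogdet(cyy)

    joint = np.empty((n_surr, dx + dy, dx + dy))
    if xb is None:
        joint[:, :dx, :dx] = cx
    else:
        joint[:, :dx, :dx] = cxx
    joint[:, :dx, dx:] = cxy
    joint[:, dx:, :dx] = np.swapaxes(cxy, 1, 2)
    joint[:, dx:, dx:] = cyy
    _, ldj = np.linalg.slogdet(joint)

    ldx_all = ldx_r if xb is not None else ldx
    mi = 0.5 * (ldx_all + ldy - ldj) - _mi_bias_nats(n_eff, dx, dy)
    return mi / _LN2


def run_trial_coupling(
    trial,
    rate: float,
    config: PipelineConfig,
    roi: str = "iPCG",
    auditory: str = "pSTG",
    hemisphere: str = "L",
    subject=0,
    trial_id=0,
) -> CouplingResult:
    """Estimate raw and surrogate-normalised GCMI for one trial and ROI pair.

    Per frequency: PCA-reduced region series -> band-limited phase -> delay
    scan for the observed GCMI; segment-shuffled surrogates (shuffling the
    motor region's series, keeping the auditory region fixed) provide a null
    mean and SD estimated at the extraction delay, used to z-score the delay
    row. Raises :class:`TrialTooShortError` if the epoch cannot hold two
    segments at the trial's rate.
    """
    fs = trial.fs
    key_x, key_y = (auditory, hemisphere), (roi, hemisphere)
    for key in (key_x, key_y):
        if key not in trial.regions:
            raise KeyError(f"trial has no region {key}")
    seg_s = segment_length(rate, config.surrogate_fraction)
    seg = max(int(round(seg_s * fs)), 1)
    xs, _ = pca_reduce(trial.regions[key_x], config.n_components)
    ys, _ = pca_reduce(trial.regions[key_y], config.n_components)
    n_raw = xs.shape[0]
    if n_raw // seg < 2:
        raise TrialTooShortError(
            f"epoch of {n_raw / fs:.2f} s holds fewer than 2 segments of "
            f"{seg_s * 1e3:.1f} ms at {rate} Syl/s")

    delays_s = np.asarray(config.delays_ms, dtype=float) / 1000.0
    shifts = np.round(delays_s * fs).astype(int)
    ke = int(round(config.extraction_delay_ms / 1000.0 * fs))
    ext_idx = int(np.argmin(np.abs(np.asarray(config.delays_ms, float)
                                   - config.extraction_delay_ms)))

    freqs = np.asarray(config.freqs, dtype=float)
    n_f, n_d = len(freqs), len(delays_s)
    gcmi_grid = np.empty((n_f, n_d))
    z_grid = np.empty((n_f, n_d))
    s_mean = np.empty(n_f)
    s_sd = np.empty(n_f)

    for fi, f0 in enumerate(freqs):
        px = band_phase(xs, fs, f0, config.bandwidth, config.edge_trim,
                        config.phase_only)
        py = band_phase(ys, fs, f0, config.bandwidth, config.edge_trim,
                        config.phase_only)
        xm, ym = px.trimmed(), py.trimmed()
        n_valid = min(xm.shape[0], ym.shape[0])
        n_eff = n_valid - int(shifts.max())
        gcmi_grid[fi] = delay_gcmi(px, py, delays_s)
        xn = copula_normalize(xm[:n_eff])
        xn = xn - xn.mean(axis=0)
        rng = _child_rng(config.seed, subject, trial_id, roi, hemisphere, f0)
        surr = _surrogate_mi(xs, ys, fs, f0, config, seg, ke, n_eff, xn, rng)
        mu, sd = surr.mean(), surr.std(ddof=1)
        if sd == 0:
            raise ValueError("surrogate distribution has zero spread")
        s_mean[fi], s_sd[fi] = mu, sd
        z_grid[fi] = (gcmi_grid[fi] - mu) / sd

    lo, hi = config.theta_band
    theta_rows = (freqs >= lo) & (freqs <= hi)
    theta_mean_z = float(z_grid[theta_rows, ext_idx].mean())
    return CouplingResult(
        subject=subject, trial=trial_id, roi_pair=f"{roi}-{auditory}",
        hemisphere=hemisphere, freqs=freqs,
        delays_ms=np.asarray(config.delays_ms, dtype=float),
        gcmi=gcmi_grid, z_gcmi=z_grid,
        surrogate_mean=s_mean, surrogate_sd=s_sd,
        theta_mean_z=theta_mean_z,
    )


def run_cohort_coupling(
    entries,
    config: PipelineConfig,
    rois: tuple = ("iPCG",),
    hemispheres: tuple = ("L",),
    auditory: str = "pSTG",
    log=None,
) -> tuple[list, list]:
    """Run the trial pipeline over a cohort; skip (and log) too-short trials.

    ``entries`` is an iterable of mappings with keys ``trial`` (TrialData),
    ``rate``, ``subject`` and ``trial_id``. Returns ``(results, skipped)``
    where ``skipped`` lists ``(subject, trial_id, reason)`` tuples.
    """
    results, skipped = [], []
    for entry in entries:
        for roi in rois:
            for hemi in hemispheres:
                if (roi, hemi) not in entry["trial"].regions:
                    continue
                try:
                    results.append(run_trial_coupling(
                        entry["trial"], entry["rate"], config, roi=roi,
                        auditory=auditory, hemisphere=hemi,
                        subject=entry["subject"], trial_id=entry["trial_id"]))
                except TrialTooShortError as err:
                    skipped.append((entry["subject"], entry["trial_id"], str(err)))
                    if log is not None:
                        log(f"skipped subject={entry['subject']} "
                            f"trial={entry['trial_id']}: {err}")
    return results, skipped


def results_frame(results: list) -> pd.DataFrame:
    """Concatenate per-trial tidy frames (frequency x delay rows)."""
    return pd.concat([r.to_frame() for r in results], ignore_index=True)


def theta_table(results: list) -> pd.DataFrame:
    """One row per trial x ROI pair x hemisphere with the theta-band z."""
    return pd.DataFrame([{
        "subject": r.subject,
        "trial": r.trial,
        "roi_pair": r.roi_pair,
        "hemisphere": r.hemisphere,
        "theta_mean_z": r.theta_mean_z,
    } for r in results])


def assemble_dataset(
    coupling: pd.DataFrame | list,
    behavior: pd.DataFrame,
    periodicity: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Join neural, behavioral and periodicity records into one analysis table.

    Joins coupling rows (``subject, trial``) with behavioral records
    (``subject, trial, sentence_id, score`` + covariates) and periodicity
    records (``sentence_id``). Returns the joined table (one row per trial x
    ROI pair x hemisphere) and a report of unmatched keys; duplicate keys in
    any input raise ``ValueError``.
    """
    if not isinstance(coupling, pd.DataFrame):
        coupling = theta_table(coupling)
    for name, df, keys in (
        ("coupling", coupling, ["subject", "trial", "roi_pair", "hemisphere"]),
        ("behavior", behavior, ["subject", "trial"]),
        ("periodicity", periodicity, ["sentence_id"]),
    ):
        dupes = df[df.duplicated(keys, keep=False)]
        if len(dupes):
            listing = dupes[keys].drop_duplicates().to_dict("records")
            raise ValueError(f"duplicate keys in {name} table: {listing}")

    behav = behavior.merge(periodicity, on="sentence_id", how="inner",
                           suffixes=("", "_per"))
    table = coupling.merge(behav, on=["subject", "trial"], how="inner")

    matched_bt = set(map(tuple, table[["subject", "trial"]].drop_duplicates()
                         .itertuples(index=False)))
    coup_keys = set(map(tuple, coupling[["subject", "trial"]].drop_duplicates()
                        .itertuples(index=False)))
    behav_keys = set(map(tuple, behavior[["subject", "trial"]].drop_duplicates()
                         .itertuples(index=False)))
    per_ids = set(periodicity["sentence_id"])
    behav_ids = set(behavior["sentence_id"]) if "sentence_id" in behavior else set()
    report = {
        "coupling_unmatched": sorted(coup_keys - matched_bt),
        "behavior_unmatched": sorted(behav_keys - matched_bt),
        "periodicity_unmatched": sorted(per_ids - behav_ids),
    }
    return table, report
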