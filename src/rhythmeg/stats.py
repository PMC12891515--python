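"""Beta-family regression and inference utilities.

Comprehension scores and (min-max normalised) coupling values live in [0, 1]
and are modelled with a beta likelihood: logit(mu_i) = x_i' beta with constant
precision phi, fitted by maximum likelihood. Boundary responses are nudged
into the open interval by +/- (median / sample size). Uncertainty for
clustered data (trials nested in subjects) comes from a cluster bootstrap;
the random-effects structure of a mixed model is deliberately not estimated.
Rate enters models as an orthogonal polynomial basis of degree up to 3;
multiple comparisons use Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.othermod.betareg import BetaModel
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BetaFit",
    "BetaRegression",
    "boundary_adjust",
    "minmax_normalize",
    "ortho_poly",
    "beta_regression_fit",
    "cluster_bootstrap",
    "bh_fdr",
    "slope_contrast",
    "write_fit_report",
]


def boundary_adjust(y, groups=None):
    """Move responses at 0 or 1 into the open interval by median/n.

    ``eps = median(y) / len(y)``; exact zeros become ``eps``, exact ones
    become ``1 - eps``, interior values are untouched. With ``groups`` the
    median (and n) are taken per group instead of over the full vector.
    """
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("responses must lie in [0, 1]")
    out = y.copy()
    if groups is None:
        groups_arr = np.zeros(len(y), dtype=int)
    else:
        groups_arr = np.asarray(groups)
    for g in np.unique(groups_arr):
        m = groups_arr == g
        yg = y[m]
        at_boundary = (yg == 0) | (yg == 1)
        if not at_boundary.any():
            continue
        eps = np.median(yg) / len(yg)
        if eps == 0 or eps >= 0.5:
            raise ValueError(
                "degenerate boundary adjustment: median/n is "
                f"{eps} for group {g}")
        adj = yg.copy()
        adj[yg == 0] = eps
        adj[yg == 1] = 1 - eps
        out[m] = adj
    return out


def minmax_normalize(x) -> np.ndarray:
    """Affine map of x onto [0, 1]; order statistics are preserved."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("cannot min-max normalize a constant vector")
    return (x - lo) / (hi - lo)


def ortho_poly(x, degree: int) -> np.ndarray:
    """Orthonormal polynomial basis of x (degree columns, no intercept).

    Columns span {x, x^2, ..., x^degree} after centering, are mutually
    orthonormal with zero mean, and carry a deterministic sign (positive
    leading coefficient on the raw power basis). Mirrors the contrast basis
    produced by orthogonal-polynomial coding in standard statistical
    environments, up to column scale.
    """
    x = np.asarray(x, dtype=float)
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if len(np.unique(x)) < degree + 1:
        raise ValueError(f"need at least {degree + 1} distinct values")
    v = np.vander(x - x.mean(), degree + 1, increasing=True)
    q, r = np.linalg.qr(v)
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    basis = q[:, 1:] * signs[1:]
    return basis


@dataclass
class BetaFit:
    """Result of a beta-regression maximum-likelihood fit."""

    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    pvalues: pd.Series
    phi: float
    llf: float
    pseudo_r2: float
    pseudo_r2_lr: float
    converged: bool
    n: int


class BetaRegression(BaseEstimator, RegressorMixin):
    """Beta regression with a logit mean link and constant precision.

    A scikit-learn style estimator: ``fit(X, y)`` with y strictly inside
    (0, 1), ``predict(X)`` returning the fitted mean. ``X`` may be a
    DataFrame (column names become coefficient names) or an array. Fitted
    attributes carry a trailing underscore; the likelihood machinery is
    statsmodels' beta model.

    Parameters
    ----------
    add_intercept : bool
        Prepend a constant column (default True).
    maxiter : int
        Maximum optimizer iterations.
    """

    def __init__(self, add_intercept: bool = True, maxiter: int = 500):
        self.add_intercept = add_intercept
        self.maxiter = maxiter

    def _design(self, X) -> tuple[np.ndarray, list[str]]:
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            mat = X.to_numpy(dtype=float)
        else:
            mat = np.asarray(X, dtype=float)
            if mat.ndim == 1:
                mat = mat[:, None]
            names = [f"x{i}" for i in range(mat.shape[1])]
        if self.add_intercept:
            mat = np.column_stack([np.ones(len(mat)), mat])
            names = ["intercept"] + names
        return mat, names

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        if np.any((y <= 0) | (y >= 1)):
            raise ValueError(
                "responses must lie strictly inside (0, 1); apply "
                "boundary_adjust first")
        mat, names = self._design(X)
        rank = np.linalg.matrix_rank(mat)
        if rank < mat.shape[1]:
            _, r = np.linalg.qr(mat)
            dep = [names[j] for j in range(mat.shape[1])
                   if abs(r[j, j]) < 1e-8 * max(abs(np.diag(r)).max(), 1.0)]
            raise ValueError(f"design is rank deficient; collinear columns: {dep}")
        model = BetaModel(y, mat)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=self.maxiter, disp=0)
        all_names = names + ["log_precision"]
        self.feature_names_ = names
        self.params_ = pd.Series(res.params, index=all_names)
        self.bse_ = pd.Series(res.bse, index=all_names)
        self.cov_ = pd.DataFrame(np.asarray(res.cov_params()),
                                 index=all_names, columns=all_names)
        self.pvalues_ = pd.Series(res.pvalues, index=all_names)
        self.phi_ = float(np.exp(res.params[-1]))
        self.llf_ = float(res.llf)
        self.converged_ = bool(res.mle_retvals.get("converged", False))
        self.n_ = len(y)
        mu = expit(mat @ res.params[:-1])
        self.pseudo_r2_ = float(np.corrcoef(logit(y), logit(mu))[0, 1] ** 2)
        null = BetaModel(y, np.ones((len(y), 1)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            llf0 = float(null.fit(disp=0).llf)
        self.pseudo_r2_lr_ = float(1.0 - np.exp(-2.0 * (self.llf_ - llf0) / len(y)))
        self.coef_ = self.params_.iloc[int(self.add_intercept):-1].to_numpy()
        self.intercept_ = (float(self.params_.iloc[0])
                           if self.add_intercept else 0.0)
        return self

    def predict(self, X) -> np.ndarray:
        mat, _ = self._design(X)
        return expit(mat @ self.params_.iloc[:-1].to_numpy())

    def result_(self) -> BetaFit:
        return BetaFit(
            params=self.params_.iloc[:-1], bse=self.bse_.iloc[:-1],
            cov=self.cov_.iloc[:-1, :-1], pvalues=self.pvalues_.iloc[:-1],
            phi=self.phi_, llf=self.llf_, pseudo_r2=self.pseudo_r2_,
            pseudo_r2_lr=self.pseudo_r2_lr_, converged=self.converged_,
            n=self.n_)


def beta_regression_fit(design: pd.DataFrame, y, add_intercept: bool = True) -> BetaFit:
    """Fit a beta regression and return the coefficient table as a BetaFit."""
    est = BetaRegression(add_intercept=add_intercept).fit(design, y)
    return est.result_()


def cluster_bootstrap(
    design: pd.DataFrame,
    y,
    clusters,
    B: int = 500,
    seed: int = 0,
    add_intercept: bool = True,
) -> pd.DataFrame:
    """Cluster bootstrap SEs and percentile CIs for beta-regression terms.

    Clusters (e.g. subjects) are resampled with replacement B times and the
    model refitted on each resample. Returns a table with bootstrap SD and
    2.5/97.5 percentile bounds per coefficient; warns if more than 5% of
    refits fail.
    """
    clusters = np.asarray(clusters)
    ids = np.unique(clusters)
    if len(ids) < 10:
        raise ValueError("need at least 10 clusters for a cluster bootstrap")
    if B < 200:
        raise ValueError("need at least B = 200 bootstrap replicates")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    member_rows = {c: np.nonzero(clusters == c)[0] for c in ids}
    draws, failures = [], 0
    for _ in range(B):
        chosen = rng.choice(ids, size=len(ids), replace=True)
        rows = np.concatenate([member_rows[c] for c in chosen])
        try:
            fit = beta_regression_fit(design.iloc[rows], y[rows],
                                      add_intercept=add_intercept)
            if not fit.converged:
                raise RuntimeError("refit did not converge")
            draws.append(fit.params)
        except Exception:
            failures += 1
    if failures > 0.05 * B:
        warnings.warn(f"{failures} of {B} bootstrap refits failed",
                      RuntimeWarning, stacklevel=2)
    boot = pd.DataFrame(draws)
    out = pd.DataFrame({
        "boot_se": boot.std(ddof=1),
        "ci_low": boot.quantile(0.025),
        "ci_high": boot.quantile(0.975),
    })
    out.attrs["n_failures"] = failures
    out.attrs["draws"] = boot
    return out


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, <= 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def write_fit_report(
    fit: BetaFit,
    csv_path,
    json_path=None,
    bootstrap: pd.DataFrame | None = None,
    fdr: bool = True,
    meta: dict | None = None,
) -> pd.DataFrame:
    """Write a coefficient table (CSV) and a fit report (JSON) for a BetaFit.

    The table holds term, estimate, SE, optional bootstrap SE/CI, Wald p and
    (with ``fdr``) BH-adjusted q per coefficient; the JSON report carries the
    likelihood, pseudo-R² values, precision, convergence and any caller
    metadata (e.g. seed, bootstrap B).
    """
    table = pd.DataFrame({
        "term": fit.params.index,
        "estimate": fit.params.to_numpy(),
        "se": fit.bse.to_numpy(),
        "p": fit.pvalues.to_numpy(),
    })
    if bootstrap is not None:
        table = table.merge(
            bootstrap.rename_axis("term").reset_index(), on="term", how="left")
    if fdr:
        table["q"] = bh_fdr(table["p"].to_numpy())
    table.to_csv(csv_path, index=False)
    if json_path is not None:
        import json as _json

        report = {
            "log_likelihood": fit.llf,
            "pseudo_r2": fit.pseudo_r2,
            "pseudo_r2_lr": fit.pseudo_r2_lr,
            "precision_phi": fit.phi,
            "converged": fit.converged,
            "n": fit.n,
        }
        report.update(meta or {})
        from pathlib import Path

        Path(json_path).write_text(_json.dumps(report, indent=1))
    return table


def slope_contrast(
    fit: BetaFit,
    slope_term: str,
    modifiers: dict,
    boot_draws: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simple slopes of a moderated effect at chosen moderator levels.

    The slope of ``slope_term`` at moderator level L is the linear combination
    ``beta[slope_term] + sum_t modifiers[L][t] * beta[t]`` over that level's
    interaction terms. Returns per-level slopes and all pairwise differences;
    when ``boot_draws`` (a coefficient table from :func:`cluster_bootstrap`'s
    ``attrs['draws']``) is supplied, percentile CIs are attached to both.
    """
    if slope_term not in fit.params.index:
        raise ValueError(f"{slope_term!r} is not a fitted term")
    levels = list(modifiers)

    def combo(params) -> dict:
        out = {}
        for lev in levels:
            s = params[slope_term]
            for term, w in modifiers[lev].items():
                if term not in params.index:
                    raise ValueError(f"interaction term {term!r} not in fit")
                s = s + w * params[term]
            out[lev] = float(s)
        return out

    slopes = combo(fit.params)
    rows = [{"level": lev, "slope": slopes[lev]} for lev in levels]
    diffs = [{"level_a": a, "level_b": b, "difference": slopes[a] - slopes[b]}
             for i, a in enumerate(levels) for b in levels[i + 1:]]
    slopes_df = pd.DataFrame(rows)
    diffs_df = pd.DataFrame(diffs)
    if boot_draws is not None:
        per_draw = [combo(row) for _, row in boot_draws.iterrows()]
        for lev, col in zip(levels, range(len(levels))):
            vals = np.array([d[lev] for d in per_draw])
            slopes_df.loc[col, "ci_low"] = np.quantile(vals, 0.025)
            slopes_df.loc[col, "ci_high"] = np.quantile(vals, 0.975)
        for idx, row in diffs_df.iterrows():
            vals = np.array([d[row["level_a"]] - d[row["level_b"]]
                             for d in per_draw])
            diffs_df.loc[idx, "ci_low"] = np.quantile(vals, 0.025)
            diffs_df.loc[idx, "ci_high"] = np.quantile(vals, 0.975)
    return slopes_df, diffs_df
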