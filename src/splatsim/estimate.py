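"""Estimate simulation parameters from a real count matrix.

The estimators mirror the simulation hierarchy: a gamma fit to winsorized,
library-size-normalized gene means (mean shape/rate); a closed-form
log-normal fit to raw library sizes; a median + 2*MAD rule for expression
outliers; a profile-likelihood common negative-binomial dispersion with an
affine correction for the common BCV; and a logistic curve fit of per-gene
zero proportions against log mean expression for the dropout parameters.

Conventions fixed here and used throughout: quantiles are linear-interpolation
(type 7); the MAD carries the 1.4826 normal-consistency constant; log-normal
fits use the maximum-likelihood (population, ddof=0) standard deviation.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, gammaln

from .io import CountMatrix
from .params import (
    LunParams,
    SimpleParams,
    SplatParams,
    default_params,
)

__all__ = [
    "normalize_library_size",
    "winsorize",
    "fit_gamma_cvm",
    "estimate_mean_params",
    "estimate_libsize_params",
    "estimate_outlier_params",
    "estimate_common_dispersion",
    "correct_dispersion",
    "fit_dropout_logistic",
    "estimate_dropout_params",
    "splat_estimate",
    "simple_estimate",
    "lun_estimate",
]

#: Fallback outlier-factor parameters used when no outlier gene is detected.
DEFAULT_OUT_LOC = 4.0
DEFAULT_OUT_SCALE = 0.5

#: MAD normal-consistency constant.
MAD_CONSTANT = 1.4826


def _as_matrix(m) -> np.ndarray:
    if isinstance(m, CountMatrix):
        return np.asarray(m.values, dtype=float)
    return np.asarray(m, dtype=float)


def normalize_library_size(m):
    """Rescale every cell to the median library size; drop all-zero genes.

    Returns ``(normalized, reference_size)`` where ``normalized`` is a real
    genes x cells array whose columns each sum to the median of the original
    cell totals.  A cell with zero total is an error (it cannot be rescaled).
    """
    values = _as_matrix(m)
    totals = values.sum(axis=0)
    if np.any(totals <= 0):
        j = int(np.argmax(totals <= 0))
        name = m.cell_ids[j] if isinstance(m, CountMatrix) else f"column {j}"
        raise ValueError(f"cell {name} has zero total count and cannot be normalized")
    reference = float(np.median(totals))
    normalized = values * (reference / totals)
    keep = normalized.sum(axis=1) > 0
    return normalized[keep], reference


def winsorize(values, fraction: float) -> np.ndarray:
    """Clamp both tails of ``values`` to the ``fraction``/``1-fraction`` quantiles.

    Quantiles use linear interpolation (type 7).  ``fraction`` must lie in
    [0, 0.5); 0 is the identity.
    """
    if not (0.0 <= fraction < 0.5):
        raise ValueError(f"fraction must be in [0, 0.5), got {fraction}")
    values = np.asarray(values, dtype=float)
    if fraction == 0.0 or values.size == 0:
        return values.copy()
    lo, hi = np.quantile(values, [fraction, 1.0 - fraction])
    return np.clip(values, lo, hi)


def fit_gamma_cvm(values) -> tuple[float, float]:
    """Fit a gamma distribution by minimum Cramér-von Mises distance.

    Moment-matching initializes (shape, rate); Nelder-Mead then minimizes the
    CvM statistic between the fitted CDF and the empirical CDF.  Minimum-
    distance fitting is far less sensitive than maximum likelihood to the
    point masses that winsorizing places at the clamp values.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 values to fit a gamma distribution")
    mean, var = x.mean(), x.var()
    if var <= 0:
        raise ValueError("values are constant; gamma fit is degenerate")
    emp = (2.0 * np.arange(1, n + 1) - 1.0) / (2.0 * n)

    def cvm(t):
        shape, rate = np.exp(t)
        cdf = stats.gamma.cdf(x, shape, scale=1.0 / rate)
        return 1.0 / (12.0 * n) + np.sum((cdf - emp) ** 2)

    t0 = np.log([mean * mean / var, mean / var])
    res = optimize.minimize(cvm, t0, method="Nelder-Mead",
                            options=dict(xatol=1e-8, fatol=1e-12, maxiter=2000))
    shape, rate = np.exp(res.x)
    return float(shape), float(rate)


def estimate_mean_params(m) -> tuple[float, float]:
    """Gamma (shape, rate) fitted to winsorized normalized gene means.

    Gene means are computed on library-size-normalized counts, the top and
    bottom 10% winsorized to the 10th/90th percentiles, and a gamma fitted by
    minimum CvM distance.
    """
    normalized, _ = normalize_library_size(m)
    if normalized.shape[0] < 10:
        raise ValueError("need at least 10 non-zero genes to fit mean parameters")
    means = normalized.mean(axis=1)
    if np.ptp(means) == 0:
        raise ValueError("gene means are constant; gamma fit is degenerate")
    return fit_gamma_cvm(winsorize(means, 0.1))


def estimate_libsize_params(m) -> tuple[float, float]:
    """Closed-form log-normal MLE for the unnormalized library sizes.

    Returns ``(lib_loc, lib_scale)``: the mean and population (ddof=0)
    standard deviation of the log cell totals.
    """
    values = _as_matrix(m)
    if values.shape[1] < 2:
        raise ValueError("need at least 2 cells to fit library sizes")
    totals = values.sum(axis=0)
    if np.any(totals <= 0):
        j = int(np.argmax(totals <= 0))
        raise ValueError(f"cell column {j} has zero total count")
    logs = np.log(totals)
    return float(logs.mean()), float(logs.std(ddof=0))


def estimate_outlier_params(m) -> tuple[float, float, float]:
    """Outlier probability and log-normal inflation-factor parameters.

    A gene is an expression outlier when its normalized mean exceeds
    median + 2 * MAD (MAD with the 1.4826 consistency constant).  The
    probability is the detected fraction; (loc, scale) come from a log-normal
    fit to outlier-mean / median ratios.  With no (or a single) outlier the
    factor parameters fall back to documented defaults.
    """
    normalized, _ = normalize_library_size(m)
    means = normalized.mean(axis=1)
    med = float(np.median(means))
    mad = MAD_CONSTANT * float(np.median(np.abs(means - med)))
    outliers = means > med + 2.0 * mad
    out_prob = float(outliers.mean())
    if outliers.sum() == 0 or med <= 0:
        return 0.0, DEFAULT_OUT_LOC, DEFAULT_OUT_SCALE
    ratios = means[outliers] / med
    logs = np.log(ratios)
    out_loc = float(logs.mean())
    out_scale = float(logs.std(ddof=0)) if logs.size > 1 else DEFAULT_OUT_SCALE
    return out_prob, out_loc, out_scale


def _nb_profile_nll(y: np.ndarray, mu: np.ndarray):
    """Negative log-likelihood of a shared NB dispersion with plug-in means."""

    def nll(log_d: float) -> float:
        r = np.exp(-log_d)  # r = 1/dispersion
        p = r / (r + mu)
        ll = (
            gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
            + r * np.log(p) + y * np.log1p(-p)
        )
        return -float(ll.sum())

    return nll


def estimate_common_dispersion(m, lower: float = 1e-6, upper: float = 10.0) -> float:
    """Shared NB dispersion by profile likelihood on normalized counts.

    Gene means are fixed at their observed normalized means and a single
    dispersion maximizes the summed negative-binomial log-likelihood over a
    bounded search in [``lower``, ``upper``].  The likelihood uses the
    continuous (gamma-function) extension so real-valued normalized counts
    are handled directly.
    """
    values = _as_matrix(m)
    if values.shape[1] < 2:
        raise ValueError("need at least 2 cells to estimate a dispersion")
    if values.sum() == 0:
        raise ValueError("all-zero matrix; dispersion is undefined")
    normalized, _ = normalize_library_size(m)
    mu = np.maximum(normalized.mean(axis=1, keepdims=True), 1e-12)
    nll = _nb_profile_nll(normalized, mu)
    res = optimize.minimize_scalar(
        nll, bounds=(np.log(lower), np.log(upper)), method="bounded",
        options=dict(xatol=1e-8),
    )
    return float(np.exp(res.x))


def correct_dispersion(raw: float) -> float:
    """Affine correction from a raw common-dispersion estimate to the common BCV.

    ``bcv_common = 0.1 + 0.25 * raw``; raw must be non-negative.
    """
    if raw < 0:
        raise ValueError(f"raw dispersion must be >= 0, got {raw}")
    return 0.1 + 0.25 * raw


def fit_dropout_logistic(log_means, zero_props) -> tuple[float, float]:
    """Least-squares fit of ``p_zero = 1 / (1 + exp(k * (x - x0)))``.

    The midpoint is initialized at the log mean closest to a 50% zero
    proportion, the shape at 1.  Returns ``(dropout_mid, dropout_shape)``.
    """
    x = np.asarray(log_means, dtype=float)
    p_zero = np.asarray(zero_props, dtype=float)
    if x.size != p_zero.size or x.size < 3:
        raise ValueError("need matching log_means/zero_props with at least 3 genes")
    if np.unique(p_zero).size < 2:
        raise ValueError("zero proportions are constant; dropout fit is degenerate")

    def curve(x, x0, k):
        return expit(-k * (x - x0))

    x0_init = float(x[np.argmin(np.abs(p_zero - 0.5))])
    try:
        popt, _ = optimize.curve_fit(curve, x, p_zero, p0=(x0_init, 1.0), maxfev=10000)
    except RuntimeError as err:  # pragma: no cover - pathological data
        raise RuntimeError(f"dropout logistic fit did not converge: {err}") from err
    return float(popt[0]), float(popt[1])


def estimate_dropout_params(m):
    """Fit the logistic dropout curve to a count matrix's zero pattern.

    For each gene the natural-log mean of the normalized counts is paired
    with its fraction of zero cells and passed to
    :func:`fit_dropout_logistic`.  Returns ``(dropout_mid, dropout_shape)``,
    or None (the documented "dropout not estimable" sentinel) when the
    matrix contains no zeros at all.
    """
    values = _as_matrix(m)
    if (values == 0).sum() == 0:
        return None
    normalized, _ = normalize_library_size(m)
    if normalized.shape[0] < 10:
        raise ValueError("need at least 10 non-zero genes to fit dropout parameters")
    x = np.log(np.maximum(normalized.mean(axis=1), 1e-12))
    p_zero = (normalized == 0).mean(axis=1)
    return fit_dropout_logistic(x, p_zero)


# ---------------------------------------------------------------------------
# composite estimators


def _require_matrix(m) -> CountMatrix:
    if not isinstance(m, CountMatrix):
        m = CountMatrix(np.asarray(m))
    if m.n_genes < 2 or m.n_cells < 2:
        raise ValueError("estimation needs at least 2 genes and 2 cells")
    return m


def splat_estimate(m) -> SplatParams:
    """Estimate every estimable splat parameter from a count matrix.

    Runs all the estimators above; sets ``n_genes``/``n_cells`` from the
    matrix shape and tags estimated fields ``provenance="estimated"``.
    Group/batch/path structure and ``bcv_df`` cannot be estimated and stay at
    their defaults.  Only counts are used; identifiers and any annotations
    are ignored.
    """
    m = _require_matrix(m)
    p = default_params("splat")

    estimated: dict = {"n_genes": m.n_genes, "n_cells": m.n_cells}
    try:
        estimated["mean_shape"], estimated["mean_rate"] = estimate_mean_params(m)
    except ValueError as err:
        raise ValueError(f"mean_shape/mean_rate estimation failed: {err}") from err
    try:
        estimated["lib_loc"], estimated["lib_scale"] = estimate_libsize_params(m)
    except ValueError as err:
        raise ValueError(f"lib_loc/lib_scale estimation failed: {err}") from err
    out_prob, out_loc, out_scale = estimate_outlier_params(m)
    estimated.update(out_prob=out_prob, out_loc=out_loc, out_scale=out_scale)
    raw = estimate_common_dispersion(m)
    estimated["bcv_common"] = correct_dispersion(raw)
    dropout = estimate_dropout_params(m)

    for name, value in estimated.items():
        setattr(p, name, value)
        p.provenance[name] = "estimated"
    if dropout is not None:
        p.dropout_mid, p.dropout_shape = dropout
        p.provenance["dropout_mid"] = "estimated"
        p.provenance["dropout_shape"] = "estimated"
    else:
        warnings.warn("matrix has no zeros; dropout parameters are not estimable "
                      "and keep their defaults", stacklevel=2)
    p.batch_cells = [m.n_cells]  # structural, not estimated
    return p


def simple_estimate(m) -> SimpleParams:
    """Estimate the simple model's gamma means and NB dispersion."""
    m = _require_matrix(m)
    p = default_params("simple")
    p.n_genes, p.n_cells = m.n_genes, m.n_cells
    p.mean_shape, p.mean_rate = estimate_mean_params(m)
    p.dispersion = estimate_common_dispersion(m)
    for name in ("n_genes", "n_cells", "mean_shape", "mean_rate", "dispersion"):
        p.provenance[name] = "estimated"
    return p


def lun_estimate(m) -> LunParams:
    """Estimate the Lun model's gamma mean parameters (its only estimable ones)."""
    m = _require_matrix(m)
    p = default_params("lun")
    p.n_genes, p.n_cells = m.n_genes, m.n_cells
    p.mean_shape, p.mean_rate = estimate_mean_params(m)
    for name in ("n_genes", "n_cells", "mean_shape", "mean_rate"):
        p.provenance[name] = "estimated"
    return p
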