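"""Additive-noise-model (ANM) causal discovery.

Assumes Y = f(X) + eps with eps independent of X. The generating
function is fitted nonparametrically in both directions (penalized
cubic B-spline GAM, smoothing chosen by GCV) and the residuals are
tested for independence from the putative cause with the Hilbert-
Schmidt independence criterion (HSIC, Gaussian kernels, median-
heuristic bandwidths). The direction whose residuals pass the
independence test is the causal one; if both or neither pass, the
result is inconclusive (linear-Gaussian pairs are a known
non-identifiable case).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist
from statsmodels.gam.api import BSplines, GLMGam
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .data_model import CausalVerdict, PairedSample
from .errors import ConfigurationError, DegenerateInputError

logger = logging.getLogger(__name__)

__all__ = ["AdditiveFit", "ANMResult", "fit_additive_model",
           "hsic_statistic", "hsic_pvalue", "anm_direction"]

_ALPHA_GRID = np.logspace(-4.0, 6.0, 15)


@dataclass
class AdditiveFit:
    direction: str
    fitted_values: np.ndarray
    residuals: np.ndarray
    smoothing_info: dict = field(default_factory=dict)


@dataclass
class ANMResult:
    fit_xy: AdditiveFit
    fit_yx: AdditiveFit
    hsic_xy: float
    hsic_yx: float
    p_xy: float
    p_yx: float
    alpha: float


def fit_additive_model(predictor, response, direction: str = "x_to_y") -> AdditiveFit:
    """Penalized-spline regression of ``response`` on ``predictor``.

    Cubic B-splines with basis size min(10, #distinct - 1); the penalty
    weight is selected by generalized cross-validation over a fixed
    log-spaced grid, so the fit is deterministic given the data. With
    fewer than 5 distinct predictor values the basis degenerates and a
    low-order polynomial fit is used instead (logged).
    """
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(response, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("predictor and response must be equal-length 1-d vectors")
    n = len(x)
    distinct = np.unique(x).size
    if distinct < 2:
        raise DegenerateInputError("constant predictor")
    if n < 30:
        logger.warning("ANM regression on n=%d < 30: results may be unstable", n)
    if distinct < 10:
        logger.warning("predictor has only %d distinct values; basis reduced", distinct)

    basis_size = min(10, distinct - 1)
    if basis_size < 5:
        # too few distinct values for a cubic spline basis: polynomial fallback
        deg = min(3, distinct - 1)
        coefs = np.polynomial.polynomial.polyfit(x, y, deg)
        fitted = np.polynomial.polynomial.polyval(x, coefs)
        fitted += (y - fitted).mean()  # center residuals exactly
        return AdditiveFit(direction, fitted, y - fitted,
                           {"basis": "polynomial", "basis_size": deg + 1,
                            "alpha": 0.0, "edf": deg + 1})

    bs = BSplines(x, df=[basis_size], degree=[3], include_intercept=False)
    intercept = np.ones((n, 1))
    best = None
    for alpha in _ALPHA_GRID:
        try:
            with np.errstate(invalid="ignore"):  # extreme penalties: harmless sqrt warnings
                res = GLMGam(y, exog=intercept, smoother=bs, alpha=alpha).fit()
        except PerfectSeparationError:
            # (near-)noiseless response inside the spline span; the
            # unpenalized basis regression is the exact answer
            design = np.column_stack([intercept, bs.basis])
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            fitted = design @ beta
            return AdditiveFit(direction, fitted, y - fitted,
                               {"basis": "cubic_bspline", "basis_size": basis_size,
                                "alpha": 0.0, "edf": float(design.shape[1]),
                                "note": "unpenalized (perfect fit)"})
        rss = float(np.sum((y - res.fittedvalues) ** 2))
        with np.errstate(invalid="ignore"):  # edf is lazy; same harmless sqrt
            edf = float(np.sum(res.edf))
        gcv = n * rss / (n - edf) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, alpha, res, edf)
    _, alpha_opt, res, edf = best
    fitted = np.asarray(res.fittedvalues)
    return AdditiveFit(direction, fitted, y - fitted,
                       {"basis": "cubic_bspline", "basis_size": basis_size,
                        "alpha": float(alpha_opt), "edf": edf, "gcv": best[0]})


# ---------------------------------------------------------------------------
# HSIC


def _gaussian_kernel(v: np.ndarray, bandwidth) -> np.ndarray:
    d = np.abs(v[:, None] - v[None, :])
    if bandwidth == "median_heuristic":
        off = d[~np.eye(len(v), dtype=bool)]
        sigma = float(np.median(off))
        if sigma == 0.0:
            raise DegenerateInputError("median pairwise distance is zero (all ties)")
    else:
        sigma = float(bandwidth)
        if sigma <= 0:
            raise ConfigurationError("fixed bandwidth must be positive")
    return np.exp(-(d ** 2) / (2.0 * sigma ** 2)), sigma


def _centered_kernels(u, v, bandwidth):
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ConfigurationError("u and v must be equal-length 1-d vectors")
    n = len(u)
    if n < 10:
        raise ConfigurationError("HSIC needs at least 10 observations")
    bu, bv = bandwidth if isinstance(bandwidth, tuple) else (bandwidth, bandwidth)
    K, su = _gaussian_kernel(u, bu)
    L, sv = _gaussian_kernel(v, bv)
    Kc = K - K.mean(axis=0, keepdims=True) - K.mean(axis=1, keepdims=True) + K.mean()
    Lc = L - L.mean(axis=0, keepdims=True) - L.mean(axis=1, keepdims=True) + L.mean()
    return K, L, Kc, Lc, n


def hsic_statistic(u, v, bandwidth="median_heuristic") -> float:
    """Biased V-statistic HSIC scaled by n: n * HSIC_b = trace(KHLH)/n.

    Gaussian kernels on both inputs; widths from the median pairwise
    distance unless a fixed bandwidth (or a (bw_u, bw_v) tuple) is given.
    Translation-invariant in either argument.
    """
    _, _, Kc, Lc, n = _centered_kernels(u, v, bandwidth)
    return float(np.sum(Kc * Lc) / n)


def hsic_pvalue(u, v, method: str = "gamma", n_perm: int = 1000,
                seed: int = 0, bandwidth="median_heuristic") -> float:
    """P-value for the HSIC independence test.

    ``permutation``: fraction of permuted statistics at least as large as
    the observed one, with (count + 1)/(n_perm + 1) smoothing.
    ``gamma``: moment-matched gamma approximation to the permutation null
    (fast, no randomness).
    """
    K, L, Kc, Lc, n = _centered_kernels(u, v, bandwidth)
    stat = float(np.sum(Kc * Lc) / n)

    if method == "permutation":
        if n_perm < 100:
            raise ConfigurationError("n_perm must be at least 100")
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            idx = rng.permutation(n)
            perm_stat = float(np.sum(Kc[np.ix_(idx, idx)] * Lc) / n)
            if perm_stat >= stat:
                count += 1
        return (count + 1) / (n_perm + 1)

    if method == "gamma":
        # moment matching of the null distribution of n * HSIC_b
        var_term = (Kc * Lc / 6.0) ** 2
        var_hsic = (var_term.sum() - np.trace(var_term)) / (n * (n - 1))
        var_hsic *= 72.0 * (n - 4) * (n - 5) / (n * (n - 1) * (n - 2) * (n - 3))
        K0 = K - np.diag(np.diag(K))
        L0 = L - np.diag(np.diag(L))
        mu_x = K0.sum() / (n * (n - 1))
        mu_y = L0.sum() / (n * (n - 1))
        m_hsic = (1.0 + mu_x * mu_y - mu_x - mu_y) / n
        if var_hsic <= 0 or m_hsic <= 0:
            return 1.0
        shape = m_hsic ** 2 / var_hsic
        scale = n * var_hsic / m_hsic
        return float(gamma_dist.sf(stat, a=shape, scale=scale))

    raise ConfigurationError(f"unknown p-value method {method!r}")


def anm_direction(sample: PairedSample, alpha: float = 0.05,
                  pvalue_method: str = "gamma", n_perm: int = 1000,
                  seed: int = 0) -> CausalVerdict:
    """Fit both directions and test residual independence each way.

    Decision at level ``alpha``: residuals independent of the predictor
    in exactly one direction -> that direction; otherwise inconclusive.
    Both p-values are always reported.
    """
    fit_xy = fit_additive_model(sample.x, sample.y, "x_to_y")
    fit_yx = fit_additive_model(sample.y, sample.x, "y_to_x")
    kw = {"method": pvalue_method, "n_perm": n_perm}
    p_xy = hsic_pvalue(sample.x, fit_xy.residuals, seed=seed, **kw)
    p_yx = hsic_pvalue(sample.y, fit_yx.residuals, seed=seed + 1, **kw)
    s_xy = hsic_statistic(sample.x, fit_xy.residuals)
    s_yx = hsic_statistic(sample.y, fit_yx.residuals)

    if p_xy > alpha and p_yx <= alpha:
        direction = "x_causes_y"
    elif p_yx > alpha and p_xy <= alpha:
        direction = "y_causes_x"
    else:
        direction = "inconclusive"

    result = ANMResult(fit_xy, fit_yx, s_xy, s_yx, p_xy, p_yx, alpha)
    verdict = CausalVerdict(
        method="anm",
        direction=direction,
        statistics={"hsic_xy": s_xy, "hsic_yx": s_yx},
        p_values={"p_xy": p_xy, "p_yx": p_yx},
        diagnostics=(f"x={sample.x_name}, y={sample.y_name}, n={len(sample)}, "
                     f"pvalue_method={pvalue_method}, alpha={alpha}"),
    )
    verdict.anm_result = result
    return verdict
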