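"""Multivariable MR: joint direct effects of several exposures on one outcome.

The instrument-outcome effects are regressed on the J x K matrix of
instrument-exposure effects (no intercept for IVW, free intercept for the
Egger variant) with weights 1/sigma_y^2 and multiplicative random-effects
SE inflation floored at 1, mirroring the univariable estimators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .estimators import Z95
from .sumstats import HarmonizedSet


@dataclass
class MvmrResult:
    method: str
    exposure_names: tuple
    theta_hat: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pval: np.ndarray
    n_snp: int
    cond_f: np.ndarray
    q: float
    q_df: int
    q_pval: float
    egger_intercept: Optional[float] = None
    egger_intercept_se: Optional[float] = None
    egger_intercept_pval: Optional[float] = None


def conditional_f(h: HarmonizedSet) -> np.ndarray:
    """Conditional instrument-strength F per exposure.

    Exposure k's instrument effects are regressed on the other exposures'
    effects (weights 1/sigma_xk^2); F_cond = Q_resid / (J - K + 1).  With a
    single exposure this is the ordinary mean F.  Cross-exposure sampling
    covariance is ignored (summary-data approximation).
    """
    G = h.gamma
    S = h.sigma_x
    J, K = G.shape
    out = np.empty(K)
    for k in range(K):
        w = 1.0 / S[:, k] ** 2
        y = G[:, k]
        others = np.delete(G, k, axis=1)
        if others.shape[1]:
            sw = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(sw[:, None] * others, sw * y, rcond=None)
            resid = y - others @ coef
        else:
            resid = y
        q = float(np.sum(w * resid**2))
        out[k] = q / (J - K + 1)
    return out


def _fit(h: HarmonizedSet, intercept: bool, method: str) -> MvmrResult:
    import statsmodels.api as sm

    G = h.gamma.copy()
    Y = h.Gamma.copy()
    J, K = G.shape
    min_snp = K + (2 if intercept else 1)
    if J < min_snp:
        raise ValueError(f"{method} needs >= {min_snp} SNPs for {K} exposures, got {J}")
    if intercept:
        # orient rows so the first exposure's effects are non-negative
        flip = np.where(G[:, 0] < 0, -1.0, 1.0)
        G = G * flip[:, None]
        Y = Y * flip
    w = 1.0 / h.sigma_y**2
    # exposures with no instrument signal at all (all-zero column) carry no
    # information: excluded from the fit, reported with a null coefficient
    live = np.nonzero(np.any(G != 0, axis=0))[0]
    G_fit = G[:, live]
    X = sm.add_constant(G_fit) if intercept else G_fit
    if np.linalg.matrix_rank(np.sqrt(w)[:, None] * X) < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"collinear exposures in MVMR: {h.exposure_names}")
    fit = sm.WLS(Y, X, weights=w).fit()
    q = float(np.sum(w * fit.resid**2))
    df = J - X.shape[1]
    infl = np.sqrt(max(1.0, q / df)) if df > 0 else 1.0
    se_all = np.sqrt(np.diag(fit.normalized_cov_params)) * infl
    params = np.asarray(fit.params)
    if intercept:
        inter, theta_live = params[0], params[1:]
        se_inter, se_live = se_all[0], se_all[1:]
        p_inter = float(2 * stats.t.sf(abs(inter) / se_inter, df))
    else:
        theta_live, se_live = params, se_all
        inter = se_inter = p_inter = None
    theta = np.zeros(K)
    se = np.full(K, np.inf)
    theta[live] = theta_live
    se[live] = se_live
    pval = np.ones(K)
    pval[live] = 2 * stats.norm.sf(np.abs(theta_live) / se_live)
    res = MvmrResult(
        method=method, exposure_names=h.exposure_names,
        theta_hat=theta, se=se,
        ci_low=theta - Z95 * se, ci_high=theta + Z95 * se,
        pval=pval, n_snp=J, cond_f=conditional_f(h),
        q=q, q_df=df, q_pval=float(stats.chi2.sf(q, df)) if df > 0 else 1.0)
    if intercept:
        res.egger_intercept = float(inter)
        res.egger_intercept_se = float(se_inter)
        res.egger_intercept_pval = p_inter
    return res


def mvmr_ivw(h: HarmonizedSet) -> MvmrResult:
    """Multivariable IVW: through-origin weighted regression of Gamma on the
    exposure-effect matrix; coefficients are direct effects."""
    return _fit(h, intercept=False, method="mvmr_ivw")


def mvmr_egger(h: HarmonizedSet) -> MvmrResult:
    """Multivariable Egger: as IVW with a free intercept reported as the
    directional-pleiotropy diagnostic."""
    return _fit(h, intercept=True, method="mvmr_egger")
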