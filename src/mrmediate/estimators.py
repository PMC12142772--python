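"""Univariable two-sample MR estimators and sensitivity diagnostics.

All estimators consume a single-exposure :class:`~mrmediate.sumstats.HarmonizedSet`
with per-SNP exposure effects ``gamma`` (SE ``sigma_x``) and outcome effects
``Gamma`` (SE ``sigma_y``).  Inverse-variance weighting uses multiplicative
random effects: the fixed-effect SE is inflated by sqrt(max(1, Q/df)) so
heterogeneity can widen but never narrow the interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .sumstats import HarmonizedSet

Z95 = float(stats.norm.ppf(0.975))


@dataclass
class MRResult:
    """A causal estimate with its diagnostics."""

    method: str
    theta_hat: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    q: Optional[float] = None
    q_df: Optional[int] = None
    q_pval: Optional[float] = None
    egger_intercept: Optional[float] = None
    egger_intercept_se: Optional[float] = None
    egger_intercept_pval: Optional[float] = None

    def odds_ratio(self):
        """(OR, 95% CI) on the exp scale, for binary outcomes."""
        return beta_to_or(self.theta_hat, self.se)


def _normal_result(method, theta, se, n_snp, **diag) -> MRResult:
    p = 2.0 * stats.norm.sf(abs(theta) / se) if se > 0 else (1.0 if theta == 0 else 0.0)
    return MRResult(method, float(theta), float(se),
                    float(theta - Z95 * se), float(theta + Z95 * se),
                    float(min(max(p, np.nextafter(0, 1)), 1.0)), n_snp, **diag)


def wald_ratio(gamma: float, sigma_x: float, Gamma: float, sigma_y: float) -> MRResult:
    """Single-SNP causal estimate Gamma/gamma with first-order SE sigma_y/|gamma|."""
    if gamma == 0:
        raise ZeroDivisionError("Wald ratio undefined for gamma = 0")
    theta = Gamma / gamma
    se = sigma_y / abs(gamma)
    return _normal_result("wald", theta, se, 1)


def ivw(h: HarmonizedSet) -> MRResult:
    """Random-effects inverse-variance-weighted estimate.

    Weighted through-origin regression of Gamma on gamma with weights
    1/sigma_y^2; for a single SNP this reduces exactly to the Wald ratio.
    """
    g, sx, G, sy = h._single()
    J = len(g)
    if J == 0:
        raise ValueError("empty instrument set")
    w = 1.0 / sy**2
    denom = float(np.sum(w * g * g))
    theta = float(np.sum(w * g * G)) / denom
    se_fe = np.sqrt(1.0 / denom)
    if J >= 2:
        q = float(np.sum(w * (G - theta * g) ** 2))
        scale = np.sqrt(max(1.0, q / (J - 1)))
        return _normal_result("ivw_re", theta, se_fe * scale, J,
                              q=q, q_df=J - 1,
                              q_pval=float(stats.chi2.sf(q, J - 1)))
    return _normal_result("ivw_re", theta, se_fe, 1)


def _orient(g, sx, G, sy):
    """Flip rows so all exposure effects are non-negative (Egger convention)."""
    flip = np.where(g < 0, -1.0, 1.0)
    return g * flip, sx, G * flip, sy


def mr_egger(h: HarmonizedSet) -> MRResult:
    """MR-Egger weighted regression with a free (pleiotropy) intercept.

    Instruments are oriented to non-negative gamma before fitting; slope and
    intercept use t reference with J-2 df and multiplicative random-effects
    inflation floored at 1.
    """
    import statsmodels.api as sm

    g, sx, G, sy = _orient(*h._single())
    J = len(g)
    if J < 3:
        raise ValueError(f"MR-Egger needs >= 3 SNPs, got {J}")
    w = 1.0 / sy**2
    X = sm.add_constant(g)
    fit = sm.WLS(G, X, weights=w).fit()
    q = float(np.sum(w * fit.resid**2))
    df = J - 2
    # fixed-effect covariance is (X'WX)^-1; inflate by max(1, Q/df)
    se_fe = np.sqrt(np.diag(fit.normalized_cov_params))
    infl = np.sqrt(max(1.0, q / df))
    inter, slope = fit.params
    se_inter, se_slope = se_fe * infl
    p_slope = 2.0 * stats.t.sf(abs(slope) / se_slope, df)
    p_inter = 2.0 * stats.t.sf(abs(inter) / se_inter, df)
    tcrit = float(stats.t.ppf(0.975, df))
    return MRResult("egger", float(slope), float(se_slope),
                    float(slope - tcrit * se_slope), float(slope + tcrit * se_slope),
                    float(p_slope), J,
                    q=q, q_df=df, q_pval=float(stats.chi2.sf(q, df)),
                    egger_intercept=float(inter),
                    egger_intercept_se=float(se_inter),
                    egger_intercept_pval=float(p_inter))


def _weighted_median_rows(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted median with interpolation at cumulative weight 0.5."""
    ratios = np.atleast_2d(ratios)
    weights = np.atleast_2d(weights)
    order = np.argsort(ratios, axis=1)
    r = np.take_along_axis(ratios, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    w = w / w.sum(axis=1, keepdims=True)
    cs = np.cumsum(w, axis=1) - 0.5 * w
    idx = (cs < 0.5).sum(axis=1)
    J = r.shape[1]
    out = np.empty(len(r))
    lo_edge = idx == 0
    hi_edge = idx == J
    out[lo_edge] = r[lo_edge, 0]
    out[hi_edge] = r[hi_edge, -1]
    mid = ~(lo_edge | hi_edge)
    if mid.any():
        i = idx[mid]
        rows = np.nonzero(mid)[0]
        c_lo = cs[rows, i - 1]
        c_hi = cs[rows, i]
        r_lo = r[rows, i - 1]
        r_hi = r[rows, i]
        out[mid] = r_lo + (r_hi - r_lo) * (0.5 - c_lo) / (c_hi - c_lo)
    return out


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted-median estimator with parametric-bootstrap SE.

    Consistent when >= 50% of the total inverse-variance weight comes from
    valid instruments.  The SE comes from a parametric bootstrap with the
    stated SEs: exposure effects are resampled about their observed values
    and outcome effects about the fitted ratio line ``theta_hat * gamma``.
    Centring the outcome draws on the fit rather than on the observed
    ``Gamma`` matters for a median-type statistic: resampling around values
    that already contain sampling scatter convolves the noise twice, which
    flattens the density at the median and inflates the SE by up to ~sqrt(2).
    """
    g, sx, G, sy = h._single()
    J = len(g)
    if J < 3:
        raise ValueError(f"weighted median needs >= 3 SNPs, got {J}")
    ratios = G / g
    weights = g**2 / sy**2
    theta = float(_weighted_median_rows(ratios, weights)[0])
    rng = np.random.default_rng(seed)
    gb = g + sx * rng.standard_normal((n_boot, J))
    Gb = theta * g + sy * rng.standard_normal((n_boot, J))
    boots = _weighted_median_rows(Gb / gb, gb**2 / sy**2)
    se = float(np.std(boots, ddof=1))
    return _normal_result("weighted_median", theta, se, J)


def cochran_q(h: HarmonizedSet, theta: float):
    """Cochran's Q heterogeneity statistic around ``theta`` (IVW weights)."""
    g, sx, G, sy = h._single()
    J = len(g)
    if J < 2:
        raise ValueError("Cochran's Q needs >= 2 SNPs")
    w = g**2 / sy**2
    q = float(np.sum(w * (G / g - theta) ** 2))
    df = J - 1
    return q, df, float(stats.chi2.sf(q, df))


@dataclass
class LooResult:
    """One leave-one-out refit, tagged by the omitted SNP."""

    omitted_snp: str
    result: MRResult
    influential: bool


def leave_one_out(h: HarmonizedSet) -> list:
    """IVW refit omitting each SNP in turn.

    A refit is flagged influential when dropping the SNP changes the sign of
    the estimate or moves its p-value across 0.05.
    """
    if h.n_snp < 2:
        raise ValueError("leave-one-out needs >= 2 SNPs")
    full = ivw(h)
    out = []
    for j in range(h.n_snp):
        idx = np.r_[0:j, j + 1:h.n_snp]
        res = ivw(h.subset(idx))
        flag = (np.sign(res.theta_hat) != np.sign(full.theta_hat)
                or (res.pval < 0.05) != (full.pval < 0.05))
        out.append(LooResult(str(h.snp_ids[j]), res, bool(flag)))
    return out


def beta_to_or(theta: float, se: float):
    """Exponentiate a log-odds effect to an odds ratio with 95% CI."""
    if se < 0:
        raise ValueError("se must be >= 0")
    return (float(np.exp(theta)),
            float(np.exp(theta - Z95 * se)),
            float(np.exp(theta + Z95 * se)))
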