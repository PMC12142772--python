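"""Two-step MR mediation: mediator screening, product-of-coefficients
mediated effects with delta-method SEs, and BH-FDR evidence grading.

The mediated effect of exposure X on outcome Y through mediator M is
``beta1 * beta2`` where beta1 is the X->M effect (univariable MR) and beta2
the M->Y effect adjusted for X (the mediator's multivariable-MR coefficient).
Dividing by the total X->Y effect gives the mediated proportion.  Because the
two coefficients come from non-overlapping samples their sampling covariance
is taken as zero in the delta expansion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .estimators import MRResult, Z95, ivw
from .mvmr import mvmr_ivw
from .sumstats import LdMatrix, SumStats, clump, harmonize, select_instruments

logger = logging.getLogger(__name__)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def grade_evidence(pval: float, qval: float) -> str:
    """Evidence tier: 'strong' (p<.05 and q<.05), 'indicative' (p<.05,
    q>=.05), else 'none'."""
    if not (0 <= pval <= 1 and 0 <= qval <= 1):
        raise ValueError("pval and qval must lie in [0,1]")
    if pval < 0.05:
        return "strong" if qval < 0.05 else "indicative"
    return "none"


@dataclass
class MediationResult:
    """Mediated effect and proportion for one mediator."""

    mediator_name: str
    beta1: float          # exposure -> mediator
    se1: float
    beta2: float          # mediator -> outcome, adjusted for the exposure
    se2: float
    beta_total: float     # total exposure -> outcome
    se_total: float
    mediated_effect: float
    mediated_se: float
    proportion: float
    proportion_se: float
    ci_low: float
    ci_high: float
    pval: float
    qval: Optional[float] = None
    tier: Optional[str] = None
    selected: Optional[bool] = None
    reasons: tuple = ()
    beta2_unadjusted: Optional[float] = None  # UVMR mediator->outcome, for transparency


def mediation_effect(beta1: float, se1: float, beta2: float, se2: float,
                     beta_total: float, se_total: float,
                     mediator_name: str = "") -> MediationResult:
    """Product-of-coefficients mediated effect and proportion.

    SE of the product by the delta method (zero covariance):
    ``sqrt(beta2^2 se1^2 + beta1^2 se2^2)``; SE of the proportion by the
    delta expansion of the ratio with the total effect.  Proportions outside
    [0, 1] (inconsistent mediation) are reported with a warning, never
    truncated.
    """
    if beta_total == 0:
        raise ZeroDivisionError("mediated proportion undefined for zero total effect")
    med = beta1 * beta2
    se_med = float(np.sqrt(beta2**2 * se1**2 + beta1**2 * se2**2))
    prop = med / beta_total
    se_prop = float(np.sqrt((se_med / beta_total) ** 2
                            + (med * se_total / beta_total**2) ** 2))
    if not 0 <= prop <= 1:
        logger.warning("%s: mediated proportion %.3f outside [0,1] "
                       "(inconsistent mediation)", mediator_name or "mediator", prop)
    p = float(2 * stats.norm.sf(abs(med) / se_med)) if se_med > 0 else 1.0
    return MediationResult(
        mediator_name=mediator_name,
        beta1=beta1, se1=se1, beta2=beta2, se2=se2,
        beta_total=beta_total, se_total=se_total,
        mediated_effect=float(med), mediated_se=se_med,
        proportion=float(prop), proportion_se=se_prop,
        ci_low=float(prop - Z95 * se_prop), ci_high=float(prop + Z95 * se_prop),
        pval=p)


def screen_mediators(mediator_outcome: Mapping[str, MRResult],
                     exposure_mediator: Mapping[str, MRResult],
                     mediator_exposure: Mapping[str, MRResult],
                     total_sign: float) -> pd.DataFrame:
    """Apply the three mediator-inclusion criteria.

    A candidate passes iff (i) its effect on the outcome reaches at least
    indicative evidence after BH-FDR over the whole candidate family, (ii)
    the exposure affects the mediator (p < .05) with no reverse
    mediator->exposure effect (p >= .05, unidirectionality), and (iii) the
    implied mediated effect beta1*beta2 has the same sign as the total
    effect.  The FDR family for the exposure->mediator step is restricted to
    candidates passing step (i).
    """
    names = list(mediator_outcome)
    p_mo = [mediator_outcome[m].pval for m in names]
    q_mo = bh_fdr(p_mo)
    tier_mo = [grade_evidence(p, q) for p, q in zip(p_mo, q_mo)]

    passers = [m for m, t in zip(names, tier_mo) if t != "none"]
    q_em_map = {}
    if passers:
        q_em = bh_fdr([exposure_mediator[m].pval for m in passers])
        q_em_map = dict(zip(passers, q_em))

    rows = []
    for m, p1, q1, t1 in zip(names, p_mo, q_mo, tier_mo):
        em = exposure_mediator[m]
        rev = mediator_exposure[m]
        reasons = []
        if t1 == "none":
            reasons.append("no_mediator_outcome_effect")
        if em.pval >= 0.05:
            reasons.append("no_exposure_mediator_effect")
        if rev.pval < 0.05:
            reasons.append("bidirectional")
        if np.sign(em.theta_hat * mediator_outcome[m].theta_hat) != np.sign(total_sign):
            reasons.append("direction")
        rows.append({
            "mediator": m,
            "beta_mediator_outcome": mediator_outcome[m].theta_hat,
            "p_mediator_outcome": p1, "q_mediator_outcome": q1, "tier": t1,
            "beta_exposure_mediator": em.theta_hat,
            "p_exposure_mediator": em.pval,
            "q_exposure_mediator": q_em_map.get(m, np.nan),
            "p_reverse": rev.pval,
            "selected": not reasons,
            "reasons": ";".join(reasons),
        })
    return pd.DataFrame(rows)


@dataclass
class TwoStepConfig:
    """Thresholds and tuning for the two-step mediation pipeline."""

    p_threshold_exposure: float = 5e-6
    p_threshold_mediator: float = 5e-6
    clump_r2: float = 0.001
    clump_kb: int = 10_000
    palindrome_eaf_window: float = 0.08
    fdr_alpha: float = 0.05
    seed: int = 0
    exclusion_list: tuple = ()
    ld: Optional[LdMatrix] = None


@dataclass
class TwoStepResult:
    total: MRResult
    screen: pd.DataFrame
    results: list  # MediationResult, ranked by mediated proportion

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.results])


def _instruments(ss: SumStats, cfg: TwoStepConfig, p_threshold: float) -> SumStats:
    inst = select_instruments(ss, p_threshold, cfg.exclusion_list)
    return clump(inst, cfg.ld, cfg.clump_r2, cfg.clump_kb)


def uvmr_between(exposure: SumStats, outcome: SumStats, cfg: TwoStepConfig,
                 p_threshold: float) -> MRResult:
    """Instrument selection + clumping + harmonisation + IVW for one pair."""
    inst = _instruments(exposure, cfg, p_threshold)
    h = harmonize(inst, outcome, cfg.palindrome_eaf_window)
    return ivw(h)


def two_step(exposure: SumStats, outcome: SumStats,
             mediator_panel: Mapping[str, SumStats],
             cfg: TwoStepConfig | None = None) -> TwoStepResult:
    """Run the full two-step mediation procedure over a candidate panel.

    Stage A screens the panel with three univariable MR passes per mediator
    (mediator->outcome, exposure->mediator, mediator->exposure); stage B, for
    each selected mediator, takes beta1 from the exposure->mediator UVMR and
    beta2 from the mediator's coefficient in a multivariable MR of the
    outcome on (exposure, mediator), and forms the mediated proportion
    against the exposure->outcome total effect.  Results are ranked by
    proportion, largest first.
    """
    cfg = cfg or TwoStepConfig()
    total = uvmr_between(exposure, outcome, cfg, cfg.p_threshold_exposure)

    mo, em, rev = {}, {}, {}
    for name, med in mediator_panel.items():
        mo[name] = uvmr_between(med, outcome, cfg, cfg.p_threshold_mediator)
        em[name] = uvmr_between(exposure, med, cfg, cfg.p_threshold_exposure)
        rev[name] = uvmr_between(med, exposure, cfg, cfg.p_threshold_mediator)
    screen = screen_mediators(mo, em, rev, np.sign(total.theta_hat))

    results = []
    selected = screen.loc[screen["selected"], "mediator"].tolist()
    for name in selected:
        med = mediator_panel[name]
        exp_inst = _instruments(exposure, cfg, cfg.p_threshold_exposure)
        med_inst = _instruments(med, cfg, cfg.p_threshold_mediator)
        union_ids = pd.unique(np.concatenate([exp_inst.data["snp"].to_numpy(),
                                              med_inst.data["snp"].to_numpy()]))
        exp_union = exposure.subset(exposure.data["snp"].isin(union_ids).to_numpy())
        med_union = med.subset(med.data["snp"].isin(union_ids).to_numpy())
        h = harmonize([exp_union, med_union], outcome, cfg.palindrome_eaf_window)
        mv = mvmr_ivw(h)
        b1 = em[name]
        res = mediation_effect(b1.theta_hat, b1.se,
                               float(mv.theta_hat[1]), float(mv.se[1]),
                               total.theta_hat, total.se, mediator_name=name)
        res.beta2_unadjusted = mo[name].theta_hat
        results.append(res)

    if results:
        qs = bh_fdr([r.pval for r in results])
        for r, q in zip(results, qs):
            r.qval = float(q)
            r.tier = grade_evidence(r.pval, r.qval)
            r.selected = True
        results.sort(key=lambda r: r.proportion, reverse=True)
    return TwoStepResult(total=total, screen=screen, results=results)
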