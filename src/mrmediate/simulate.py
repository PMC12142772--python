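"""Synthetic GWAS summary statistics from a known causal chain.

Individual-level data are generated for non-overlapping cohorts — one per
GWAS, so between-study error correlation is zero by construction — from the
structural model

    X = sum_j gamma_j g_j + e_x
    M_k = theta_XM,k * X + sum_j delta_kj g_j + e_mk
    Y = sum_k theta_MY,k * M_k + theta_XY_direct * X + sum_j (alpha_j + eta_j) g_j + e_y

where eta carries the outcome's own loci (the reverse-direction instruments)

with genotypes g ~ Binomial(2, maf), optional within-block LD via a Gaussian
copula, and per-SNP horizontal pleiotropy alpha drawn from a configurable
law.  Each cohort is reduced to per-SNP univariable regression summary
statistics in the standard table dialect, so the whole MR pipeline runs on
the output exactly as it would on real GWAS tables.  All traits default to
unit variance; binary traits are produced by thresholding the liability at a
configured prevalence and analysed with a per-SNP logistic score
approximation, emitting effects on the log-odds scale.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import LdMatrix, SumStats

# non-complementary allele pairs: harmonisation never drops these as palindromic
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
                 ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]


@dataclass
class MediatorSpec:
    """One mediator node of the chain: its effects and its own instruments."""

    name: str
    theta_xm: float         # exposure -> mediator
    theta_my: float         # mediator -> outcome (direct, adjusted scale)
    n_snps: int = 20        # mediator-specific instruments
    h2: float = 0.08        # variance explained by its own instruments
    trait_type: str = "continuous"
    prevalence: float = 0.1


@dataclass
class SimConfig:
    """Generative parameters; defaults are the package's study conditions."""

    seed: int = 0
    n_exposure_snps: int = 30
    maf_range: tuple = (0.1, 0.5)
    n_exp: int = 20_000
    n_out: int = 20_000
    n_med: int = 20_000
    h2_exposure: float = 0.10
    n_outcome_snps: int = 20    # outcome-specific loci (reverse-MR instruments)
    h2_outcome: float = 0.08
    theta_xy_direct: float = 0.35
    mediators: tuple = (MediatorSpec("mediator", 0.3, 0.5),)
    pleiotropy: tuple = ("none",)   # | ("balanced", tau) | ("directional", mu, tau)
    ld_blocks: tuple = ()           # ((size, r), ...) over exposure SNPs
    exposure_trait_type: str = "continuous"
    exposure_prevalence: float = 0.1
    outcome_trait_type: str = "continuous"
    outcome_prevalence: float = 0.1

    def __post_init__(self) -> None:
        if min(self.n_exp, self.n_out, self.n_med) < 100:
            raise ValueError("per-GWAS sample sizes must be >= 100")
        if self.n_exposure_snps < 4:
            raise ValueError("need >= 4 exposure instruments")
        for size, r in self.ld_blocks:
            if not abs(r) < 1:
                raise ValueError("within-block AR(1) r must satisfy |r| < 1")
        if sum(s for s, _ in self.ld_blocks) > self.n_exposure_snps:
            raise ValueError("LD blocks exceed the exposure SNP panel")


@dataclass
class SimOutput:
    """Emitted summary statistics plus the generating truth."""

    sumstats: dict            # trait name -> SumStats ("exposure", "outcome", mediators)
    ld: LdMatrix
    truth: dict
    config: SimConfig


def _scaled_effects(rng, mafs, h2):
    """Effect sizes with Sum 2 maf(1-maf) beta^2 = h2."""
    raw = rng.standard_normal(len(mafs))
    var = 2 * mafs * (1 - mafs)
    scale = np.sqrt(h2 / np.sum(var * raw**2))
    return raw * scale


def _draw_genotypes(rng, n, mafs, blocks):
    """Binomial(2, maf) genotypes; within-block correlation via Gaussian copula."""
    P = len(mafs)
    z = rng.standard_normal((n, P))
    start = 0
    for size, r in blocks:
        for j in range(start + 1, start + size):
            z[:, j] = r * z[:, j - 1] + np.sqrt(1 - r**2) * z[:, j]
        start += size
    u = stats.norm.cdf(z)
    p0 = (1 - mafs) ** 2           # P(g=0)
    p01 = 1 - mafs**2              # P(g<=1)
    return (u > p0).astype(np.float64) + (u > p01)


def _gwas_continuous(g, y):
    """Vectorised per-SNP simple linear regression."""
    n = len(y)
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = np.sum(gc * gc, axis=0)
    beta = gc.T @ yc / sxx
    rss = np.sum(yc * yc) - beta**2 * sxx
    se = np.sqrt(rss / (n - 2) / sxx)
    z = beta / se
    pval = 2 * stats.norm.sf(np.abs(z))
    return beta, se, pval


def _gwas_binary(g, y):
    """Per-SNP logistic score approximation; effects on the log-odds scale."""
    mu = y.mean()
    gc = g - g.mean(axis=0)
    sxx = np.sum(gc * gc, axis=0)
    beta = gc.T @ (y - mu) / (mu * (1 - mu) * sxx)
    se = 1.0 / np.sqrt(mu * (1 - mu) * sxx)
    pval = 2 * stats.norm.sf(np.abs(beta / se))
    return beta, se, pval


def _make_table(name, trait_type, snp, chrom, pos, ea, oa, eaf, beta, se, pval, n):
    pval = np.clip(pval, np.nextafter(0, 1), 1.0)
    df = pd.DataFrame({"snp": snp, "chr": chrom, "pos": pos,
                       "effect_allele": ea, "other_allele": oa,
                       "eaf": eaf, "beta": beta, "se": se,
                       "pval": pval, "n": n})
    return SumStats(name, trait_type, df)


def simulate_chain(config: SimConfig) -> SimOutput:
    """Generate one synthetic study: exposure, mediator(s) and outcome GWAS.

    Deterministic for a fixed config (single RNG stream, fixed draw order).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_x = cfg.n_exposure_snps
    med_sizes = [m.n_snps for m in cfg.mediators]
    P = n_x + sum(med_sizes) + cfg.n_outcome_snps

    mafs = rng.uniform(*cfg.maf_range, size=P)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=P)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    snp = np.array([f"rs{i + 1:05d}" for i in range(P)])

    # exposure SNPs on chr 1; each mediator's on its own chromosome.
    # unlinked SNPs sit > 10 Mb apart so only declared LD blocks fall inside
    # the default clump window; block members are 10 kb apart.
    chrom = np.empty(P, dtype=object)
    pos = np.empty(P, dtype=int)
    cursor = 0
    j = 0
    block_members = []
    for size, _ in cfg.ld_blocks:
        base = 1_000_000 + cursor * 20_000_000
        for t in range(size):
            chrom[j] = "1"
            pos[j] = base + t * 10_000
            j += 1
        block_members.append(list(range(j - size, j)))
        cursor += 1
    while j < n_x:
        chrom[j] = "1"
        pos[j] = 1_000_000 + cursor * 20_000_000
        j += 1
        cursor += 1
    for k, size in enumerate(med_sizes):
        for t in range(size):
            chrom[j] = str(2 + k)
            pos[j] = 1_000_000 + t * 20_000_000
            j += 1
    for t in range(cfg.n_outcome_snps):
        chrom[j] = str(2 + len(med_sizes))
        pos[j] = 1_000_000 + t * 20_000_000
        j += 1

    x_idx = np.arange(n_x)
    med_idx = []
    off = n_x
    for size in med_sizes:
        med_idx.append(np.arange(off, off + size))
        off += size
    y_idx = np.arange(off, off + cfg.n_outcome_snps)

    gamma = np.zeros(P)
    gamma[x_idx] = _scaled_effects(rng, mafs[x_idx], cfg.h2_exposure)
    deltas = np.zeros((len(cfg.mediators), P))
    for k, (m, idx) in enumerate(zip(cfg.mediators, med_idx)):
        deltas[k, idx] = _scaled_effects(rng, mafs[idx], m.h2)
    eta = np.zeros(P)
    if cfg.n_outcome_snps:
        eta[y_idx] = _scaled_effects(rng, mafs[y_idx], cfg.h2_outcome)

    law = cfg.pleiotropy
    alpha = np.zeros(P)
    if law[0] == "balanced":
        alpha[x_idx] = rng.normal(0.0, law[1], size=n_x)
    elif law[0] == "directional":
        alpha[x_idx] = rng.normal(law[1], law[2], size=n_x)
    elif law[0] != "none":
        raise ValueError(f"unknown pleiotropy law {law[0]!r}")

    # variance budget (all traits aim at unit variance)
    sd_x = np.sqrt(_require_positive(1.0 - cfg.h2_exposure, "exposure noise"))
    sd_m = [np.sqrt(_require_positive(1.0 - m.theta_xm**2 - m.h2,
                                      f"{m.name} noise"))
            for m in cfg.mediators]
    theta_total = cfg.theta_xy_direct + sum(m.theta_xm * m.theta_my
                                            for m in cfg.mediators)
    h2_alpha = float(np.sum(2 * mafs * (1 - mafs) * alpha**2))
    h2_out = cfg.h2_outcome if cfg.n_outcome_snps else 0.0
    var_y_sys = (theta_total**2
                 + sum(m.theta_my**2 * (1 - m.theta_xm**2) for m in cfg.mediators)
                 + h2_alpha + h2_out)
    sd_y = np.sqrt(_require_positive(1.0 - var_y_sys, "outcome noise"))

    def liabilities(n):
        g = _draw_genotypes(rng, n, mafs, cfg.ld_blocks)
        x = g @ gamma + sd_x * rng.standard_normal(n)
        ms = [m.theta_xm * x + g @ deltas[k] + sd_m[k] * rng.standard_normal(n)
              for k, m in enumerate(cfg.mediators)]
        y = (cfg.theta_xy_direct * x
             + sum(m.theta_my * mk for m, mk in zip(cfg.mediators, ms))
             + g @ (alpha + eta) + sd_y * rng.standard_normal(n))
        return g, x, ms, y

    def gwas(g, pheno, trait_type, prevalence, name, n):
        if trait_type == "binary":
            yb = (pheno > np.quantile(pheno, 1 - prevalence)).astype(float)
            beta, se, pval = _gwas_binary(g, yb)
        else:
            beta, se, pval = _gwas_continuous(g, pheno)
        eaf = g.mean(axis=0) / 2
        return _make_table(name, trait_type, snp, chrom, pos, ea, oa,
                           eaf, beta, se, pval, n)

    tables = {}
    g_exp, x, _, _ = liabilities(cfg.n_exp)
    tables["exposure"] = gwas(g_exp, x, cfg.exposure_trait_type,
                              cfg.exposure_prevalence, "exposure", cfg.n_exp)
    # empirical LD (r^2) from the exposure cohort
    r = np.corrcoef(g_exp, rowvar=False)
    ld = LdMatrix(list(snp), np.clip(r**2, 0.0, 1.0))
    del g_exp

    for k, m in enumerate(cfg.mediators):
        g, _, ms, _ = liabilities(cfg.n_med)
        tables[m.name] = gwas(g, ms[k], m.trait_type, m.prevalence,
                              m.name, cfg.n_med)
        del g
    g, _, _, y = liabilities(cfg.n_out)
    tables["outcome"] = gwas(g, y, cfg.outcome_trait_type,
                             cfg.outcome_prevalence, "outcome", cfg.n_out)
    del g

    truth = {
        "gamma": gamma, "delta": deltas, "alpha": alpha, "eta": eta, "maf": mafs,
        "exposure_snps": list(snp[x_idx]),
        "outcome_snps": list(snp[y_idx]),
        "mediator_snps": {m.name: list(snp[idx])
                          for m, idx in zip(cfg.mediators, med_idx)},
        "ld_block_members": [list(snp[b]) for b in block_members],
        "theta_xy_direct": cfg.theta_xy_direct,
        "theta_xm": {m.name: m.theta_xm for m in cfg.mediators},
        "theta_my": {m.name: m.theta_my for m in cfg.mediators},
        "theta_total": theta_total,
        "proportion": {m.name: m.theta_xm * m.theta_my / theta_total
                       for m in cfg.mediators},
        "outlier_snps": [],
    }
    return SimOutput(tables, ld, truth, cfg)


def _require_positive(v: float, what: str) -> float:
    if v <= 0:
        raise ValueError(f"infeasible variance budget: {what} variance {v:.3f} <= 0")
    return v


def inject_outliers(s: SimOutput, k: int, magnitude: float, seed: int = 0) -> SimOutput:
    """Add ``magnitude * sigma_y`` to the outcome effect of ``k`` random
    exposure instruments (pleiotropic-outlier fixture); ids recorded in truth."""
    J = len(s.truth["exposure_snps"])
    if k >= J:
        raise ValueError("k must be smaller than the exposure instrument count")
    out = copy.deepcopy(s)
    if k == 0 or magnitude == 0:
        out.truth["outlier_snps"] = [] if k == 0 else out.truth["outlier_snps"]
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(J, size=k, replace=False)) if k else []
    ids = [s.truth["exposure_snps"][j] for j in chosen]
    df = out.sumstats["outcome"].data
    mask = df["snp"].isin(ids)
    df.loc[mask, "beta"] = df.loc[mask, "beta"] + magnitude * df.loc[mask, "se"]
    out.truth["outlier_snps"] = ids
    return out


def simulate_summary_instruments(J: int = 50, theta: float = 0.0,
                                 gamma_loc: float = 0.10, gamma_scale: float = 0.05,
                                 sigma_x: float = 0.005, sigma_y: float = 0.05,
                                 pleiotropy: tuple = ("none",),
                                 seed: int | np.random.Generator = 0):
    """Summary-level instrument generator for estimator calibration studies.

    Draws true instrument effects gamma_j ~ N(gamma_loc, gamma_scale^2),
    observes them with error sigma_x, and emits outcome effects
    ``theta * gamma_j + alpha_j`` observed with error sigma_y, where alpha
    follows the pleiotropy law.  Returns a single-exposure HarmonizedSet.

    The defaults keep measurement error in the exposure effects small
    relative to their spread (I2_GX ~ 0.99), the validity condition under
    which MR-Egger's slope is unattenuated.
    """
    from .sumstats import HarmonizedSet

    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    g_true = rng.normal(gamma_loc, gamma_scale, size=J)
    alpha = np.zeros(J)
    if pleiotropy[0] == "balanced":
        alpha = rng.normal(0.0, pleiotropy[1], size=J)
    elif pleiotropy[0] == "directional":
        alpha = np.full(J, pleiotropy[1]) if len(pleiotropy) == 2 else \
            rng.normal(pleiotropy[1], pleiotropy[2], size=J)
    elif pleiotropy[0] != "none":
        raise ValueError(f"unknown pleiotropy law {pleiotropy[0]!r}")
    g_hat = g_true + sigma_x * rng.standard_normal(J)
    G_hat = theta * g_true + alpha + sigma_y * rng.standard_normal(J)
    return HarmonizedSet(("exposure",), "outcome",
                         np.array([f"rs{i + 1:05d}" for i in range(J)]),
                         g_hat, np.full(J, sigma_x),
                         G_hat, np.full(J, sigma_y))
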