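"""GWAS summary-statistics tables, instrument selection, harmonisation and LD clumping.

The central containers are :class:`SumStats` (one trait's per-SNP association
table) and :class:`HarmonizedSet` (an allele-aligned join of one or more
exposures with an outcome, the input to every MR estimator).  Tables are plain
tab-delimited files with a header row and ``NA`` for missing values, the
dialect exported by most GWAS pipelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order of the on-disk dialect
COLUMNS = ["snp", "chr", "pos", "effect_allele", "other_allele",
           "eaf", "beta", "se", "pval", "n"]

_BASES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT[ea] == oa


@dataclass
class SumStats:
    """Per-SNP association summary statistics for a single trait.

    ``beta`` is on the SD scale for continuous traits and the log-odds scale
    for binary ones; ``trait_type`` records which convention applies.
    """

    trait_name: str
    trait_type: str  # "continuous" | "binary"
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous|binary, got {self.trait_type!r}")
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"SumStats missing columns {missing}")
        df = self.data
        if df["snp"].duplicated().any():
            dupes = df.loc[df["snp"].duplicated(), "snp"].tolist()
            raise ValueError(f"duplicate snp ids: {dupes[:5]}")
        if (df["se"] <= 0).any():
            raise ValueError("se must be > 0")
        if ((df["pval"] <= 0) | (df["pval"] > 1)).any():
            raise ValueError("pval must lie in (0, 1]")
        eaf = df["eaf"]
        if ((eaf < 0) | (eaf > 1)).any():
            raise ValueError("eaf must lie in [0, 1] when present")

    @property
    def n_snp(self) -> int:
        return len(self.data)

    def subset(self, mask) -> "SumStats":
        return SumStats(self.trait_name, self.trait_type,
                        self.data.loc[mask].reset_index(drop=True))


def _clean_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Normalise and drop rows violating the container invariants (logged)."""
    n0 = len(df)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper().str.strip()
    for col in ("pos", "eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    snv = (df["effect_allele"].isin(_BASES) & df["other_allele"].isin(_BASES)
           & (df["effect_allele"] != df["other_allele"]))
    if (~snv).any():
        logger.info("dropped %d non-SNV or degenerate-allele rows", int((~snv).sum()))
    ok = (snv
          & df["beta"].notna()
          & (df["se"] > 0)
          & (df["pval"] > 0) & (df["pval"] <= 1)
          & (df["pos"] >= 1)
          & (df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1))))
    df = df.loc[ok]
    dup = df["snp"].duplicated()
    if dup.any():
        logger.info("dropped %d duplicate snp ids (first kept)", int(dup.sum()))
        df = df.loc[~dup]
    dropped = n0 - len(df)
    if dropped:
        logger.info("dropped %d/%d invalid rows", dropped, n0)
    return df.reset_index(drop=True)


def read_sumstats(path, trait_type: str = "continuous",
                  column_map: Mapping[str, str] | None = None,
                  trait_name: str | None = None) -> SumStats:
    """Read a tab-delimited summary-statistics table.

    ``column_map`` maps canonical column names (:data:`COLUMNS`) to the names
    used in the file; unmapped names are taken as-is.  Rows violating the row
    invariants (non-SNV alleles, se<=0, p outside (0,1], ...) are dropped with
    a logged count; a file yielding zero valid rows is an error.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""], dtype={"snp": str})
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        df = df.rename(columns=rename)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    df = _clean_frame(df[COLUMNS].copy())
    df["snp"] = df["snp"].astype(str)
    df["chr"] = df["chr"].astype(str)
    if df.empty:
        raise ValueError(f"{path}: no valid rows after filtering")
    name = trait_name if trait_name is not None else str(path)
    return SumStats(name, trait_type, df)


def write_sumstats(s: SumStats, path) -> None:
    s.data.to_csv(path, sep="\t", index=False, na_rep="NA")


def select_instruments(s: SumStats, p_threshold: float,
                       exclusion_list: Iterable[str] = ()) -> SumStats:
    """Keep genome-wide (or relaxed) significant SNPs, minus a confounder list.

    ``exclusion_list`` holds SNP ids known to act through confounders (the
    role PhenoScanner look-ups play in practice); they are removed regardless
    of p-value.
    """
    if not 0 < p_threshold < 1:
        raise ValueError(f"p_threshold must be in (0,1), got {p_threshold}")
    excl = set(exclusion_list)
    mask = (s.data["pval"] < p_threshold) & ~s.data["snp"].isin(excl)
    n_excl = int((s.data["snp"].isin(excl)).sum())
    if n_excl:
        logger.info("%s: removed %d SNP(s) on the exclusion list", s.trait_name, n_excl)
    out = s.subset(mask)
    if out.n_snp == 0:
        raise ValueError(
            f"no instruments for {s.trait_name!r} at p < {p_threshold:g}")
    return out


@dataclass
class LdMatrix:
    """Squared-correlation (r2) matrix over an ordered SNP panel."""

    snp_ids: list
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = list(self.snp_ids)
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValueError("r2 shape does not match snp_ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ValueError("r2 must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-6):
            raise ValueError("r2 diagonal must be 1")
        if (self.r2 < -1e-12).any() or (self.r2 > 1 + 1e-8).any():
            raise ValueError("r2 entries must lie in [0,1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def lookup(self, a: str, b: str) -> float | None:
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])

    @classmethod
    def from_tsv(cls, path) -> "LdMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(
            path, sep="\t")


def clump(s: SumStats, ld: LdMatrix | None, r2_max: float = 0.001,
          window_kb: int = 10_000) -> SumStats:
    """Greedy LD clumping: keep the most significant SNP per correlated region.

    SNPs are visited in order of ascending p-value; one is accepted iff its r2
    with every already-accepted SNP on the same chromosome within
    ``window_kb`` is below ``r2_max``.  SNP pairs absent from ``ld`` are
    treated as independent (logged), as are cross-chromosome or out-of-window
    pairs.
    """
    if not 0 < r2_max < 1:
        raise ValueError("r2_max must be in (0,1)")
    df = s.data
    order = df.sort_values(["pval", "snp"], kind="mergesort").index
    accepted: list[int] = []
    n_missing = 0
    win = window_kb * 1000
    for i in order:
        ok = True
        for j in accepted:
            if df.at[i, "chr"] != df.at[j, "chr"]:
                continue
            if abs(df.at[i, "pos"] - df.at[j, "pos"]) > win:
                continue
            r2 = ld.lookup(df.at[i, "snp"], df.at[j, "snp"]) if ld is not None else None
            if r2 is None:
                n_missing += 1
                continue  # assumed independent
            if r2 >= r2_max:
                ok = False
                break
        if ok:
            accepted.append(i)
    if n_missing:
        logger.info("%s: %d SNP pair(s) absent from LD matrix, assumed independent",
                    s.trait_name, n_missing)
    keep = df.index.isin(accepted)
    return s.subset(keep)


@dataclass
class HarmonizedSet:
    """Allele-aligned instrument table joining exposures with an outcome.

    ``gamma``/``sigma_x`` are (J, K) instrument-exposure effects and SEs;
    ``Gamma``/``sigma_y`` the (J,) instrument-outcome effects.  After
    harmonisation every effect refers to the same effect allele per SNP.
    """

    exposure_names: tuple
    outcome_name: str
    snp_ids: np.ndarray
    gamma: np.ndarray
    sigma_x: np.ndarray
    Gamma: np.ndarray
    sigma_y: np.ndarray

    def __post_init__(self) -> None:
        self.exposure_names = tuple(self.exposure_names)
        self.snp_ids = np.asarray(self.snp_ids)
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        self.sigma_x = np.atleast_2d(np.asarray(self.sigma_x, dtype=float))
        if self.gamma.shape[0] == 1 and len(self.snp_ids) != 1:
            self.gamma = self.gamma.T
            self.sigma_x = self.sigma_x.T
        self.Gamma = np.asarray(self.Gamma, dtype=float)
        self.sigma_y = np.asarray(self.sigma_y, dtype=float)
        J = len(self.snp_ids)
        if self.gamma.shape != (J, len(self.exposure_names)):
            raise ValueError(f"gamma shape {self.gamma.shape} inconsistent with "
                             f"{J} SNPs x {len(self.exposure_names)} exposures")
        if self.sigma_x.shape != self.gamma.shape:
            raise ValueError("sigma_x shape must match gamma")
        if self.Gamma.shape != (J,) or self.sigma_y.shape != (J,):
            raise ValueError("Gamma/sigma_y must be length-J vectors")
        if (self.sigma_x <= 0).any() or (self.sigma_y <= 0).any():
            raise ValueError("all standard errors must be positive")

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    @property
    def n_exposures(self) -> int:
        return self.gamma.shape[1]

    def _single(self):
        if self.n_exposures != 1:
            raise ValueError("operation requires a single-exposure set")
        return self.gamma[:, 0], self.sigma_x[:, 0], self.Gamma, self.sigma_y

    def subset(self, idx) -> "HarmonizedSet":
        idx = np.asarray(idx)
        return HarmonizedSet(self.exposure_names, self.outcome_name,
                             self.snp_ids[idx], self.gamma[idx], self.sigma_x[idx],
                             self.Gamma[idx], self.sigma_y[idx])

    def to_frame(self) -> pd.DataFrame:
        d = {"snp": self.snp_ids}
        for k, name in enumerate(self.exposure_names):
            d[f"beta__{name}"] = self.gamma[:, k]
            d[f"se__{name}"] = self.sigma_x[:, k]
        d["beta__outcome"] = self.Gamma
        d["se__outcome"] = self.sigma_y
        return pd.DataFrame(d)

    def to_tsv(self, path, outcome_label: str | None = None) -> None:
        df = self.to_frame()
        df.attrs["outcome"] = outcome_label or self.outcome_name
        df.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path, outcome_name: str = "outcome") -> "HarmonizedSet":
        df = pd.read_csv(path, sep="\t")
        names = [c[len("beta__"):] for c in df.columns
                 if c.startswith("beta__") and c != "beta__outcome"]
        gamma = df[[f"beta__{n}" for n in names]].to_numpy()
        sx = df[[f"se__{n}" for n in names]].to_numpy()
        return cls(tuple(names), outcome_name, df["snp"].to_numpy(),
                   gamma, sx, df["beta__outcome"].to_numpy(),
                   df["se__outcome"].to_numpy())


def _align_to_reference(ref: pd.DataFrame, other: pd.DataFrame,
                        palindrome_eaf_window: float,
                        label: str) -> pd.DataFrame:
    """Align ``other``'s effects to ``ref``'s effect alleles (both indexed by snp).

    Returns the aligned subset of ``other`` (columns beta, se, eaf); SNPs that
    cannot be reconciled, and ambiguous palindromic SNPs, are dropped with a
    logged count.
    """
    rows = {}
    n_drop_pal = n_drop_irrec = 0
    for snp in ref.index:
        r = ref.loc[snp]
        o = other.loc[snp]
        rea, roa = r["effect_allele"], r["other_allele"]
        oea, ooa = o["effect_allele"], o["other_allele"]
        sign = None
        if _is_palindromic(rea, roa):
            # strand cannot be told from alleles; use frequency if unambiguous
            if {oea, ooa} != {rea, roa}:
                n_drop_irrec += 1
                continue
            sign = 1.0 if oea == rea else -1.0
            eaf_o = o["eaf"] if sign > 0 else (1.0 - o["eaf"])
            eaf_r = r["eaf"]
            w = palindrome_eaf_window
            if (pd.isna(eaf_r) or pd.isna(eaf_o)
                    or abs(eaf_r - 0.5) <= w or abs(eaf_o - 0.5) <= w
                    or (eaf_r - 0.5) * (eaf_o - 0.5) < 0):
                n_drop_pal += 1
                continue
        else:
            if (oea, ooa) == (rea, roa):
                sign = 1.0
            elif (oea, ooa) == (roa, rea):
                sign = -1.0
            else:
                cea, coa = _COMPLEMENT[oea], _COMPLEMENT[ooa]
                if (cea, coa) == (rea, roa):
                    sign = 1.0
                elif (cea, coa) == (roa, rea):
                    sign = -1.0
                else:
                    n_drop_irrec += 1
                    continue
            eaf_o = o["eaf"] if sign > 0 else (1.0 - o["eaf"])
        rows[snp] = (sign * o["beta"], o["se"], eaf_o)
    if n_drop_pal:
        logger.info("%s: dropped %d ambiguous palindromic SNP(s)", label, n_drop_pal)
    if n_drop_irrec:
        logger.info("%s: dropped %d SNP(s) with irreconcilable alleles", label, n_drop_irrec)
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=["beta", "se", "eaf"])


def harmonize(exposure: SumStats | Sequence[SumStats], outcome: SumStats,
              palindrome_eaf_window: float = 0.08) -> HarmonizedSet:
    """Inner-join exposure(s) with the outcome on snp id and align alleles.

    The first exposure's allele coding is the reference: swapped codings flip
    the effect sign (and eaf -> 1-eaf), strand flips are resolved by
    complementing, and palindromic (A/T, C/G) SNPs are kept only when both
    effect-allele frequencies are outside ``0.5 +- palindrome_eaf_window`` and
    fall on the same side of 0.5.
    """
    exposures = [exposure] if isinstance(exposure, SumStats) else list(exposure)
    ref_ss = exposures[0]
    ref = ref_ss.data.set_index("snp")
    shared = ref.index
    others = [e.data.set_index("snp") for e in exposures[1:]]
    out = outcome.data.set_index("snp")
    for tab in others + [out]:
        shared = shared.intersection(tab.index)
    if len(shared) == 0:
        raise ValueError(
            f"no shared SNPs between {ref_ss.trait_name!r} and {outcome.trait_name!r}")
    ref = ref.loc[shared]
    aligned = [_align_to_reference(ref, tab.loc[shared], palindrome_eaf_window,
                                   label)
               for tab, label in zip(others + [out],
                                     [e.trait_name for e in exposures[1:]]
                                     + [outcome.trait_name])]
    keep = shared
    for a in aligned:
        keep = keep.intersection(a.index)
    if len(keep) == 0:
        raise ValueError("no SNPs survived harmonisation")
    ref = ref.loc[keep]
    gamma = np.column_stack([ref["beta"].to_numpy()]
                            + [a.loc[keep, "beta"].to_numpy() for a in aligned[:-1]])
    sx = np.column_stack([ref["se"].to_numpy()]
                         + [a.loc[keep, "se"].to_numpy() for a in aligned[:-1]])
    out_a = aligned[-1].loc[keep]
    return HarmonizedSet(
        tuple(e.trait_name for e in exposures), outcome.trait_name,
        keep.to_numpy(), gamma, sx,
        out_a["beta"].to_numpy(), out_a["se"].to_numpy())


def f_statistic(h: HarmonizedSet):
    """Per-instrument strength F_j = (gamma_j / se_j)^2 and the mean F.

    Returns ``(per_snp_f, mean_f, weak_flag)``; mean F <= 10 raises the
    conventional weak-instrument flag.
    """
    g, sx, _, _ = h._single()
    f = (g / sx) ** 2
    mean_f = float(f.mean())
    weak = mean_f <= 10.0
    if weak:
        logger.warning("mean F = %.2f <= 10: weak instruments", mean_f)
    return f, mean_f, weak
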