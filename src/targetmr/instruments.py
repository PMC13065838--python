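"""Instrument construction for two-sample MR.

Significance filtering (p < 5e-8, strict), greedy LD clumping (r^2 kept
below 0.001 within 10 Mbp), weak-instrument statistics (F = (beta/se)^2,
instruments with F < 10 removed), MHC exclusion (chr6:28.5-33.5 Mb),
cis-window selection for pQTLs (<= 1 Mbp from the gene's TSS),
protein-altering-variant flagging (the variant or any r^2 > 0.6 proxy),
intragenic intermediate-trait instrument selection, and exposure-outcome
allele harmonization.

Every operation is a pure function of its inputs; filtering decisions are
reported through a per-call drop log and the module logger.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io import GeneAnnotation, LDMatrix

logger = logging.getLogger(__name__)

GW_SIGNIFICANCE = 5e-8
CLUMP_R2 = 0.001
CLUMP_WINDOW_BP = 10_000_000
F_MIN = 10.0
MHC_CHROM = "6"
MHC_LO = 28_500_000
MHC_HI = 33_500_000
CIS_WINDOW_BP = 1_000_000
PAV_PROXY_R2 = 0.6
PALINDROME_EAF_WINDOW = 0.08

_PALINDROMIC_SETS = ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class InstrumentStats:
    """Instrument-strength summary: mean F, total exposure r^2, SNP count."""

    mean_f: float
    total_r2_exp: float
    k: int


@dataclass
class HarmonizedSet:
    """Allele-aligned exposure/outcome pairs forming one MR instrument.

    ``df`` has one row per SNP with columns: variant_id, chrom, pos,
    beta_exp, se_exp, beta_out, se_out, eaf_exp, eaf_out, n_exp, n_out,
    f_stat, r2_exp, r2_out, steiger_keep, pav_flag.
    """

    df: pd.DataFrame
    exposure_id: str = ""
    outcome_id: str = ""
    drop_log: dict[str, int] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.df)

    def subset(self, mask) -> "HarmonizedSet":
        return HarmonizedSet(
            self.df[np.asarray(mask)].reset_index(drop=True),
            self.exposure_id, self.outcome_id, dict(self.drop_log),
        )

    def without_mhc(
        self, chrom: str = MHC_CHROM, lo: int = MHC_LO, hi: int = MHC_HI
    ) -> "HarmonizedSet":
        in_mhc = (
            (self.df["chrom"].astype(str) == str(chrom))
            & (self.df["pos"] >= lo)
            & (self.df["pos"] <= hi)
        )
        return self.subset(~in_mhc)

    def stats(self) -> InstrumentStats:
        return InstrumentStats(
            mean_f=float(self.df["f_stat"].mean()) if self.k else float("nan"),
            total_r2_exp=float(self.df["r2_exp"].sum()),
            k=self.k,
        )


def gw_filter(assocs: pd.DataFrame, p_thresh: float = GW_SIGNIFICANCE) -> pd.DataFrame:
    """Keep genome-wide significant rows (p strictly below the threshold)."""
    kept = assocs[assocs["pval"] < p_thresh].reset_index(drop=True)
    logger.info("gw_filter: kept %d / %d at p < %g", len(kept), len(assocs), p_thresh)
    return kept


def clump(
    assocs: pd.DataFrame,
    ld: LDMatrix,
    r2_thresh: float = CLUMP_R2,
    window_bp: int = CLUMP_WINDOW_BP,
) -> pd.DataFrame:
    """Greedy LD clumping by p-value.

    Repeatedly take the remaining variant with the smallest p as index
    (ties broken by chrom, pos, variant_id) and remove all others on the
    same chromosome within ``window_bp`` whose r^2 with the index is at
    or above ``r2_thresh``. Variants absent from the LD matrix are
    treated as unlinked and logged. The index set is returned sorted by
    genomic position; by construction all pairwise r^2 within a window
    are below the threshold.
    """
    if assocs.empty:
        return assocs.reset_index(drop=True)
    df = assocs.sort_values(
        ["pval", "chrom", "pos", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)
    missing = [v for v in df["variant_id"] if v not in ld._index]
    if missing:
        logger.warning(
            "clump: %d variant(s) absent from LD matrix, treated as unlinked: %s",
            len(missing), ", ".join(missing[:5]),
        )
    alive = np.ones(len(df), dtype=bool)
    chosen: list[int] = []
    chroms = df["chrom"].astype(str).to_numpy()
    poss = df["pos"].to_numpy()
    vids = df["variant_id"].to_numpy()
    for i in range(len(df)):
        if not alive[i]:
            continue
        chosen.append(i)
        near = (
            alive
            & (chroms == chroms[i])
            & (np.abs(poss - poss[i]) <= window_bp)
        )
        near[i] = False
        for j in np.flatnonzero(near):
            r2 = ld.r2(vids[i], vids[j])
            if r2 is not None and r2 >= r2_thresh:
                alive[j] = False
    out = df.iloc[chosen].sort_values(["chrom", "pos", "variant_id"])
    return out.reset_index(drop=True)


def compute_f_r2(beta, se, n):
    """Per-SNP instrument strength: F = (beta/se)^2, r^2 = F/(F + n - 2)."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    n = np.asarray(n, dtype=float)
    f = (beta / se) ** 2
    r2 = f / (f + n - 2.0)
    return f, r2


def filter_weak(hset: HarmonizedSet, f_min: float = F_MIN) -> HarmonizedSet:
    """Drop weak instruments (keep per-SNP F >= f_min, inclusive)."""
    keep = hset.df["f_stat"] >= f_min
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_weak: dropped %d SNP(s) with F < %g", dropped, f_min)
    if keep.sum() == 0:
        logger.warning("filter_weak: no instruments remain")
    out = hset.subset(keep)
    out.drop_log["weak_instrument"] = out.drop_log.get("weak_instrument", 0) + dropped
    return out


def exclude_mhc(
    assocs: pd.DataFrame,
    chrom: str = MHC_CHROM,
    lo: int = MHC_LO,
    hi: int = MHC_HI,
) -> pd.DataFrame:
    """Remove variants in the MHC region (chr6 28.5-33.5 Mb by default)."""
    in_mhc = (
        (assocs["chrom"].astype(str) == str(chrom))
        & (assocs["pos"] >= lo)
        & (assocs["pos"] <= hi)
    )
    if in_mhc.any():
        logger.info("exclude_mhc: removed %d variant(s)", int(in_mhc.sum()))
    return assocs[~in_mhc].reset_index(drop=True)


def cis_filter(
    assocs: pd.DataFrame,
    gene: GeneAnnotation,
    max_dist: int = CIS_WINDOW_BP,
) -> pd.DataFrame:
    """Keep cis variants: same chromosome, |pos - TSS| <= max_dist."""
    keep = (assocs["chrom"].astype(str) == gene.chrom) & (
        (assocs["pos"] - gene.tss).abs() <= max_dist
    )
    n_trans = int((~keep).sum())
    if n_trans:
        logger.info("cis_filter(%s): discarded %d trans variant(s)", gene.symbol, n_trans)
    return assocs[keep].reset_index(drop=True)


def flag_pav(
    variant_ids,
    ld: LDMatrix | None,
    consequences: pd.DataFrame,
    r2_proxy: float = PAV_PROXY_R2,
) -> pd.Series:
    """Flag variants that are protein-altering or have a PAV proxy.

    A variant is flagged when its own consequence is protein-altering or
    when any variant with r^2 strictly above ``r2_proxy`` to it is.
    Flagged variants are retained downstream, never removed.
    """
    pav_ids = set(consequences.loc[consequences["is_pav"], "variant_id"])
    flags = []
    for v in variant_ids:
        if v in pav_ids:
            flags.append(True)
            continue
        proxied = False
        if ld is not None and v in ld._index:
            for p in pav_ids:
                r2 = ld.r2(v, p)
                if r2 is not None and r2 > r2_proxy:
                    proxied = True
                    break
        flags.append(proxied)
    return pd.Series(flags, index=pd.Index(list(variant_ids)), name="pav_flag")


def select_intragenic(
    hits: pd.DataFrame,
    genes: list[GeneAnnotation],
    consequences: pd.DataFrame,
    ld: LDMatrix | None = None,
    r2_thresh: float = CLUMP_R2,
    window_bp: int = CLUMP_WINDOW_BP,
) -> dict[str, pd.DataFrame]:
    """Select intragenic intermediate-trait instruments per gene.

    For each gene, keep genome-wide-significant hits inside the gene body
    (1-based inclusive interval), retain those with the best (lowest)
    severity rank present, then clump when an LD matrix is supplied.
    Genes without overlapping hits are absent from the result.
    """
    ranks = consequences.set_index("variant_id")["severity_rank"]
    worst = (
        int(consequences["severity_rank"].max()) + 1
        if len(consequences)
        else 0
    )
    out: dict[str, pd.DataFrame] = {}
    for gene in genes:
        inside = hits[
            (hits["chrom"].astype(str) == gene.chrom)
            & (hits["pos"] >= gene.start)
            & (hits["pos"] <= gene.end)
        ].copy()
        if inside.empty:
            continue
        inside["severity_rank"] = (
            inside["variant_id"].map(ranks).fillna(worst).astype(int)
        )
        best = inside["severity_rank"].min()
        inside = inside[inside["severity_rank"] == best].drop(
            columns="severity_rank"
        )
        if ld is not None:
            inside = clump(inside, ld, r2_thresh, window_bp)
        out[gene.gene_id] = inside.reset_index(drop=True)
    return out


def _is_palindromic(ea: str, oa: str) -> bool:
    return {ea, oa} in _PALINDROMIC_SETS


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_window: float = PALINDROME_EAF_WINDOW,
    exposure_id: str | None = None,
    outcome_id: str | None = None,
) -> HarmonizedSet:
    """Align outcome records to the exposure's effect allele.

    Inner join on variant_id. Outcome rows whose alleles are swapped
    relative to the exposure have their beta negated and EAF
    complemented; incompatible allele pairs are dropped. Palindromic
    variants (A/T, C/G) are dropped when either EAF lies within
    ``palindrome_window`` of 0.5 or is missing, and otherwise aligned by
    allele frequency. All drops are counted in ``drop_log``.
    """
    exposure_id = exposure_id or (
        str(exposure["trait_id"].iloc[0]) if "trait_id" in exposure and len(exposure) else ""
    )
    outcome_id = outcome_id or (
        str(outcome["trait_id"].iloc[0]) if "trait_id" in outcome and len(outcome) else ""
    )
    merged = exposure.merge(
        outcome, on="variant_id", suffixes=("_exp", "_out"), how="inner"
    )
    drop_log = {"not_in_outcome": int(len(exposure) - len(merged))}
    rows = []
    n_incompatible = n_palindromic = 0
    for row in merged.itertuples(index=False):
        ea_x, oa_x = row.effect_allele_exp, row.other_allele_exp
        ea_y, oa_y = row.effect_allele_out, row.other_allele_out
        beta_out, eaf_out = row.beta_out, row.eaf_out
        if (ea_y, oa_y) == (ea_x, oa_x):
            pass
        elif (ea_y, oa_y) == (oa_x, ea_x):
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out if pd.notna(eaf_out) else eaf_out
        else:
            n_incompatible += 1
            continue
        if _is_palindromic(ea_x, oa_x):
            eaf_x = row.eaf_exp
            ambiguous = (
                pd.isna(eaf_x)
                or pd.isna(eaf_out)
                or abs(eaf_x - 0.5) <= palindrome_window
                or abs(eaf_out - 0.5) <= palindrome_window
            )
            if ambiguous:
                n_palindromic += 1
                continue
            if (eaf_x < 0.5) != (eaf_out < 0.5):
                # opposite strand reported: realign by frequency
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out
        rows.append(
            {
                "variant_id": row.variant_id,
                "chrom": str(row.chrom_exp),
                "pos": int(row.pos_exp),
                "beta_exp": row.beta_exp,
                "se_exp": row.se_exp,
                "beta_out": beta_out,
                "se_out": row.se_out,
                "eaf_exp": row.eaf_exp,
                "eaf_out": eaf_out,
                "n_exp": row.n_exp,
                "n_out": row.n_out,
                "pval_exp": row.pval_exp,
                "pval_out": row.pval_out,
            }
        )
    drop_log["incompatible_alleles"] = n_incompatible
    drop_log["palindromic_ambiguous"] = n_palindromic
    for reason, count in drop_log.items():
        if count:
            logger.info("harmonize: dropped %d row(s): %s", count, reason)

    df = pd.DataFrame(
        rows,
        columns=[
            "variant_id", "chrom", "pos", "beta_exp", "se_exp", "beta_out",
            "se_out", "eaf_exp", "eaf_out", "n_exp", "n_out", "pval_exp",
            "pval_out",
        ],
    )
    if len(df):
        f_exp, r2_exp = compute_f_r2(df["beta_exp"], df["se_exp"], df["n_exp"])
        _, r2_out = compute_f_r2(df["beta_out"], df["se_out"], df["n_out"])
        df["f_stat"] = f_exp
        df["r2_exp"] = r2_exp
        df["r2_out"] = r2_out
        df["steiger_keep"] = df["r2_exp"] > df["r2_out"]
    else:
        for col in ("f_stat", "r2_exp", "r2_out"):
            df[col] = pd.Series(dtype=float)
        df["steiger_keep"] = pd.Series(dtype=bool)
        logger.warning("harmonize: empty intersection of %s and %s", exposure_id, outcome_id)
    df["pav_flag"] = False
    return HarmonizedSet(df, exposure_id, outcome_id, drop_log)


def attach_pav_flags(
    hset: HarmonizedSet,
    ld: LDMatrix | None,
    consequences: pd.DataFrame,
    r2_proxy: float = PAV_PROXY_R2,
) -> HarmonizedSet:
    """Return a copy of the set with pav_flag filled from a consequence table."""
    flags = flag_pav(hset.df["variant_id"], ld, consequences, r2_proxy)
    out = HarmonizedSet(
        hset.df.copy(), hset.exposure_id, hset.outcome_id, dict(hset.drop_log)
    )
    out.df["pav_flag"] = flags.to_numpy()
    return out
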