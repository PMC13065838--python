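"""Reading, validating and writing the external tables.

GWAS summary statistics are carried as :class:`pandas.DataFrame` objects
with a fixed internal schema (:data:`SUMSTATS_COLUMNS`); on disk they use
GWAS-SSF-style tab-delimited headers. LD matrices, BED-like gene
annotations, VEP-style consequence tables and the drug target-indication
registry have their own small readers. All coordinates are 1-based
inclusive internally; BED input (0-based half-open) is converted on read.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError

logger = logging.getLogger(__name__)

#: Internal column order for summary-statistics frames.
SUMSTATS_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

#: On-disk GWAS-SSF-style canonical headers, keyed by internal name.
SSF_HEADERS = {
    "variant_id": "variant_id",
    "chrom": "chromosome",
    "pos": "base_pair_location",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "effect_allele_frequency",
    "beta": "beta",
    "se": "standard_error",
    "pval": "p_value",
    "n": "n",
}

#: Consequence terms treated as protein-altering (epitope-artefact risk).
PAV_TERMS = frozenset({
    "stop_gained", "stop_lost", "frameshift_variant", "start_lost",
    "inframe_insertion", "inframe_deletion", "missense_variant",
    "protein_altering_variant",
})

#: Default severity ranking (lower = more severe / higher priority).
DEFAULT_SEVERITY_ORDER = [
    "stop_gained", "frameshift_variant", "stop_lost", "start_lost",
    "inframe_insertion", "inframe_deletion", "missense_variant",
    "protein_altering_variant", "splice_region_variant",
    "5_prime_UTR_variant", "3_prime_UTR_variant", "intron_variant",
]

MECHANISMS = frozenset({"agonist", "antagonist", "inhibitor", "other"})
STATUSES = frozenset(
    {"approved", "phase1", "phase2", "phase3", "preclinical", "ceased"}
)


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP-trait summary record (beta, SE, p, EAF, N, alleles)."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float  # may be NaN
    beta: float
    se: float
    pval: float
    n: float
    trait_id: str = ""


@dataclass
class LDMatrix:
    """Square matrix of signed LD correlations r, keyed by variant id."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.variant_ids)
        if self.r.shape != (k, k):
            raise FormatError(
                f"LD matrix shape {self.r.shape} does not match "
                f"{k} variant ids"
            )
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-6):
            raise FormatError("LD matrix diagonal must be exactly 1")
        if np.nanmax(np.abs(self.r)) > 1 + 1e-6:
            raise FormatError("LD correlations must satisfy |r| <= 1")
        asym = np.max(np.abs(self.r - self.r.T)) if k else 0.0
        if asym > 1e-6:
            raise FormatError(f"LD matrix asymmetric (max |r_ij - r_ji| = {asym:.3g})")
        self.r = np.clip((self.r + self.r.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(self.r, 1.0)
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def r2(self, a: str, b: str) -> float | None:
        """Squared correlation between two variants, None if either is absent."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r[ia, ib] ** 2)

    def subset(self, ids: Sequence[str]) -> "LDMatrix":
        idx = [self._index[v] for v in ids]
        return LDMatrix(list(ids), self.r[np.ix_(idx, idx)])


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene interval with transcription start site (1-based inclusive)."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str
    tss: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise FormatError(f"gene {self.gene_id}: strand must be + or -")
        if self.tss == -1:
            object.__setattr__(
                self, "tss", self.start if self.strand == "+" else self.end
            )


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing mandatory column(s) {missing}")


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str = "",
) -> pd.DataFrame:
    """Read a tab-delimited summary-statistics file.

    Parameters
    ----------
    path
        Tab-delimited file with GWAS-SSF-style headers (or headers
        resolvable through ``column_map``).
    column_map
        Optional mapping of internal column name -> header in the file,
        overriding the canonical GWAS-SSF headers.
    trait_id
        Label attached to every row (stored in a ``trait_id`` column).

    Rows violating the record invariants (se <= 0, p outside (0, 1],
    eaf outside (0, 1), identical or empty alleles, pos < 1) are dropped
    with a logged count. Duplicated variant ids keep the smallest p.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    headers = dict(SSF_HEADERS)
    if column_map:
        headers.update(column_map)
    _require_columns(raw, list(headers.values()), f"sumstats {path}")
    df = raw.rename(columns={v: k for k, v in headers.items()})
    df = df[SUMSTATS_COLUMNS].copy()
    df["chrom"] = df["chrom"].astype(str)
    for col in ("eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce").astype("Int64")
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    n_in = len(df)
    ok = (
        (df["se"] > 0)
        & (df["pval"] > 0) & (df["pval"] <= 1)
        & (df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1)))
        & (df["pos"].notna()) & (df["pos"] >= 1)
        & (df["effect_allele"] != "") & (df["other_allele"] != "")
        & (df["effect_allele"] != df["other_allele"])
        & df["beta"].notna() & df["se"].notna() & df["pval"].notna()
    )
    dropped = int(n_in - ok.sum())
    if dropped:
        logger.warning("read_sumstats(%s): dropped %d invalid row(s)", path, dropped)
    df = df[ok]

    # duplicate variant ids within a trait: keep smallest p, preserve order
    if df["variant_id"].duplicated().any():
        n_dup = int(df["variant_id"].duplicated().sum())
        logger.warning(
            "read_sumstats(%s): %d duplicate variant id(s); keeping smallest p",
            path, n_dup,
        )
        best = df.groupby("variant_id", sort=False)["pval"].idxmin()
        df = df.loc[sorted(best)]

    df = df.reset_index(drop=True)
    df["pos"] = df["pos"].astype(int)
    df["trait_id"] = trait_id
    return df


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    """Write a summary-statistics frame with canonical GWAS-SSF headers."""
    _require_columns(df, SUMSTATS_COLUMNS, "write_sumstats input")
    out = df[SUMSTATS_COLUMNS].rename(columns=SSF_HEADERS)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_ld_matrix(path: str | Path) -> LDMatrix:
    """Read a square tab-delimited LD matrix with id header row and column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != ids:
        raise FormatError(f"LD matrix {path}: row and column ids differ")
    return LDMatrix(ids, df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.r, index=ld.variant_ids, columns=ld.variant_ids).to_csv(
        path, sep="\t"
    )


def read_gene_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read a BED6-compatible gene annotation (plus gene_id/symbol columns).

    BED coordinates (0-based half-open) are converted to 1-based inclusive;
    TSS is the start for + strand genes and the end for - strand genes.
    """
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand", "symbol"],
        dtype={"chrom": str},
    )
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneAnnotation(
                gene_id=str(row.gene_id),
                symbol=str(row.symbol),
                chrom=str(row.chrom),
                start=int(row.start) + 1,
                end=int(row.end),
                strand=str(row.strand),
            )
        )
    return genes


def write_gene_annotations(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    rows = [
        (g.chrom, g.start - 1, g.end, g.gene_id, 0, g.strand, g.symbol)
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_consequences(
    path: str | Path,
    severity_order: Sequence[str] = DEFAULT_SEVERITY_ORDER,
    pav_terms: frozenset[str] = PAV_TERMS,
) -> pd.DataFrame:
    """Read a variant-consequence table (variant_id, consequence_term).

    Severity ranks come from ``severity_order`` (lower = higher priority);
    terms not listed rank below every listed term. ``is_pav`` marks terms
    in the configured protein-altering set.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["variant_id", "consequence_term"], f"consequences {path}")
    return annotate_consequences(df, severity_order, pav_terms)


def annotate_consequences(
    df: pd.DataFrame,
    severity_order: Sequence[str] = DEFAULT_SEVERITY_ORDER,
    pav_terms: frozenset[str] = PAV_TERMS,
) -> pd.DataFrame:
    """Attach severity_rank and is_pav columns to a consequence frame."""
    rank = {term: i for i, term in enumerate(severity_order)}
    out = df[["variant_id", "consequence_term"]].copy()
    out["severity_rank"] = out["consequence_term"].map(
        lambda t: rank.get(t, len(severity_order))
    )
    out["is_pav"] = out["consequence_term"].isin(pav_terms)
    return out


def write_consequences(df: pd.DataFrame, path: str | Path) -> None:
    df[["variant_id", "consequence_term"]].to_csv(path, sep="\t", index=False)


def read_target_table(path: str | Path) -> pd.DataFrame:
    """Read the drug target-indication registry.

    Tab-delimited with columns gene_symbol, disease, drug_name, mechanism,
    status; mechanism and status must come from their closed vocabularies.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = ["gene_symbol", "disease", "drug_name", "mechanism", "status"]
    _require_columns(df, cols, f"target table {path}")
    df = df[cols].copy()
    bad_mech = set(df["mechanism"]) - MECHANISMS
    if bad_mech:
        raise FormatError(f"target table {path}: unknown mechanism(s) {sorted(bad_mech)}")
    bad_status = set(df["status"]) - STATUSES
    if bad_status:
        raise FormatError(f"target table {path}: unknown status(es) {sorted(bad_status)}")
    if df.duplicated(["gene_symbol", "disease", "drug_name"]).any():
        raise FormatError(
            f"target table {path}: duplicate gene-disease-drug row(s)"
        )
    return df


def write_target_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
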