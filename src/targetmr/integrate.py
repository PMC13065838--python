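"""Study-design orchestration and drug-target triangulation.

Bidirectional MR with the four-analysis suite (IVW with and without the
MHC region, outlier-adjusted MR-PRESSO with and without the MHC),
high-confidence intersection of nominally significant results,
Bonferroni thresholds, replicate-outcome concordance, cross-approach
overlap counts, and classification of gene-disease evidence against a
drug target-indication registry (validation / misaligned / repurposing /
novel calls with direction-of-effect semantics).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mr as mr_mod
from .coloc import ColocConfig, coloc_instrument
from .instruments import (
    HarmonizedSet,
    clump,
    cis_filter,
    filter_weak,
    gw_filter,
    harmonize,
)
from .io import LDMatrix
from .mr import MRResult, PressoResult, SensitivityStats, SteigerResult
from .simulate import TargetUniverse

logger = logging.getLogger(__name__)

PP_H4_SUPPORT = 0.8  # coloc support boundary (inclusive)
NOMINAL_ALPHA = 0.05

ANALYSES = ("ivw_all", "ivw_nomhc", "presso_all", "presso_nomhc")


@dataclass
class AssociationRecord:
    """One exposure-outcome MR analysis with its sensitivity suite."""

    exposure_id: str
    outcome_id: str
    gene: str | None = None
    approach: str = "immune_cell"  # immune_cell | intermediate_trait | pqtl
    cohort: str | None = None
    mr: MRResult | None = None
    sens: SensitivityStats | None = None
    steiger: SteigerResult | None = None
    presso: PressoResult | None = None
    coloc_pp_h4: float | None = None
    analysis_pvals: dict[str, float] = field(default_factory=dict)
    status: str = "ok"

    @property
    def flags(self) -> set[str]:
        """Analyses significant at the nominal 0.05 level."""
        return {
            a for a, p in self.analysis_pvals.items()
            if p is not None and p < NOMINAL_ALPHA
        }


def _four_analyses(hset: HarmonizedSet) -> tuple[dict[str, float], dict]:
    """IVW and outlier-adjusted PRESSO, each with and without the MHC."""
    pvals: dict[str, float] = {}
    detail: dict = {}
    for label, subset in (("all", hset), ("nomhc", hset.without_mhc())):
        if subset.k == 0:
            pvals[f"ivw_{label}"] = None
            pvals[f"presso_{label}"] = None
            continue
        res, sens = mr_mod.ivw(subset)
        pvals[f"ivw_{label}"] = res.pval
        detail[f"ivw_{label}"] = (res, sens)
        if subset.k >= 4:
            presso = mr_mod.mr_presso(subset)
            corrected = presso.corrected_estimate
            pvals[f"presso_{label}"] = (
                corrected.pval if corrected is not None else None
            )
            detail[f"presso_{label}"] = presso
        else:
            pvals[f"presso_{label}"] = None
    return pvals, detail


def _one_direction(
    exposure_gwas: pd.DataFrame,
    outcome_gwas: pd.DataFrame,
    ld: LDMatrix,
    exposure_id: str,
    outcome_id: str,
    p_thresh: float,
    f_min: float,
) -> AssociationRecord:
    hits = gw_filter(exposure_gwas, p_thresh)
    index = clump(hits, ld)
    hset = harmonize(index, outcome_gwas, exposure_id=exposure_id,
                     outcome_id=outcome_id)
    hset = filter_weak(hset, f_min)
    if hset.k == 0:
        return AssociationRecord(
            exposure_id, outcome_id, status="no_instruments"
        )
    pvals, detail = _four_analyses(hset)
    res, sens = detail.get("ivw_all", (None, None))
    return AssociationRecord(
        exposure_id, outcome_id,
        mr=res, sens=sens,
        steiger=mr_mod.steiger(hset),
        presso=detail.get("presso_all"),
        analysis_pvals=pvals,
    )


def run_bidirectional(
    exposure_gwas: pd.DataFrame,
    outcome_gwas: pd.DataFrame,
    ld: LDMatrix,
    exposure_id: str = "exposure",
    outcome_id: str = "outcome",
    p_thresh: float = 5e-8,
    f_min: float = 10.0,
) -> tuple[AssociationRecord, AssociationRecord]:
    """Forward and reverse MR with Steiger applied to both directions.

    Forward instruments come from the exposure GWAS with effects on the
    outcome; the reverse analysis swaps the roles. Each direction runs
    the four analyses: IVW on all SNPs, IVW excluding the MHC, PRESSO on
    all SNPs, PRESSO excluding the MHC.
    """
    forward = _one_direction(
        exposure_gwas, outcome_gwas, ld, exposure_id, outcome_id,
        p_thresh, f_min,
    )
    reverse = _one_direction(
        outcome_gwas, exposure_gwas, ld, outcome_id, exposure_id,
        p_thresh, f_min,
    )
    return forward, reverse


def intersect_high_confidence(
    records: list[AssociationRecord],
) -> list[AssociationRecord]:
    """Keep records nominally significant (p < 0.05) in all four analyses."""
    out = []
    for rec in records:
        pvals = [rec.analysis_pvals.get(a) for a in ANALYSES]
        if all(p is not None and p < NOMINAL_ALPHA for p in pvals):
            out.append(rec)
    return out


def bonferroni_threshold(
    n_exposures: int, n_outcomes: int, alpha: float = 0.05
) -> float:
    """alpha / (number of exposures x number of outcomes), full precision."""
    if n_exposures < 1 or n_outcomes < 1:
        raise ValueError("exposure and outcome counts must be >= 1")
    return alpha / (n_exposures * n_outcomes)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (display convention)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def replicate_concordance(
    records_a: list[AssociationRecord],
    records_b: list[AssociationRecord],
) -> tuple[float | None, int]:
    """Fraction of shared exposure-outcome pairs with the same effect sign.

    Returns ``(None, 0)`` when the two sets share no pairs — an
    undefined concordance, not zero.
    """
    by_pair_a = {
        (r.exposure_id, r.outcome_id): r for r in records_a if r.mr is not None
    }
    shared = [
        (r_a, by_pair_a[(r_b.exposure_id, r_b.outcome_id)])
        for r_b in records_b
        if r_b.mr is not None
        for r_a in [r_b]
        if (r_b.exposure_id, r_b.outcome_id) in by_pair_a
    ]
    if not shared:
        return None, 0
    same = sum(
        1 for r_b, r_a in shared
        if np.sign(r_a.mr.estimate) == np.sign(r_b.mr.estimate)
    )
    return same / len(shared), len(shared)


@dataclass(frozen=True)
class OverlapCounts:
    """Venn counts of significant gene-disease pairs across two approaches."""

    only_a: int
    shared: int
    only_b: int


def _significant_pairs(
    records: list[AssociationRecord], p_thresh: float
) -> set[tuple[str, str]]:
    return {
        (r.gene, r.outcome_id)
        for r in records
        if r.gene is not None and r.mr is not None and r.mr.pval < p_thresh
    }


def overlap_sets(
    intermediate_records: list[AssociationRecord],
    pqtl_records: list[AssociationRecord],
    p_thresh: float = NOMINAL_ALPHA,
    restrict_to_shared_genes: bool = False,
) -> OverlapCounts:
    """Gene-disease association overlap between the two MR approaches.

    With ``restrict_to_shared_genes`` only genes instrumented (tested)
    in both approaches enter the counts, separating genuine discordance
    from instrument availability.
    """
    sig_a = _significant_pairs(intermediate_records, p_thresh)
    sig_b = _significant_pairs(pqtl_records, p_thresh)
    if restrict_to_shared_genes:
        tested_a = {r.gene for r in intermediate_records if r.gene}
        tested_b = {r.gene for r in pqtl_records if r.gene}
        both = tested_a & tested_b
        sig_a = {p for p in sig_a if p[0] in both}
        sig_b = {p for p in sig_b if p[0] in both}
    return OverlapCounts(
        only_a=len(sig_a - sig_b),
        shared=len(sig_a & sig_b),
        only_b=len(sig_b - sig_a),
    )


@dataclass(frozen=True)
class TargetEvidence:
    """Per gene-disease pair: MR + coloc evidence merged with drug status."""

    gene: str
    disease: str
    best_pval: float
    direction: int  # sign of the MR estimate
    coloc_support: bool
    registry_status: str | None
    mechanism: str | None
    call: str


_ALIGNED_POSITIVE = {"antagonist", "inhibitor"}  # block a risk-increasing protein
_ALIGNED_NEGATIVE = {"agonist"}  # boost a protective protein


def classify_target(
    gene: str,
    disease: str,
    direction: int,
    pp_h4: float | None,
    registry: pd.DataFrame,
    best_pval: float = float("nan"),
    pp_h4_support: float = PP_H4_SUPPORT,
) -> TargetEvidence:
    """Classify one gene-disease MR signal against the drug registry.

    Calls: ``validation`` (registered for this disease, drug mechanism
    aligned with the MR direction), ``misaligned`` (registered but the
    mechanism opposes the direction), ``direction_unassessed``
    (registered, mechanism outside the agonist/antagonist/inhibitor
    vocabulary), ``repurposing`` (registered only for other diseases),
    ``novel`` (absent from the registry). Coloc support
    (PP_H4 >= ``pp_h4_support``) is required for any call stronger than
    ``nominal``.
    """
    coloc_support = pp_h4 is not None and pp_h4 >= pp_h4_support
    same = registry[
        (registry["gene_symbol"] == gene) & (registry["disease"] == disease)
    ]
    any_gene = registry[registry["gene_symbol"] == gene]
    status = same["status"].iloc[0] if len(same) else (
        any_gene["status"].iloc[0] if len(any_gene) else None
    )
    mechanism = same["mechanism"].iloc[0] if len(same) else (
        any_gene["mechanism"].iloc[0] if len(any_gene) else None
    )

    if not coloc_support:
        call = "nominal"
    elif len(same):
        mechs = set(same["mechanism"])
        aligned = (direction > 0 and mechs & _ALIGNED_POSITIVE) or (
            direction < 0 and mechs & _ALIGNED_NEGATIVE
        )
        assessable = mechs & (_ALIGNED_POSITIVE | _ALIGNED_NEGATIVE)
        if aligned:
            call = "validation"
        elif assessable:
            call = "misaligned"
        else:
            call = "direction_unassessed"
    elif len(any_gene):
        call = "repurposing"
    else:
        call = "novel"
    return TargetEvidence(
        gene, disease, best_pval, int(np.sign(direction)), coloc_support,
        status, mechanism, call,
    )


@dataclass
class SensitivityReport:
    """Per-disease MR sensitivity against registered drug targets."""

    per_disease: pd.DataFrame
    mean: float
    sd: float


def sensitivity_vs_registry(
    records: list[AssociationRecord],
    registry: pd.DataFrame,
    status_filter: str = "approved",
    p_thresh: float = NOMINAL_ALPHA,
    require_coloc: bool = False,
    pp_h4_support: float = PP_H4_SUPPORT,
) -> SensitivityReport:
    """Fraction of registered targets recovered by MR, per disease.

    The primary denominator is restricted to *instrumentable* targets
    (genes actually tested for that disease); the all-targets
    denominator is reported alongside, since computing against every
    registered target conflates instrument coverage with power.
    Diseases with no instrumentable target are excluded from the mean
    and logged.
    """
    tested: dict[str, set[str]] = {}
    significant: dict[str, set[str]] = {}
    for r in records:
        if r.gene is None:
            continue
        tested.setdefault(r.outcome_id, set()).add(r.gene)
        if r.mr is not None and r.mr.pval < p_thresh:
            if require_coloc and not (
                r.coloc_pp_h4 is not None and r.coloc_pp_h4 >= pp_h4_support
            ):
                continue
            significant.setdefault(r.outcome_id, set()).add(r.gene)

    rows = []
    reg = registry[registry["status"] == status_filter]
    for disease, sub in reg.groupby("disease"):
        targets = set(sub["gene_symbol"])
        instrumentable = targets & tested.get(disease, set())
        detected = targets & significant.get(disease, set())
        if not instrumentable:
            logger.info(
                "sensitivity: disease %s has no instrumentable %s target; excluded",
                disease, status_filter,
            )
            continue
        rows.append(
            {
                "disease": disease,
                "n_registered": len(targets),
                "n_instrumentable": len(instrumentable),
                "n_detected": len(detected & instrumentable),
                "sensitivity": len(detected & instrumentable) / len(instrumentable),
                "sensitivity_all_targets": len(detected) / len(targets),
            }
        )
    per_disease = pd.DataFrame(
        rows,
        columns=[
            "disease", "n_registered", "n_instrumentable", "n_detected",
            "sensitivity", "sensitivity_all_targets",
        ],
    )
    if len(per_disease):
        mean = float(per_disease["sensitivity"].mean())
        sd = (
            float(per_disease["sensitivity"].std(ddof=1))
            if len(per_disease) > 1
            else 0.0
        )
    else:
        mean = sd = float("nan")
    return SensitivityReport(per_disease, mean, sd)


def run_target_pipeline(
    universe: TargetUniverse,
    coloc_cfg: ColocConfig | None = None,
    p_thresh: float = 5e-8,
    f_min: float = 10.0,
) -> tuple[list[AssociationRecord], pd.DataFrame]:
    """End-to-end triangulation over a synthetic target universe.

    For each gene: genome-wide filter of its cis-pQTL study, cis-window
    selection around the TSS, LD clumping; then for each disease:
    harmonization, weak-instrument filtering, IVW/Wald MR, Steiger,
    per-instrument-SNP colocalisation (max PP_H4 region) and
    classification against the registry. Returns the association
    records and the evidence table.
    """
    coloc_cfg = coloc_cfg or ColocConfig()
    records: list[AssociationRecord] = []
    evidence_rows = []
    for gene in universe.genes:
        exposure = universe.exposures[gene.symbol]
        ld = universe.ld_by_gene[gene.symbol]
        hits = gw_filter(exposure, p_thresh)
        hits = cis_filter(hits, gene)
        index = clump(hits, ld)
        for disease, outcome in universe.outcomes.items():
            if index.empty:
                records.append(
                    AssociationRecord(
                        gene.symbol, disease, gene=gene.symbol,
                        approach="pqtl", status="no_instruments",
                    )
                )
                continue
            hset = harmonize(index, outcome, exposure_id=gene.symbol,
                             outcome_id=disease)
            hset = filter_weak(hset, f_min)
            if hset.k == 0:
                records.append(
                    AssociationRecord(
                        gene.symbol, disease, gene=gene.symbol,
                        approach="pqtl", status="no_instruments",
                    )
                )
                continue
            res, sens = mr_mod.ivw(hset)
            coloc_res, best_snp = coloc_instrument(
                exposure, outcome, list(hset.df["variant_id"]), coloc_cfg,
            )
            pp_h4 = (
                coloc_res.pp.get("PP_H4") if coloc_res.status == "ok" else None
            )
            rec = AssociationRecord(
                gene.symbol, disease, gene=gene.symbol, approach="pqtl",
                mr=res, sens=sens, steiger=mr_mod.steiger(hset),
                coloc_pp_h4=pp_h4,
            )
            records.append(rec)
            if res.pval < NOMINAL_ALPHA:
                ev = classify_target(
                    gene.symbol, disease, int(np.sign(res.estimate)),
                    pp_h4, universe.registry, best_pval=res.pval,
                )
                evidence_rows.append(ev)
    evidence = pd.DataFrame(
        [
            {
                "gene": e.gene, "disease": e.disease,
                "best_pval": e.best_pval, "direction": e.direction,
                "coloc_support": e.coloc_support,
                "registry_status": e.registry_status,
                "mechanism": e.mechanism, "call": e.call,
            }
            for e in evidence_rows
        ],
        columns=[
            "gene", "disease", "best_pval", "direction", "coloc_support",
            "registry_status", "mechanism", "call",
        ],
    )
    return records, evidence


def records_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    """Flatten association records into a results table (one row each)."""
    rows = []
    for r in records:
        row = {
            "exposure_id": r.exposure_id,
            "outcome_id": r.outcome_id,
            "gene": r.gene,
            "approach": r.approach,
            "cohort": r.cohort,
            "status": r.status,
        }
        if r.mr is not None:
            row.update(
                method=r.mr.method, k=r.mr.k, estimate=r.mr.estimate,
                se=r.mr.se, ci_low=r.mr.ci_low, ci_high=r.mr.ci_high,
                pval=r.mr.pval, odds_ratio=r.mr.odds_ratio,
            )
        if r.sens is not None:
            row.update(q=r.sens.q, q_df=r.sens.q_df, q_pval=r.sens.q_pval,
                       i2=r.sens.i2)
        if r.steiger is not None:
            row.update(
                r2_exp_total=r.steiger.r2_exp_total,
                r2_out_total=r.steiger.r2_out_total,
                steiger_direction=r.steiger.direction_correct,
                steiger_pval=r.steiger.steiger_pval,
            )
        if r.coloc_pp_h4 is not None:
            row["coloc_pp_h4"] = r.coloc_pp_h4
        for a in ANALYSES:
            if a in r.analysis_pvals:
                row[f"pval_{a}"] = r.analysis_pvals[a]
        rows.append(row)
    return pd.DataFrame(rows)
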