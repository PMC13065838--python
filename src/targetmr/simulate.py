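"""Synthetic GWAS summary statistics with known ground truth.

The generators emulate the statistical structure of two-sample MR inputs:
per-SNP effects drawn from a hierarchical model, standard errors derived
from allele frequency and sample size, block-diagonal AR(1) LD, balanced
or directional pleiotropy, reverse causation, epitope-artefact pQTLs and
regional association signals with shared or distinct causal variants.

Model
-----
For SNP j with minor allele frequency ``maf_j`` and exposure sample size
``N_x``, the exposure standard error is ``1 / sqrt(2 maf_j (1-maf_j) N_x)``
(standardized-trait scale); outcome SEs are analogous. True per-SNP
exposure effects are gamma_j ~ N(0, gamma_sd^2), direct (pleiotropic)
outcome effects alpha_j ~ N(pleiotropy_mean, pleiotropy_sd^2), and the
true marginal outcome effect is ``theta * gamma_j + alpha_j``. Observed
z-scores are the LD-propagated true z-scores plus noise correlated
according to the LD matrix — the standard regional summary-statistic
model; with singleton LD blocks this reduces to independent
``beta_obs ~ N(beta_true, se^2)``.

Binary outcomes are simulated on the log-odds scale with the same normal
approximation, so summary-level MR treats quantitative and case-control
traits identically.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError
from .io import GeneAnnotation, LDMatrix, SUMSTATS_COLUMNS, annotate_consequences

# non-palindromic allele pairs cycled across simulated variants
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the instrument-set generator.

    Defaults encode the reference condition used throughout the test
    suite: 50 strong instruments for a quantitative exposure measured in
    100,000 individuals, causal effect 0.3 per exposure SD, no
    pleiotropy, no LD between instruments (post-clumping world).
    """

    n_snps: int = 50
    n_exposure: int = 100_000
    n_outcome: int = 100_000
    theta: float = 0.3
    gamma_sd: float = 0.1
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    maf_range: tuple[float, float] = (0.01, 0.5)
    ld_block_size: int = 1
    ld_rho: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ConfigError("n_snps must be >= 1")
        if self.n_exposure <= 0 or self.n_outcome <= 0:
            raise ConfigError("sample sizes must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 0.5 or (0 < lo <= hi == 0.5)):
            raise ConfigError("maf_range bounds must lie in (0, 0.5]")
        if abs(self.ld_rho) >= 1:
            raise ConfigError("|ld_rho| must be < 1")
        if self.gamma_sd < 0 or self.pleiotropy_sd < 0:
            raise ConfigError("standard deviations must be >= 0")
        if self.ld_block_size < 1:
            raise ConfigError("ld_block_size must be >= 1")


@dataclass(frozen=True)
class Truth:
    """Ground truth behind one simulated study pair."""

    theta: float
    gamma: np.ndarray
    alpha: np.ndarray
    causal_direction: str = "forward"  # or "reverse"


@dataclass
class SimulatedStudyPair:
    """Exposure and outcome summary statistics over identical variants."""

    exposure: pd.DataFrame
    outcome: pd.DataFrame
    ld: LDMatrix
    truth: Truth

    def copy(self) -> "SimulatedStudyPair":
        return SimulatedStudyPair(
            self.exposure.copy(), self.outcome.copy(), self.ld, self.truth
        )

    def to_harmonized(self):
        """Harmonize the pair (fast path when alleles are already aligned).

        Simulation studies that run thousands of estimator fits use the
        direct construction when exposure and outcome report the same
        effect alleles; otherwise the full harmonization routine runs.
        """
        from .instruments import HarmonizedSet, compute_f_r2, harmonize

        if not (
            self.exposure["effect_allele"].equals(self.outcome["effect_allele"])
            and self.exposure["variant_id"].equals(self.outcome["variant_id"])
        ):
            return harmonize(self.exposure, self.outcome)
        df = pd.DataFrame(
            {
                "variant_id": self.exposure["variant_id"],
                "chrom": self.exposure["chrom"],
                "pos": self.exposure["pos"],
                "beta_exp": self.exposure["beta"],
                "se_exp": self.exposure["se"],
                "beta_out": self.outcome["beta"],
                "se_out": self.outcome["se"],
                "eaf_exp": self.exposure["eaf"],
                "eaf_out": self.outcome["eaf"],
                "n_exp": self.exposure["n"],
                "n_out": self.outcome["n"],
                "pval_exp": self.exposure["pval"],
                "pval_out": self.outcome["pval"],
            }
        )
        f_exp, r2_exp = compute_f_r2(df["beta_exp"], df["se_exp"], df["n_exp"])
        _, r2_out = compute_f_r2(df["beta_out"], df["se_out"], df["n_out"])
        df["f_stat"] = f_exp
        df["r2_exp"] = r2_exp
        df["r2_out"] = r2_out
        df["steiger_keep"] = df["r2_exp"] > df["r2_out"]
        df["pav_flag"] = False
        return HarmonizedSet(
            df,
            str(self.exposure["trait_id"].iloc[0]),
            str(self.outcome["trait_id"].iloc[0]),
        )


def simulate_ld_blocks(
    n_snps: int,
    block_size: int,
    rho: float,
    seed: int | None = None,
    variant_ids: Sequence[str] | None = None,
) -> LDMatrix:
    """Block-diagonal AR(1) LD: within a block r(i,j) = rho^|i-j|.

    Positive semi-definite by construction (each block is an AR(1)
    correlation matrix); zero correlation across blocks. ``seed`` is
    accepted for signature stability but the construction is
    deterministic.
    """
    if n_snps < 1:
        raise ConfigError("n_snps must be >= 1")
    if abs(rho) >= 1:
        raise ConfigError("|rho| must be < 1")
    if block_size < 1:
        raise ConfigError("block_size must be >= 1")
    r = np.zeros((n_snps, n_snps))
    for start in range(0, n_snps, block_size):
        stop = min(start + block_size, n_snps)
        idx = np.arange(start, stop)
        lag = np.abs(idx[:, None] - idx[None, :])
        r[np.ix_(idx, idx)] = rho ** lag
    np.fill_diagonal(r, 1.0)
    if variant_ids is None:
        variant_ids = [f"rs{i + 1}" for i in range(n_snps)]
    return LDMatrix(list(variant_ids), r)


def _chol(ld: LDMatrix) -> np.ndarray:
    # jitter only if strictly necessary (AR1 blocks are PD for |rho|<1)
    try:
        return np.linalg.cholesky(ld.r)
    except np.linalg.LinAlgError:
        k = ld.r.shape[0]
        return np.linalg.cholesky(ld.r + 1e-10 * np.eye(k))


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _sumstats_frame(
    variant_ids: Sequence[str],
    chrom: str,
    pos: np.ndarray,
    alleles: list[tuple[str, str]],
    eaf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    n: int,
    trait_id: str,
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": list(variant_ids),
            "chrom": chrom,
            "pos": pos.astype(int),
            "effect_allele": [a for a, _ in alleles],
            "other_allele": [b for _, b in alleles],
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": _two_sided_p(beta / se),
            "n": float(n),
            "trait_id": trait_id,
        }
    )[SUMSTATS_COLUMNS + ["trait_id"]]


def _flip_orientation(df: pd.DataFrame, flip: np.ndarray) -> pd.DataFrame:
    """Relabel the effect allele for the flagged rows (beta and EAF follow)."""
    out = df.copy()
    ea = out["effect_allele"].to_numpy().copy()
    oa = out["other_allele"].to_numpy().copy()
    ea[flip], oa[flip] = oa[flip], ea[flip].copy()
    out["effect_allele"], out["other_allele"] = ea, oa
    out.loc[flip, "beta"] = -out.loc[flip, "beta"]
    out.loc[flip, "eaf"] = 1.0 - out.loc[flip, "eaf"]
    return out


def simulate_instrument_set(
    cfg: SimulationConfig,
    chrom: str = "1",
    pos_start: int = 1_000_000,
    pos_step: int = 50_000,
    exposure_id: str = "exposure",
    outcome_id: str = "outcome",
    flip_alleles: bool = True,
) -> SimulatedStudyPair:
    """Simulate an exposure/outcome summary-statistic pair.

    The exposure and outcome studies independently choose which allele
    they report as the effect allele (``flip_alleles``), so the pair
    exercises harmonization before any estimator sees it. Ground truth
    (``pair.truth``) is stored in the canonical orientation shared by
    the LD matrix.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_snps
    lo, hi = cfg.maf_range
    maf = rng.uniform(lo, hi, size=k)
    gamma = rng.normal(0.0, cfg.gamma_sd, size=k)
    # Directional pleiotropy is defined relative to the exposure-increasing
    # allele (the orientation in which MR-Egger fits): the direct outcome
    # effect is drawn as N(mean, sd^2) in that orientation and mapped back
    # to the canonical allele. For pleiotropy_mean == 0 this is
    # distributionally identical to a plain N(0, sd^2) draw.
    eta = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=k)
    alpha = np.where(gamma < 0, -eta, eta)
    beta_out_true = cfg.theta * gamma + alpha

    se_x = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * cfg.n_exposure)
    se_y = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * cfg.n_outcome)

    ld = simulate_ld_blocks(k, cfg.ld_block_size, cfg.ld_rho)
    if cfg.ld_block_size == 1 or cfg.ld_rho == 0.0:
        z_x = gamma / se_x + rng.standard_normal(k)
        z_y = beta_out_true / se_y + rng.standard_normal(k)
    else:
        chol = _chol(ld)
        z_x = ld.r @ (gamma / se_x) + chol @ rng.standard_normal(k)
        z_y = ld.r @ (beta_out_true / se_y) + chol @ rng.standard_normal(k)

    pos = pos_start + pos_step * np.arange(k)
    alleles = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(k)]
    exposure = _sumstats_frame(
        ld.variant_ids, chrom, pos, alleles, maf, z_x * se_x, se_x,
        cfg.n_exposure, exposure_id,
    )
    outcome = _sumstats_frame(
        ld.variant_ids, chrom, pos, alleles, maf, z_y * se_y, se_y,
        cfg.n_outcome, outcome_id,
    )
    if flip_alleles:
        exposure = _flip_orientation(exposure, rng.random(k) < 0.5)
        outcome = _flip_orientation(outcome, rng.random(k) < 0.5)

    truth = Truth(theta=cfg.theta, gamma=gamma, alpha=alpha)
    return SimulatedStudyPair(exposure, outcome, ld, truth)


def simulate_reverse(cfg: SimulationConfig, **kwargs) -> SimulatedStudyPair:
    """Simulate under outcome -> exposure causation.

    The SNPs truly drive the trait labelled *outcome*, which causally
    affects the trait labelled *exposure*; roles are swapped before
    relabeling, so Steiger filtering applied to the (exposure, outcome)
    pair should detect the reversed direction.
    """
    swapped = replace(cfg, n_exposure=cfg.n_outcome, n_outcome=cfg.n_exposure)
    base = simulate_instrument_set(
        swapped, exposure_id="outcome", outcome_id="exposure", **kwargs
    )
    truth = Truth(
        theta=base.truth.theta,
        gamma=base.truth.gamma,
        alpha=base.truth.alpha,
        causal_direction="reverse",
    )
    return SimulatedStudyPair(base.outcome, base.exposure, base.ld, truth)


def inject_outlier(
    pair: SimulatedStudyPair, variant_id: str, shift_in_se_units: float
) -> SimulatedStudyPair:
    """Shift one variant's outcome beta by ``shift * SE_out`` (new pair)."""
    mask = pair.outcome["variant_id"] == variant_id
    if not mask.any():
        raise KeyError(f"variant {variant_id!r} not present in outcome")
    out = pair.copy()
    out.outcome.loc[mask, "beta"] += (
        shift_in_se_units * out.outcome.loc[mask, "se"]
    )
    z = out.outcome["beta"] / out.outcome["se"]
    out.outcome["pval"] = _two_sided_p(z.to_numpy())
    return out


@dataclass
class RegionPair:
    """Regional exposure/outcome association statistics for coloc tests."""

    exposure: pd.DataFrame
    outcome: pd.DataFrame
    ld: LDMatrix
    hypothesis: str
    causal_exposure_idx: int | None
    causal_outcome_idx: int | None


_HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")


def simulate_region_pair(
    hypothesis: str,
    n_variants: int = 100,
    ld: LDMatrix | None = None,
    effect_z: float = 12.0,
    seed: int = 0,
    n_exposure: int = 50_000,
    n_outcome: int = 50_000,
    chrom: str = "1",
    pos_start: int = 5_000_000,
    pos_step: int = 1_000,
    exposure_id: str = "exposure",
    outcome_id: str = "outcome",
) -> RegionPair:
    """Simulate one regional association pair under a coloc hypothesis.

    H0: neither trait has a causal variant; H1/H2: one trait only;
    H3: two distinct causal variants (drawn from different LD blocks,
    hence near-zero r); H4: one shared causal variant. Observed regional
    z-scores are the causal z propagated through LD plus noise with the
    LD correlation structure.
    """
    if hypothesis not in _HYPOTHESES:
        raise ConfigError(f"hypothesis must be one of {_HYPOTHESES}")
    if n_variants < 2:
        raise ConfigError("n_variants must be >= 2")
    rng = np.random.default_rng(seed)
    if ld is None:
        ld = simulate_ld_blocks(n_variants, block_size=5, rho=0.5)
    elif len(ld.variant_ids) != n_variants:
        raise ConfigError("ld size does not match n_variants")
    chol = _chol(ld)

    c_exp: int | None = None
    c_out: int | None = None
    if hypothesis == "H1":
        c_exp = int(rng.integers(n_variants))
    elif hypothesis == "H2":
        c_out = int(rng.integers(n_variants))
    elif hypothesis == "H3":
        # distinct causal variants from different halves of the region so
        # their LD is (near-)zero under the block-diagonal default
        c_exp = int(rng.integers(0, n_variants // 2))
        c_out = int(rng.integers(n_variants // 2, n_variants))
    elif hypothesis == "H4":
        c_exp = c_out = int(rng.integers(n_variants))

    def regional_z(causal: int | None) -> np.ndarray:
        z_true = np.zeros(n_variants)
        if causal is not None:
            z_true = effect_z * ld.r[:, causal]
        return z_true + chol @ rng.standard_normal(n_variants)

    z1 = regional_z(c_exp)
    z2 = regional_z(c_out)

    maf = rng.uniform(0.1, 0.5, size=n_variants)
    se1 = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_exposure)
    se2 = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_outcome)
    pos = pos_start + pos_step * np.arange(n_variants)
    alleles = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(n_variants)]
    exposure = _sumstats_frame(
        ld.variant_ids, chrom, pos, alleles, maf, z1 * se1, se1,
        n_exposure, exposure_id,
    )
    outcome = _sumstats_frame(
        ld.variant_ids, chrom, pos, alleles, maf, z2 * se2, se2,
        n_outcome, outcome_id,
    )
    return RegionPair(exposure, outcome, ld, hypothesis, c_exp, c_out)


@dataclass
class PavPqtlResult:
    """A cis-pQTL study pair with an epitope-artefact index variant."""

    pair: SimulatedStudyPair
    gene: GeneAnnotation
    consequences: pd.DataFrame
    flagged_variant: str


def simulate_pav_pqtl(
    cfg: SimulationConfig,
    artifact_scale: float,
    seed_offset: int = 0,
) -> PavPqtlResult:
    """Simulate a cis-pQTL instrument whose signal is an epitope artefact.

    A protein-altering variant can change assay capture affinity rather
    than true protein abundance. Here the index cis variant carries an
    artefactual pQTL association of ``artifact_scale`` exposure-SE units
    and a direct variant-disease effect of half that size in outcome-SE
    units, while the true protein-on-disease effect is zero — so a Wald
    MR on the flagged variant is nominally significant for large scales
    and the PAV flag is the only defence. The emitted consequence table
    marks the index variant ``missense_variant`` and all other variants
    ``intron_variant``.
    """
    cfg = replace(cfg, theta=0.0, seed=cfg.seed + seed_offset)
    base = simulate_instrument_set(cfg, flip_alleles=False)
    pair = base.copy()
    idx = 0
    se_x = float(pair.exposure.loc[idx, "se"])
    se_y = float(pair.outcome.loc[idx, "se"])
    # replace any true signal at the index with the pure artefact
    pair.exposure.loc[idx, "beta"] = artifact_scale * se_x
    pair.outcome.loc[idx, "beta"] = (
        float(pair.outcome.loc[idx, "beta"]) + 0.5 * artifact_scale * se_y
    )
    for df in (pair.exposure, pair.outcome):
        df["pval"] = _two_sided_p((df["beta"] / df["se"]).to_numpy())

    flagged = str(pair.exposure.loc[idx, "variant_id"])
    tss = int(pair.exposure.loc[idx, "pos"])
    gene = GeneAnnotation(
        gene_id="GENE_PAV", symbol="GENEPAV",
        chrom=str(pair.exposure.loc[idx, "chrom"]),
        start=tss, end=tss + 50_000, strand="+",
    )
    terms = ["missense_variant"] + ["intron_variant"] * (cfg.n_snps - 1)
    consequences = annotate_consequences(
        pd.DataFrame(
            {"variant_id": pair.exposure["variant_id"], "consequence_term": terms}
        )
    )
    truth = Truth(0.0, base.truth.gamma, base.truth.alpha)
    return PavPqtlResult(
        SimulatedStudyPair(pair.exposure, pair.outcome, pair.ld, truth),
        gene, consequences, flagged,
    )


@dataclass
class TargetUniverse:
    """A synthetic drug-target study: genes x diseases with known truth.

    One cis-pQTL study per gene, one disease GWAS per outcome covering
    every gene's region, block AR(1) LD per region, a drug registry and
    the set of truly causal (gene symbol, disease) pairs sharing a causal
    variant.
    """

    genes: list[GeneAnnotation]
    exposures: dict[str, pd.DataFrame]  # gene symbol -> cis-pQTL sumstats
    outcomes: dict[str, pd.DataFrame]  # disease -> genome-wide sumstats
    ld_by_gene: dict[str, LDMatrix]
    registry: pd.DataFrame
    causal_pairs: set[tuple[str, str]]


def simulate_target_universe(
    n_genes: int = 5,
    n_diseases: int = 3,
    causal_pairs: Sequence[tuple[int, int]] = ((0, 0),),
    n_region_variants: int = 120,
    exposure_z: float = 14.0,
    outcome_z: float = 10.0,
    n_exposure: int = 35_000,
    n_outcome: int = 150_000,
    seed: int = 0,
) -> TargetUniverse:
    """Simulate the full triangulation study with known causal pairs.

    Each gene occupies its own region on chromosome 1 (10 Mb apart).
    The gene's protein has one causal cis variant (|z| = ``exposure_z``).
    For a causal (gene, disease) pair the disease shares that causal
    variant with |z| = ``outcome_z``; everywhere else the disease signal
    is pure noise. The registry lists the first causal gene as an
    approved antagonist for its disease (a validation case) plus decoy
    entries to exercise repurposing/novel calls.
    """
    rng = np.random.default_rng(seed)
    causal = {(g, d) for g, d in causal_pairs}
    genes: list[GeneAnnotation] = []
    exposures: dict[str, pd.DataFrame] = {}
    ld_by_gene: dict[str, LDMatrix] = {}
    outcome_frames: dict[str, list[pd.DataFrame]] = {
        f"disease_{d + 1}": [] for d in range(n_diseases)
    }

    for g in range(n_genes):
        symbol = f"GENE{g + 1}"
        region_start = 10_000_000 * (g + 1)
        tss = region_start + (n_region_variants // 2) * 1_000
        genes.append(
            GeneAnnotation(
                gene_id=f"ENSG{g + 1:011d}", symbol=symbol, chrom="1",
                start=tss, end=tss + 60_000, strand="+",
            )
        )
        ids = [f"g{g + 1}_v{i + 1}" for i in range(n_region_variants)]
        ld = simulate_ld_blocks(
            n_region_variants, block_size=5, rho=0.5, variant_ids=ids
        )
        ld_by_gene[symbol] = ld
        chol = _chol(ld)
        causal_idx = n_region_variants // 2  # at the TSS, comfortably cis
        maf = rng.uniform(0.1, 0.5, size=n_region_variants)
        pos = region_start + 1_000 * np.arange(n_region_variants)
        alleles = [
            _ALLELE_PAIRS[i % len(_ALLELE_PAIRS)]
            for i in range(n_region_variants)
        ]

        se_x = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_exposure)
        z_x = exposure_z * ld.r[:, causal_idx] + chol @ rng.standard_normal(
            n_region_variants
        )
        exposures[symbol] = _sumstats_frame(
            ids, "1", pos, alleles, maf, z_x * se_x, se_x, n_exposure,
            f"pqtl_{symbol}",
        )

        se_y = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_outcome)
        for d in range(n_diseases):
            disease = f"disease_{d + 1}"
            z_true = (
                outcome_z * ld.r[:, causal_idx]
                if (g, d) in causal
                else np.zeros(n_region_variants)
            )
            z_y = z_true + chol @ rng.standard_normal(n_region_variants)
            outcome_frames[disease].append(
                _sumstats_frame(
                    ids, "1", pos, alleles, maf, z_y * se_y, se_y,
                    n_outcome, disease,
                )
            )

    outcomes = {
        disease: pd.concat(frames, ignore_index=True)
        for disease, frames in outcome_frames.items()
    }

    registry_rows = [
        # validation case: first causal gene, its disease, an antagonist
        ("GENE1", "disease_1", "drug_a", "antagonist", "approved"),
        # repurposing decoy: causal gene registered for a different disease
        ("GENE1", "disease_2", "drug_b", "antagonist", "phase2"),
        # registered gene without simulated evidence
        ("GENE2", "disease_2", "drug_c", "agonist", "phase3"),
        ("GENE3", "disease_3", "drug_d", "inhibitor", "ceased"),
    ]
    registry = pd.DataFrame(
        registry_rows,
        columns=["gene_symbol", "disease", "drug_name", "mechanism", "status"],
    )
    causal_symbols = {
        (f"GENE{g + 1}", f"disease_{d + 1}") for g, d in causal
    }
    return TargetUniverse(
        genes, exposures, outcomes, ld_by_gene, registry, causal_symbols
    )
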