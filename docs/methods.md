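# Methods

## Scope and design

`targetmr` is organised as a pipeline of pure functions over pandas
frames plus scikit-learn-style estimator classes for the MR fits. The
stages are independent: instrument selection (`instruments`), causal
estimation and sensitivity analysis (`mr`), colocalisation (`coloc`),
study-level integration (`integrate`), table I/O (`io`), synthetic data
(`simulate`) and seeded calibration studies (`benchmarks`). The CLI is a
thin orchestration layer; every analysis is reachable as a library call.

## Summary-statistic model

All estimation is on the additive scale: per-SD units for quantitative
traits and log-odds for case–control traits, treated identically (the
standard two-sample summary-data approximation); odds ratios are
exponentiated only at reporting time. Coordinates are 1-based inclusive
throughout; BED input is converted on read. The genome build is carried
as a config label and never inferred.

## Instrument selection

- Genome-wide significance is strict (p < 5e-8); clumping keeps pairwise
  r² < 0.001 within 10 Mbp by greedy p-ordered selection, with ties
  broken by (chrom, pos, variant_id) so output is deterministic and
  invariant to input row order. Variants missing from the LD matrix are
  treated as unlinked and logged loudly — safe for synthetic data,
  surfaced for real data.
- Weak-instrument filtering keeps per-SNP F = (β/se)² ≥ 10 (inclusive);
  per-SNP variance explained uses r² = F/(F + n − 2), the summary-data
  approximation of the regression t²/(t² + n − 2), which the tests
  cross-check against an individual-level regression.
- The MHC exclusion window (chr6:28.5–33.5 Mb) and the cis window
  (≤ 1 Mb from the TSS, inclusive) are config defaults; the
  protein-altering-variant proxy rule is strict (r² > 0.6). PAV-flagged
  variants are retained, never removed — the flag marks epitope-artefact
  risk, and the simulator's `simulate_pav_pqtl` demonstrates the failure
  mode the flag guards against (an artefactual pQTL plus a direct
  variant–disease effect produces a significant Wald ratio with a truly
  null protein effect).
- Harmonization aligns outcome records to the exposure's effect allele
  (swap → negate β, complement EAF; incompatible → drop). Palindromic
  A/T and C/G variants are dropped when either EAF is missing or within
  0.08 of 0.5, otherwise aligned by frequency; the window mirrors common
  two-sample MR defaults and is configurable. Harmonization is
  involution-safe: relabeling every outcome record's alleles leaves the
  result unchanged (property-tested).

## Estimators

- **IVW** is the zero-intercept WLS slope with weights 1/se_out².
  The default is a multiplicative random-effects model: the fixed-effect
  SE is scaled by max(1, √(Q/(k−1))). p-values are normal-theory. Under
  extreme additive heterogeneity the 1/se² weights are no longer optimal
  and the test can become mildly anticonservative; at moderate
  heterogeneity (I² ≈ 50%) the measured type-I error is 0.059 and without
  heterogeneity 0.045 (see `benchmarks`).
- **MR-Egger** reorients every SNP so exposure betas are non-negative,
  fits WLS with intercept, scales SEs by max(1, √(Q/(k−2))) and uses t
  reference distributions with k−2 df. I²_GX uses 1/se_exp² weights (the
  weighting convention is not fixed by prior literature; this choice is
  documented and tested). The degenerate all-equal-beta design is
  handled via a pseudoinverse with Q_GX = 0 → I²_GX = 0 by truncation.
- **Weighted median/mode** operate on per-SNP Wald ratios with
  first-order delta SEs. The median interpolates the weighted 0.5
  quantile; the mode maximises a normal-kernel weighted density with
  bandwidth φ·0.9·min(sd, IQR/1.349)·k^(−1/5) on a 512-point grid
  spanning the ratios ± 3 bandwidths (all-equal ratios short-circuit to
  that value). SEs come from a seeded parametric bootstrap (betas
  redrawn from their sampling distributions). The median's validity
  requires a strict weight-majority of valid instruments; its robustness
  test uses a 40% invalid minority for exactly that reason.
- **Cochran's Q / I²** use the residual form Σ wⱼ(β̂_Yj − θ̂β̂_Xj)²,
  algebraically identical to the ratio form with first-order SEs;
  I² = max(0, (Q − df)/Q).
- **Steiger** compares summed variance explained; the p-value is a
  two-sided z-test on the difference of Fisher-transformed |r| values
  treating the two GWAS as independent samples (the cohorts are
  disjoint by design; overlap correction is out of scope). Under no
  effect in either direction the z statistic is symmetric but
  under-dispersed relative to N(0,1) (the Fisher SE overstates the
  sampling SD of a difference of two small r² totals), so the null p is
  conservative rather than uniform — tested as such.
- **MR-PRESSO** computes the observed residual sum of squares about
  leave-one-out IVW predictions, simulates its null by redrawing outcome
  betas from N(loo_slope·β̂_X, se_out²), and uses the (1 + #exceedances)/
  (n_sim + 1) convention so p-values are never zero. Per-SNP p-values
  are Bonferroni-adjusted across k; the corrected estimate is IVW on the
  non-outliers (undefined with an explicit status when every SNP is
  flagged). The distortion p compares the observed corrected-minus-full
  difference against the same simulated null with the observed outlier
  indices removed — a simplification of the original bootstrap-based
  distortion test that keeps its interpretation.

## Colocalisation

Per-variant Wakefield log-ABFs (prior effect SD 0.2 for quantitative
traits, 0.15 on log-odds for binary — the upstream method's defaults;
only the p₁/p₂/p₁₂ priors are fixed by the study configuration) combine
into the five-hypothesis posterior in log space. The H3 mass (sum over
ordered pairs of distinct variants) is evaluated by pairwise log-sum-exp
with the diagonal excluded — exact and free of the cancellation that the
naive exp(S1)exp(S2) − exp(S12) subtraction suffers — for regions up to
1500 variants, beyond which a guarded log-space subtraction is used.
Regions are the instrument SNP ± 100 kb with ≥ 50 shared variants
required; multi-SNP instruments test one region per SNP and report the
maximum-PP_H4 region (the consolidation rule is a documented choice).
Variants are matched across traits by id; alleles are assumed
pre-harmonized upstream. The method assumes a single causal variant per
trait per region; multi-causal colocalisation is out of scope.

## Integration and triangulation

The four-analysis high-confidence intersection requires nominal
significance (p < 0.05) in IVW and outlier-corrected PRESSO, each with
and without the MHC. Bonferroni thresholds are α/(n_exposures ×
n_outcomes) at full precision (displayed at 2 significant figures).
Coloc support uses PP_H4 ≥ 0.8 (boundary inclusive). Classification:
a registry match for the same disease is `validation` when the MR
direction aligns with the drug mechanism (risk-increasing protein ↔
antagonist/inhibitor; protective ↔ agonist), `misaligned` when it
opposes it, and `direction_unassessed` for mechanisms outside that
vocabulary; a gene registered only for other diseases is `repurposing`;
an unregistered gene is `novel`; evidence without coloc support stays
`nominal` regardless of the registry. Sensitivity against registered
targets is reported with two denominators — instrumentable targets
(primary; avoids conflating coverage with power) and all registered
targets — with the per-disease mean ± SD (ddof = 1).

## Synthetic data

The generator emulates the statistical structure of the real inputs, not
their biology. For SNP j: maf_j ~ U(maf_range); exposure effects
γ_j ~ N(0, γ_sd²); direct (pleiotropic) outcome effects are
N(pleiotropy_mean, pleiotropy_sd²) *in the exposure-increasing-allele
orientation* (the orientation in which directional pleiotropy is defined
and in which MR-Egger fits; for mean 0 this coincides with a plain
symmetric draw); true outcome effects are θγ_j + α_j. Standard errors
are 1/√(2·maf(1−maf)·N) exactly; observed z-scores are LD-propagated
true z-scores plus noise with the LD correlation (block AR(1) matrices,
positive semi-definite by construction); p-values are two-sided normal.
Studies independently relabel effect alleles at random so harmonization
is always exercised. Regional scenarios place causal variants per the
H0–H4 sharing hypotheses (H3 draws from different LD blocks so the two
causal variants are uncorrelated). The target universe puts 5 genes
10 Mb apart on one chromosome, 120 regional variants each, one causal
cis variant per protein (|z| = 14 at N = 35,000) and a shared disease
signal (|z| = 10 at N = 150,000) only for truly causal pairs, plus a
small registry with validation/repurposing/decoy entries.

What the simulations do **not** model: realistic human LD maps,
individual-level genotypes, trans-pQTL networks, sample overlap between
cohorts, population stratification, or winner's-curse selection of
instruments. Passing tests therefore demonstrate internal statistical
correctness and calibration under the stated generative model, not
performance on any particular real cohort.

## Reference simulation conditions

The calibration studies (`targetmr.benchmarks`, also run by
`scripts/acceptance.py` and `tests/test_acceptance.py`) use:

- **Recovery/coverage**: θ = 0.3, 50 instruments, γ_sd = 0.1,
  N = 100,000 both sides, no pleiotropy; 1000 repetitions.
- **Type-I error**: θ = 0 with balanced pleiotropy sd 0.005 — chosen as
  the standard moderate-heterogeneity calibration where the pleiotropy
  variance is comparable to the median outcome-SE variance (measured
  I² ≈ 43%); extreme heterogeneity is a different regime in which
  multiplicative-RE IVW is known to inflate mildly and is discussed, not
  targeted, here. 1000 repetitions.
- **Egger recovery**: directional pleiotropy mean 0.02, sd 0.01, with
  the pipeline's F ≥ 10 filter applied before the fit as in the full
  procedure; without that filter, mis-orientation of near-null
  instruments dilutes the intercept by ~9% — an inherent property of
  Egger's reorientation, demonstrable with the same generator. 500
  repetitions.
- **PRESSO**: 20 SNPs, a 10-SE injected outlier, 1000 simulations per
  test; detection over 200 repetitions and null calibration (KS against
  uniform) over 200 repetitions.
- **Coloc scenarios**: 100 variants, AR(1) blocks of 5 at ρ = 0.5,
  causal |z| = 12, N = 50,000; 200 repetitions per hypothesis.
- **End-to-end**: the default target universe, 100 repetitions; a pair
  counts as supported at nominal MR p < 0.05 with PP_H4 ≥ 0.8.

These sizes keep the full suite around a minute on one CPU while leaving
Monte-Carlo error well below the asserted margins.

## Numerical conventions and edge cases

Degenerate inputs raise typed errors: zero exposure beta (Wald), all
zero exposure betas (IVW), k below the estimator minimum (Egger and
median/mode need 3, PRESSO needs 4). Bootstrap and simulation paths take
explicit seeds and are bit-for-bit reproducible; no global RNG state is
used by the library. p-values are floored at the smallest positive
float; posterior vectors renormalise to machine precision. File outputs
are written atomically (temp + rename) and runs record a manifest with
config echo, package version, input checksums and row counts.

## Known limitations

Multivariable MR, sample-overlap correction, CAUSE/contamination-mixture
estimators, SuSiE-style multi-causal colocalisation, proxy lookup for
missing outcome variants and LD estimation from genotypes are explicitly
out of scope. The Bonferroni threshold helper implements the
count-based formula; any externally imposed threshold can be supplied as
an override. MR-PRESSO's distortion test is the simplified null
described above.
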