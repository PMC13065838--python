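"""Two-sample MR estimators and sensitivity analyses.

Implements the Wald ratio, inverse-variance-weighted (IVW) regression,
MR-Egger (slope, intercept test and the I2_GX attenuation statistic),
the weighted median and weighted mode estimators, Cochran's Q / I2
heterogeneity statistics, the MR-PRESSO global/outlier/distortion tests
and Steiger directionality filtering.

Estimators are scikit-learn-style fitter classes (``get_params`` /
``set_params``, ``fit``, trailing-underscore fitted attributes); the
module-level functions are thin wrappers returning frozen result
records. All estimation is on the additive (log-odds for binary traits)
scale; odds ratios are derived only at reporting time.

Conventions
-----------
* IVW defaults to multiplicative random effects: the fixed-effects SE is
  inflated by ``max(1, sqrt(Q / (k - 1)))``.
* MR-Egger reorients every SNP so exposure betas are non-negative before
  fitting, and uses t reference distributions with k - 2 df.
* Per-SNP variance explained is approximated by ``r^2 = F / (F + n - 2)``
  with ``F = (beta / se)^2``.
* Bootstrap and simulation p-values use the ``(1 + #exceedances)/(n + 1)``
  convention, so they are never exactly zero.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .exceptions import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
)
from .instruments import HarmonizedSet

__all__ = [
    "MRResult", "SensitivityStats", "SteigerResult", "PressoResult",
    "WaldRatio", "IVW", "Egger", "WeightedMedian", "WeightedMode",
    "MRPresso",
    "wald_ratio", "ivw", "egger", "weighted_median", "weighted_mode",
    "cochran_q", "steiger", "mr_presso",
]

_Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class MRResult:
    """A causal-effect estimate with normal-theory 95% interval."""

    method: str
    k: int
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pval: float

    @property
    def odds_ratio(self) -> float:
        """exp(estimate): the OR interpretation for binary outcomes."""
        return float(np.exp(self.estimate))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


@dataclass(frozen=True)
class SensitivityStats:
    """Heterogeneity and pleiotropy diagnostics for a multi-SNP instrument."""

    q: float
    q_df: int
    q_pval: float
    i2: float
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None
    i2_gx: float | None = None


@dataclass(frozen=True)
class SteigerResult:
    """Directionality assessment: variance explained in exposure vs outcome."""

    r2_exp_total: float
    r2_out_total: float
    direction_correct: bool
    steiger_pval: float


@dataclass(frozen=True)
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    global_rss_obs: float
    global_pval: float
    per_snp_outlier_pval: pd.Series
    outlier_ids: list[str]
    corrected_estimate: MRResult | None
    distortion_pval: float | None
    n_sim: int
    seed: int
    status: str = "ok"


def _extract(data) -> pd.DataFrame:
    if isinstance(data, HarmonizedSet):
        df = data.df
    elif isinstance(data, pd.DataFrame):
        df = data
    else:
        raise TypeError(
            "expected a HarmonizedSet or DataFrame with beta_exp/se_exp/"
            f"beta_out/se_out columns, got {type(data).__name__}"
        )
    required = ["beta_exp", "se_exp", "beta_out", "se_out"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"instrument data missing column(s) {missing}")
    arr = df[required].to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("instrument betas/SEs must be finite")
    if np.any(arr[:, [1, 3]] <= 0):
        raise ValueError("all standard errors must be positive")
    return df


def _normal_result(method: str, k: int, est: float, se: float) -> MRResult:
    z = est / se if se > 0 else np.inf * np.sign(est)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z)))) if se > 0 else 0.0
    p = max(p, np.finfo(float).tiny)
    return MRResult(
        method, k, float(est), float(se),
        float(est - _Z975 * se), float(est + _Z975 * se), p,
    )


def _q_statistic(bx, by, sy, estimate) -> float:
    """Cochran's Q about a candidate slope, residual form: sum w (by - b*bx)^2."""
    return float(np.sum(((by - estimate * bx) / sy) ** 2))


class _MRFitter(BaseEstimator):
    """Shared fit plumbing for the MR estimators."""

    _method = "base"
    _min_k = 1

    def fit(self, X, y=None):
        df = _extract(X)
        if len(df) < self._min_k:
            raise InsufficientInstrumentsError(
                f"{self._method} requires at least {self._min_k} SNP(s), "
                f"got {len(df)}"
            )
        self.k_ = len(df)
        self._fit(
            df["beta_exp"].to_numpy(dtype=float),
            df["se_exp"].to_numpy(dtype=float),
            df["beta_out"].to_numpy(dtype=float),
            df["se_out"].to_numpy(dtype=float),
            df,
        )
        result = _normal_result(self._method, self.k_, self.estimate_, self.se_)
        if getattr(self, "_df_resid", None):
            p = 2.0 * stats.t.sf(abs(self.estimate_ / self.se_), self._df_resid)
            result = MRResult(
                self._method, self.k_, self.estimate_, self.se_,
                result.ci_low, result.ci_high,
                float(max(min(1.0, p), np.finfo(float).tiny)),
            )
        self.result_ = result
        self.pval_ = result.pval
        self.ci_low_, self.ci_high_ = result.ci_low, result.ci_high
        return self

    def _fit(self, bx, sx, by, sy, df):  # pragma: no cover - abstract
        raise NotImplementedError


class WaldRatio(_MRFitter):
    """Single-SNP causal estimate: beta_out / beta_exp.

    The default SE is the first-order delta method ``se_out / |beta_exp|``;
    ``second_order=True`` adds the exposure-uncertainty term
    ``beta_out^2 se_exp^2 / beta_exp^4``.
    """

    _method = "wald_ratio"
    _min_k = 1

    def __init__(self, second_order: bool = False):
        self.second_order = second_order

    def _fit(self, bx, sx, by, sy, df):
        if len(bx) != 1:
            raise InsufficientInstrumentsError(
                f"wald_ratio requires exactly one SNP, got {len(bx)}"
            )
        if bx[0] == 0:
            raise DegenerateInstrumentError(
                "wald_ratio undefined: beta_exp is zero"
            )
        self.estimate_ = float(by[0] / bx[0])
        var = (sy[0] / bx[0]) ** 2
        if self.second_order:
            var += by[0] ** 2 * sx[0] ** 2 / bx[0] ** 4
        self.se_ = float(np.sqrt(var))


class IVW(_MRFitter):
    """Inverse-variance-weighted estimator (zero-intercept WLS).

    Slope of beta_out on beta_exp with weights 1/se_out^2. With
    ``random_effects=True`` (default) the fixed-effects SE is scaled by
    ``max(1, sqrt(Q/(k-1)))`` (multiplicative random-effects model).
    A single SNP delegates to the Wald ratio.
    """

    _method = "ivw"
    _min_k = 1

    def __init__(self, random_effects: bool = True):
        self.random_effects = random_effects

    def _fit(self, bx, sx, by, sy, df):
        if np.all(bx == 0):
            raise DegenerateInstrumentError("IVW degenerate: all beta_exp are zero")
        w = 1.0 / sy**2
        sxx = float(np.sum(w * bx**2))
        self.estimate_ = float(np.sum(w * bx * by) / sxx)
        self.se_fixed_ = float(1.0 / np.sqrt(sxx))
        k = len(bx)
        self.q_ = _q_statistic(bx, by, sy, self.estimate_)
        self.q_df_ = k - 1
        if k > 1:
            self.q_pval_ = float(stats.chi2.sf(self.q_, self.q_df_))
            self.i2_ = float(max(0.0, (self.q_ - self.q_df_) / self.q_)) if self.q_ > 0 else 0.0
            self.re_scale_ = (
                max(1.0, float(np.sqrt(self.q_ / self.q_df_)))
                if self.random_effects
                else 1.0
            )
        else:
            self.q_pval_ = float("nan")
            self.i2_ = float("nan")
            self.re_scale_ = 1.0
        self.se_ = self.se_fixed_ * self.re_scale_

    def sensitivity_(self) -> SensitivityStats:
        return SensitivityStats(self.q_, self.q_df_, self.q_pval_, self.i2_)


class Egger(_MRFitter):
    """MR-Egger regression: WLS of beta_out on beta_exp with intercept.

    Rows are reoriented so every exposure beta is non-negative before
    fitting. A non-zero intercept indicates directional pleiotropy. SEs
    use the multiplicative random-effects scale ``max(1, sqrt(Q/(k-2)))``
    and t reference distributions with k - 2 df. ``I2_GX`` quantifies
    attenuation from exposure-measurement error (NOME violation).

    ``with_intercept=False`` is an internal check mode that reproduces
    the fixed-effects IVW slope.
    """

    _method = "egger"
    _min_k = 3

    def __init__(self, with_intercept: bool = True):
        self.with_intercept = with_intercept

    def _fit(self, bx, sx, by, sy, df):
        # reorient so all exposure effects are non-negative
        sign = np.where(bx < 0, -1.0, 1.0)
        bx, by = bx * sign, by * sign
        w = 1.0 / sy**2
        k = len(bx)
        if self.with_intercept:
            X = np.column_stack([np.ones(k), bx])
        else:
            X = bx[:, None]
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], by * sw, rcond=None)
        resid = by - X @ coef
        q = float(np.sum(w * resid**2))
        df_resid = k - X.shape[1]
        scale = max(1.0, np.sqrt(q / df_resid)) if df_resid > 0 else 1.0
        # pinv tolerates the collinear degenerate design (all bx equal)
        with np.errstate(invalid="ignore"):
            cov = np.linalg.pinv(X.T @ (X * w[:, None])) * scale**2
        if self.with_intercept:
            self.intercept_ = float(coef[0])
            self.intercept_se_ = float(np.sqrt(cov[0, 0]))
            tstat = self.intercept_ / self.intercept_se_
            self.intercept_pval_ = float(
                max(min(1.0, 2.0 * stats.t.sf(abs(tstat), df_resid)),
                    np.finfo(float).tiny)
            )
            slope_idx = 1
        else:
            self.intercept_ = self.intercept_se_ = None
            self.intercept_pval_ = None
            slope_idx = 0
        self.estimate_ = float(coef[slope_idx])
        self.se_ = float(np.sqrt(cov[slope_idx, slope_idx]))
        self.q_ = q
        self.q_df_ = df_resid
        self.q_pval_ = (
            float(stats.chi2.sf(q, df_resid)) if df_resid > 0 else float("nan")
        )
        self.i2_ = float(max(0.0, (q - df_resid) / q)) if q > 0 else 0.0
        self._df_resid = df_resid

        # I2_GX: weighted heterogeneity of the exposure betas themselves
        wx = 1.0 / sx**2
        bx_wbar = float(np.sum(wx * bx) / np.sum(wx))
        q_gx = float(np.sum((bx - bx_wbar) ** 2 * wx))
        self.i2_gx_ = (
            float(max(0.0, (q_gx - (k - 1)) / q_gx)) if q_gx > 0 else 0.0
        )

    def sensitivity_(self) -> SensitivityStats:
        return SensitivityStats(
            self.q_, self.q_df_, self.q_pval_, self.i2_,
            self.intercept_, self.intercept_se_, self.intercept_pval_,
            self.i2_gx_,
        )


def _ratios(bx, by, sy):
    """Per-SNP Wald ratios with first-order delta SEs."""
    ratio = by / bx
    se_r = np.abs(sy / bx)
    return ratio, se_r


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if cum[0] >= 0.5:
        return float(v[0])
    below = int(np.max(np.flatnonzero(cum < 0.5)))
    if below == len(v) - 1:
        return float(v[-1])
    frac = (0.5 - cum[below]) / (cum[below + 1] - cum[below])
    return float(v[below] + (v[below + 1] - v[below]) * frac)


def _weighted_median_rows(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted median for a (B, k) matrix (bootstrap helper)."""
    order = np.argsort(values, axis=1, kind="stable")
    v = np.take_along_axis(values, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    cum = (np.cumsum(w, axis=1) - 0.5 * w) / np.sum(w, axis=1, keepdims=True)
    out = np.empty(len(values))
    for i in range(len(values)):
        ci, vi = cum[i], v[i]
        if ci[0] >= 0.5:
            out[i] = vi[0]
            continue
        below = int(np.max(np.flatnonzero(ci < 0.5)))
        if below == len(vi) - 1:
            out[i] = vi[-1]
        else:
            frac = (0.5 - ci[below]) / (ci[below + 1] - ci[below])
            out[i] = vi[below] + (vi[below + 1] - vi[below]) * frac
    return out


class WeightedMedian(_MRFitter):
    """Weighted median of per-SNP Wald ratios (inverse-variance weights).

    Consistent when at least half the weight comes from valid
    instruments. The SE is a seeded parametric bootstrap: exposure and
    outcome betas are resampled from their normal distributions and the
    weighted median recomputed.
    """

    _method = "weighted_median"
    _min_k = 3

    def __init__(self, n_boot: int = 1000, seed: int = 0):
        self.n_boot = n_boot
        self.seed = seed

    def _fit(self, bx, sx, by, sy, df):
        if np.any(bx == 0):
            raise DegenerateInstrumentError(
                "weighted_median undefined with a zero beta_exp"
            )
        ratio, se_r = _ratios(bx, by, sy)
        self.estimate_ = _weighted_median(ratio, 1.0 / se_r**2)
        rng = np.random.default_rng(self.seed)
        bxs = rng.normal(bx, sx, size=(self.n_boot, len(bx)))
        bys = rng.normal(by, sy, size=(self.n_boot, len(bx)))
        bxs = np.where(bxs == 0, np.finfo(float).eps, bxs)
        r = bys / bxs
        w = (bxs / sy) ** 2
        self.boot_estimates_ = _weighted_median_rows(r, w)
        self.se_ = float(np.std(self.boot_estimates_, ddof=1))


def _mode_bandwidth(ratio: np.ndarray, phi: float) -> float:
    """phi x modified Silverman rule on the per-SNP ratios."""
    s = np.std(ratio, ddof=1)
    iqr = np.subtract(*np.percentile(ratio, [75, 25]))
    spread = min(s, iqr / 1.349) if iqr > 0 else s
    return phi * 0.9 * spread * len(ratio) ** (-0.2)


def _kde_mode(ratio: np.ndarray, weights: np.ndarray, h: float, grid_n: int = 512) -> float:
    if h <= 0 or not np.isfinite(h):
        # degenerate spread: all ratios (essentially) identical
        return float(ratio[0])
    grid = np.linspace(ratio.min() - 3 * h, ratio.max() + 3 * h, grid_n)
    dens = np.sum(
        weights[None, :] * np.exp(-0.5 * ((grid[:, None] - ratio[None, :]) / h) ** 2),
        axis=1,
    )
    return float(grid[int(np.argmax(dens))])


class WeightedMode(_MRFitter):
    """Mode of the weighted kernel density of per-SNP Wald ratios.

    Normal kernel with bandwidth ``phi`` times a modified Silverman rule
    (0.9 min(sd, IQR/1.349) k^(-1/5)); SE by seeded parametric bootstrap.
    Consistent when the largest group of instruments sharing a ratio is
    valid (ZEMPA assumption).
    """

    _method = "weighted_mode"
    _min_k = 3

    def __init__(self, phi: float = 1.0, n_boot: int = 1000, seed: int = 0):
        self.phi = phi
        self.n_boot = n_boot
        self.seed = seed

    def _fit(self, bx, sx, by, sy, df):
        if np.any(bx == 0):
            raise DegenerateInstrumentError(
                "weighted_mode undefined with a zero beta_exp"
            )
        ratio, se_r = _ratios(bx, by, sy)
        w = 1.0 / se_r**2
        h = _mode_bandwidth(ratio, self.phi)
        self.bandwidth_ = h
        self.estimate_ = _kde_mode(ratio, w, h)
        rng = np.random.default_rng(self.seed)
        boots = np.empty(self.n_boot)
        for b in range(self.n_boot):
            bxs = rng.normal(bx, sx)
            bys = rng.normal(by, sy)
            bxs = np.where(bxs == 0, np.finfo(float).eps, bxs)
            r = bys / bxs
            wb = (bxs / sy) ** 2
            boots[b] = _kde_mode(r, wb, _mode_bandwidth(r, self.phi))
        self.boot_estimates_ = boots
        self.se_ = float(np.std(boots, ddof=1))


class MRPresso(BaseEstimator):
    """MR-PRESSO: simulation-based global heterogeneity and outlier test.

    The observed global statistic is the weighted residual sum of squares
    about leave-one-out IVW predictions. Its null distribution is built
    by redrawing outcome betas from ``N(loo_slope_j * beta_exp_j,
    se_out_j^2)`` ``n_sim`` times and re-running the same procedure.
    Per-SNP outlier p-values (Bonferroni-adjusted across k) flag
    outliers; the corrected estimate is IVW on the non-outliers; the
    distortion p-value compares the observed corrected-minus-full
    difference with its simulated null.
    """

    def __init__(self, n_sim: int = 1000, seed: int = 0, outlier_alpha: float = 0.05):
        self.n_sim = n_sim
        self.seed = seed
        self.outlier_alpha = outlier_alpha

    def fit(self, X, y=None):
        df = _extract(X)
        k = len(df)
        if k < 4:
            raise InsufficientInstrumentsError(
                f"MR-PRESSO requires at least 4 SNPs, got {k}"
            )
        bx = df["beta_exp"].to_numpy(dtype=float)
        by = df["beta_out"].to_numpy(dtype=float)
        sy = df["se_out"].to_numpy(dtype=float)
        ids = (
            df["variant_id"].astype(str).to_numpy()
            if "variant_id" in df
            else np.array([str(i) for i in range(k)])
        )
        w = 1.0 / sy**2

        def loo_slopes(yvec: np.ndarray) -> np.ndarray:
            sxy = np.sum(w * bx * yvec, axis=-1, keepdims=True)
            sxx = np.sum(w * bx**2)
            return (sxy - w * bx * yvec) / (sxx - w * bx**2)

        loo = loo_slopes(by)
        rss_obs = w * (by - loo * bx) ** 2
        self.global_rss_obs_ = float(np.sum(rss_obs))

        rng = np.random.default_rng(self.seed)
        y_sim = rng.normal(loo * bx, sy, size=(self.n_sim, k))
        loo_sim = loo_slopes(y_sim)
        rss_sim = w * (y_sim - loo_sim * bx) ** 2
        global_sim = np.sum(rss_sim, axis=1)
        self.global_pval_ = float(
            (1 + np.sum(global_sim >= self.global_rss_obs_)) / (self.n_sim + 1)
        )
        per_snp = (1 + np.sum(rss_sim >= rss_obs[None, :], axis=0)) / (self.n_sim + 1)
        adjusted = np.minimum(1.0, per_snp * k)
        self.per_snp_outlier_pval_ = pd.Series(adjusted, index=ids)
        outlier_mask = adjusted < self.outlier_alpha
        self.outlier_ids_ = list(ids[outlier_mask])

        full = IVW().fit(df)
        self.full_estimate_ = full.result_
        self.status_ = "ok"
        if outlier_mask.all():
            self.corrected_estimate_ = None
            self.distortion_pval_ = None
            self.status_ = "all_snps_flagged"
        elif outlier_mask.any():
            corrected = IVW().fit(df[~outlier_mask])
            self.corrected_estimate_ = corrected.result_
            obs_d = corrected.result_.estimate - full.result_.estimate
            # simulated null of no distortion: same indices removed
            d_sim = _ivw_slopes(bx[~outlier_mask], y_sim[:, ~outlier_mask],
                                sy[~outlier_mask]) - _ivw_slopes(bx, y_sim, sy)
            self.distortion_pval_ = float(
                (1 + np.sum(np.abs(d_sim) >= abs(obs_d))) / (self.n_sim + 1)
            )
        else:
            self.corrected_estimate_ = full.result_
            self.distortion_pval_ = None
        return self

    def result_(self) -> PressoResult:
        return PressoResult(
            self.global_rss_obs_, self.global_pval_,
            self.per_snp_outlier_pval_, self.outlier_ids_,
            self.corrected_estimate_, self.distortion_pval_,
            self.n_sim, self.seed, self.status_,
        )


def _ivw_slopes(bx: np.ndarray, y: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Vectorized fixed-effects IVW slope for rows of simulated outcomes."""
    w = 1.0 / sy**2
    return np.sum(w * bx * y, axis=-1) / np.sum(w * bx**2)


# ---------------------------------------------------------------------------
# functional wrappers

def wald_ratio(data, second_order: bool = False) -> MRResult:
    return WaldRatio(second_order=second_order).fit(data).result_


def ivw(data, random_effects: bool = True) -> tuple[MRResult, SensitivityStats]:
    df = _extract(data)
    if len(df) == 1:
        res = wald_ratio(df)
        return res, SensitivityStats(0.0, 0, float("nan"), 0.0)
    est = IVW(random_effects=random_effects).fit(df)
    return est.result_, est.sensitivity_()


def egger(data) -> tuple[MRResult, SensitivityStats]:
    est = Egger().fit(data)
    return est.result_, est.sensitivity_()


def weighted_median(data, n_boot: int = 1000, seed: int = 0) -> MRResult:
    return WeightedMedian(n_boot=n_boot, seed=seed).fit(data).result_


def weighted_mode(
    data, phi: float = 1.0, n_boot: int = 1000, seed: int = 0
) -> MRResult:
    return WeightedMode(phi=phi, n_boot=n_boot, seed=seed).fit(data).result_


def cochran_q(data, estimate: float) -> tuple[float, int, float, float]:
    """Cochran's Q of per-SNP ratios about ``estimate`` (+ df, p, I2)."""
    df = _extract(data)
    bx = df["beta_exp"].to_numpy(dtype=float)
    by = df["beta_out"].to_numpy(dtype=float)
    sy = df["se_out"].to_numpy(dtype=float)
    q = _q_statistic(bx, by, sy, estimate)
    q_df = len(df) - 1
    pval = float(stats.chi2.sf(q, q_df)) if q_df > 0 else float("nan")
    i2 = float(max(0.0, (q - q_df) / q)) if q > 0 else 0.0
    return q, q_df, pval, i2


def steiger(data) -> SteigerResult:
    """Steiger directionality: does the instrument explain more exposure
    than outcome variance?

    The p-value is a two-sided z-test on the difference of
    Fisher-transformed |r| values, treating the two GWAS as independent
    samples.
    """
    df = _extract(data)
    r2_exp = float(df["r2_exp"].sum())
    r2_out = float(df["r2_out"].sum())
    n_exp = float(df["n_exp"].mean())
    n_out = float(df["n_out"].mean())
    r_exp = min(np.sqrt(max(r2_exp, 0.0)), 1 - 1e-12)
    r_out = min(np.sqrt(max(r2_out, 0.0)), 1 - 1e-12)
    denom = np.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    z = (np.arctanh(r_exp) - np.arctanh(r_out)) / denom
    pval = float(max(min(1.0, 2.0 * stats.norm.sf(abs(z))), np.finfo(float).tiny))
    return SteigerResult(r2_exp, r2_out, r2_exp > r2_out, pval)


def mr_presso(
    data, n_sim: int = 1000, seed: int = 0, outlier_alpha: float = 0.05
) -> PressoResult:
    return (
        MRPresso(n_sim=n_sim, seed=seed, outlier_alpha=outlier_alpha)
        .fit(data)
        .result_()
    )
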