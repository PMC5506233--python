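"""Causal-effect estimators for summarized two-sample MR data.

The model is the per-variant decomposition

    beta_Yj = alpha_j + theta * beta_Xj

where alpha_j is the direct (pleiotropic) effect of variant j on the
outcome and theta the causal effect of the risk factor. Estimators:

* ``ratio_estimate`` — the single-variant Wald ratio beta_y/beta_x.
* ``ivw_estimate`` — inverse-variance weighted combination of the ratios,
  equivalently a weighted no-intercept regression of beta_y on beta_x.
* ``egger_estimate`` — the same regression with a free intercept; the
  intercept estimates the average pleiotropic effect (MR-Egger).
* ``median_estimate`` — simple or weighted median of the per-variant
  ratios, robust to <50% invalid instruments; bootstrap SE.
* ``robust_ivw`` — the no-intercept weighted regression refitted with
  Tukey's bisquare loss (MM-type estimation), bounding the contribution
  of any single variant.

Variance models: ``fixed`` takes the residual standard error sigma as 1
(no heterogeneity between per-variant causal estimates);
``random_multiplicative`` estimates sigma from the regression residuals,
truncated below at one — underdispersion of uncorrelated genetic
associations is not biologically plausible, so a random-effects analysis
never reports a smaller SE than the fixed-effect one. The untruncated
sigma is always reported so underdispersion remains visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import (
    ConfigurationError,
    ConvergenceError,
    EggerResult,
    InsufficientVariantsError,
    MRDataset,
    MREstimate,
    NonIdentifiableError,
    UndefinedRatioError,
    VariantAssociation,
)

__all__ = [
    "VarianceModelConfig",
    "BootstrapConfig",
    "ratio_estimate",
    "ivw_estimate",
    "egger_estimate",
    "median_estimate",
    "robust_ivw",
    "weighted_median",
]


@dataclass(frozen=True)
class VarianceModelConfig:
    """How standard errors, intervals and p-values are formed.

    ``model``: 'fixed' (sigma = 1) or 'random_multiplicative' (sigma
    estimated, truncated below at 1 when ``truncate_sigma_at_one``).
    ``df_rule``: 't_residual_df' uses a t reference with the regression's
    residual degrees of freedom (J-1 for IVW, J-2 for MR-Egger); 'normal'
    uses z quantiles (for large-J work).
    """

    model: str = "random_multiplicative"
    truncate_sigma_at_one: bool = True
    df_rule: str = "t_residual_df"
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.model not in ("fixed", "random_multiplicative"):
            raise ConfigurationError(f"unknown variance model {self.model!r}")
        if self.df_rule not in ("t_residual_df", "normal"):
            raise ConfigurationError(f"unknown df_rule {self.df_rule!r}")
        if not (0 < self.ci_level < 1):
            raise ConfigurationError("ci_level must lie in (0, 1)")


@dataclass(frozen=True)
class BootstrapConfig:
    """Parametric-bootstrap settings for median-method standard errors."""

    n_iterations: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 100:
            raise ConfigurationError("n_iterations must be at least 100")


# ---------------------------------------------------------------------------
# Shared inference helpers
# ---------------------------------------------------------------------------

def _interval(estimate: float, se: float, df: int | None, ci_level: float,
              df_rule: str) -> tuple[float, float, float]:
    """CI bounds and two-sided p-value; t when df allows, else normal."""
    if df_rule == "t_residual_df" and df is not None and df >= 1:
        dist = stats.t(df)
    else:
        dist = stats.norm()
    q = dist.ppf(0.5 + ci_level / 2.0)
    p = 2.0 * dist.sf(abs(estimate / se))
    return estimate - q * se, estimate + q * se, float(min(p, 1.0))


def _apply_sigma(se_fixed: float, sigma_hat: float, cfg: VarianceModelConfig) -> float:
    if cfg.model == "fixed":
        return se_fixed
    sigma = sigma_hat
    if cfg.truncate_sigma_at_one:
        sigma = max(sigma, 1.0)
    return se_fixed * sigma


def _or_view(est: float, lo: float, hi: float,
             outcome_scale: str) -> tuple[float, float, float] | None:
    if outcome_scale != "log_odds":
        return None
    return (float(np.exp(est)), float(np.exp(lo)), float(np.exp(hi)))


def _make_estimate(method: str, estimate: float, se: float, df: int | None,
                   cfg: VarianceModelConfig, sigma_hat: float, n: int,
                   outcome_scale: str, variance_model: str | None = None) -> MREstimate:
    lo, hi, p = _interval(estimate, se, df, cfg.ci_level, cfg.df_rule)
    return MREstimate(
        method=method,
        estimate=float(estimate),
        se=float(se),
        ci_lower=float(lo),
        ci_upper=float(hi),
        p_value=p,
        variance_model=variance_model or cfg.model,
        sigma_hat=float(sigma_hat),
        n_variants=n,
        ci_level=cfg.ci_level,
        odds_ratio_view=_or_view(estimate, lo, hi, outcome_scale),
    )


# ---------------------------------------------------------------------------
# Ratio and IVW
# ---------------------------------------------------------------------------

def ratio_estimate(v: VariantAssociation, ci_level: float = 0.95,
                   outcome_scale: str = "continuous") -> MREstimate:
    """Single-variant Wald ratio beta_y/beta_x.

    The SE is the leading delta-method term se_y/|beta_x| (uncertainty in
    beta_x ignored), matching the weights used by the IVW method.
    """
    estimate = v.ratio  # raises UndefinedRatioError if beta_x == 0
    se = v.se_y / abs(v.beta_x)
    lo, hi, p = _interval(estimate, se, None, ci_level, "normal")
    return MREstimate(
        method="ratio", estimate=float(estimate), se=float(se),
        ci_lower=float(lo), ci_upper=float(hi), p_value=p,
        variance_model="fixed", sigma_hat=float("nan"), n_variants=1,
        ci_level=ci_level,
        odds_ratio_view=_or_view(estimate, lo, hi, outcome_scale),
    )


def _check_uncorrelated(data: MRDataset) -> None:
    if data.correlation is not None:
        raise ConfigurationError(
            "dataset carries a variant correlation matrix; use the "
            "correlated-variant estimators (mrkit.correlated) instead"
        )


def ivw_estimate(data: MRDataset, cfg: VarianceModelConfig | None = None) -> MREstimate:
    """Inverse-variance weighted causal estimate.

    Closed form: theta = sum(by*bx*w) / sum(bx^2*w) with w = se_y^-2 —
    identical to the weighted no-intercept regression of beta_y on beta_x.
    Variance = sigma^2 / sum(bx^2 * w); sigma = 1 under the fixed model,
    otherwise the regression residual standard error (reported untruncated
    in ``sigma_hat``, truncated below at 1 for the SE).
    """
    cfg = cfg or VarianceModelConfig()
    _check_uncorrelated(data)
    J = len(data)
    bx, by, w = data.beta_x, data.beta_y, data.se_y ** -2.0
    denom = float(np.sum(bx ** 2 * w))
    if denom == 0:
        raise NonIdentifiableError("all beta_x are zero: IVW is undefined")
    estimate = float(np.sum(by * bx * w) / denom)
    se_fixed = denom ** -0.5
    df = J - 1
    if df >= 1:
        sigma_hat = float(np.sqrt(np.sum(w * (by - estimate * bx) ** 2) / df))
    else:
        sigma_hat = float("nan")
        if cfg.model == "random_multiplicative":
            warnings.warn(
                "single-variant dataset: residual scale is not estimable; "
                "reporting the fixed-effect standard error",
                UserWarning, stacklevel=2,
            )
            cfg = VarianceModelConfig("fixed", cfg.truncate_sigma_at_one,
                                      cfg.df_rule, cfg.ci_level)
    se = _apply_sigma(se_fixed, sigma_hat, cfg)
    return _make_estimate("ivw", estimate, se, df if df >= 1 else None,
                          cfg, sigma_hat, J, data.outcome_scale)


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

def egger_estimate(data: MRDataset, cfg: VarianceModelConfig | None = None) -> EggerResult:
    """MR-Egger regression: weighted regression of beta_y on beta_x with a
    free intercept (weights se_y^-2).

    The intercept estimates the inverse-variance weighted average
    pleiotropic effect; its test against zero is the intercept test for
    directional pleiotropy. The slope is the causal estimate under the
    InSIDE assumption. Heterogeneity is expected when variants are
    pleiotropic, so the default variance model is multiplicative random
    effects; the slope variance is sigma'^2 / sum(w*(bx - bx_bar)^2).
    Datasets should be orientated first (the result depends on the allele
    coding); a warning is emitted if any beta_x is negative.
    """
    cfg = cfg or VarianceModelConfig()
    _check_uncorrelated(data)
    J = len(data)
    if J < 3:
        raise InsufficientVariantsError(
            f"MR-Egger needs at least 3 variants (got {J}): two regression "
            "parameters plus at least one residual degree of freedom"
        )
    bx, by, w = data.beta_x, data.beta_y, data.se_y ** -2.0
    if np.any(bx < 0):
        warnings.warn(
            "some beta_x are negative: MR-Egger depends on variant "
            "orientation; consider orient_variants() first",
            UserWarning, stacklevel=2,
        )
    sw = float(np.sum(w))
    bx_bar = float(np.sum(w * bx) / sw)
    by_bar = float(np.sum(w * by) / sw)
    sxx = float(np.sum(w * (bx - bx_bar) ** 2))
    if sxx <= 1e-24 * max(1.0, float(np.sum(w * bx ** 2))):
        raise NonIdentifiableError(
            "all risk-factor associations are (numerically) equal: with no "
            "spread in beta_x neither the MR-Egger intercept nor the slope "
            "is identified"
        )
    slope = float(np.sum(w * (bx - bx_bar) * (by - by_bar)) / sxx)
    intercept = by_bar - slope * bx_bar
    df = J - 2
    resid = by - intercept - slope * bx
    sigma_hat = float(np.sqrt(np.sum(w * resid ** 2) / df))
    se_slope_fixed = sxx ** -0.5
    se_int_fixed = float(np.sqrt(1.0 / sw + bx_bar ** 2 / sxx))
    se_slope = _apply_sigma(se_slope_fixed, sigma_hat, cfg)
    se_int = _apply_sigma(se_int_fixed, sigma_hat, cfg)

    from .diagnostics import i_squared_gx  # local import avoids a cycle

    i2 = i_squared_gx(data) if J >= 2 else 0.0
    slope_est = _make_estimate("egger_slope", slope, se_slope, df, cfg,
                               sigma_hat, J, data.outcome_scale)
    int_est = _make_estimate("egger_intercept", intercept, se_int, df, cfg,
                             sigma_hat, J, "continuous")
    return EggerResult(intercept=int_est, slope=slope_est, i2_gx=i2,
                       beta_x_bar=bx_bar)


# ---------------------------------------------------------------------------
# Median methods
# ---------------------------------------------------------------------------

def weighted_median(values: np.ndarray, weights: np.ndarray,
                    tiebreak: np.ndarray | None = None) -> float:
    """Interpolated weighted median.

    Sort values (stably, by (value, tiebreak)); with normalized weights
    w_(j), form cumulative midpoints s_j = sum_{k<=j} w_(k) - w_(j)/2 and
    linearly interpolate the sorted values at s = 1/2. With equal weights
    this reduces to the ordinary median (mean of the central pair for
    even counts).
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ConfigurationError("values and weights must have equal length")
    if tiebreak is None:
        order = np.argsort(values, kind="stable")
    else:
        order = np.lexsort((np.asarray(tiebreak), values))
    v, w = values[order], weights[order]
    wn = w / np.sum(w)
    s = np.cumsum(wn) - wn / 2.0
    if 0.5 <= s[0]:
        return float(v[0])
    if 0.5 >= s[-1]:
        return float(v[-1])
    return float(np.interp(0.5, s, v))


def _ratio_weights(bx: np.ndarray, by: np.ndarray, se_x: np.ndarray,
                   se_y: np.ndarray, second_order: bool) -> np.ndarray:
    var = se_y ** 2 / bx ** 2
    if second_order:
        var = var + by ** 2 * se_x ** 2 / bx ** 4
    return 1.0 / var


def median_estimate(
    data: MRDataset,
    weighting: str = "weighted",
    boot: BootstrapConfig | None = None,
    ci_level: float = 0.95,
    second_order_weights: bool = False,
) -> MREstimate:
    """Simple or weighted median of the per-variant ratio estimates.

    Consistent when variants carrying at least half the weight are valid
    instruments. Weighted-median weights are the inverse first-order
    delta-method variances se_y^2/beta_x^2 of the ratio estimates
    (optionally with the second-order term beta_y^2*se_x^2/beta_x^4). The
    SE comes from a seeded parametric bootstrap: beta_x and beta_y are
    redrawn from normal distributions centred at their estimates with the
    reported SEs and the median recomputed each iteration.
    """
    if weighting not in ("simple", "weighted"):
        raise ConfigurationError(f"unknown weighting {weighting!r}")
    boot = boot or BootstrapConfig()
    J = len(data)
    if J < 3:
        raise InsufficientVariantsError(
            f"median methods need at least 3 variants (got {J})"
        )
    bad = [v.variant_id for v in data.variants if v.beta_x == 0]
    if bad:
        raise UndefinedRatioError(
            f"ratio estimates undefined (beta_x == 0) for variants: {bad}; "
            "exclude them before a median analysis"
        )
    bx, by, se_x, se_y = data.beta_x, data.beta_y, data.se_x, data.se_y
    ids = np.asarray(data.variant_ids)
    ratios = by / bx

    def point(bx_, by_):
        r = by_ / bx_
        if weighting == "simple":
            w = np.ones_like(r)
        else:
            w = _ratio_weights(bx_, by_, se_x, se_y, second_order_weights)
        return weighted_median(r, w, tiebreak=ids)

    estimate = point(bx, by)

    rng = np.random.default_rng(boot.seed)
    B = boot.n_iterations
    bx_b = rng.normal(bx, se_x, size=(B, J))
    by_b = rng.normal(by, se_y, size=(B, J))
    # resampled beta_x sitting exactly at 0 has probability 0; nudge if hit
    bx_b[bx_b == 0] = np.finfo(float).tiny
    boots = np.empty(B)
    for b in range(B):
        boots[b] = point(bx_b[b], by_b[b])
    se = float(np.std(boots, ddof=1))
    if se == 0:
        se = np.finfo(float).tiny  # degenerate bootstrap; keep SE positive
    lo, hi, p = _interval(estimate, se, None, ci_level, "normal")
    return MREstimate(
        method=f"{weighting}_median", estimate=float(estimate), se=se,
        ci_lower=float(lo), ci_upper=float(hi), p_value=p,
        variance_model="bootstrap", sigma_hat=float("nan"), n_variants=J,
        ci_level=ci_level,
        odds_ratio_view=_or_view(estimate, lo, hi, data.outcome_scale),
    )


# ---------------------------------------------------------------------------
# Robust IVW (Tukey bisquare)
# ---------------------------------------------------------------------------

def _bisquare_weights(u: np.ndarray) -> np.ndarray:
    out = np.zeros_like(u)
    inside = np.abs(u) < 1
    out[inside] = (1 - u[inside] ** 2) ** 2
    return out


def robust_ivw(
    data: MRDataset,
    tuning: float = 4.685,
    cfg: VarianceModelConfig | None = None,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> MREstimate:
    """Robust IVW: the no-intercept weighted regression refitted with
    Tukey's bisquare objective (MM-type estimation).

    Working in the whitened coordinates x = beta_x/se_y, y = beta_y/se_y,
    the slope is initialized by a least-absolute-deviations fit (the
    |x|-weighted median of y/x), the residual scale fixed at the
    normalized MAD of the initial residuals, then iteratively reweighted
    least squares with bisquare weights is run to convergence. The default
    tuning constant 4.685 gives 95% efficiency at the Gaussian model; the
    contribution of any single variant to the objective is bounded. SE via
    the Huber sandwich on the bisquare psi-function.
    """
    cfg = cfg or VarianceModelConfig()
    _check_uncorrelated(data)
    J = len(data)
    if J < 3:
        raise InsufficientVariantsError(
            f"robust IVW needs at least 3 variants (got {J})"
        )
    if tuning <= 0:
        raise ConfigurationError("tuning constant must be positive")
    x = data.beta_x / data.se_y
    y = data.beta_y / data.se_y
    nz = x != 0
    if not np.any(nz):
        raise NonIdentifiableError("all beta_x are zero: slope undefined")
    theta = weighted_median(y[nz] / x[nz], np.abs(x[nz]))  # LAD initial fit
    r = y - theta * x
    scale = float(np.median(np.abs(r)) / 0.6744897501960817)
    if scale < 1e-12 * max(1.0, float(np.max(np.abs(y))) ):
        # exact fit: no downweighting possible, bisquare = least squares
        ivw = ivw_estimate(data, VarianceModelConfig(
            "fixed", cfg.truncate_sigma_at_one, cfg.df_rule, cfg.ci_level))
        return MREstimate(
            method="robust_ivw", estimate=ivw.estimate, se=ivw.se,
            ci_lower=ivw.ci_lower, ci_upper=ivw.ci_upper, p_value=ivw.p_value,
            variance_model="robust", sigma_hat=0.0, n_variants=J,
            ci_level=cfg.ci_level,
            odds_ratio_view=ivw.odds_ratio_view,
        )
    for _ in range(max_iter):
        u = (y - theta * x) / (tuning * scale)
        om = _bisquare_weights(u)
        denom = float(np.sum(om * x ** 2))
        if denom == 0:
            raise ConvergenceError(
                f"all variants downweighted to zero at iterate {theta!r}; "
                "increase the tuning constant"
            )
        theta_new = float(np.sum(om * x * y) / denom)
        if abs(theta_new - theta) <= tol * (1.0 + abs(theta)):
            theta = theta_new
            break
        theta = theta_new
    else:
        raise ConvergenceError(
            f"bisquare IRLS did not converge in {max_iter} iterations; "
            f"last iterate {theta!r}"
        )
    e = (y - theta * x) / scale
    inside = np.abs(e) < tuning
    psi = np.where(inside, e * (1 - (e / tuning) ** 2) ** 2, 0.0)
    dpsi = np.where(
        inside, (1 - (e / tuning) ** 2) * (1 - 5 * (e / tuning) ** 2), 0.0
    )
    mean_dpsi = float(np.mean(dpsi))
    if mean_dpsi <= 0:
        raise ConvergenceError("degenerate psi-derivative; fit unreliable")
    var = (
        scale ** 2
        * (float(np.sum(psi ** 2)) / (J - 1))
        / (mean_dpsi ** 2 * float(np.sum(x ** 2)))
    )
    se = float(np.sqrt(var))
    lo, hi, p = _interval(theta, se, J - 1, cfg.ci_level, cfg.df_rule)
    return MREstimate(
        method="robust_ivw", estimate=float(theta), se=se,
        ci_lower=float(lo), ci_upper=float(hi), p_value=p,
        variance_model="robust", sigma_hat=scale, n_variants=J,
        ci_level=cfg.ci_level,
        odds_ratio_view=_or_view(theta, lo, hi, data.outcome_scale),
    )
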