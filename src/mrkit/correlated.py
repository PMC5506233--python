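"""IVW and MR-Egger for correlated variants (generalized least squares).

When variants are in linkage disequilibrium their outcome-association
estimates are correlated, and the simple inverse-variance weights are
replaced by a weighting matrix: Omega[j1, j2] = se_y[j1] * se_y[j2] *
rho[j1, j2], with rho the variant correlation matrix. The causal estimate
is the generalized weighted regression of beta_y on beta_x using
Omega^-1; equivalently, pre-multiplying the associations by the inverse
Cholesky factor of Omega and running an ordinary unweighted regression.
Both routes are implemented and agree to numerical precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from .data_model import (
    ConfigurationError,
    EggerResult,
    InsufficientVariantsError,
    MRDataset,
    MREstimate,
    NonIdentifiableError,
)
from .estimators import VarianceModelConfig, _apply_sigma, _interval, _or_view

__all__ = ["WeightingMatrix", "build_omega", "ivw_correlated", "egger_correlated"]

_EIG_FLOOR = 1e-8


@dataclass
class WeightingMatrix:
    """The GLS weighting matrix Omega and whether rho was regularized."""

    omega: np.ndarray
    regularized: bool = False


def _regularize_correlation(rho: np.ndarray) -> tuple[np.ndarray, bool]:
    """Clip eigenvalues at a small floor and re-normalize to unit diagonal.

    User-supplied LD matrices are often numerically indefinite; clipping
    keeps the GLS solvable while perturbing rho as little as possible.
    """
    rho = (rho + rho.T) / 2.0
    vals, vecs = np.linalg.eigh(rho)
    if vals.min() >= _EIG_FLOOR:
        return rho, False
    vals = np.maximum(vals, _EIG_FLOOR)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    warnings.warn(
        "correlation matrix was not positive definite; eigenvalues clipped "
        f"at {_EIG_FLOOR:g} and the diagonal re-normalized",
        UserWarning, stacklevel=3,
    )
    return (fixed + fixed.T) / 2.0, True


def build_omega(data: MRDataset) -> WeightingMatrix:
    """Omega[j1, j2] = se_y[j1] * se_y[j2] * rho[j1, j2].

    With an identity correlation this is diag(se_y^2) and GLS collapses to
    the ordinary inverse-variance weighting.
    """
    if data.correlation is None:
        raise ConfigurationError(
            "dataset has no correlation matrix; use the uncorrelated "
            "estimators (mrkit.estimators) instead"
        )
    rho, regularized = _regularize_correlation(np.asarray(data.correlation, float))
    se_y = data.se_y
    omega = np.outer(se_y, se_y) * rho
    return WeightingMatrix(omega=omega, regularized=regularized)


def _gls_fit(X: np.ndarray, y: np.ndarray, omega: np.ndarray, route: str):
    """GLS coefficients, fixed-model covariance and weighted RSS."""
    if route == "matrix":
        try:
            oi_X = np.linalg.solve(omega, X)
            oi_y = np.linalg.solve(omega, y)
        except np.linalg.LinAlgError as exc:
            raise ConfigurationError(
                f"weighting matrix is singular beyond regularization: {exc}"
            ) from exc
        A = X.T @ oi_X
        coef = np.linalg.solve(A, X.T @ oi_y)
        cov_fixed = np.linalg.inv(A)
        resid = y - X @ coef
        rss = float(resid @ np.linalg.solve(omega, resid))
    elif route == "cholesky":
        try:
            L = np.linalg.cholesky(omega)
        except np.linalg.LinAlgError as exc:
            raise ConfigurationError(
                f"weighting matrix is not positive definite: {exc}"
            ) from exc
        Xs = sla.solve_triangular(L, X, lower=True)
        ys = sla.solve_triangular(L, y, lower=True)
        A = Xs.T @ Xs
        coef = np.linalg.solve(A, Xs.T @ ys)
        cov_fixed = np.linalg.inv(A)
        rss = float(np.sum((ys - Xs @ coef) ** 2))
    else:
        raise ConfigurationError(f"unknown route {route!r}")
    return coef, cov_fixed, rss


def _sigma_with_flag(rss: float, df: int, cfg: VarianceModelConfig) -> float:
    sigma_hat = float(np.sqrt(rss / df)) if df > 0 else float("nan")
    if (
        cfg.model == "random_multiplicative"
        and cfg.truncate_sigma_at_one
        and np.isfinite(sigma_hat)
        and sigma_hat < 1.0
    ):
        # With correlated variants underdispersion can be genuine (the
        # no-biological-underdispersion argument holds for uncorrelated
        # variants only); the truncation is still applied, but flagged.
        warnings.warn(
            f"residual scale {sigma_hat:.3f} < 1 truncated to 1; with "
            "correlated variants underdispersion can be genuine — inspect "
            "sigma_hat",
            UserWarning, stacklevel=3,
        )
    return sigma_hat


def ivw_correlated(
    data: MRDataset,
    cfg: VarianceModelConfig | None = None,
    route: str = "matrix",
) -> MREstimate:
    """Correlation-aware IVW: no-intercept GLS of beta_y on beta_x."""
    cfg = cfg or VarianceModelConfig()
    omega = build_omega(data).omega
    J = len(data)
    X = data.beta_x[:, None]
    coef, cov_fixed, rss = _gls_fit(X, data.beta_y, omega, route)
    estimate = float(coef[0])
    se_fixed = float(np.sqrt(cov_fixed[0, 0]))
    df = J - 1
    sigma_hat = _sigma_with_flag(rss, df, cfg)
    local = cfg
    if df < 1 and cfg.model == "random_multiplicative":
        local = VarianceModelConfig("fixed", cfg.truncate_sigma_at_one,
                                    cfg.df_rule, cfg.ci_level)
    se = _apply_sigma(se_fixed, sigma_hat, local)
    lo, hi, p = _interval(estimate, se, df if df >= 1 else None,
                          cfg.ci_level, cfg.df_rule)
    return MREstimate(
        method="ivw", estimate=estimate, se=se, ci_lower=lo, ci_upper=hi,
        p_value=p, variance_model=local.model, sigma_hat=sigma_hat,
        n_variants=J, ci_level=cfg.ci_level,
        odds_ratio_view=_or_view(estimate, lo, hi, data.outcome_scale),
    )


def egger_correlated(
    data: MRDataset,
    cfg: VarianceModelConfig | None = None,
    route: str = "matrix",
) -> EggerResult:
    """Correlation-aware MR-Egger: GLS with a free intercept."""
    cfg = cfg or VarianceModelConfig()
    omega = build_omega(data).omega
    J = len(data)
    if J < 3:
        raise InsufficientVariantsError(
            f"MR-Egger needs at least 3 variants (got {J})"
        )
    bx = data.beta_x
    if np.allclose(bx, bx[0], rtol=0.0, atol=1e-12 * max(1.0, abs(bx[0]))):
        raise NonIdentifiableError(
            "no spread in beta_x: neither MR-Egger parameter is identified"
        )
    if np.any(bx < 0):
        warnings.warn(
            "some beta_x are negative: MR-Egger depends on variant "
            "orientation; consider orient_variants() first",
            UserWarning, stacklevel=2,
        )
    X = np.column_stack([np.ones(J), bx])
    coef, cov_fixed, rss = _gls_fit(X, data.beta_y, omega, route)
    df = J - 2
    sigma_hat = _sigma_with_flag(rss, df, cfg)
    se_int = _apply_sigma(float(np.sqrt(cov_fixed[0, 0])), sigma_hat, cfg)
    se_slope = _apply_sigma(float(np.sqrt(cov_fixed[1, 1])), sigma_hat, cfg)

    from .diagnostics import i_squared_gx

    oi_one = np.linalg.solve(omega, np.ones(J))
    bx_bar = float(bx @ oi_one / np.sum(oi_one))  # Omega^-1-weighted mean

    lo_s, hi_s, p_s = _interval(coef[1], se_slope, df, cfg.ci_level, cfg.df_rule)
    lo_i, hi_i, p_i = _interval(coef[0], se_int, df, cfg.ci_level, cfg.df_rule)
    slope = MREstimate(
        method="egger_slope", estimate=float(coef[1]), se=se_slope,
        ci_lower=lo_s, ci_upper=hi_s, p_value=p_s,
        variance_model=cfg.model, sigma_hat=sigma_hat, n_variants=J,
        ci_level=cfg.ci_level,
        odds_ratio_view=_or_view(coef[1], lo_s, hi_s, data.outcome_scale),
    )
    intercept = MREstimate(
        method="egger_intercept", estimate=float(coef[0]), se=se_int,
        ci_lower=lo_i, ci_upper=hi_i, p_value=p_i,
        variance_model=cfg.model, sigma_hat=sigma_hat, n_variants=J,
        ci_level=cfg.ci_level,
    )
    return EggerResult(intercept=intercept, slope=slope,
                       i2_gx=i_squared_gx(data), beta_x_bar=bx_bar)
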