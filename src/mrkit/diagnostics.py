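"""Instrument strength, heterogeneity and per-variant influence measures.

MR-Egger's precision depends on the spread of the risk-factor
associations relative to their precision; the instrument-strength I²
statistic diagnoses the resulting "weak instrument" (regression dilution)
bias. Single variants can dominate the MR-Egger fit, so standard weighted
least squares influence measures (Cook's distance, externally Studentized
residuals) and leave-one-out refits are provided. Diagnostics flag
variants; they never delete them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    ConfigurationError,
    InsufficientVariantsError,
    MRDataset,
    MREstimate,
)
from .estimators import VarianceModelConfig, egger_estimate, ivw_estimate

__all__ = [
    "DiagnosticsReport",
    "i_squared_gx",
    "influence_measures",
    "leave_one_out",
    "heterogeneity_q",
]

#: conventional annotation thresholds, printed in reports, never enforced
COOKS_ANNOTATION = "4/J"
STUDENTIZED_ANNOTATION = "|t| > 3"


@dataclass
class DiagnosticsReport:
    """Per-variant influence measures plus fit-level summaries."""

    per_variant: pd.DataFrame  # variant_id, cooks_distance, studentized_residual, loo_estimate, loo_se
    q_statistic: float
    q_p_value: float
    i2_gx: float
    sigma_hat: float
    fitted_method: str

    def __post_init__(self) -> None:
        if not (0 <= self.i2_gx <= 1):
            raise ConfigurationError("i2_gx must lie in [0, 1]")

    def to_csv(self, path: str | Path) -> None:
        self.per_variant.to_csv(Path(path), index=False, float_format="%.17g")

    def summary_dict(self) -> dict:
        return {
            "fitted_method": self.fitted_method,
            "q_statistic": self.q_statistic,
            "q_p_value": self.q_p_value,
            "i2_gx": self.i2_gx,
            "sigma_hat": self.sigma_hat,
            "n_variants": int(len(self.per_variant)),
            "cooks_threshold_annotation": COOKS_ANNOTATION,
            "studentized_threshold_annotation": STUDENTIZED_ANNOTATION,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary_dict(), indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Instrument strength
# ---------------------------------------------------------------------------

def i_squared_gx(data: MRDataset, weight_rule: str = "se_x") -> float:
    """Instrument-strength I² for MR-Egger.

    Q = sum_j w_j (beta_xj - bx_bar)^2 with bx_bar the w-weighted mean;
    I²_GX = max(0, (Q - (J-1)) / Q). Values near 1 mean the spread in the
    risk-factor associations is large relative to their measurement error,
    so MR-Egger suffers little regression-dilution bias; 0 means the
    associations are indistinguishable and neither MR-Egger parameter is
    identified. Weights are se_x^-2 by default (the instrument-strength
    convention) or se_y^-2 (the weighting used by the MR-Egger variance).
    """
    if len(data) < 2:
        raise InsufficientVariantsError("I²_GX needs at least 2 variants")
    if weight_rule == "se_x":
        w = data.se_x ** -2.0
    elif weight_rule == "se_y":
        w = data.se_y ** -2.0
    else:
        raise ConfigurationError(f"unknown weight_rule {weight_rule!r}")
    bx = data.beta_x
    bx_bar = float(np.sum(w * bx) / np.sum(w))
    q = float(np.sum(w * (bx - bx_bar) ** 2))
    if q == 0:
        return 0.0
    return float(max(0.0, (q - (len(data) - 1)) / q))


# ---------------------------------------------------------------------------
# WLS machinery shared by the influence measures
# ---------------------------------------------------------------------------

def _design(data: MRDataset, method: str) -> np.ndarray:
    bx = data.beta_x
    if method == "ivw":
        return bx[:, None]
    if method == "egger":
        return np.column_stack([np.ones_like(bx), bx])
    raise ConfigurationError(f"unknown method {method!r}")


def _wls_influence(data: MRDataset, method: str):
    """Leverages, weighted residuals and scale of the WLS fit."""
    X = _design(data, method)
    y = data.beta_y
    w = data.se_y ** -2.0
    sw = np.sqrt(w)
    Xt = X * sw[:, None]
    yt = y * sw
    coef, *_ = np.linalg.lstsq(Xt, yt, rcond=None)
    G = np.linalg.pinv(Xt.T @ Xt)
    h = np.einsum("ij,jk,ik->i", Xt, G, Xt)  # leverages of the weighted fit
    e = yt - Xt @ coef  # sqrt(w)-scaled residuals
    p = X.shape[1]
    dof = len(y) - p
    s2 = float(np.sum(e ** 2) / dof) if dof > 0 else float("nan")
    return coef, h, e, p, s2


def influence_measures(data: MRDataset, method: str = "egger") -> DiagnosticsReport:
    """Cook's distances and externally Studentized residuals of the fit.

    Both are the standard weighted-least-squares quantities of the IVW
    (no-intercept) or MR-Egger (with-intercept) regression: leverages from
    the weighted hat matrix, Cook's D_j = e_j^2 h_j / (p s^2 (1-h_j)^2)
    with p the number of regression parameters, and residuals Studentized
    against a leave-one-out scale estimate. A leverage of 1 yields
    infinite influence with a warning rather than an error.
    """
    J = len(data)
    minimum = 3 if method == "egger" else 2
    if J < minimum:
        raise InsufficientVariantsError(
            f"influence measures for {method} need at least {minimum} variants"
        )
    coef, h, e, p, s2 = _wls_influence(data, method)
    dof = J - p
    ones = np.isclose(h, 1.0, atol=1e-12)
    if np.any(ones):
        warnings.warn(
            "leverage of 1 for variant(s) "
            f"{[data.variant_ids[i] for i in np.flatnonzero(ones)]}: "
            "infinite influence reported",
            UserWarning, stacklevel=2,
        )
    one_minus_h = np.where(ones, np.nan, 1.0 - h)
    # an (up to roundoff) exact fit leaves no residual scale to Studentize
    # against; ratios of machine-epsilon residuals are meaningless
    y_scale = max(float(np.max(np.abs(data.beta_y / data.se_y))), 1e-300)
    if np.sqrt(s2) <= 1e-10 * y_scale:
        cooks = np.zeros(J)
        student = np.zeros(J)
    else:
        cooks = e ** 2 * h / (p * s2 * one_minus_h ** 2)
        cooks = np.where(ones, np.inf, cooks)
        if dof > 1:
            s2_loo = (dof * s2 - e ** 2 / one_minus_h) / (dof - 1)
            s2_loo = np.maximum(s2_loo, 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                student = e / np.sqrt(s2_loo * one_minus_h)
            student = np.where(ones, np.inf * np.sign(e), student)
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                student = e / np.sqrt(s2 * one_minus_h)  # internal fallback
    q, q_p = heterogeneity_q(data, method)
    try:
        loo = leave_one_out(data, method)
        loo_est = {vid: est.estimate for vid, est in loo}
        loo_se = {vid: est.se for vid, est in loo}
    except InsufficientVariantsError:
        loo_est, loo_se = {}, {}
    per_variant = pd.DataFrame(
        {
            "variant_id": data.variant_ids,
            "cooks_distance": cooks,
            "studentized_residual": student,
            "loo_estimate": [loo_est.get(v, np.nan) for v in data.variant_ids],
            "loo_se": [loo_se.get(v, np.nan) for v in data.variant_ids],
        }
    )
    return DiagnosticsReport(
        per_variant=per_variant,
        q_statistic=q,
        q_p_value=q_p,
        i2_gx=i_squared_gx(data) if J >= 2 else 0.0,
        sigma_hat=float(np.sqrt(s2)) if dof > 0 else float("nan"),
        fitted_method=method,
    )


def leverages(data: MRDataset, method: str = "egger") -> np.ndarray:
    """Diagonal of the weighted hat matrix (sums to the parameter count)."""
    _, h, *_ = _wls_influence(data, method)
    return h


# ---------------------------------------------------------------------------
# Leave-one-out
# ---------------------------------------------------------------------------

def leave_one_out(
    data: MRDataset,
    method: str = "ivw",
    cfg: VarianceModelConfig | None = None,
) -> list[tuple[str, MREstimate]]:
    """Refit the estimator J times, leaving each variant out in turn."""
    J = len(data)
    minimum = 4 if method == "egger" else 3
    if J < minimum:
        raise InsufficientVariantsError(
            f"leave-one-out for {method} needs at least {minimum} variants"
        )
    out: list[tuple[str, MREstimate]] = []
    for vid in data.variant_ids:
        sub = data.without(vid)
        if method == "ivw":
            out.append((vid, ivw_estimate(sub, cfg)))
        elif method == "egger":
            out.append((vid, egger_estimate(sub, cfg).slope))
        else:
            raise ConfigurationError(f"unknown method {method!r}")
    return out


# ---------------------------------------------------------------------------
# Heterogeneity
# ---------------------------------------------------------------------------

def heterogeneity_q(data: MRDataset, method: str = "ivw") -> tuple[float, float]:
    """Heterogeneity statistic Q = sum w_j (beta_yj - fitted_j)^2, w = se_y^-2.

    Under homogeneity Q is approximately chi-square with the residual
    degrees of freedom (J-1 for IVW, J-2 for MR-Egger). Q/(J-1) for IVW
    equals the squared residual scale of the multiplicative random-effects
    fit, so large Q and overdispersion are the same diagnosis.
    """
    J = len(data)
    minimum = 3 if method == "egger" else 2
    if J < minimum:
        raise InsufficientVariantsError(
            f"heterogeneity Q for {method} needs at least {minimum} variants"
        )
    coef, h, e, p, s2 = _wls_influence(data, method)
    q = float(np.sum(e ** 2))
    df = J - p
    q_p = float(stats.chi2(df).sf(q))
    return q, q_p
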