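"""Synthetic summarized MR datasets under controlled pleiotropy scenarios.

Data are generated at the summary-statistic level: true risk-factor
associations beta_Xj are drawn, direct (pleiotropic) effects alpha_j are
drawn per scenario, true outcome associations follow the decomposition
beta_Yj = alpha_j + theta * beta_Xj, and the observed estimates are the
truths plus independent normal noise at the configured SE levels (SEs are
treated as known, matching the weighting assumptions of the estimators).

Scenarios:

* ``no_pleiotropy`` — all alpha_j = 0 (valid instruments).
* ``balanced_direct`` — alpha_j direct on the outcome, zero mean.
* ``directional_direct`` — alpha_j direct, nonzero mean, independent of
  instrument strength (InSIDE satisfied): MR-Egger is consistent, IVW is
  biased.
* ``via_single_confounder`` — each variant acts on a shared confounder
  with effect gamma_j, which feeds BOTH the risk factor and the outcome,
  so alpha_j and beta_Xj are positively correlated (InSIDE violated).
* ``via_multiple_confounders`` — one distinct confounder per variant;
  the induced coupling between strength and pleiotropy is the same, so
  InSIDE is still violated.

``bias_study`` runs a seeded Monte-Carlo over replicates and tabulates
bias, empirical SE and rejection rates for IVW, MR-Egger and the median
methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ConfigurationError, MRDataset
from .estimators import (
    BootstrapConfig,
    VarianceModelConfig,
    egger_estimate,
    ivw_estimate,
    median_estimate,
)

__all__ = [
    "SCENARIOS",
    "ScenarioConfig",
    "SimulationTruth",
    "simulate_dataset",
    "weighted_covariance",
    "bias_study",
]

SCENARIOS = (
    "no_pleiotropy",
    "balanced_direct",
    "directional_direct",
    "via_single_confounder",
    "via_multiple_confounders",
)

# Path coefficients mapping a variant's confounder effect gamma_j onto
# instrument strength (lambda_x * gamma_j added to beta_Xj) and onto the
# pleiotropic effect (alpha_j = lambda_y * gamma_j). With the default
# gamma ~ N(0.05, 0.02), alpha then has mean 0.01 and sd 0.004 — the same
# scale as directional direct pleiotropy — while beta_X gains a component
# proportional to gamma, coupling strength and pleiotropy.
CONFOUNDER_TO_X = 0.5
CONFOUNDER_TO_Y = 0.2

_MOD = 2 ** 31


@dataclass(frozen=True)
class ScenarioConfig:
    """Generator settings; defaults are the package's standard conditions.

    ``beta_x_distribution`` is (min, max) of a uniform law for the true
    instrument strengths; ``alpha_distribution`` is (mean, sd) of the
    normal law for direct pleiotropic effects (``None`` picks the
    scenario's standard values: (0, 0.004) balanced, (0.01, 0.004)
    directional); ``confounder_effect_distribution`` is (mean, sd) for
    gamma_j in the confounder scenarios. ``se_x_level``/``se_y_level``
    are the known sampling-error SDs of the observed associations.
    """

    scenario: str = "no_pleiotropy"
    J: int = 25
    theta: float = 0.0
    alpha_distribution: tuple[float, float] | None = None
    beta_x_distribution: tuple[float, float] = (0.05, 0.15)
    se_x_level: float = 0.005
    se_y_level: float = 0.01
    confounder_effect_distribution: tuple[float, float] = (0.05, 0.02)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(
                f"unknown scenario {self.scenario!r}; valid: {list(SCENARIOS)}"
            )
        if self.J < 1:
            raise ConfigurationError("J must be at least 1")
        if not (self.se_x_level > 0 and self.se_y_level > 0):
            raise ConfigurationError("se levels must be positive")

    @property
    def alpha_params(self) -> tuple[float, float]:
        if self.alpha_distribution is not None:
            return self.alpha_distribution
        if self.scenario == "directional_direct":
            return (0.01, 0.004)
        return (0.0, 0.004)


@dataclass
class SimulationTruth:
    """The generating parameters behind one simulated dataset."""

    true_theta: float
    true_alphas: np.ndarray
    true_beta_x: np.ndarray
    inside_weighted_covariance: float


def weighted_covariance(alphas, beta_xs, weights) -> float:
    """Weighted covariance between pleiotropic effects and strengths.

    Weights are normalized to sum to one; returns
    sum_j w_j (alpha_j - mean_w(alpha)) (beta_Xj - mean_w(beta_X)). MR-Egger
    is consistent (for fixed J, growing samples) exactly when this
    inverse-variance weighted covariance is zero — the finite-sample form
    of the InSIDE assumption.
    """
    a = np.asarray(alphas, dtype=float)
    b = np.asarray(beta_xs, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (a.shape == b.shape == w.shape):
        raise ConfigurationError("alphas, beta_xs and weights must have equal length")
    if a.size < 2:
        raise ConfigurationError("need at least 2 entries")
    if np.any(w <= 0):
        raise ConfigurationError("weights must be positive")
    wn = w / np.sum(w)
    return float(np.sum(wn * (a - np.sum(wn * a)) * (b - np.sum(wn * b))))


def simulate_dataset(cfg: ScenarioConfig) -> tuple[MRDataset, SimulationTruth]:
    """Draw one summarized dataset plus its generating truth.

    Deterministic given ``cfg.seed``: the same config always yields a
    bit-identical dataset.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.beta_x_distribution
    base_bx = rng.uniform(lo, hi, size=cfg.J)
    if (
        hi == lo
        and cfg.scenario in ("directional_direct", "balanced_direct", "no_pleiotropy")
    ):
        warnings.warn(
            "degenerate beta_x distribution (no spread in instrument "
            "strengths): MR-Egger is not identified on such data",
            UserWarning, stacklevel=2,
        )
    if cfg.scenario == "no_pleiotropy":
        alphas = np.zeros(cfg.J)
        bx = base_bx
    elif cfg.scenario in ("balanced_direct", "directional_direct"):
        mean, sd = cfg.alpha_params
        alphas = rng.normal(mean, sd, size=cfg.J)
        bx = base_bx
    else:  # confounder-mediated pleiotropy: InSIDE violated
        gmean, gsd = cfg.confounder_effect_distribution
        gamma = rng.normal(gmean, gsd, size=cfg.J)
        bx = base_bx + CONFOUNDER_TO_X * gamma
        alphas = CONFOUNDER_TO_Y * gamma
    by = alphas + cfg.theta * bx
    bx_obs = bx + rng.normal(0.0, cfg.se_x_level, size=cfg.J)
    by_obs = by + rng.normal(0.0, cfg.se_y_level, size=cfg.J)
    se_x = np.full(cfg.J, cfg.se_x_level)
    se_y = np.full(cfg.J, cfg.se_y_level)
    data = MRDataset.from_arrays(bx_obs, se_x, by_obs, se_y)
    cov = (
        weighted_covariance(alphas, bx, se_y ** -2.0) if cfg.J >= 2 else 0.0
    )
    truth = SimulationTruth(
        true_theta=cfg.theta,
        true_alphas=alphas,
        true_beta_x=bx,
        inside_weighted_covariance=cov,
    )
    return data, truth


def replicate_seed(master_seed: int, index: int) -> int:
    """Stated counter scheme: (master * 1_000_003 + index) mod 2^31."""
    return int((int(master_seed) * 1_000_003 + int(index)) % _MOD)


def bias_study(
    cfg: ScenarioConfig,
    n_replicates: int = 500,
    boot_iterations: int = 200,
    alpha_level: float = 0.05,
    include_medians: bool = True,
    variance_model: VarianceModelConfig | None = None,
) -> pd.DataFrame:
    """Monte-Carlo summary of the estimators under one scenario.

    Each replicate re-simulates a dataset (per-replicate seeds derived
    from the master seed by a counter scheme), applies IVW, MR-Egger and
    (optionally) the median methods, and tabulates mean estimate,
    empirical SE, bias against the generating truth and the rejection
    rate of the two-sided test at ``alpha_level``. The MR-Egger intercept
    row is judged against the true mean pleiotropic effect.

    ``variance_model`` defaults to the fixed-effect model: the generator
    draws observations with known SEs and (absent pleiotropy) no
    heterogeneity, which is exactly the fixed-effect sampling model, so
    rejection rates are interpretable as calibration of the nominal test.
    Pass a random-multiplicative config to study the (conservative)
    truncated random-effects procedure instead.
    """
    if n_replicates < 100:
        raise ConfigurationError("n_replicates must be at least 100")
    vm = variance_model or VarianceModelConfig(model="fixed")
    methods = ["ivw", "egger_slope", "egger_intercept"]
    if include_medians:
        methods += ["simple_median", "weighted_median"]
    est = {m: np.empty(n_replicates) for m in methods}
    rej = {m: np.empty(n_replicates, dtype=bool) for m in methods}
    mean_alpha = np.empty(n_replicates)
    for i in range(n_replicates):
        seed_i = replicate_seed(cfg.seed, i)
        rep_cfg = ScenarioConfig(
            scenario=cfg.scenario, J=cfg.J, theta=cfg.theta,
            alpha_distribution=cfg.alpha_distribution,
            beta_x_distribution=cfg.beta_x_distribution,
            se_x_level=cfg.se_x_level, se_y_level=cfg.se_y_level,
            confounder_effect_distribution=cfg.confounder_effect_distribution,
            seed=seed_i,
        )
        data, truth = simulate_dataset(rep_cfg)
        mean_alpha[i] = float(np.mean(truth.true_alphas))
        ivw = ivw_estimate(data, vm)
        egger = egger_estimate(data, vm)
        est["ivw"][i] = ivw.estimate
        rej["ivw"][i] = ivw.p_value < alpha_level
        est["egger_slope"][i] = egger.slope.estimate
        rej["egger_slope"][i] = egger.slope.p_value < alpha_level
        est["egger_intercept"][i] = egger.intercept.estimate
        rej["egger_intercept"][i] = egger.intercept.p_value < alpha_level
        if include_medians:
            for kind in ("simple", "weighted"):
                m = median_estimate(
                    data, weighting=kind,
                    boot=BootstrapConfig(boot_iterations, seed=replicate_seed(seed_i, 1)),
                )
                est[f"{kind}_median"][i] = m.estimate
                rej[f"{kind}_median"][i] = m.p_value < alpha_level
    rows = []
    for m in methods:
        true_value = cfg.theta if m != "egger_intercept" else float(np.mean(mean_alpha))
        mean_est = float(np.mean(est[m]))
        rows.append(
            {
                "method": m,
                "true_value": true_value,
                "mean_estimate": mean_est,
                "empirical_se": float(np.std(est[m], ddof=1)),
                "bias": mean_est - true_value,
                f"rejection_rate_at_{alpha_level:g}": float(np.mean(rej[m])),
                "n_replicates": n_replicates,
            }
        )
    return pd.DataFrame(rows)
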