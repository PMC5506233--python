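"""Summarized-data containers, validation, variant orientation, and I/O.

Two-sample Mendelian randomization operates on per-variant summary
statistics: for each genetic variant j, its association with the risk
factor (beta_x, se_x) and with the outcome (beta_y, se_y), estimated in
non-overlapping samples. This module defines the in-memory containers
(:class:`VariantAssociation`, :class:`MRDataset`, :class:`MREstimate`,
:class:`EggerResult`), reads/writes delimited summary-statistics files
with a configurable column mapping, and implements variant orientation:
recoding variants so that every risk-factor association is non-negative,
which fixes the reference allele convention that the MR-Egger intercept
depends on.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MRError",
    "DataValidationError",
    "ConfigurationError",
    "UndefinedRatioError",
    "InsufficientVariantsError",
    "NonIdentifiableError",
    "ConvergenceError",
    "VariantAssociation",
    "MRDataset",
    "MREstimate",
    "EggerResult",
    "DEFAULT_COLUMNS",
    "read_dataset",
    "read_correlation",
    "orient_variants",
    "write_dataset",
    "write_results",
    "results_to_frame",
    "write_results_json",
]

_CORR_TOL = 1e-8


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class MRError(Exception):
    """Base class for all package errors."""


class DataValidationError(MRError):
    """Input data violate a container invariant (e.g. non-positive SE)."""


class ConfigurationError(MRError):
    """A user-supplied configuration is inconsistent with the data."""


class UndefinedRatioError(MRError):
    """A per-variant ratio estimate is undefined (beta_x == 0)."""


class InsufficientVariantsError(MRError):
    """Too few variants for the requested analysis."""


class NonIdentifiableError(MRError):
    """Regression parameters are not identified (no spread in beta_x)."""


class ConvergenceError(MRError):
    """An iterative fit failed to converge."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantAssociation:
    """Summarized associations of one genetic variant.

    ``beta_x``/``se_x`` are the association with the risk factor per copy
    of the effect allele; ``beta_y``/``se_y`` the association with the
    outcome (a log odds ratio for binary outcomes).
    """

    variant_id: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    effect_allele: str | None = None
    other_allele: str | None = None

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise DataValidationError("variant_id must be a non-empty string")
        for name in ("beta_x", "beta_y"):
            if not math.isfinite(getattr(self, name)):
                raise DataValidationError(
                    f"{name} is not finite for variant {self.variant_id!r}"
                )
        for name in ("se_x", "se_y"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise DataValidationError(
                    f"{name} must be a positive finite number for variant "
                    f"{self.variant_id!r} (got {value!r})"
                )

    @property
    def ratio(self) -> float:
        """Per-variant (Wald) ratio estimate beta_y / beta_x."""
        if self.beta_x == 0:
            raise UndefinedRatioError(
                f"ratio estimate undefined for variant {self.variant_id!r}: "
                "beta_x is exactly zero"
            )
        return self.beta_y / self.beta_x


def _validate_correlation(corr: np.ndarray, n: int) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (n, n):
        raise DataValidationError(
            f"correlation matrix shape {corr.shape} does not match the "
            f"number of variants ({n})"
        )
    if not np.allclose(corr, corr.T, atol=_CORR_TOL):
        raise DataValidationError("correlation matrix is not symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=_CORR_TOL):
        raise DataValidationError("correlation matrix diagonal must be 1")
    if np.any(np.abs(corr) > 1 + _CORR_TOL):
        raise DataValidationError("correlation entries must lie in [-1, 1]")
    if np.min(np.linalg.eigvalsh((corr + corr.T) / 2.0)) < -_CORR_TOL:
        raise DataValidationError(
            "correlation matrix is not positive semi-definite within 1e-8"
        )
    return corr


@dataclass
class MRDataset:
    """An ordered collection of variant associations; the unit of analysis.

    Optionally carries a J x J correlation matrix between variants (for
    variants in linkage disequilibrium) and the measurement scale of the
    outcome associations (``continuous`` or ``log_odds``).
    """

    variants: list[VariantAssociation]
    correlation: np.ndarray | None = None
    outcome_scale: str = "continuous"

    def __post_init__(self) -> None:
        self.variants = list(self.variants)
        if len(self.variants) < 1:
            raise DataValidationError("a dataset needs at least one variant")
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataValidationError(f"duplicate variant ids: {dupes}")
        if self.outcome_scale not in ("continuous", "log_odds"):
            raise DataValidationError(
                f"unknown outcome_scale {self.outcome_scale!r}"
            )
        if self.correlation is not None:
            self.correlation = _validate_correlation(
                self.correlation, len(self.variants)
            )

    # -- array views -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    @property
    def beta_x(self) -> np.ndarray:
        return np.array([v.beta_x for v in self.variants])

    @property
    def se_x(self) -> np.ndarray:
        return np.array([v.se_x for v in self.variants])

    @property
    def beta_y(self) -> np.ndarray:
        return np.array([v.beta_y for v in self.variants])

    @property
    def se_y(self) -> np.ndarray:
        return np.array([v.se_y for v in self.variants])

    # -- construction helpers ---------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        beta_x: Sequence[float],
        se_x: Sequence[float],
        beta_y: Sequence[float],
        se_y: Sequence[float],
        variant_ids: Sequence[str] | None = None,
        correlation: np.ndarray | None = None,
        outcome_scale: str = "continuous",
    ) -> "MRDataset":
        n = len(beta_x)
        if variant_ids is None:
            variant_ids = [f"snp_{i + 1:04d}" for i in range(n)]
        variants = [
            VariantAssociation(
                variant_id=str(variant_ids[i]),
                beta_x=float(beta_x[i]),
                se_x=float(se_x[i]),
                beta_y=float(beta_y[i]),
                se_y=float(se_y[i]),
            )
            for i in range(n)
        ]
        return cls(variants, correlation=correlation, outcome_scale=outcome_scale)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": self.variant_ids,
                "effect_allele": [v.effect_allele for v in self.variants],
                "other_allele": [v.other_allele for v in self.variants],
                "beta_exposure": self.beta_x,
                "se_exposure": self.se_x,
                "beta_outcome": self.beta_y,
                "se_outcome": self.se_y,
            }
        )

    def without(self, variant_id: str) -> "MRDataset":
        """Dataset with one variant removed (for leave-one-out analyses)."""
        ids = self.variant_ids
        if variant_id not in ids:
            raise KeyError(variant_id)
        keep = [i for i, v in enumerate(ids) if v != variant_id]
        corr = None
        if self.correlation is not None:
            corr = self.correlation[np.ix_(keep, keep)]
        return MRDataset(
            [self.variants[i] for i in keep],
            correlation=corr,
            outcome_scale=self.outcome_scale,
        )


@dataclass
class MREstimate:
    """A causal-effect estimate with its uncertainty summary."""

    method: str
    estimate: float
    se: float
    ci_lower: float
    ci_upper: float
    p_value: float
    variance_model: str
    sigma_hat: float
    n_variants: int
    ci_level: float = 0.95
    odds_ratio_view: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise DataValidationError(
                f"standard error must be positive (got {self.se!r})"
            )
        if not (self.ci_lower <= self.estimate <= self.ci_upper):
            raise DataValidationError(
                "confidence interval must bracket the point estimate"
            )
        if not (0 < self.ci_level < 1):
            raise DataValidationError("ci_level must lie in (0, 1)")
        if self.sigma_hat < 0:  # NaN (not estimable) passes
            raise DataValidationError("sigma_hat cannot be negative")


@dataclass
class EggerResult:
    """Paired MR-Egger intercept and slope with instrument strength.

    ``intercept`` estimates the average pleiotropic (direct) effect of a
    variant; its test against zero is the MR-Egger intercept test.
    ``slope`` is the causal-effect estimate under the InSIDE assumption.
    ``i2_gx`` is the instrument-strength I² statistic; ``beta_x_bar`` the
    inverse-variance weighted mean risk-factor association.
    """

    intercept: MREstimate
    slope: MREstimate
    i2_gx: float
    beta_x_bar: float

    def __post_init__(self) -> None:
        if not (0 <= self.i2_gx <= 1):
            raise DataValidationError("i2_gx must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Reading summary statistics
# ---------------------------------------------------------------------------

DEFAULT_COLUMNS: dict[str, str] = {
    "snp": "snp",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta_exposure": "beta_exposure",
    "se_exposure": "se_exposure",
    "beta_outcome": "beta_outcome",
    "se_outcome": "se_outcome",
}

_REQUIRED_KEYS = ("snp", "beta_exposure", "se_exposure", "beta_outcome", "se_outcome")
_NUMERIC_KEYS = ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome")


def _infer_delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_dataset(
    path: str | Path,
    format_config: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    outcome_scale: str = "continuous",
) -> MRDataset:
    """Read a delimited summary-statistics file into an :class:`MRDataset`.

    ``format_config`` maps logical names (keys of :data:`DEFAULT_COLUMNS`)
    to the column names in the file. The delimiter is inferred from the
    extension (tab for .tsv/.tab/.txt, comma otherwise) unless given.
    Rows with missing required fields are dropped with a per-row warning;
    a non-positive standard error raises, naming the variant.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    mapping = dict(DEFAULT_COLUMNS)
    if format_config:
        unknown = set(format_config) - set(DEFAULT_COLUMNS)
        if unknown:
            raise ConfigurationError(
                f"unknown column-mapping keys: {sorted(unknown)}; "
                f"valid keys are {sorted(DEFAULT_COLUMNS)}"
            )
        mapping.update(format_config)
    sep = delimiter if delimiter is not None else _infer_delimiter(path)
    frame = pd.read_csv(path, sep=sep, dtype=str)
    frame.columns = [c.strip() for c in frame.columns]

    for key in _REQUIRED_KEYS:
        if mapping[key] not in frame.columns:
            raise ConfigurationError(
                f"required column {mapping[key]!r} (for field {key!r}) "
                f"not found in {path.name}; available: {list(frame.columns)}"
            )
    have_alleles = {
        key: mapping[key] in frame.columns
        for key in ("effect_allele", "other_allele")
    }

    numeric = {
        key: pd.to_numeric(frame[mapping[key]], errors="coerce")
        for key in _NUMERIC_KEYS
    }
    snp = frame[mapping["snp"]].astype(str).str.strip()
    bad_rows = snp.isna() | (snp == "") | (snp.str.lower() == "nan")
    for key in _NUMERIC_KEYS:
        bad_rows |= numeric[key].isna()
    if bad_rows.any():
        report = "; ".join(
            f"row {i + 2}: snp={snp.iloc[i]!r}"  # +2: header + 1-based
            for i in np.flatnonzero(bad_rows.to_numpy())
        )
        warnings.warn(
            f"rejected {int(bad_rows.sum())} row(s) with missing or "
            f"unparseable required fields: {report}",
            UserWarning,
            stacklevel=2,
        )
    keep = ~bad_rows
    if not keep.any():
        raise DataValidationError(f"no valid rows in {path.name}")

    variants = []
    for i in np.flatnonzero(keep.to_numpy()):
        variants.append(
            VariantAssociation(
                variant_id=snp.iloc[i],
                beta_x=float(numeric["beta_exposure"].iloc[i]),
                se_x=float(numeric["se_exposure"].iloc[i]),
                beta_y=float(numeric["beta_outcome"].iloc[i]),
                se_y=float(numeric["se_outcome"].iloc[i]),
                effect_allele=(
                    str(frame[mapping["effect_allele"]].iloc[i])
                    if have_alleles["effect_allele"]
                    else None
                ),
                other_allele=(
                    str(frame[mapping["other_allele"]].iloc[i])
                    if have_alleles["other_allele"]
                    else None
                ),
            )
        )
    return MRDataset(variants, outcome_scale=outcome_scale)


def read_correlation(
    path: str | Path, variant_ids: Sequence[str] | None = None
) -> np.ndarray:
    """Read a square correlation matrix CSV with a header row of variant ids.

    If ``variant_ids`` is given, rows/columns are re-ordered to match it.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_infer_delimiter(path), index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if variant_ids is not None:
        missing = [v for v in variant_ids if v not in frame.columns]
        if missing:
            raise ConfigurationError(
                f"correlation matrix lacks variants: {missing}"
            )
        frame = frame.loc[list(variant_ids), list(variant_ids)]
    return frame.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Orientation
# ---------------------------------------------------------------------------

def orient_variants(data: MRDataset) -> tuple[MRDataset, list[str]]:
    """Recode variants so every risk-factor association is non-negative.

    For each flipped variant both betas are negated (the per-variant ratio
    beta_y/beta_x is unchanged), effect and other alleles are swapped, and
    SEs are untouched. If a correlation matrix is present, off-diagonal
    entries involving a flipped variant change sign (recoding an allele
    negates its allele-count correlations with other variants). A variant
    with beta_x exactly zero cannot be orientated; it is kept as-is with a
    warning (median methods later exclude it since its ratio is undefined).
    """
    flips: list[str] = []
    new_variants: list[VariantAssociation] = []
    signs = np.ones(len(data))
    for i, v in enumerate(data.variants):
        if v.beta_x < 0:
            flips.append(v.variant_id)
            signs[i] = -1.0
            new_variants.append(
                replace(
                    v,
                    beta_x=-v.beta_x,
                    beta_y=-v.beta_y,
                    effect_allele=v.other_allele,
                    other_allele=v.effect_allele,
                )
            )
        else:
            if v.beta_x == 0:
                warnings.warn(
                    f"variant {v.variant_id!r} has beta_x exactly 0 and "
                    "cannot be orientated; kept as-is (its ratio estimate "
                    "is undefined and it is excluded from median methods)",
                    UserWarning,
                    stacklevel=2,
                )
            new_variants.append(v)
    corr = data.correlation
    if corr is not None and flips:
        corr = signs[:, None] * corr * signs[None, :]
    return (
        MRDataset(new_variants, correlation=corr, outcome_scale=data.outcome_scale),
        flips,
    )


# ---------------------------------------------------------------------------
# Writing results
# ---------------------------------------------------------------------------

_RESULT_COLUMNS = [
    "method",
    "estimate",
    "se",
    "ci_lower",
    "ci_upper",
    "ci_level",
    "p_value",
    "variance_model",
    "sigma_hat",
    "n_variants",
    "i2_gx",
    "odds_ratio",
    "or_ci_lower",
    "or_ci_upper",
]


def _estimate_row(est: MREstimate, i2_gx: float = float("nan")) -> dict:
    orv = est.odds_ratio_view or (float("nan"),) * 3
    return {
        "method": est.method,
        "estimate": est.estimate,
        "se": est.se,
        "ci_lower": est.ci_lower,
        "ci_upper": est.ci_upper,
        "ci_level": est.ci_level,
        "p_value": est.p_value,
        "variance_model": est.variance_model,
        "sigma_hat": est.sigma_hat,
        "n_variants": est.n_variants,
        "i2_gx": i2_gx,
        "odds_ratio": orv[0],
        "or_ci_lower": orv[1],
        "or_ci_upper": orv[2],
    }


def results_to_frame(results: Iterable[MREstimate | EggerResult]) -> pd.DataFrame:
    """Flatten estimates into a tidy results table (one row per estimate)."""
    rows: list[dict] = []
    for res in results:
        if isinstance(res, EggerResult):
            rows.append(_estimate_row(res.slope, i2_gx=res.i2_gx))
            rows.append(_estimate_row(res.intercept, i2_gx=res.i2_gx))
        elif isinstance(res, MREstimate):
            rows.append(_estimate_row(res))
        else:
            raise DataValidationError(
                f"cannot serialize result of type {type(res).__name__}"
            )
    if not rows:
        raise DataValidationError("no results to write")
    return pd.DataFrame(rows, columns=_RESULT_COLUMNS)


def write_results(
    results: Iterable[MREstimate | EggerResult], path: str | Path
) -> None:
    """Write a delimited results table; round-trips numerics to 1e-12."""
    frame = results_to_frame(list(results))
    path = Path(path)
    sep = _infer_delimiter(path)
    frame.to_csv(path, sep=sep, index=False, float_format="%.17g")


def write_results_json(
    results: Iterable[MREstimate | EggerResult], path: str | Path
) -> None:
    """Machine-readable JSON variant of :func:`write_results` (sorted keys)."""
    frame = results_to_frame(list(results))
    records = frame.to_dict(orient="records")
    Path(path).write_text(json.dumps(records, indent=2, sort_keys=True, allow_nan=True))


def write_dataset(data: MRDataset, path: str | Path) -> None:
    """Write a dataset in the default summary-statistics dialect."""
    path = Path(path)
    data.to_frame().to_csv(
        path, sep=_infer_delimiter(path), index=False, float_format="%.17g"
    )
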