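import numpy as np
import pytest

from mrkit import MRDataset


def random_dataset(rng: np.random.Generator, J: int = 8,
                   theta: float = 0.4, noise: float = 0.3,
                   correlation: np.ndarray | None = None) -> MRDataset:
    """A generic random summarized dataset (not necessarily orientated)."""
    bx = rng.uniform(-0.3, 0.5, size=J)
    se_x = rng.uniform(0.01, 0.05, size=J)
    se_y = rng.uniform(0.02, 0.2, size=J)
    by = theta * bx + noise * se_y * rng.standard_normal(J)
    return MRDataset.from_arrays(bx, se_x, by, se_y, correlation=correlation)


def random_correlation(rng: np.random.Generator, J: int) -> np.ndarray:
    """A random well-conditioned correlation matrix."""
    A = rng.standard_normal((J, J + 5))
    S = A @ A.T + J * np.eye(J)
    d = np.sqrt(np.diag(S))
    rho = S / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return (rho + rho.T) / 2.0


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_dataset():
    """Five positively orientated variants with mild heterogeneity."""
    return MRDataset.from_arrays(
        beta_x=[0.10, 0.20, 0.30, 0.15, 0.25],
        se_x=[0.01] * 5,
        beta_y=[0.05, 0.11, 0.14, 0.08, 0.12],
        se_y=[0.02] * 5,
        variant_ids=[f"rs{i}" for i in range(1, 6)],
    )
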