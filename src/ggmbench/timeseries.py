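"""AR(1)-autocorrelated multivariate Gaussian time series.

The observation law: each time point is N(0, Sigma) cross-sectionally, with
temporal correlation rho^|lag| per node.  The explicit construction with the
T x T Toeplitz Cholesky factor is replaced by the equivalent stationary
AR(1) recursion, which has the same Gaussian law at O(pT) cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TimeSeries:
    """p nodes x T time points of simulated observations."""

    values: np.ndarray  # shape (p, T), node-major
    rho: float
    seed: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("values must be a p x T matrix")
        if v.shape[1] < 2:
            raise ValueError("need at least T = 2 time points")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


def simulate_ar1_gaussian(
    Sigma: np.ndarray, T: int, rho: float = 0.5, seed: int = 0
) -> TimeSeries:
    """Simulate T observations of N(0, Sigma) with AR(1) temporal structure.

    Innovations are colored by the Cholesky factor of Sigma; the AR(1)
    recursion ``y_t = rho*y_{t-1} + sqrt(1-rho^2)*x_t`` with stationary
    initialization then yields temporal correlation rho^|lag| while leaving
    the cross-sectional covariance at Sigma.
    """
    Sigma = np.asarray(Sigma, dtype=float)
    if T < 2:
        raise ValueError("T must be >= 2")
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must lie in (-1, 1)")
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("Sigma must be positive definite") from exc
    p = Sigma.shape[0]
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((p, T))
    X = L @ Z
    Y = np.empty_like(X)
    Y[:, 0] = X[:, 0]
    a = np.sqrt(1.0 - rho * rho)
    for t in range(1, T):
        Y[:, t] = rho * Y[:, t - 1] + a * X[:, t]
    return TimeSeries(Y, rho, seed)


def nested_subsets(ts: TimeSeries, lengths) -> list[TimeSeries]:
    """Prefix subsets: subset k is a prefix of subset k+1."""
    lengths = list(lengths)
    for n in lengths:
        if n > ts.n_timepoints:
            raise ValueError(f"requested length {n} exceeds T={ts.n_timepoints}")
        if n < 2:
            raise ValueError("subset length must be >= 2")
    return [TimeSeries(ts.values[:, :n], ts.rho, ts.seed) for n in lengths]


def effective_sample_size(n: int, rho: float) -> float:
    """Independent-observation equivalent of n AR(1) observations.

    n' = n * (1 - rho) / (1 + rho).
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must lie in (-1, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    return n * (1.0 - rho) / (1.0 + rho)


def lag_autocorrelation(ts: TimeSeries, lag: int = 1) -> float:
    """Mean lag-k sample autocorrelation across nodes (diagnostic helper)."""
    v = ts.values - ts.values.mean(axis=1, keepdims=True)
    num = (v[:, lag:] * v[:, :-lag]).sum(axis=1)
    den = (v * v).sum(axis=1)
    ok = den > 0
    return float(np.mean(num[ok] / den[ok]))
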