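"""Valid Gaussian graphical models on a fixed topology.

A topology is turned into a partial correlation matrix ``R`` (unit diagonal,
support exactly the edge set, positive definite implied concentration
matrix), then into the implied correlation matrix ``C`` and the
data-generating covariance ``Sigma = variance * C``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ggmbench.topology import NetworkTopology

#: smallest admissible eigenvalue of the implied concentration matrix.
#: Floors much below ~1e-3 make the implied covariance effectively rank
#: deficient: one eigen-direction dominates, every marginal correlation
#: approaches +-1, and all estimators (and glasso solvers) degenerate.
EIG_FLOOR = 5e-3


def _check_square(M: np.ndarray, name: str = "matrix") -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square")
    return M


def sample_edge_weights(topology: NetworkTopology, seed: int = 0) -> np.ndarray:
    """Raw partial correlation matrix with uniform edge weights.

    Each edge weight is drawn from U([-1, -.01] ∪ [.01, 1]); non-edges are
    exactly 0 and the diagonal is 1.  The result may not yet correspond to a
    positive definite model — see :func:`regularize_to_pd`.
    """
    rng = np.random.default_rng(seed)
    p = topology.n_nodes
    R = np.eye(p)
    ea = topology.edge_array()
    m = len(ea)
    if m:
        mags = rng.uniform(0.01, 1.0, size=m)
        signs = rng.integers(0, 2, size=m) * 2 - 1
        w = mags * signs
        R[ea[:, 0], ea[:, 1]] = w
        R[ea[:, 1], ea[:, 0]] = w
    return R


def regularize_to_pd(
    raw: np.ndarray,
    topology: NetworkTopology,
    eig_floor: float = EIG_FLOOR,
) -> tuple[np.ndarray, float]:
    """Shrink off-diagonal weights by a common factor until PD.

    The implied concentration matrix of a partial correlation matrix
    ``I + c*M`` (``M`` = off-diagonal part) is ``I - c*M``, whose minimum
    eigenvalue is ``1 - c*lambda_max(M)`` — linear in ``c``.  The largest
    admissible factor is therefore available in closed form; scaling
    preserves the sign pattern and the exact-zero support, so the re-zeroing
    pass is a no-op enforced defensively.

    Returns
    -------
    (R, c):
        Regularized partial correlation matrix and the shrink factor used.
    """
    raw = _check_square(raw, "raw partial correlation matrix")
    p = raw.shape[0]
    if p != topology.n_nodes:
        raise ValueError("matrix dimension does not match topology")
    M = raw - np.diag(np.diag(raw))
    if not np.allclose(np.diag(raw), 1.0):
        raise ValueError("raw matrix must have unit diagonal")
    if not np.allclose(M, M.T):
        raise ValueError("raw matrix must be symmetric")
    lam_max = float(np.linalg.eigvalsh(M)[-1]) if p > 1 else 0.0
    if lam_max <= 1.0 - eig_floor:
        c = 1.0
    else:
        c = (1.0 - eig_floor) / lam_max
    R = np.eye(p) + c * M
    # enforce exact zeros off the support
    A = topology.adjacency(sparse=False).astype(bool)
    off = ~np.eye(p, dtype=bool)
    R[off & ~A] = 0.0
    min_eig = float(np.linalg.eigvalsh(np.eye(p) - (R - np.eye(p)))[0])
    if min_eig <= 0:
        raise RuntimeError(
            f"regularization failed: min concentration eigenvalue {min_eig:.3e}"
        )
    return R, c


def pcor_to_cor(R: np.ndarray) -> np.ndarray:
    """Implied correlation matrix of a partial correlation matrix.

    Off-diagonal entries are negated to form the (standardized)
    concentration matrix, which is then inverted and rescaled to unit
    diagonal.  A pseudoinverse is used only if the matrix is rank deficient.
    """
    R = _check_square(R, "partial correlation matrix")
    p = R.shape[0]
    K = -R.copy()
    np.fill_diagonal(K, np.diag(R))
    eigs = np.linalg.eigvalsh(K)
    if eigs[0] < -1e-10:
        raise ValueError(
            f"implied concentration matrix is not PSD (min eig {eigs[0]:.3e})"
        )
    if eigs[0] > 1e-12:
        cov = np.linalg.inv(K)
    else:  # rank-deficient edge case
        cov = np.linalg.pinv(K, hermitian=True)
    d = np.sqrt(np.diag(cov))
    C = cov / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return (C + C.T) / 2.0


def cor_to_pcor(C: np.ndarray) -> np.ndarray:
    """Partial correlation matrix implied by a correlation (or covariance) matrix."""
    C = _check_square(C, "correlation matrix")
    eigs = np.linalg.eigvalsh(C)
    if eigs[0] <= 0:
        raise ValueError(f"matrix is not positive definite (min eig {eigs[0]:.3e})")
    G = np.linalg.inv(C)
    d = np.sqrt(np.diag(G))
    R = -G / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return (R + R.T) / 2.0


def scale_to_covariance(C: np.ndarray, variance: float = 2.0) -> np.ndarray:
    """Covariance with uniform variance: ``Sigma = variance * C``."""
    C = _check_square(C, "correlation matrix")
    if variance <= 0:
        raise ValueError("variance must be positive")
    if not np.allclose(np.diag(C), 1.0):
        raise ValueError("C must have unit diagonal")
    return variance * C


@dataclass(frozen=True)
class GGM:
    """Finalized Gaussian graphical model for a topology."""

    topology: NetworkTopology
    pcor: np.ndarray  # R: regularized partial correlations
    cor: np.ndarray  # C: implied correlation matrix
    cov: np.ndarray  # Sigma = variance * C
    shrink_factor: float
    variance: float
    seed: int


def build_ggm(
    topology: NetworkTopology,
    seed: int = 0,
    variance: float = 2.0,
    eig_floor: float = EIG_FLOOR,
) -> GGM:
    """Topology -> (R, C, Sigma) with sampled weights, in one call."""
    raw = sample_edge_weights(topology, seed)
    R, c = regularize_to_pd(raw, topology, eig_floor=eig_floor)
    C = pcor_to_cor(R)
    Sigma = scale_to_covariance(C, variance)
    return GGM(topology, R, C, Sigma, c, variance, seed)
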