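"""Network-weight estimators.

Four estimators of edge weights from a p x T time-series matrix:

* pairwise Pearson correlation,
* partial correlation by shrinkage covariance estimation,
* partial correlation by Moore-Penrose pseudoinverse of the sample covariance,
* partial correlation by the graphical lasso with a density-targeted penalty.

All return a :class:`WeightMatrix` whose symmetric off-diagonal values feed
the fixed-density edge selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import graphical_lasso

from ggmbench.timeseries import TimeSeries


class EstimationError(RuntimeError):
    """Raised when an estimator cannot produce a valid weight matrix."""


@dataclass(frozen=True)
class WeightMatrix:
    """Symmetric p x p matrix of estimated edge weights."""

    values: np.ndarray
    method: str  # pairwise | shrinkage | pseudoinverse | glasso
    tuning: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be square")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("weight matrix must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def _values(ts) -> np.ndarray:
    if isinstance(ts, TimeSeries):
        return ts.values
    v = np.asarray(ts, dtype=float)
    if v.ndim != 2:
        raise ValueError("expected a p x T matrix")
    return v


def sample_covariance(ts) -> np.ndarray:
    """Unbiased sample covariance S over time points (denominator n - 1)."""
    v = _values(ts)
    if v.shape[1] < 2:
        raise ValueError("need at least 2 time points")
    return np.cov(v, ddof=1)


def pearson_correlation(ts) -> WeightMatrix:
    """Pairwise Pearson correlations from the sample covariance."""
    S = sample_covariance(ts)
    d = np.diag(S)
    bad = np.flatnonzero(d <= 0)
    if bad.size:
        raise ValueError(f"zero-variance node(s): {bad.tolist()}")
    sd = np.sqrt(d)
    C = S / np.outer(sd, sd)
    np.fill_diagonal(C, 1.0)
    return WeightMatrix((C + C.T) / 2.0, "pairwise")


def concentration_to_pcor(Gamma: np.ndarray) -> np.ndarray:
    """Partial correlations from a concentration matrix.

    ``pcor_ij = -gamma_ij / sqrt(gamma_ii * gamma_jj)``; diagonal set to 1.
    Invariant under positive rescaling of Gamma.
    """
    G = np.asarray(Gamma, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("concentration matrix must be square")
    if not np.allclose(G, G.T, atol=1e-8):
        raise ValueError("concentration matrix must be symmetric")
    d = np.diag(G)
    if np.any(d <= 0):
        raise ValueError("concentration matrix has non-positive diagonal entries")
    R = -G / np.sqrt(np.outer(d, d))
    np.fill_diagonal(R, 1.0)
    return (R + R.T) / 2.0


def shrinkage_intensity(ts) -> float:
    """Analytic optimal shrinkage of off-diagonal correlations toward zero.

    lambda* = sum_ij Var(r_ij) / sum_ij r_ij^2 over i != j, estimated from
    the data and clipped to [0, 1].
    """
    v = _values(ts)
    p, n = v.shape
    if n < 3:
        return 1.0
    xc = v - v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    xs = (xc / sd[:, None]).T  # n x p standardized observations
    wbar = xs.T @ xs / n
    w2sum = (xs**2).T @ (xs**2)
    var_r = n / (n - 1.0) ** 3 * (w2sum - n * wbar**2)
    r = n / (n - 1.0) * wbar
    off = ~np.eye(p, dtype=bool)
    denom = float((r[off] ** 2).sum())
    if denom <= 0:
        return 1.0
    lam = float(var_r[off].sum()) / denom
    return float(np.clip(lam, 0.0, 1.0))


def shrinkage_pcor(ts, lam: float | None = None) -> WeightMatrix:
    """Partial correlations from the shrunk covariance.

    ``Sigma_hat = (1 - lam)*S + lam*T`` where the target T carries the
    sample variances on the diagonal and zeros elsewhere.  ``lam`` is
    estimated from the data unless forced.
    """
    S = sample_covariance(ts)
    if lam is None:
        lam = shrinkage_intensity(ts)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    target = np.diag(np.diag(S))
    shrunk = (1.0 - lam) * S + lam * target
    if lam == 1.0:
        p = S.shape[0]
        return WeightMatrix(np.eye(p), "shrinkage", {"lambda_s": lam})
    try:
        Gamma = np.linalg.inv(shrunk)
    except np.linalg.LinAlgError as exc:
        raise EstimationError(
            f"shrunk covariance is singular at lambda_s={lam}"
        ) from exc
    R = concentration_to_pcor(Gamma)
    return WeightMatrix(R, "shrinkage", {"lambda_s": lam})


def pseudoinverse_pcor(ts) -> WeightMatrix:
    """Partial correlations from the Moore-Penrose pseudoinverse of S.

    Singular values below ``max(p, T) * eps * sigma_max`` are treated as
    zero; for full-rank S this coincides with the true inverse.
    """
    S = sample_covariance(ts)
    if not np.any(S):
        raise ValueError("sample covariance is the zero matrix")
    rcond = max(S.shape[0], _values(ts).shape[1]) * np.finfo(float).eps
    G = np.linalg.pinv(S, rcond=rcond, hermitian=True)
    d = np.diag(G).copy()
    if np.any(d <= 0):
        # rank-deficient corner: nodes annihilated by the pseudoinverse carry
        # no partial correlation information
        d = np.where(d > 0, d, np.inf)
        R = -G / np.sqrt(np.outer(d, d))
        np.fill_diagonal(R, 1.0)
        R = (R + R.T) / 2.0
    else:
        R = concentration_to_pcor(G)
    return WeightMatrix(R, "pseudoinverse", {"rcond": rcond})


def _admm_glasso(
    S: np.ndarray,
    alpha: float,
    rho: float = 1.0,
    max_iter: int = 250,
    tol: float = 1e-5,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """L1-penalized precision estimate by ADMM (off-diagonal penalty).

    Robust fallback for inputs too ill-conditioned for coordinate descent
    (e.g. near-singular correlation matrices when n < p).  The returned
    matrix combines the PD iterate with the exact-zero support of the
    soft-thresholded iterate.  ``init`` warm-starts the (Z, U) iterates,
    which pays off during the penalty-path search.
    """
    p = S.shape[0]
    if init is not None:
        Z, U = init[0].copy(), init[1].copy()
    else:
        Z = np.eye(p)
        U = np.zeros((p, p))
    offdiag = ~np.eye(p, dtype=bool)
    thr = alpha / rho
    for _ in range(max_iter):
        d, Q = np.linalg.eigh(rho * (Z - U) - S)
        theta_d = (d + np.sqrt(d * d + 4.0 * rho)) / (2.0 * rho)
        Theta = (Q * theta_d) @ Q.T
        Z_old = Z
        A = Theta + U
        Z = A.copy()
        Z[offdiag] = np.sign(A[offdiag]) * np.maximum(np.abs(A[offdiag]) - thr, 0.0)
        U = U + Theta - Z
        r = np.linalg.norm(Theta - Z)
        s = rho * np.linalg.norm(Z - Z_old)
        if r < tol * max(1.0, np.linalg.norm(Theta)) and s < tol * max(
            1.0, np.linalg.norm(U)
        ):
            break
    prec = Theta.copy()
    prec[offdiag & (Z == 0.0)] = 0.0
    return (prec + prec.T) / 2.0, (Z, U)


def _glasso_precision(
    C: np.ndarray, alpha: float, admm_state: dict | None = None
) -> np.ndarray:
    """Graphical-lasso precision estimate at penalty alpha (0 = MLE)."""
    if alpha <= 0:
        try:
            return np.linalg.inv(C)
        except np.linalg.LinAlgError as exc:
            raise EstimationError(
                "unpenalized MLE requires a non-singular input matrix"
            ) from exc
    skip_cd = admm_state is not None and admm_state.get("use_admm", False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if skip_cd:
                raise FloatingPointError
            _, prec = graphical_lasso(C, alpha=alpha, max_iter=200)
        except FloatingPointError:
            # coordinate descent diverged once for this input: don't retry it
            # at every penalty on the path
            init = admm_state.get("ZU") if admm_state is not None else None
            prec, zu = _admm_glasso(C, alpha, init=init)
            if admm_state is not None:
                admm_state["ZU"] = zu
                admm_state["use_admm"] = True
    return prec


def _support_size(prec: np.ndarray, tol: float = 1e-8) -> int:
    p = prec.shape[0]
    iu = np.triu_indices(p, 1)
    return int((np.abs(prec[iu]) > tol).sum())


def glasso_pcor(
    ts,
    target_edges: int | None = None,
    *,
    alpha: float | None = None,
    tol_frac: float = 0.02,
    max_bisect: int = 40,
) -> WeightMatrix:
    """Graphical-lasso partial correlations at a target edge count.

    The penalty ``lambda_l`` is found by bisection on the log scale so that
    the estimated support size is within ``tol_frac`` of ``target_edges``
    (or the closest size achievable on the path; ties resolved toward the
    sparser solution).  Pass ``alpha`` to skip the search and use a fixed
    penalty.
    """
    v = _values(ts)
    p = v.shape[0]
    C = pearson_correlation(ts).values
    if alpha is not None:
        prec = _glasso_precision(C, alpha)
        R = concentration_to_pcor(prec)
        return WeightMatrix(
            R, "glasso", {"lambda_l": float(alpha), "n_edges": _support_size(prec)}
        )
    max_possible = p * (p - 1) // 2
    if target_edges is None or not 0 <= target_edges <= max_possible:
        raise ValueError(f"target_edges must be in [0, {max_possible}]")
    iu = np.triu_indices(p, 1)
    hi = float(np.abs(C[iu]).max())
    if hi == 0 or target_edges == 0:
        prec = _glasso_precision(C, max(hi, 1.0))
        R = concentration_to_pcor(prec)
        return WeightMatrix(
            R, "glasso", {"lambda_l": max(hi, 1.0), "n_edges": _support_size(prec)}
        )
    tol = max(1, int(np.ceil(tol_frac * target_edges)))
    path: list[tuple[float, int]] = []
    admm_state: dict = {}
    best_alpha = best_prec = best_n = None

    def _better(n_new, a_new, n_old, a_old):
        d_new, d_old = abs(n_new - target_edges), abs(n_old - target_edges)
        if d_new != d_old:
            return d_new < d_old
        return a_new > a_old  # tie -> sparser (larger penalty)

    def _eval(alpha_val):
        nonlocal best_alpha, best_prec, best_n
        prec = _glasso_precision(C, alpha_val, admm_state)
        n_edges = _support_size(prec)
        path.append((alpha_val, n_edges))
        if best_n is None or _better(n_edges, alpha_val, best_n, best_alpha):
            best_alpha, best_prec, best_n = alpha_val, prec, n_edges
        return n_edges

    # geometric descent from the fully penalized end until the support
    # reaches the target or the solver leaves its stable range (n < p makes
    # near-zero penalties ill-conditioned -> treat divergence as a floor)
    a_hi = np.log(hi)
    a_lo = None
    alpha_cur, n_steps = hi, 0
    while n_steps < max_bisect:
        alpha_cur *= 0.3
        n_steps += 1
        try:
            n_cur = _eval(alpha_cur)
        except EstimationError:
            break
        if n_cur >= target_edges:
            a_lo = np.log(alpha_cur)
            break
        a_hi = np.log(alpha_cur)
    if best_n is None:
        raise EstimationError(
            f"graphical lasso produced no stable solution; path={path}"
        )
    if a_lo is None:
        a_lo = np.log(alpha_cur)  # divergence floor: bisect down toward it
    for _ in range(max_bisect - n_steps):
        if abs(best_n - target_edges) <= tol:
            break
        a_mid = 0.5 * (a_lo + a_hi)
        alpha_mid = float(np.exp(a_mid))
        try:
            n_mid = _eval(alpha_mid)
        except EstimationError:
            a_lo = a_mid  # unstable -> raise the floor
            continue
        if n_mid > target_edges:
            a_lo = a_mid
        else:
            a_hi = a_mid
    R = concentration_to_pcor(best_prec)
    return WeightMatrix(
        R,
        "glasso",
        {"lambda_l": best_alpha, "n_edges": best_n, "path": path},
    )


ESTIMATORS = ("pairwise", "shrinkage", "pseudoinverse", "glasso")


def estimate(method: str, ts, target_edges: int | None = None) -> WeightMatrix:
    """Dispatch helper used by the study runner."""
    if method == "pairwise":
        return pearson_correlation(ts)
    if method == "shrinkage":
        return shrinkage_pcor(ts)
    if method == "pseudoinverse":
        return pseudoinverse_pcor(ts)
    if method == "glasso":
        return glasso_pcor(ts, target_edges)
    raise ValueError(f"unknown estimator {method!r}; choose from {ESTIMATORS}")
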