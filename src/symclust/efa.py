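"""Exploratory factor analysis: ULS extraction and geomin oblique rotation.

Extraction minimizes the unweighted least squares criterion — the sum of
squared off-diagonal residuals of ``R - Lambda Lambda'`` — by iterated
principal-axis factoring: communalities seeded from squared multiple
correlations, eigendecomposition of the reduced matrix, top-k factors kept,
communalities updated, repeated to convergence. Communalities that reach 1
(Heywood cases) are capped during extraction.

Rotation minimizes the geomin criterion

    Q(Lambda) = sum_i ( prod_j (lambda_ij^2 + eps) )^(1/k)

over oblique rotations by the gradient projection algorithm of Jennrich,
restarted from multiple random orthonormal matrices because the criterion
is multi-modal; the number of starts agreeing with the best optimum is
reported as a local-minimum diagnostic. Rotated loadings are regression
coefficients, not correlations, and may legitimately exceed 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "FactorSolution",
    "uls_extract",
    "geomin_rotate",
    "fit_solutions",
    "tucker_congruence",
    "match_factors",
]


@dataclass
class FactorSolution:
    """One extracted-and-rotated factor solution.

    ``factor_correlations`` is the oblique Phi; for k = 1 it is the 1x1
    identity. ``n_random_starts_agreeing`` counts rotation restarts whose
    converged criterion is within 1e-5 of the best.
    """

    n_factors: int
    unrotated_loadings: np.ndarray
    rotated_loadings: np.ndarray
    factor_correlations: np.ndarray
    communalities: np.ndarray
    residual_rmsr: float
    converged: bool
    rotation_criterion_value: float
    n_random_starts_agreeing: int
    heywood_items: list[int] = field(default_factory=list)
    item_codes: list[str] | None = None

    def rotated_frame(self, factor_names: list[str] | None = None) -> pd.DataFrame:
        k = self.n_factors
        cols = factor_names or [f"F{j + 1}" for j in range(k)]
        idx = self.item_codes or [f"item{i}" for i in range(self.rotated_loadings.shape[0])]
        return pd.DataFrame(self.rotated_loadings, index=idx, columns=cols)


def _offdiag_rmsr(R: np.ndarray, model: np.ndarray) -> float:
    p = R.shape[0]
    resid = R - model
    mask = ~np.eye(p, dtype=bool)
    return float(np.sqrt(np.mean(resid[mask] ** 2)))


def _smc(R: np.ndarray) -> np.ndarray:
    """Squared multiple correlations (communality seeds)."""
    try:
        Rinv = np.linalg.inv(R)
        smc = 1.0 - 1.0 / np.diag(Rinv)
    except np.linalg.LinAlgError:
        Rinv = np.linalg.pinv(R)
        d = np.diag(Rinv)
        smc = np.where(d > 0, 1.0 - 1.0 / d, 0.5)
    return np.clip(smc, 0.0, 1.0)


def uls_extract(
    R: np.ndarray,
    k: int,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    callback=None,
) -> tuple[np.ndarray, np.ndarray, float, bool, list[int]]:
    """Iterated principal-axis ULS extraction of ``k`` factors.

    Returns ``(loadings, communalities, residual_rmsr, converged,
    heywood_items)``. Convergence is a maximum communality change below
    ``tol``; the ULS objective is non-increasing across iterations (each
    step is a block update of the residual with a free diagonal).
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if R.shape != (p, p) or not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("R must be square and symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("R must have a unit diagonal")
    if not 1 <= k < p:
        raise ValueError(f"need 1 <= k < {p}, got k={k}")

    h = _smc(R)
    lam = np.zeros((p, k))
    converged = False
    for _ in range(max_iter):
        Rh = R.copy()
        np.fill_diagonal(Rh, h)
        w, V = np.linalg.eigh(Rh)
        idx = np.argsort(w)[::-1][:k]
        wk = np.clip(w[idx], 0.0, None)
        lam = V[:, idx] * np.sqrt(wk)
        h_new = np.clip(np.sum(lam**2, axis=1), 0.0, 1.0)
        if callback is not None:
            callback(_offdiag_rmsr(R, lam @ lam.T))
        delta = np.max(np.abs(h_new - h))
        h = h_new
        if delta < tol:
            converged = True
            break
    heywood = [int(i) for i in np.nonzero(h >= 1.0 - 1e-12)[0]]
    # deterministic sign: largest-|loading| entry of each column positive
    lam = _fix_signs(lam)
    rmsr = _offdiag_rmsr(R, lam @ lam.T)
    return lam, h, rmsr, converged, heywood


def _fix_signs(lam: np.ndarray, phi: np.ndarray | None = None):
    lam = lam.copy()
    k = lam.shape[1]
    signs = np.ones(k)
    for j in range(k):
        i = np.argmax(np.abs(lam[:, j]))
        if lam[i, j] < 0:
            signs[j] = -1.0
    lam *= signs
    if phi is not None:
        phi = signs[:, None] * phi * signs[None, :]
        np.fill_diagonal(phi, 1.0)
        return lam, phi
    return lam


def _geomin_q(L: np.ndarray, eps: float) -> tuple[float, np.ndarray]:
    """Geomin criterion value and its gradient with respect to L."""
    k = L.shape[1]
    L2 = L**2 + eps
    pro = np.exp(np.sum(np.log(L2), axis=1) / k)
    f = float(np.sum(pro))
    G = (2.0 / k) * (L / L2) * pro[:, None]
    return f, G


def _gpa_oblique(
    A: np.ndarray, T0: np.ndarray, eps: float, tol: float = 1e-6, max_iter: int = 2000
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Gradient projection algorithm for oblique rotation (geomin criterion).

    Follows Jennrich's GPA: T carries unit-length columns, L = A (T')^{-1},
    Phi = T'T. Step length is halved until sufficient decrease.
    """
    T = T0.copy()
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _geomin_q(L, eps)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    converged = False
    for _ in range(max_iter):
        Gp = G - T * np.sum(T * G, axis=0, keepdims=True)
        s = np.sqrt(np.sum(Gp**2))
        if s < tol:
            converged = True
            break
        al *= 2.0
        for _ in range(12):
            X = T - al * Gp
            X /= np.sqrt(np.sum(X**2, axis=0, keepdims=True))
            Xi = np.linalg.inv(X)
            Lt = A @ Xi.T
            ft, Gqt = _geomin_q(Lt, eps)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T, f, L = X, ft, Lt
        G = -(L.T @ Gqt @ Xi).T
    phi = T.T @ T
    return L, phi, f, converged


def _random_orthonormal(k: int, rng: np.random.Generator) -> np.ndarray:
    M = rng.standard_normal((k, k))
    Q, R = np.linalg.qr(M)
    return Q * np.sign(np.diag(R))


def geomin_rotate(
    unrotated: np.ndarray,
    epsilon: float = 0.01,
    n_starts: int = 30,
    seed: int = 0,
    agree_tol: float = 1e-5,
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Oblique geomin rotation with random restarts.

    Returns ``(rotated_loadings, factor_correlations, criterion_value,
    n_starts_agreeing)``. Column signs are fixed so each factor's largest
    loading is positive; for a single factor the identity rotation is
    returned.
    """
    A = np.asarray(unrotated, dtype=float)
    k = A.shape[1]
    if k == 1:
        return A.copy(), np.eye(1), _geomin_q(A, epsilon)[0], n_starts
    rng = np.random.default_rng(seed)
    results = []
    starts = [np.eye(k)] + [_random_orthonormal(k, rng) for _ in range(max(0, n_starts - 1))]
    for T0 in starts:
        L, phi, f, _ = _gpa_oblique(A, T0, epsilon)
        results.append((f, L, phi))
    best_f = min(r[0] for r in results)
    n_agree = sum(1 for r in results if r[0] <= best_f + agree_tol)
    f, L, phi = min(results, key=lambda r: r[0])
    L, phi = _fix_signs(L, phi)
    # deterministic column order: descending sum of squared loadings
    order = np.argsort(-np.sum(L**2, axis=0), kind="stable")
    L = L[:, order]
    phi = phi[np.ix_(order, order)]
    return L, phi, float(best_f), int(n_agree)


def factor_solution(
    R: np.ndarray,
    k: int,
    epsilon: float = 0.01,
    n_starts: int = 30,
    seed: int = 0,
    item_codes: list[str] | None = None,
) -> FactorSolution:
    """Extract and rotate one ``k``-factor solution from a correlation matrix."""
    lam, h, rmsr, conv, heywood = uls_extract(R, k)
    if k >= 2:
        L, phi, crit, n_agree = geomin_rotate(lam, epsilon, n_starts, seed)
    else:
        L, phi, crit, n_agree = lam.copy(), np.eye(1), _geomin_q(lam, epsilon)[0], n_starts
    return FactorSolution(
        n_factors=k,
        unrotated_loadings=lam,
        rotated_loadings=L,
        factor_correlations=phi,
        communalities=h,
        residual_rmsr=rmsr,
        converged=conv,
        rotation_criterion_value=crit,
        n_random_starts_agreeing=n_agree,
        heywood_items=heywood,
        item_codes=item_codes,
    )


def fit_solutions(
    R: np.ndarray,
    k_min: int = 2,
    k_max: int = 8,
    epsilon: float = 0.01,
    n_starts: int = 30,
    seed: int = 0,
    loading_threshold: float = 0.40,
    item_codes: list[str] | None = None,
) -> tuple[list[FactorSolution], pd.DataFrame]:
    """Factor solutions for each k in ``[k_min, k_max]`` plus diagnostics.

    The diagnostics table reports, per k: off-diagonal residual RMSR, the
    number of adequately defined factors (at least two items at the loading
    threshold), the number of items assigned to no factor, the Heywood
    count and the rotation-start agreement — the evidence on which a factor
    count is chosen. Choosing k remains a judgement call; it is configured,
    not automated.
    """
    R = np.asarray(R, dtype=float)
    if not 1 <= k_min <= k_max < R.shape[0]:
        raise ValueError("need 1 <= k_min <= k_max < number of items")
    sols = []
    diag = []
    for k in range(k_min, k_max + 1):
        sol = factor_solution(R, k, epsilon, n_starts, seed, item_codes)
        sols.append(sol)
        meets = np.abs(sol.rotated_loadings) >= loading_threshold
        per_factor = meets.sum(axis=0)
        adequate = int(np.sum(per_factor >= 2))
        unassigned = int(np.sum(~meets.any(axis=1)))
        diag.append({
            "n_factors": k,
            "residual_rmsr": sol.residual_rmsr,
            "adequately_defined_factors": adequate,
            "unassigned_items": unassigned,
            "heywood_count": len(sol.heywood_items),
            "converged": sol.converged,
            "rotation_starts_agreeing": sol.n_random_starts_agreeing,
        })
    return sols, pd.DataFrame(diag).set_index("n_factors")


# -- factor matching ----------------------------------------------------

def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence coefficient (cosine) between two loading columns."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
    if denom == 0:
        return 0.0
    return float(np.sum(a * b) / denom)


def match_factors(
    estimated: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal column matching of two loading matrices by |congruence|.

    Returns ``(permutation, congruences)`` where ``estimated[:,
    permutation[j]]`` pairs with ``target[:, j]`` and ``congruences[j]`` is
    the signed Tucker coefficient of that pair after optimal sign flip
    (reported as absolute value).
    """
    est = np.asarray(estimated, dtype=float)
    tgt = np.asarray(target, dtype=float)
    k = tgt.shape[1]
    C = np.zeros((k, est.shape[1]))
    for j in range(k):
        for m in range(est.shape[1]):
            C[j, m] = abs(tucker_congruence(est[:, m], tgt[:, j]))
    rows, cols = linear_sum_assignment(-C)
    perm = np.empty(k, dtype=int)
    cong = np.empty(k)
    for j, m in zip(rows, cols):
        perm[j] = m
        cong[j] = C[j, m]
    return perm, cong
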