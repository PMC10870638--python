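"""Tetrachoric correlation estimation for binary symptom items.

The tetrachoric model treats each observed 2x2 table as a double
dichotomization of a standard bivariate normal: thresholds are fixed from
the margins via normal quantiles (two-step estimation), and the correlation
``rho`` is the maximizer of the multinomial likelihood of the four cells.
Bivariate normal rectangle probabilities come from Owen's T function, which
gives the CDF to near machine precision without quadrature.

Pairwise estimation over an item set yields the "matrix of associations"
fed to factor extraction; because pairs are estimated separately the matrix
can be indefinite, so an eigenvalue-clipping repair to the nearest unit-
diagonal PSD matrix is provided and its use is recorded in metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .dataset import SymptomDataset

__all__ = [
    "ContingencyTable2x2",
    "CorrelationMatrixEstimate",
    "bvn_upper_tail",
    "tetrachoric_from_table",
    "tetrachoric_matrix",
    "nearest_psd",
    "pair_table",
]

_SQRT_EPS = 1e-12


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Joint presence/absence counts for an item pair.

    ``n11``: both present, ``n10``: first only, ``n01``: second only,
    ``n00``: both absent.
    """

    n11: float
    n10: float
    n01: float
    n00: float

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("cell counts must be nonnegative")
        if self.total <= 0:
            raise ValueError("table total must be positive")

    @property
    def total(self) -> float:
        return self.n11 + self.n10 + self.n01 + self.n00

    def corrected(self) -> "ContingencyTable2x2":
        """Add 0.5 to every cell (applied when any cell is zero)."""
        return ContingencyTable2x2(self.n11 + 0.5, self.n10 + 0.5,
                                   self.n01 + 0.5, self.n00 + 0.5)

    @property
    def has_zero_cell(self) -> bool:
        return min(self.n11, self.n10, self.n01, self.n00) == 0


@dataclass
class CorrelationMatrixEstimate:
    """Estimated correlation matrix plus estimation metadata."""

    matrix: pd.DataFrame
    corrections: list[tuple[str, str]] = field(default_factory=list)
    psd_adjusted: bool = False
    min_eigenvalue_before: float = float("nan")
    frobenius_change: float = 0.0

    @property
    def values(self) -> np.ndarray:
        return self.matrix.to_numpy()


def _phi2(h: float, k: float, rho: float) -> float:
    """Standard bivariate normal CDF P(X <= h, Y <= k) via Owen's T.

    Owen (1956): Phi2 = (Phi(h) + Phi(k))/2 - T(h, a_h) - T(k, a_k) - delta,
    with a_h = (k - rho h)/(h sqrt(1-rho^2)) and delta = 1/2 when the
    quadrant (h, k) straddles the origin. Zero thresholds are the limits
    T(0, +/-inf) = +/-1/4.
    """
    if abs(rho) >= 1 - _SQRT_EPS:
        if rho > 0:
            return float(stats.norm.cdf(min(h, k)))
        return float(max(0.0, stats.norm.cdf(h) - stats.norm.cdf(-k)))
    if h == 0.0 and k == 0.0:
        return float(0.25 + np.arcsin(rho) / (2.0 * np.pi))
    denom = np.sqrt(1.0 - rho * rho)
    with np.errstate(over="ignore", divide="ignore"):
        if h != 0.0:
            th = special.owens_t(h, (k - rho * h) / (h * denom))
        else:  # limit as h -> 0 with k != 0
            th = 0.25 if k > 0 else -0.25
        if k != 0.0:
            tk = special.owens_t(k, (h - rho * k) / (k * denom))
        else:
            tk = 0.25 if h > 0 else -0.25
    if h * k < 0 or (h * k == 0 and h + k < 0):
        delta = 0.5
    else:
        delta = 0.0
    return float(0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k)) - th - tk - delta)


def bvn_upper_tail(h: float, k: float, rho: float) -> float:
    """P(X > h, Y > k) for standard bivariate normal with correlation rho.

    Accurate to well below 1e-7 over |rho| < 1; the degenerate |rho| = 1
    limits are handled analytically.
    """
    if abs(rho) >= 1:
        if rho >= 1:
            return float(stats.norm.sf(max(h, k)))
        return float(max(0.0, 1.0 - stats.norm.cdf(h) - stats.norm.cdf(k)))
    p = 1.0 - stats.norm.cdf(h) - stats.norm.cdf(k) + _phi2(h, k, rho)
    return float(min(1.0, max(0.0, p)))


def _cell_probs(tau_r: float, tau_c: float, rho: float) -> np.ndarray:
    """Cell probabilities (p11, p10, p01, p00) under the threshold model."""
    p11 = bvn_upper_tail(tau_r, tau_c, rho)
    pr = stats.norm.sf(tau_r)  # P(row present)
    pc = stats.norm.sf(tau_c)
    p10 = pr - p11
    p01 = pc - p11
    p00 = 1.0 - pr - pc + p11
    return np.clip(np.array([p11, p10, p01, p00]), 1e-300, 1.0)


def tetrachoric_from_table(
    table: ContingencyTable2x2, xtol: float = 1e-7
) -> tuple[float, tuple[float, float], bool]:
    """Two-step ML tetrachoric correlation from a 2x2 table.

    Thresholds are fixed from the margins (normal quantiles); rho maximizes
    the multinomial log-likelihood by a bounded scalar search on
    (-0.999, 0.999). A zero cell triggers the +0.5 all-cells correction.

    Returns ``(rho, (tau_row, tau_col), corrected)``.
    """
    row_margin = table.n11 + table.n10
    col_margin = table.n11 + table.n01
    if row_margin in (0, table.total) or col_margin in (0, table.total):
        raise ValueError("a margin is entirely one level; tetrachoric undefined")
    corrected = table.has_zero_cell
    if corrected:
        table = table.corrected()
    n = table.total
    p_row = (table.n11 + table.n10) / n
    p_col = (table.n11 + table.n01) / n
    tau_r = float(stats.norm.isf(p_row))
    tau_c = float(stats.norm.isf(p_col))
    counts = np.array([table.n11, table.n10, table.n01, table.n00])

    def negll(rho: float) -> float:
        return -float(counts @ np.log(_cell_probs(tau_r, tau_c, rho)))

    res = optimize.minimize_scalar(
        negll, bounds=(-0.999, 0.999), method="bounded",
        options={"xatol": xtol},
    )
    return float(res.x), (tau_r, tau_c), corrected


def pair_table(dataset: SymptomDataset, i: int, j: int) -> ContingencyTable2x2:
    """Pairwise-complete 2x2 presence table for catalog items i and j."""
    a = dataset.occurrence[:, i]
    b = dataset.occurrence[:, j]
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    return ContingencyTable2x2(
        float(np.sum((a == 1) & (b == 1))),
        float(np.sum((a == 1) & (b == 0))),
        float(np.sum((a == 0) & (b == 1))),
        float(np.sum((a == 0) & (b == 0))),
    )


def tetrachoric_matrix(
    dataset: SymptomDataset, ensure_psd: bool = True
) -> CorrelationMatrixEstimate:
    """Pairwise tetrachoric correlation matrix for every item pair.

    Symmetry and a unit diagonal hold by construction; zero-cell corrections
    are logged per pair, and (optionally) an indefinite result is repaired
    by :func:`nearest_psd` with the adjustment recorded.
    """
    codes = dataset.catalog.codes
    p = len(codes)
    if p < 2:
        raise ValueError("need at least two items")
    R = np.eye(p)
    corrections: list[tuple[str, str]] = []
    failed: list[tuple[str, str]] = []
    for i in range(p):
        for j in range(i + 1, p):
            try:
                rho, _, corr = tetrachoric_from_table(pair_table(dataset, i, j))
            except ValueError:
                failed.append((codes[i], codes[j]))
                continue
            R[i, j] = R[j, i] = rho
            if corr:
                corrections.append((codes[i], codes[j]))
    if failed:
        raise ValueError(f"tetrachoric undefined for pair(s): {failed[:10]}")
    est = CorrelationMatrixEstimate(
        pd.DataFrame(R, index=codes, columns=codes), corrections=corrections
    )
    eig_min = float(np.linalg.eigvalsh(R).min())
    est.min_eigenvalue_before = eig_min
    if ensure_psd and eig_min < -1e-8:
        repaired = nearest_psd(R)
        est.frobenius_change = float(np.linalg.norm(repaired - R, "fro"))
        est.matrix = pd.DataFrame(repaired, index=codes, columns=codes)
        est.psd_adjusted = True
    return est


def nearest_psd(matrix: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipping PSD repair preserving the unit diagonal.

    Eigenvalues below ``eig_floor`` are raised to it, the matrix is
    reassembled and rescaled back to a correlation matrix. An input that is
    already PSD is returned unchanged.
    """
    M = np.asarray(matrix, dtype=float)
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    w, V = np.linalg.eigh(M)
    if w.min() >= eig_floor - 1e-15:
        return M.copy()
    w = np.clip(w, eig_floor, None)
    out = (V * w) @ V.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0
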