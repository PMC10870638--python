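"""Synthetic symptom data from a latent thresholded-Gaussian factor model.

Binary occurrence is generated exactly under the model the tetrachoric /
factor-analysis pipeline assumes: each patient draws correlated factor
scores ``f ~ N(0, Phi)``, item latents ``y_i = Lambda_i f + e_i`` with unit
total variance, and the symptom is present when ``y_i`` exceeds the item's
threshold ``tau_i``. Marginal occurrence probabilities are therefore
``1 - Phi(tau_i)`` regardless of the loadings, and the population
tetrachoric correlation of a pair is ``Lambda_i Phi Lambda_j'``.

Severity (1-4) and distress (0-4), defined only for present symptoms, are
cut from the same latent exceedance ``y_i - tau_i`` — a deliberately simple
single-latent stand-in, since the downstream factoring uses occurrence only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .catalog import ItemCatalog, default_catalog
from .dataset import SymptomDataset
from .reference import GROUP_SIZES, reference_loadings, reference_occurrence_rates

__all__ = [
    "GeneratorConfig",
    "thresholds_from_rates",
    "simulate_group",
    "default_generating_model",
    "population_correlation_matrix",
]

# Conditional cut points for present symptoms, on the latent exceedance
# scale: quartiles of the half-normal for severity, quintiles for distress.
DEFAULT_SEVERITY_CUTPOINTS = tuple(stats.norm.ppf([0.625, 0.75, 0.875]))
DEFAULT_DISTRESS_CUTPOINTS = tuple(stats.norm.ppf([0.6, 0.7, 0.8, 0.9]))


@dataclass
class GeneratorConfig:
    """Parameters of the latent factor model for one group.

    ``loadings`` is items x factors (Lambda), ``factor_correlations`` is the
    factor correlation matrix Phi (unit diagonal, positive definite), and
    ``thresholds`` holds one standard-normal threshold per item. Residual
    variances are ``1 - Lambda_i Phi Lambda_i'`` and must be nonnegative.
    """

    loadings: np.ndarray
    factor_correlations: np.ndarray
    thresholds: np.ndarray
    n: int
    seed: int
    age_range: tuple[float, float] = (30.0, 59.9)
    group: str = "younger"
    catalog: ItemCatalog = field(default_factory=default_catalog)
    severity_cutpoints: tuple[float, ...] = DEFAULT_SEVERITY_CUTPOINTS
    distress_cutpoints: tuple[float, ...] = DEFAULT_DISTRESS_CUTPOINTS

    def __post_init__(self) -> None:
        self.loadings = np.atleast_2d(np.asarray(self.loadings, dtype=float))
        self.factor_correlations = np.atleast_2d(
            np.asarray(self.factor_correlations, dtype=float)
        )
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        p, k = self.loadings.shape
        phi = self.factor_correlations
        if phi.shape != (k, k):
            raise ValueError(f"factor_correlations must be {k}x{k}, got {phi.shape}")
        if not np.allclose(phi, phi.T) or not np.allclose(np.diag(phi), 1.0):
            raise ValueError("factor_correlations must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(phi).min() <= 0:
            raise ValueError("factor_correlations must be positive definite")
        if self.thresholds.shape != (p,):
            raise ValueError(f"thresholds must have length {p}")
        comm = self.communalities
        if (comm > 1 + 1e-12).any():
            bad = [self.catalog.codes[i] for i in np.nonzero(comm > 1 + 1e-12)[0]]
            raise ValueError(f"communality exceeds 1 for item(s): {bad}")
        for name, cuts in (("severity", self.severity_cutpoints),
                           ("distress", self.distress_cutpoints)):
            if not all(a < b for a, b in zip(cuts, cuts[1:])):
                raise ValueError(f"{name}_cutpoints must be strictly increasing")

    @property
    def communalities(self) -> np.ndarray:
        lam, phi = self.loadings, self.factor_correlations
        return np.einsum("if,fg,ig->i", lam, phi, lam)


def thresholds_from_rates(rates: np.ndarray) -> np.ndarray:
    """Standard-normal thresholds reproducing given occurrence proportions.

    ``tau_i = Q(1 - p_i)``, so that ``P(Z > tau_i) = p_i``.
    """
    rates = np.asarray(rates, dtype=float)
    if ((rates <= 0) | (rates >= 1)).any():
        raise ValueError("occurrence rates must lie strictly in (0, 1)")
    return stats.norm.isf(rates)


def population_correlation_matrix(config: GeneratorConfig) -> np.ndarray:
    """Model-implied latent correlation matrix ``Lambda Phi Lambda' + Psi``."""
    lam, phi = config.loadings, config.factor_correlations
    R = lam @ phi @ lam.T
    np.fill_diagonal(R, 1.0)
    return R


def simulate_group(config: GeneratorConfig) -> SymptomDataset:
    """Draw one group's dataset from the latent factor model.

    Deterministic given ``config`` (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    p, k = config.loadings.shape
    n = config.n
    chol = np.linalg.cholesky(config.factor_correlations)
    f = rng.standard_normal((n, k)) @ chol.T
    resid_sd = np.sqrt(np.clip(1.0 - config.communalities, 0.0, None))
    y = f @ config.loadings.T + rng.standard_normal((n, p)) * resid_sd
    excess = y - config.thresholds
    present = excess > 0

    occurrence = present.astype(float)
    sev_cuts = np.asarray(config.severity_cutpoints)
    dis_cuts = np.asarray(config.distress_cutpoints)
    severity = 1.0 + (excess[:, :, None] > sev_cuts).sum(axis=2)
    distress = (excess[:, :, None] > dis_cuts).sum(axis=2).astype(float)
    severity[~present] = np.nan
    distress[~present] = np.nan

    lo, hi = config.age_range
    ages = rng.uniform(lo, hi, size=n)
    pids = [f"{config.group}-{i:05d}" for i in range(n)]
    return SymptomDataset(
        config.catalog, pids, ages, occurrence, severity, distress,
        provenance=f"simulated:{config.group}:seed={config.seed}:n={n}",
    )


def default_generating_model(
    group: str,
    n: int | None = None,
    seed: int = 0,
    factor_correlation: float = 0.2,
    loading_clip: float = 0.95,
) -> GeneratorConfig:
    """Generating model calibrated to the bundled reference tables.

    The loading pattern places each reference-cluster symptom on its cluster
    with the printed rotated loading (clipped into ``[-loading_clip,
    loading_clip]``; oblique rotated loadings can exceed 1 but a generating
    pattern must keep residual variances nonnegative), zeros elsewhere.
    Thresholds reproduce the group's reference occurrence rates. Factor
    correlations default to a modest 0.2 everywhere off the diagonal so the
    oblique-rotation code path is exercised.
    """
    if group not in GROUP_SIZES:
        raise ValueError(f"group must be 'younger' or 'older', got {group!r}")
    catalog = default_catalog()
    lam_df = reference_loadings(group)
    lam = np.clip(lam_df.to_numpy(dtype=float), -loading_clip, loading_clip)
    k = lam.shape[1]
    phi = np.full((k, k), factor_correlation)
    np.fill_diagonal(phi, 1.0)
    rates = reference_occurrence_rates()[f"rate_{group}"].to_numpy()
    return GeneratorConfig(
        loadings=lam,
        factor_correlations=phi,
        thresholds=thresholds_from_rates(rates),
        n=n if n is not None else GROUP_SIZES[group],
        seed=seed,
        age_range=(30.0, 59.9) if group == "younger" else (60.0, 85.0),
        group=group,
        catalog=catalog,
    )
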