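"""Descriptive two-group comparisons of symptom occurrence, severity, distress.

Occurrence is compared with Fisher's exact test on the 2x2 item-by-group
table; conditional severity/distress ratings with the Mann-Whitney U test
(normal approximation with midranks, tie-corrected variance and continuity
correction); continuous covariates with a two-sample t test (Welch by
default). Significance is judged against an unadjusted two-sided p < alpha,
with an optional Bonferroni adjustment that is off by default. Rankings use
"top k with ties": every item tied at an included rank is listed, so a
top-10 list may hold more than 10 entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import AgeGroupSplit, SymptomDataset

__all__ = [
    "GroupComparisonRow",
    "RankedList",
    "occurrence_rates",
    "mean_symptom_count",
    "fisher_exact_2x2",
    "mann_whitney_u",
    "two_sample_t",
    "two_sample_t_from_stats",
    "compare_groups",
    "rank_top_symptoms",
]


@dataclass
class GroupComparisonRow:
    code: str
    rate_younger: float
    rate_older: float
    fisher_p: float
    severity_mean_younger: float
    severity_sd_younger: float
    severity_mean_older: float
    severity_sd_older: float
    severity_p: float
    distress_mean_younger: float
    distress_sd_younger: float
    distress_mean_older: float
    distress_sd_older: float
    distress_p: float


@dataclass
class RankedList:
    """Descending ranking with ties sharing a rank (competition ranking)."""

    entries: list[tuple[str, float, int]]  # (code, value, rank)

    def codes(self) -> list[str]:
        return [c for c, _, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def occurrence_rates(dataset: SymptomDataset) -> pd.Series:
    """Per-item occurrence proportion, missing responses excluded per item.

    Items with no non-missing response get NaN (flagged with a warning).
    """
    if dataset.n == 0:
        raise ValueError("dataset is empty")
    occ = dataset.occurrence
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rates = np.nanmean(occ, axis=0)
    undefined = np.isnan(rates)
    if undefined.any():
        bad = [dataset.catalog.codes[i] for i in np.nonzero(undefined)[0]]
        warnings.warn(f"occurrence rate undefined (all missing) for: {bad}")
    return pd.Series(rates, index=dataset.catalog.codes, name="rate")


def mean_symptom_count(dataset: SymptomDataset) -> tuple[float, float]:
    """Mean and SD of the per-patient number of present symptoms.

    On complete data the mean equals the sum of the per-item occurrence
    rates (missing occurrences count as absent here).
    """
    if dataset.n == 0:
        raise ValueError("dataset is empty")
    counts = np.nansum(dataset.occurrence, axis=1)
    return float(np.mean(counts)), float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    The conditional test: with both margins fixed, sum hypergeometric
    probabilities of all tables no more probable than the observed one.
    """
    table = np.array([[a, b], [c, d]])
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if table.sum(axis=0).min() == 0 and table.sum(axis=1).min() == 0:
        raise ValueError("both margins must be positive")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U statistic and two-sided p (normal approximation).

    Midranks for ties, tie-corrected variance, continuity correction. When
    every value in both samples is identical the test is degenerate and
    p = 1 is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    if np.ptp(np.concatenate([x, y])) == 0:
        warnings.warn("all values identical across both samples; p = 1")
        return float(len(x) * len(y) / 2.0), 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def two_sample_t(x: np.ndarray, y: np.ndarray, pooled: bool = False) -> tuple[float, float]:
    """Two-sample t test; Welch by default, Student when ``pooled``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        raise ValueError("zero variance in both samples with unequal means")
    res = stats.ttest_ind(x, y, equal_var=pooled)
    return float(res.statistic), float(res.pvalue)


def two_sample_t_from_stats(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    pooled: bool = False,
) -> tuple[float, float]:
    """Two-sample t test from summary statistics (for printed-table replays)."""
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=pooled)
    return float(res.statistic), float(res.pvalue)


def _conditional_summary(values: np.ndarray) -> tuple[float, float]:
    vals = values[~np.isnan(values)]
    if len(vals) == 0:
        return float("nan"), float("nan")
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return float(np.mean(vals)), sd


def compare_groups(
    split: AgeGroupSplit, alpha: float = 0.05, bonferroni: bool = False
) -> tuple[list[GroupComparisonRow], int]:
    """Per-item two-group comparison battery.

    Returns one row per catalog item plus the number of items whose
    occurrence differs at ``alpha`` (unadjusted two-sided Fisher p by
    default, matching the instrument convention of no multiplicity
    correction; set ``bonferroni`` to divide alpha by the item count).
    """
    young, old = split.younger, split.older
    if young.n == 0 or old.n == 0:
        raise ValueError("both groups must be nonempty")
    rows = []
    level = alpha / len(young.catalog) if bonferroni else alpha
    n_sig = 0
    for j, code in enumerate(young.catalog.codes):
        oy = young.occurrence[:, j]
        oo = old.occurrence[:, j]
        a = int(np.nansum(oy == 1)); b = int(np.nansum(oy == 0))
        c = int(np.nansum(oo == 1)); d = int(np.nansum(oo == 0))
        fp = fisher_exact_2x2(a, b, c, d)
        if fp < level:
            n_sig += 1

        sev_y, sev_o = young.severity[:, j], old.severity[:, j]
        dis_y, dis_o = young.distress[:, j], old.distress[:, j]

        def cond_p(u: np.ndarray, v: np.ndarray) -> float:
            u = u[~np.isnan(u)]; v = v[~np.isnan(v)]
            if len(u) == 0 or len(v) == 0:
                return float("nan")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return mann_whitney_u(u, v)[1]

        my, sy = _conditional_summary(sev_y)
        mo, so = _conditional_summary(sev_o)
        dmy, dsy = _conditional_summary(dis_y)
        dmo, dso = _conditional_summary(dis_o)
        rows.append(GroupComparisonRow(
            code=code,
            rate_younger=a / (a + b) if a + b else float("nan"),
            rate_older=c / (c + d) if c + d else float("nan"),
            fisher_p=fp,
            severity_mean_younger=my, severity_sd_younger=sy,
            severity_mean_older=mo, severity_sd_older=so,
            severity_p=cond_p(sev_y, sev_o),
            distress_mean_younger=dmy, distress_sd_younger=dsy,
            distress_mean_older=dmo, distress_sd_older=dso,
            distress_p=cond_p(dis_y, dis_o),
        ))
    return rows, n_sig


def comparison_frame(rows: list[GroupComparisonRow]) -> pd.DataFrame:
    """Rows as a DataFrame (one line per item, test columns side by side)."""
    return pd.DataFrame([vars(r) for r in rows]).set_index("code")


def rank_top_symptoms(values: pd.Series, k: int = 10) -> RankedList:
    """Top ``k`` items by value, descending, with ties sharing a rank.

    Ranks are dense (1, 2, 2, 3, ...): tied items share a rank and the next
    distinct value takes the following rank, so a top-10 list with a tie
    holds 11 entries. NaN values are excluded.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    s = values.dropna().sort_values(ascending=False, kind="stable")
    entries: list[tuple[str, float, int]] = []
    rank = 0
    prev = None
    for code, val in s.items():
        if prev is None or val != prev:
            rank += 1
            if rank > k:
                break
        entries.append((str(code), float(val), rank))
        prev = val
    return RankedList(entries)
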