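"""Correlational and group-comparison statistics.

Spearman rank correlations (alpha = 0.05; |rho| >= 0.5 labelled strong) with
significance masking for heatmap export; Shapiro–Wilk normality screening as
a gate for nonparametric testing; two-sample Wilcoxon rank-sum
(Mann–Whitney) tests — exact when samples are small and tie-free, otherwise
the tie-corrected normal approximation — with Bonferroni correction and the
conventional significance stars (ns, *, **, ***, ****).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05
STRONG_RHO = 0.5
#: star cutpoints: (threshold, label); p above the first threshold is "ns".
STAR_CUTPOINTS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


@dataclass(frozen=True)
class CorrelationCell:
    var_a: str
    var_b: str
    rho: float
    p_value: float
    n: int
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    @property
    def strong(self) -> bool:
        return abs(self.rho) >= STRONG_RHO


def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided permutation p by full enumeration (n <= 8)."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    perms = list(itertools.permutations(ry))
    for perm in perms:
        if abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12:
            count += 1
    return count / len(perms)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rho: product-moment correlation of average ranks."""
    rx = sps.rankdata(np.asarray(x, float))
    ry = sps.rankdata(np.asarray(y, float))
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_cell(x: Sequence[float], y: Sequence[float], var_a: str = "x",
                  var_b: str = "y", alpha: float = ALPHA) -> CorrelationCell:
    """One Spearman cell on pairwise-complete data.

    rho comes from the product-moment formula on average ranks; p from the
    t-approximation for n > 8 and full permutation enumeration below.
    Constant variables or fewer than 5 complete pairs yield a missing cell.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 5 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationCell(var_a, var_b, math.nan, math.nan, n, alpha)
    rho, p = sps.spearmanr(x, y)
    if n <= 8:
        p = _spearman_exact_p(x, y)
    return CorrelationCell(var_a, var_b, float(rho), float(p), n, alpha)


def spearman_matrix(
    table: pd.DataFrame, alpha: float = ALPHA
) -> list[CorrelationCell]:
    """All off-diagonal Spearman cells among the numeric columns of ``table``."""
    cols = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    cells = []
    for a, b in itertools.combinations(cols, 2):
        cells.append(spearman_cell(table[a], table[b], a, b, alpha))
    return cells


def correlation_tables(
    cells: Sequence[CorrelationCell],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(full rho matrix, masked matrix) — the mask blanks cells with p >= alpha,
    matching the heatmap convention of leaving insignificant cells empty."""
    variables = sorted({c.var_a for c in cells} | {c.var_b for c in cells})
    full = pd.DataFrame(np.nan, index=variables, columns=variables)
    masked = full.copy()
    for v in variables:
        full.loc[v, v] = 1.0
        masked.loc[v, v] = 1.0
    for c in cells:
        for i, j in ((c.var_a, c.var_b), (c.var_b, c.var_a)):
            full.loc[i, j] = c.rho
            masked.loc[i, j] = c.rho if c.significant else np.nan
    return full, masked


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk W and approximate p; requires 3 <= n <= 5000.

    A constant sample has no defined W and is reported as maximally
    non-normal (W = NaN, p = 0) so it gates to the nonparametric branch.
    """
    values = np.asarray(values, float)
    if not (3 <= len(values) <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(values) == 0:
        return math.nan, 0.0
    w, p = sps.shapiro(values)
    return float(w), float(p)


def wilcoxon_ranksum(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    exact_threshold: int = 8,
) -> tuple[float, float]:
    """Two-sided two-sample Wilcoxon rank-sum (Mann–Whitney U) test.

    Exact permutation null when min(n_a, n_b) <= ``exact_threshold`` and the
    pooled sample is tie-free; otherwise the tie-corrected normal
    approximation.  Returns (U statistic for sample_a, p).
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(len(a), len(b)) <= exact_threshold and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment: min(1, p * m); m defaults to len(p_values)."""
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < 1:
        raise ValueError("number of comparisons m must be >= 1")
    return [min(1.0, p * m) for p in p_values]


def stars(p: float) -> str:
    """Significance stars: **** p<=1e-4, *** p<=1e-3, ** p<=0.01, * p<=0.05, else ns."""
    if math.isnan(p):
        return "ns"
    for threshold, label in STAR_CUTPOINTS:
        if p <= threshold:
            return label
    return "ns"


def three_group_comparison(
    values: pd.Series,
    groups: pd.Series,
    group_labels: Sequence[str] = ("Broca", "Wernicke", "control"),
    min_per_group: int = 3,
    bonferroni_m: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All pairwise Wilcoxon rank-sum tests among three groups, Bonferroni
    corrected (m = number of pairwise comparisons by default), after a
    Shapiro–Wilk normality screen recorded per group.

    Returns (pairwise test table, descriptive table with median and IQR).
    """
    samples: dict[str, np.ndarray] = {}
    desc_rows = []
    for g in group_labels:
        sample = np.asarray(values[groups == g], float)
        sample = sample[~np.isnan(sample)]
        if len(sample) < min_per_group:
            raise ValueError(f"group {g!r} has fewer than {min_per_group} observations")
        samples[g] = sample
        q1, med, q3 = np.percentile(sample, [25, 50, 75])
        _, sw_p = shapiro_wilk(sample) if len(sample) >= 3 else (math.nan, math.nan)
        desc_rows.append(
            {
                "group": g, "n": len(sample), "median": med, "iqr": q3 - q1,
                "shapiro_p": sw_p, "normal": sw_p >= ALPHA,
            }
        )
    pair_rows = []
    pairs = list(itertools.combinations(group_labels, 2))
    m = bonferroni_m if bonferroni_m is not None else len(pairs)
    raw = []
    for ga, gb in pairs:
        stat, p = wilcoxon_ranksum(samples[ga], samples[gb])
        raw.append((ga, gb, stat, p))
    adjusted = bonferroni([p for *_, p in raw], m=m)
    for (ga, gb, stat, p), p_adj in zip(raw, adjusted):
        pair_rows.append(
            {
                "group_a": ga, "group_b": gb, "statistic": stat,
                "p": p, "p_adj": p_adj, "stars": stars(p_adj),
            }
        )
    return pd.DataFrame(pair_rows), pd.DataFrame(desc_rows)
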