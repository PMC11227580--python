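"""Nonparametric statistics against brute-force enumeration oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from aphasia_surprisal.stats import (
    bonferroni,
    correlation_tables,
    shapiro_wilk,
    spearman_cell,
    spearman_matrix,
    spearman_rho,
    stars,
    three_group_comparison,
    wilcoxon_ranksum,
)


def brute_force_ranksum_p(a, b):
    """Two-sided exact p by enumerating every label assignment of the pool."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = sps.rankdata(pooled)

    def u_stat(idx_a):
        r = sum(ranks[i] for i in idx_a)
        return r - n_a * (n_a + 1) / 2

    u_obs = u_stat(range(n_a))
    us = [u_stat(c) for c in itertools.combinations(range(len(pooled)), n_a)]
    total = len(us)
    p_le = sum(u <= u_obs for u in us) / total
    p_ge = sum(u >= u_obs for u in us) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def test_wilcoxon_textbook_case():
    stat, p = wilcoxon_ranksum([1, 2, 3], [4, 5, 6])
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(0.1)  # 2 * 1/C(6,3)


def test_wilcoxon_exact_matches_enumeration():
    rng = np.random.default_rng(9)
    for n_a, n_b in [(3, 3), (4, 4), (5, 5), (4, 6), (3, 7), (2, 8)]:
        vals = rng.permutation(np.arange(1.0, n_a + n_b + 1))  # tie-free
        a, b = vals[:n_a], vals[n_a:]
        _, p = wilcoxon_ranksum(a, b)
        assert p == pytest.approx(brute_force_ranksum_p(a, b), abs=1e-12)


def test_wilcoxon_identical_samples_and_errors():
    a = [1.0, 2.0, 3.0]
    _, p = wilcoxon_ranksum(a, a)
    assert p == pytest.approx(1.0)
    with pytest.raises(ValueError):
        wilcoxon_ranksum([], [1.0])


def test_spearman_equals_correlation_of_ranks():
    rng = np.random.default_rng(4)
    for _ in range(100):
        n = rng.integers(5, 40)
        x = rng.integers(0, 10, n).astype(float)  # ties likely
        y = rng.normal(size=n)
        if np.ptp(x) == 0:
            continue
        expected = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-12)


def test_spearman_hand_value_and_monotone_invariance():
    assert spearman_rho([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)
    x = np.linspace(-2, 2, 20)
    cell = spearman_cell(x, np.exp(x))
    assert cell.rho == pytest.approx(1.0)
    assert spearman_cell(x, -x).rho == pytest.approx(-1.0)


def test_spearman_cell_missing_policies():
    cell = spearman_cell([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])
    assert math.isnan(cell.rho)  # constant variable -> undefined
    short = spearman_cell([1, 2, 3], [3, 2, 1])
    assert math.isnan(short.rho)  # < 5 complete pairs
    with_nan = spearman_cell(
        [1, 2, 3, 4, 5, np.nan, 7], [2, 1, 4, 3, 6, 5, np.nan]
    )
    assert with_nan.n == 5  # pairwise-complete deletion


def test_correlation_mask_blanks_insignificant_cells():
    rng = np.random.default_rng(1)
    n = 40
    x = rng.normal(size=n)
    df = pd.DataFrame(
        {"a": x, "b": x + 0.1 * rng.normal(size=n), "c": rng.normal(size=n)}
    )
    cells = spearman_matrix(df)
    full, masked = correlation_tables(cells)
    for cell in cells:
        shown = masked.loc[cell.var_a, cell.var_b]
        if cell.significant:
            assert shown == pytest.approx(cell.rho)
        else:
            assert math.isnan(shown)
        assert full.loc[cell.var_a, cell.var_b] == pytest.approx(cell.rho)
    ab = next(c for c in cells if {c.var_a, c.var_b} == {"a", "b"})
    assert ab.strong and ab.significant


def test_shapiro_calibration_and_power():
    rng = np.random.default_rng(6)
    normal_ok = sum(
        shapiro_wilk(rng.normal(size=500))[1] > 0.05 for _ in range(100)
    )
    assert normal_ok >= 90
    skew_reject = sum(
        shapiro_wilk(rng.lognormal(0, 1.5, size=500))[1] < 0.05
        for _ in range(100)
    )
    assert skew_reject >= 99
    w, p = shapiro_wilk([2.0] * 10)
    assert math.isnan(w) and p == 0.0  # constant reported as non-normal
    with pytest.raises(ValueError):
        shapiro_wilk([1.0, 2.0])


def test_bonferroni_values_and_monotonicity():
    assert bonferroni([0.01], m=5) == [pytest.approx(0.05)]
    assert bonferroni([0.4], m=5) == [1.0]
    assert stars(bonferroni([0.012], m=3)[0]) == "*"
    ps = [0.001, 0.02, 0.2]
    for m1, m2 in [(1, 2), (2, 5), (5, 50)]:
        a1, a2 = bonferroni(ps, m1), bonferroni(ps, m2)
        assert all(x2 >= x1 >= p for p, x1, x2 in zip(ps, a1, a2))
    with pytest.raises(ValueError):
        bonferroni([0.1], m=0)


def test_star_cutpoints():
    assert stars(0.2) == "ns"
    assert stars(0.05) == "*"
    assert stars(0.01) == "**"
    assert stars(0.001) == "***"
    assert stars(0.00005) == "****"


def test_three_group_comparison_detects_shift():
    rng = np.random.default_rng(12)
    values, labels = [], []
    for g, shift in [("Broca", 2.0), ("Wernicke", 0.0), ("control", 0.0)]:
        values.extend(rng.normal(5 + shift, 1.0, 50))
        labels.extend([g] * 50)
    pairwise, desc = three_group_comparison(pd.Series(values), pd.Series(labels))
    row = pairwise.set_index(["group_a", "group_b"]).loc[("Broca", "control")]
    assert row["p_adj"] < 0.05
    assert set(desc["group"]) == {"Broca", "Wernicke", "control"}
    assert (desc["iqr"] > 0).all()


def test_three_group_null_rarely_rejects():
    rng = np.random.default_rng(13)
    n_any = 0
    for seed in range(20):
        r = np.random.default_rng(seed)
        vals = pd.Series(r.normal(0, 1, 90))
        labels = pd.Series(["Broca"] * 30 + ["Wernicke"] * 30 + ["control"] * 30)
        pairwise, _ = three_group_comparison(vals, labels)
        if (pairwise["p_adj"] < 0.05).any():
            n_any += 1
    assert n_any <= 1


def test_three_group_disjoint_supports():
    vals = pd.Series([1, 2, 3, 11, 12, 13, 21, 22, 23], dtype=float)
    labels = pd.Series(["Broca"] * 3 + ["Wernicke"] * 3 + ["control"] * 3)
    pairwise, _ = three_group_comparison(vals, labels)
    # exact-test floor for n=3 vs 3: p = 2/C(6,3) = 0.1, times m=3
    assert pairwise["p"].unique() == pytest.approx([0.1])
    assert pairwise["p_adj"].unique() == pytest.approx([0.3])
    with pytest.raises(ValueError):
        three_group_comparison(vals, labels.replace("control", "Broca"))


def test_type_one_error_rate():
    rng = np.random.default_rng(99)
    rejections = 0
    reps = 1000
    for _ in range(reps):
        a = rng.normal(size=50)
        b = rng.normal(size=50)
        _, p = wilcoxon_ranksum(a, b)
        rejections += p < 0.05
    assert abs(rejections / reps - 0.05) <= 0.02
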