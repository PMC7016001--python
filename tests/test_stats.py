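"""Cohort statistics vs exact/permutation/closed-form oracles."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from meniscus_qmri.stats import (
    DEFAULT_ALPHA,
    TestResult,
    anova_across_groups,
    compare_deltas,
    compare_grades,
    compare_loading,
    correlate_qmri_biomech,
    repeated_measures_anova,
    screen_normality,
    ttest_deltas,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def kruskal_exact_enumeration(groups):
    """Exact permutation p for the KW test by enumerating group assignments."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)

    def h_of(assign):
        h = 0.0
        for gi, n_i in enumerate(sizes):
            r = ranks[np.asarray(assign) == gi]
            h += r.sum() ** 2 / n_i
        return 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)

    observed = h_of(np.repeat(np.arange(len(sizes)), sizes))
    count = total = 0
    idx = list(range(N))
    for combo1 in itertools.combinations(idx, sizes[0]):
        rest = [i for i in idx if i not in combo1]
        for combo2 in itertools.combinations(rest, sizes[1]):
            assign = np.full(N, 2)
            assign[list(combo1)] = 0
            assign[list(combo2)] = 1
            total += 1
            if h_of(assign) >= observed - 1e-12:
                count += 1
    return count / total


def friedman_exact_enumeration(data):
    """Exact p for the Friedman test over all within-block orderings."""
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, data)

    def chi2_of(r):
        col = r.sum(axis=0)
        return 12.0 / (n * k * (k + 1)) * (col**2).sum() - 3.0 * n * (k + 1)

    observed = chi2_of(ranks)
    perms = list(itertools.permutations(range(k)))
    count = total = 0
    for combo in itertools.product(range(len(perms)), repeat=n):
        r = np.vstack([ranks[i, list(perms[j])] for i, j in enumerate(combo)])
        total += 1
        if chi2_of(r) >= observed - 1e-12:
            count += 1
    return count / total


def pooled_t_oracle(a, b):
    """Hand-computed pooled-variance two-sample t statistic and p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * sps.t.sf(abs(t), na + nb - 2)
    return t, p


def spearman_rank_formula(x, y):
    """rho = 1 - 6*sum(d^2)/(n(n^2-1)) for tie-free data."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    d = rx - ry
    n = len(x)
    return 1 - 6 * float(d @ d) / (n * (n**2 - 1))


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

class TestCompareGrades:
    def test_identical_groups_h_zero_p_one(self):
        res = compare_grades({"I": [5, 5, 5], "II": [5, 5, 5], "III": [5, 5, 5]})
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_matches_scipy_on_regular_data(self, rng):
        groups = {k: rng.normal(i, 1, 8) for i, k in enumerate(["I", "II", ">=III"])}
        res = compare_grades(groups)
        h, p = sps.kruskal(*groups.values())
        assert res.statistic == pytest.approx(h, rel=1e-9)
        assert res.pvalue == pytest.approx(p, rel=1e-9)

    def test_permutation_p_matches_exact_enumeration(self):
        groups = {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        p_exact = kruskal_exact_enumeration(list(groups.values()))
        res = compare_grades(groups, p_method="permutation", n_permutations=20000, seed=1)
        mc_se = np.sqrt(p_exact * (1 - p_exact) / 20000)
        assert abs(res.pvalue - p_exact) < 4 * mc_se + 1e-4

    def test_alpha_frozen_at_0_005(self):
        res = compare_grades({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert res.alpha == DEFAULT_ALPHA == 0.005

    def test_degenerate_groups_yield_missing_result(self):
        assert compare_grades({"a": [1.0], "b": [2.0]}) is None


# ---------------------------------------------------------------------------
# Friedman + Dunn
# ---------------------------------------------------------------------------

class TestCompareLoading:
    def test_identical_values_chi2_zero_p_one_no_flags(self):
        data = np.tile([40.0, 40.0, 40.0], (6, 1))
        res = compare_loading(data)
        assert res.statistic == 0.0 and res.pvalue == 1.0
        assert res.posthoc_flags == "ns, ns, ns"

    def test_exact_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        base = rng.normal(600, 50, 6)
        data = np.column_stack([base, base - 80 + rng.normal(0, 4, 6), base - 140 + rng.normal(0, 4, 6)])
        res = compare_loading(data, p_method="exact")
        p_oracle = friedman_exact_enumeration(data)
        assert res.pvalue == pytest.approx(p_oracle, abs=1e-12)

    def test_matches_scipy_asymptotic_without_ties(self, rng):
        data = rng.normal(0, 1, (10, 3))
        res = compare_loading(data)
        chi2, p = sps.friedmanchisquare(data[:, 0], data[:, 1], data[:, 2])
        assert res.statistic == pytest.approx(chi2, rel=1e-9)
        assert res.pvalue == pytest.approx(p, rel=1e-9)

    def test_posthoc_order_is_fixed(self, rng):
        data = rng.normal(0, 1, (8, 3))
        res = compare_loading(data)
        assert [c.pair for c in res.posthoc] == [
            ("delta0", "delta1"),
            ("delta0", "delta2"),
            ("delta1", "delta2"),
        ]

    def test_perfect_ordering_n15_reproduces_star_star_star(self):
        # strictly decreasing triplets for every sample: the printed pattern
        # "*, *, *" is attainable on adjusted p <= 0.05, and the delta0-delta2
        # contrast is overwhelming
        rng = np.random.default_rng(8)
        base = rng.normal(700, 60, 15)
        data = np.column_stack([base, base - 120, base - 200])
        res = compare_loading(data)
        assert res.pvalue < 1e-5
        assert res.posthoc_flags == "*, *, *"
        assert res.posthoc[1].p_adj < 1e-6

    def test_incomplete_triplets_dropped(self):
        data = np.array([[1.0, 2.0, 3.0], [2.0, np.nan, 4.0], [3.0, 4.0, 5.0]])
        res = compare_loading(data)
        assert res.extras["n"] == 2


# ---------------------------------------------------------------------------
# Deltas: ANOVA, t-test, normality gate
# ---------------------------------------------------------------------------

class TestDeltaBattery:
    def test_identical_distributions_f_near_zero(self, rng):
        x = rng.normal(0, 1, 12)
        res = anova_across_groups({"a": x, "b": x, "c": x})
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.pvalue == pytest.approx(1.0, abs=1e-9)

    def test_ttest_matches_pooled_closed_form(self):
        a, b = [1.0, 2.0, 3.0], [2.5, 3.5, 4.5]
        res = ttest_deltas(a, b)
        t_o, p_o = pooled_t_oracle(a, b)
        assert res.statistic == pytest.approx(t_o, rel=1e-12)
        assert res.pvalue == pytest.approx(p_o, rel=1e-12)

    def test_battery_structure(self, rng):
        df = pd.DataFrame(
            {
                "grade_group": np.repeat(["I", "II", ">=III"], 8),
                "delta1": rng.normal(-15, 5, 24),
                "delta2": rng.normal(-20, 5, 24),
            }
        )
        res = compare_deltas(df)
        assert set(res) == {"anova_delta1", "anova_delta2", "ttest"}
        assert all(isinstance(v, TestResult) for v in res.values())
        assert "normality" in res["ttest"].extras

    def test_normality_gate(self, rng):
        normal = rng.normal(0, 1, 60)
        skewed = rng.exponential(1, 60) ** 2
        assert screen_normality(normal)[0] is True
        assert screen_normality(skewed)[0] is False
        assert screen_normality(np.ones(5))[0] is False  # too small / constant

    def test_small_cells_yield_missing(self):
        assert ttest_deltas([1.0, 2.0], [1.0, 2.0, 3.0]) is None


# ---------------------------------------------------------------------------
# Spearman and repeated-measures ANOVA
# ---------------------------------------------------------------------------

class TestCorrelation:
    def test_perfect_inverse_monotone(self):
        res = correlate_qmri_biomech([1, 2, 3, 4, 5], [50, 40, 30, 20, 10])
        assert res.statistic == pytest.approx(-1.0)

    def test_six_pair_rank_formula(self):
        x = [46.7, 53.3, 41.7, 48.3, 44.0, 51.0]
        y = [15.5, 10.2, 20.1, 12.8, 18.0, 11.5]
        res = correlate_qmri_biomech(x, y)
        assert res.statistic == pytest.approx(spearman_rank_formula(x, y), rel=1e-12)

    def test_constant_input_missing(self):
        assert correlate_qmri_biomech([1, 1, 1, 1, 1], [1, 2, 3, 4, 5]) is None

    def test_too_few_pairs_missing(self):
        assert correlate_qmri_biomech([1, 2, 3], [3, 2, 1]) is None


class TestRepeatedMeasures:
    def test_decreasing_pixel_counts_significant(self, rng):
        rows = []
        for i in range(12):
            base = rng.normal(800, 100)
            for load, mean in zip(("delta0", "delta1", "delta2"), (0, -85, -200)):
                rows.append(
                    {
                        "sample": f"S{i}",
                        "load": load,
                        "pixel_count": base + mean + rng.normal(0, 10),
                    }
                )
        res = repeated_measures_anova(pd.DataFrame(rows))
        assert res.pvalue < 1e-6
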