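"""ICC(1), category bands, deviations, Mann-Whitney and exceedance curves."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from morphrel import phantoms, reliability
from morphrel.io_formats import SessionMatrix


def _matrix(values):
    values = np.asarray(values, float)
    n, k = values.shape
    return SessionMatrix(values, [f"s{i}" for i in range(n)], [f"t{j}" for j in range(k)])


def _icc_oracle(y: np.ndarray) -> float:
    """Independent one-way ANOVA ICC via explicit double-loop sums of squares."""
    n, k = y.shape
    grand = sum(y[i, j] for i in range(n) for j in range(k)) / (n * k)
    ss_b = ss_w = 0.0
    for i in range(n):
        mi = sum(y[i, j] for j in range(k)) / k
        ss_b += k * (mi - grand) ** 2
        for j in range(k):
            ss_w += (y[i, j] - mi) ** 2
    ms_b = ss_b / (n - 1)
    ms_w = ss_w / (n * (k - 1))
    return (ms_b - ms_w) / (ms_b + (k - 1) * ms_w)


def _exact_mw_p(a, b):
    """Exhaustive two-sided permutation p for the Mann-Whitney U."""
    from scipy.stats import rankdata

    pooled = np.asarray(list(a) + list(b), float)
    n_a = len(a)
    ranks = rankdata(pooled)
    mu = n_a * (len(pooled) - n_a) / 2
    obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    dev = abs(obs - mu)
    hits = total = 0
    for comb in combinations(range(len(pooled)), n_a):
        u = ranks[list(comb)].sum() - n_a * (n_a + 1) / 2
        hits += abs(u - mu) >= dev - 1e-12
        total += 1
    return hits / total


class TestICC:
    def test_worked_example(self):
        res = reliability.icc_oneway(_matrix([[1, 2], [3, 4], [5, 6]]))
        assert res.ms_between == pytest.approx(8.0, abs=1e-12)
        assert res.ms_within == pytest.approx(0.5, abs=1e-12)
        assert res.icc == pytest.approx(7.5 / 8.5, abs=1e-12)
        assert res.category == "excellent"

    def test_identical_sessions_give_unity(self):
        res = reliability.icc_oneway(_matrix([[1, 1], [2, 2], [5, 5]]))
        assert res.icc == 1.0
        assert res.ci_lower == res.ci_upper == 1.0

    def test_matches_brute_force_oracle_on_random_matrices(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 12))
            k = int(rng.integers(2, 8))
            y = rng.normal(size=(n, k)) * rng.uniform(0.5, 3) + rng.uniform(-5, 5)
            res = reliability.icc_oneway(_matrix(y))
            assert res.icc == pytest.approx(_icc_oracle(y), abs=1e-12)

    @given(
        a=st.floats(0.1, 10),
        b=st.floats(-100, 100),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_affine_invariance(self, a, b, seed):
        y = np.random.default_rng(seed).normal(size=(6, 3))
        base = reliability.icc_oneway(_matrix(y)).icc
        scaled = reliability.icc_oneway(_matrix(a * y + b)).icc
        assert scaled == pytest.approx(base, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(reliability.DegenerateDataError):
            reliability.icc_oneway(_matrix(np.full((3, 2), 4.0)))

    def test_ci_brackets_estimate(self, rng):
        for seed in range(20):
            m = phantoms.simulate_sessions(phantoms.VarianceComponentsSpec(seed=seed))
            res = reliability.icc_oneway(m)
            assert res.ci_lower <= res.icc <= res.ci_upper

    def test_ci_coverage_at_study_geometries(self):
        """95% CI covers the true reliability ~95% of the time."""
        for rho, sb in ((0.8, 2.0), (0.4, math.sqrt(2 / 3))):
            hits = 0
            n_sim = 400
            for seed in range(n_sim):
                m = phantoms.simulate_sessions(
                    phantoms.VarianceComponentsSpec(30, 10, 2.5, sb, 1.0, seed)
                )
                res = reliability.icc_oneway(m)
                hits += res.ci_lower <= rho <= res.ci_upper
            assert 0.92 <= hits / n_sim <= 0.98

    def test_fewer_sessions_widen_ci_at_fixed_n(self):
        widths = {}
        for k in (2, 10):
            ws = [
                reliability.icc_oneway(
                    phantoms.simulate_sessions(
                        phantoms.VarianceComponentsSpec(30, k, 2.5, 2.0, 1.0, seed)
                    )
                )
                for seed in range(300)
            ]
            widths[k] = float(np.mean([w.ci_upper - w.ci_lower for w in ws]))
        assert widths[2] > widths[10]


class TestClassify:
    @pytest.mark.parametrize("value,expected", [
        (0.816, "excellent"),  # whole-cortex thickness falls in the excellent band
        (1.0, "excellent"),
        (0.75, "excellent"),
        (0.749, "good"),
        (0.60, "good"),
        (0.599, "fair"),
        (0.40, "fair"),
        (0.399, "poor"),
        (0.0, "poor"),
        (-0.2, "poor"),
    ])
    def test_band_boundaries(self, value, expected):
        assert reliability.classify_icc(value) == expected

    def test_above_one_rejected(self):
        with pytest.raises(ValueError):
            reliability.classify_icc(1.2)


class TestMeanDeviation:
    def test_simple_arithmetic(self):
        res = reliability.mean_deviation(_matrix([[1, 2, 3], [1, 2, 3]]))
        np.testing.assert_allclose(res.per_subject, 2 / 3)

    def test_constant_rows_are_zero(self):
        res = reliability.mean_deviation(_matrix([[4, 4], [7, 7]]))
        assert res.overall == 0.0

    def test_matches_closed_form_for_gaussian_noise(self):
        # E|x_j - mean(x)| for x ~ N(0,1), k=10: sqrt(1 - 1/k) * sqrt(2/pi)
        expected = math.sqrt(1 - 1 / 10) * math.sqrt(2 / math.pi)
        vals = [
            reliability.mean_deviation(
                phantoms.simulate_sessions(
                    phantoms.VarianceComponentsSpec(30, 10, 0.0, 2.0, 1.0, seed)
                )
            ).overall
            for seed in range(200)
        ]
        assert float(np.mean(vals)) == pytest.approx(expected, rel=0.05)

    def test_pairwise_scheme(self):
        res = reliability.mean_deviation(_matrix([[0, 2], [0, 2]]), scheme="pairwise")
        np.testing.assert_allclose(res.per_subject, 2.0)


class TestCompareRegions:
    def test_complete_separation(self):
        res = reliability.compare_regions([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0.0
        assert res.p_value == pytest.approx(_exact_mw_p([1, 2, 3], [4, 5, 6]), abs=1e-12)

    def test_identical_groups(self):
        res = reliability.compare_regions([1, 2, 3], [1, 2, 3])
        assert res.z_value == 0.0
        assert res.p_value == 1.0

    def test_u_against_enumeration(self):
        a, b = [1, 2, 3, 4], [2, 3, 4, 5]
        res = reliability.compare_regions(a, b)
        # brute-force U: count of (a_i, b_j) pairs with a_i < b_j (+0.5 per tie)
        u_b = sum(1.0 * (x < y) + 0.5 * (x == y) for x in a for y in b)
        assert res.u_statistic == min(u_b, len(a) * len(b) - u_b)
        assert res.p_value == pytest.approx(_exact_mw_p(a, b), abs=1e-12)

    def test_exact_p_for_small_groups(self, rng):
        for _ in range(20):
            n_a, n_b = rng.integers(3, 9, 2)
            a = rng.integers(0, 10, n_a).tolist()
            b = rng.integers(0, 10, n_b).tolist()
            if len(set(a + b)) == 1:
                continue
            res = reliability.compare_regions(a, b)
            assert res.p_value == pytest.approx(_exact_mw_p(a, b), abs=0.01)

    def test_asymptotic_path_for_large_groups(self, rng):
        a = rng.normal(size=62)
        b = rng.normal(loc=1.0, size=62)
        res = reliability.compare_regions(a, b)
        from scipy.stats import mannwhitneyu

        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_all_tied_rejected(self):
        with pytest.raises(reliability.DegenerateDataError):
            reliability.compare_regions([1, 1], [1, 1, 1])


class TestExceedance:
    def test_pointwise_values(self):
        x, prop = reliability.exceedance_cdf([0.2, 0.6, 0.9], grid=[0.5])
        assert prop[0] == pytest.approx(2 / 3)

    def test_bounds(self):
        vals = [0.1, 0.4, 0.4, 0.8]
        _, at_min = reliability.exceedance_cdf(vals, grid=[min(vals)])
        _, above_max = reliability.exceedance_cdf(vals, grid=[max(vals) + 1e-9])
        assert at_min[0] == 1.0
        assert above_max[0] == 0.0

    @given(st.lists(st.floats(-1, 1), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_non_increasing(self, values):
        grid = np.linspace(-1.5, 1.5, 31)
        _, prop = reliability.exceedance_cdf(values, grid=grid)
        assert np.all(np.diff(prop) <= 1e-12)


class TestReliabilityReport:
    def test_high_reliability_simulation_is_mostly_excellent(self):
        """rho = 0.8 at n=30, k=10 should usually land in the excellent band."""
        excellent = 0
        for seed in range(100):
            m = phantoms.simulate_sessions(
                phantoms.VarianceComponentsSpec(30, 10, 2.5, 2.0, 1.0, seed=seed), "fd"
            )
            report = reliability.reliability_report([m])
            excellent += report.table.iloc[0]["category"] == "excellent"
        assert excellent > 60

    def test_duplicate_matrices_give_identical_rows(self):
        m = phantoms.simulate_sessions(phantoms.VarianceComponentsSpec(seed=1))
        report = reliability.reliability_report([m, m])
        a, b = report.table.iloc[0], report.table.iloc[1]
        assert (a.drop("metric") == b.drop("metric")).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            reliability.reliability_report([])

    def test_regional_comparisons(self, rng):
        regional = {
            "thickness": rng.uniform(0.4, 0.9, 62).tolist(),
            "gi": rng.uniform(0.7, 1.0, 62).tolist(),
        }
        m = phantoms.simulate_sessions(phantoms.VarianceComponentsSpec(seed=2))
        report = reliability.reliability_report([m], regional_iccs=regional)
        assert len(report.comparisons) == 1
        assert set(report.comparisons.columns) >= {"u", "z", "p"}
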