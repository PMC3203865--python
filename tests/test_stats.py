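"""Proportion estimates and the exact contingency-table test.

The exact-test oracle used here enumerates tables by brute force with
integer arithmetic (``math.comb``), sharing no code with the implementation.
"""

import itertools
import math

import numpy as np
import pytest

from vibracal.stats import (
    ContingencyTable,
    ResponseCounts,
    StatsError,
    cohort_report,
    compare_conditions,
    estimate_proportions,
    fisher_exact,
)


def oracle_two_row_pvalue(table):
    """Exact conditional p-value by integer-arithmetic enumeration (2 x c)."""
    table = np.asarray(table)
    assert table.shape[0] == 2
    col_m = table.sum(axis=0)
    r0 = int(table[0].sum())
    N = int(table.sum())
    denom = math.comb(N, r0)

    def numerator(first):
        return math.prod(math.comb(int(c), int(a)) for c, a in zip(col_m, first))

    obs = numerator(table[0])
    total = 0
    ranges = [range(int(c) + 1) for c in col_m]
    for first in itertools.product(*ranges):
        if sum(first) != r0:
            continue
        num = numerator(first)
        if num <= obs:  # exact integer comparison: no tie tolerance needed
            total += num
    return total / denom, obs / denom


def oracle_rxc_pvalue(table):
    """Exact conditional p-value for any r x c table, in exact rationals."""
    from fractions import Fraction

    table = np.asarray(table)
    row_m = [int(r) for r in table.sum(axis=1)]
    col_m = [int(c) for c in table.sum(axis=0)]
    N = int(table.sum())
    margin_num = math.prod(math.factorial(r) for r in row_m) * math.prod(
        math.factorial(c) for c in col_m
    )

    def prob(cells):
        den = math.factorial(N) * math.prod(math.factorial(x) for x in cells)
        return Fraction(margin_num, den)

    def compositions(total, caps):
        if len(caps) == 1:
            if total <= caps[0]:
                yield (total,)
            return
        for v in range(min(total, caps[0]) + 1):
            for rest in compositions(total - v, caps[1:]):
                yield (v, *rest)

    def tables(rows_left, caps):
        if not rows_left:
            if all(c == 0 for c in caps):
                yield ()
            return
        for first in compositions(rows_left[0], caps):
            rest_caps = [c - f for c, f in zip(caps, first)]
            for rest in tables(rows_left[1:], rest_caps):
                yield first + rest

    p_obs = prob(tuple(int(x) for x in table.ravel()))
    total = sum((p for t in tables(row_m, col_m) if (p := prob(t)) <= p_obs),
                start=Fraction(0))
    return float(total)


class TestProportions:
    def test_count_fractions(self):
        est = estimate_proportions(ResponseCounts(8, 2, 0))
        assert (est.p_g, est.p_l, est.p_n) == (0.8, 0.2, 0.0)

    def test_degenerate_condition_has_zero_sd(self):
        est = estimate_proportions(ResponseCounts(0, 0, 5))
        assert (est.p_g, est.p_l, est.p_n) == (0.0, 0.0, 1.0)
        assert (est.sd_g, est.sd_l, est.sd_n) == (0.0, 0.0, 0.0)

    def test_sd_matches_parametric_bootstrap(self):
        # sd_g for (8, 2, 0): binomial-form formula against the empirical SD
        # of p_hat over parametric resamples at the estimated probabilities
        est = estimate_proportions(ResponseCounts(8, 2, 0))
        rng = np.random.default_rng(0)
        draws = rng.binomial(10, 0.8, size=100_000) / 10.0
        assert est.sd_g == pytest.approx(0.1265, abs=5e-4)
        assert est.sd_g == pytest.approx(draws.std(), rel=0.02)

    def test_zero_total_rejected(self):
        with pytest.raises(StatsError):
            ResponseCounts(0, 0, 0)

    def test_estimator_recovers_generating_probabilities(self):
        rng = np.random.default_rng(7)
        p_hat = rng.multinomial(20, [0.8, 0.2, 0.0], size=1000)[:, 0] / 20.0
        sd = math.sqrt(0.8 * 0.2 / 20)
        assert abs(p_hat.mean() - 0.8) < 2 * sd


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[3, 1], [1, 3]], 0.4857142857142857),
            ([[5, 0], [0, 5]], 2 / 252),
        ],
    )
    def test_two_by_two_reference_values(self, table, expected):
        assert fisher_exact(np.array(table)) == pytest.approx(expected, abs=1e-10)

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            shape = (2, rng.integers(2, 4))
            t = rng.integers(0, 9, size=shape)
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            p_oracle, _ = oracle_two_row_pvalue(t)
            assert fisher_exact(t) == pytest.approx(p_oracle, abs=1e-10)

    def test_single_table_margins_give_p_one(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert fisher_exact(np.array([[2, 0], [3, 0]])) == 1.0
            assert fisher_exact(np.array([[0, 0], [2, 3]])) == 1.0

    def test_row_and_column_permutation_invariance(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            t = rng.integers(1, 9, size=(2, 3))
            p = fisher_exact(t)
            assert fisher_exact(t[::-1]) == pytest.approx(p, abs=1e-12)
            perm = rng.permutation(3)
            assert fisher_exact(t[:, perm]) == pytest.approx(p, abs=1e-12)

    def test_pvalue_in_unit_interval_and_includes_observed(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            t = rng.integers(0, 7, size=(2, 3))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            p = fisher_exact(t)
            _, p_obs = oracle_two_row_pvalue(t)
            assert 0.0 < p <= 1.0
            assert p >= p_obs - 1e-12

    def test_enumerated_probabilities_sum_to_one(self):
        from vibracal.stats import _two_row_class

        rng = np.random.default_rng(9)
        for _ in range(50):
            row = tuple(int(x) for x in rng.integers(1, 20, size=2))
            cols = rng.multinomial(sum(row), [1 / 3] * 3)
            if cols.min() == 0:
                continue
            _, csum = _two_row_class(row, tuple(int(c) for c in cols))
            assert csum[-1] == pytest.approx(1.0, abs=1e-10)

    def test_three_row_tables_use_general_enumeration(self):
        t = np.array([[3, 1, 0], [1, 2, 1], [0, 1, 4]])
        p = fisher_exact(t)
        assert p == pytest.approx(oracle_rxc_pvalue(t), abs=1e-10)
        # a 3 x 2 table transposes onto the 2-row fast path; both must agree
        t2 = np.array([[4, 1], [2, 3], [0, 4]])
        assert fisher_exact(t2) == pytest.approx(oracle_rxc_pvalue(t2), abs=1e-10)

    def test_negative_counts_rejected(self):
        with pytest.raises(StatsError):
            fisher_exact(np.array([[1, -1], [2, 3]]))


class TestCompareConditions:
    def test_identical_conditions_not_significant(self):
        c = ResponseCounts(8, 2, 0)
        res = compare_conditions(c, c)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)
        assert not res.significant

    def test_strong_treatment_effect_detected(self):
        res = compare_conditions(ResponseCounts(16, 4, 0), ResponseCounts(2, 4, 14))
        p_oracle, _ = oracle_two_row_pvalue([[16, 4, 0], [2, 4, 14]])
        assert res.p_value == pytest.approx(p_oracle, abs=1e-10)
        assert res.p_value < 0.001
        assert res.significant

    def test_zero_total_rejected(self):
        with pytest.raises(StatsError):
            compare_conditions(ResponseCounts(0, 0, 0), ResponseCounts(1, 1, 1))


class TestCohortReport:
    def test_single_condition_runs_no_tests(self):
        rep = cohort_report({"control": ["global"] * 10})
        assert rep.proportions["control"].p_g == 1.0
        assert rep.p_values == {}

    def test_identical_conditions_p_one(self):
        classes = ["global"] * 8 + ["local"] * 2
        rep = cohort_report({"control": classes, "drug": list(classes)})
        assert rep.p_values["drug"] == pytest.approx(1.0, abs=1e-9)

    def test_missing_control_rejected(self):
        with pytest.raises(StatsError, match="control"):
            cohort_report({"a": ["global"], "b": ["local"]})

    def test_unknown_class_rejected(self):
        with pytest.raises(StatsError, match="unknown"):
            cohort_report({"control": ["weird"]})

    def test_simulated_treatment_effect_power(self):
        # cohorts of 50 cells at (0.8, 0.2, 0) vs (0.1, 0.6, 0.3): the exact
        # test should flag essentially every replicate at alpha = 0.05
        rng = np.random.default_rng(123)
        hits = 0
        for _ in range(100):
            ctrl = rng.multinomial(50, [0.8, 0.2, 0.0])
            trt = rng.multinomial(50, [0.1, 0.6, 0.3])
            res = compare_conditions(ResponseCounts(*ctrl), ResponseCounts(*trt))
            hits += res.p_value < 0.05
        assert hits >= 99

    def test_report_frame_mirrors_bar_graph_content(self, tmp_path):
        rep = cohort_report(
            {"control": ["global"] * 8 + ["local"] * 2, "drug": ["none"] * 10}
        )
        df = rep.to_frame()
        assert set(df["condition"]) == {"control", "drug"}
        assert {"p_global", "sd_global", "p_value_vs_control"} <= set(df.columns)
        rep.to_csv(tmp_path / "rep.csv")
        rep.to_json(tmp_path / "rep.json")
        rep.plot(tmp_path / "rep.png")
        for name in ("rep.csv", "rep.json", "rep.png"):
            assert (tmp_path / name).stat().st_size > 0


def test_contingency_table_validation():
    with pytest.raises(StatsError):
        ContingencyTable(counts=np.array([1, 2, 3]))
    with pytest.raises(StatsError):
        ContingencyTable(counts=np.array([[1, -2], [0, 1]]))
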