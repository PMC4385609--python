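"""Contingency-test machinery: chi-squared, exact test, switching rule, selection."""

import itertools
from fractions import Fraction
from math import factorial

import numpy as np
import pytest
import scipy.stats

from cghkit.core import GroupLabels, Segment, SegmentMatrix
from cghkit.association import (
    AssociationResult,
    ContingencyTable2x3,
    DegenerateTableError,
    adjust_pvalues,
    chi2_test,
    contingency_2x3,
    expected_counts,
    fisher_exact_2x3,
    fisher_rule,
    select_segments,
)


def exact_p_oracle(table):
    """Independent Freeman-Halton enumeration in exact rational arithmetic.

    Enumerates every non-negative integer 2x3 table by brute force over the
    first row, keeping those with the observed margins, and sums the
    multivariate hypergeometric probabilities of tables no more probable
    than the observed one.  Deliberately written without sharing any code
    with the implementation under test.
    """
    obs = np.asarray(table, dtype=int)
    r = obs.sum(axis=1)
    c = obs.sum(axis=0)
    n = int(obs.sum())

    def prob(t):
        num = Fraction(
            factorial(r[0]) * factorial(r[1]) * factorial(c[0]) * factorial(c[1]) * factorial(c[2])
        )
        den = Fraction(factorial(n))
        for x in np.ravel(t):
            den *= factorial(int(x))
        return num / den

    p_obs = prob(obs)
    total = Fraction(0)
    p_value = Fraction(0)
    for a, b in itertools.product(range(c[0] + 1), range(c[1] + 1)):
        cc = r[0] - a - b
        if cc < 0 or cc > c[2]:
            continue
        t = np.array([[a, b, cc], [c[0] - a, c[1] - b, c[2] - cc]])
        if (t < 0).any():
            continue
        pt = prob(t)
        total += pt
        if pt <= p_obs:
            p_value += pt
    assert total == 1  # distribution over the margin-compatible support
    return float(p_value)


def random_table(rng, max_n=30):
    while True:
        cells = rng.integers(0, max_n // 2, size=6).reshape(2, 3)
        if 0 < cells.sum() <= max_n and cells.sum(axis=1).min() > 0:
            return ContingencyTable2x3(tuple(tuple(int(x) for x in row) for row in cells))


class TestContingency:
    def test_counting(self, labels_pq):
        row = np.array([1.0, 1.0, 0.0, -1.0])
        t = contingency_2x3(row, ["a", "b", "c", "d"], labels_pq, "P")
        assert t.counts == ((2, 0, 0), (0, 1, 1))

    def test_margins(self, labels_pq):
        row = np.array([1.0, 0.0, 0.0, -1.0])
        t = contingency_2x3(row, ["a", "b", "c", "d"], labels_pq, "P")
        assert t.row_totals.tolist() == [2, 2]
        assert t.col_totals.sum() == t.total == 4

    def test_missing_excluded_and_all_missing_errors(self, labels_pq):
        row = np.array([np.nan, 1.0, np.nan, 0.0])
        t = contingency_2x3(row, ["a", "b", "c", "d"], labels_pq, "P")
        assert t.total == 2
        with pytest.raises(DegenerateTableError):
            contingency_2x3(np.full(4, np.nan), ["a", "b", "c", "d"], labels_pq, "P")

    def test_target_must_be_proper_subset(self, labels_pq):
        row = np.zeros(4)
        with pytest.raises(ValueError):
            contingency_2x3(row, ["a", "b", "c", "d"], labels_pq, "R")


class TestExpectedAndRule:
    def test_uniform_table(self):
        t = ContingencyTable2x3(((5, 5, 5), (5, 5, 5)))
        assert np.allclose(expected_counts(t), 5)

    def test_hand_formula(self):
        t = ContingencyTable2x3(((8, 2, 0), (4, 6, 10)))
        e = expected_counts(t)
        # E_rc = row_r * col_c / n with rows (10, 20), cols (12, 8, 10), n = 30
        np.testing.assert_allclose(e[0], [4.0, 8 / 3, 10 / 3])
        np.testing.assert_allclose(e[1], [8.0, 16 / 3, 20 / 3])
        assert e.sum() == pytest.approx(t.total)

    def test_rule_thresholds(self):
        assert fisher_rule(ContingencyTable2x3(((10, 10, 10), (10, 10, 10)))) is False
        assert fisher_rule(ContingencyTable2x3(((1, 1, 1), (1, 1, 1)))) is True

    def test_rule_boundary_five_of_six(self):
        # rows (25, 15), columns (14, 14, 12): E = [[8.75, 8.75, 7.5],
        # [5.25, 5.25, 4.5]] -> exactly 5 of 6 cells > 5 -> chi2 ok
        five_of_six = ContingencyTable2x3(((9, 9, 7), (5, 5, 5)))
        e = expected_counts(five_of_six)
        assert int((e > 5).sum()) == 5
        assert fisher_rule(five_of_six) is False
        # equal rows, columns (24, 12, 4): E = observed, exactly 4 of 6 > 5
        four_of_six = ContingencyTable2x3(((12, 6, 2), (12, 6, 2)))
        e = expected_counts(four_of_six)
        assert int((e > 5).sum()) == 4
        assert fisher_rule(four_of_six) is True


class TestChi2:
    def test_identical_rows_null(self):
        stat, df, p = chi2_test(ContingencyTable2x3(((4, 4, 4), (4, 4, 4))))
        assert stat == 0 and df == 2 and p == 1

    def test_zero_column_collapses_df(self):
        stat, df, p = chi2_test(ContingencyTable2x3(((5, 0, 3), (2, 0, 6))))
        assert df == 1

    def test_single_column_undefined(self):
        with pytest.raises(DegenerateTableError):
            chi2_test(ContingencyTable2x3(((5, 0, 0), (2, 0, 0))))

    def test_hand_table_matches_textbook_formula(self):
        t = ContingencyTable2x3(((8, 2, 0), (4, 6, 10)))
        stat, df, p = chi2_test(t)
        obs = np.array(t.counts)
        e = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        expected_stat = ((obs - e) ** 2 / e).sum()
        assert stat == pytest.approx(expected_stat)
        assert p == pytest.approx(scipy.stats.chi2.sf(expected_stat, 2))

    def test_matches_scipy_contingency(self, rng):
        for _ in range(50):
            t = random_table(rng)
            if (t.col_totals == 0).any():
                continue
            stat, df, p = chi2_test(t)
            ref = scipy.stats.chi2_contingency(np.array(t.counts), correction=False)
            assert stat == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)


class TestFisherExact:
    def test_single_table_support_gives_p1(self):
        # an empty second row forces a unique table with the given margins
        t = ContingencyTable2x3(((2, 1, 0), (0, 0, 0)))
        assert fisher_exact_2x3(t) == 1.0

    def test_hand_table_matches_oracle(self):
        t = ContingencyTable2x3(((3, 1, 0), (0, 2, 3)))
        assert fisher_exact_2x3(t) == pytest.approx(exact_p_oracle(t.counts), abs=1e-12)

    def test_p_at_least_observed_probability(self, rng):
        for _ in range(20):
            t = random_table(rng)
            p = fisher_exact_2x3(t)
            assert 0 < p <= 1

    def test_matches_enumeration_oracle_randomly(self, rng):
        for _ in range(100):
            t = random_table(rng)
            assert fisher_exact_2x3(t) == pytest.approx(
                exact_p_oracle(t.counts), abs=1e-10
            )

    def test_cap_enforced(self):
        t = ContingencyTable2x3(((300, 300, 300), (300, 300, 300)))
        with pytest.raises(ValueError, match="chi2"):
            fisher_exact_2x3(t, cap=500)

    def test_agrees_with_chi2_for_large_balanced_tables(self):
        for t in [
            ContingencyTable2x3(((32, 40, 28), (28, 40, 32))),
            ContingencyTable2x3(((25, 30, 25), (24, 32, 24))),
            ContingencyTable2x3(((22, 36, 22), (26, 32, 22))),
        ]:
            assert (expected_counts(t) >= 20).all()
            _, _, p_chi = chi2_test(t)
            p_f = fisher_exact_2x3(t)
            assert abs(p_chi - p_f) < 0.02


class TestAdjust:
    def test_single_and_identity(self):
        assert adjust_pvalues([0.01], "bh") == [pytest.approx(0.01)]
        assert adjust_pvalues([0.5, 0.01], "none") == [0.5, 0.01]

    def test_bh_hand_oracle(self):
        adj = adjust_pvalues([0.01, 0.02, 0.04, 0.05], "bh")
        assert adj == pytest.approx([0.04, 0.04, 0.05, 0.05])

    def test_bh_bounds(self, rng):
        p = rng.random(25)
        adj = np.array(adjust_pvalues(list(p), "bh"))
        assert (adj >= p - 1e-12).all() and (adj <= 1).all()

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.1], "bonferroni")


def make_calls(values, samples):
    segs = [Segment("chr1", i, i + 1) for i in range(values.shape[0])]
    return SegmentMatrix(segs, samples, np.asarray(values, dtype=float))


class TestSelectSegments:
    def test_perfect_separation_selected(self):
        samples = [f"p{i}" for i in range(10)] + [f"q{i}" for i in range(10)]
        labels = GroupLabels({s: ("P" if s[0] == "p" else "Q") for s in samples})
        values = np.zeros((5, 20))
        values[2, :10] = 1.0  # region 2 gained in every P sample
        results = select_segments(make_calls(values, samples), labels, correction="none")
        hits = [r for r in results if r.selected and r.pathology == "P"]
        assert [r.region.start for r in hits] == [2]
        expected_p = exact_p_oracle([[10, 0, 0], [0, 10, 0]])
        assert hits[0].p_value == pytest.approx(expected_p)
        assert hits[0].test_used == "fisher"

    def test_all_zero_matrix_nothing_selected(self, labels_pq):
        values = np.zeros((4, 4))
        results = select_segments(make_calls(values, ["a", "b", "c", "d"]), labels_pq)
        assert all(not r.selected for r in results)
        # a constant column has a one-table support: p = 1 up to float error
        assert all(r.p_value == pytest.approx(1.0) for r in results)

    def test_sample_permutation_invariance(self, rng):
        samples = [f"s{i}" for i in range(12)]
        labels = GroupLabels({s: ("P" if i < 6 else "Q") for i, s in enumerate(samples)})
        values = rng.choice([-1.0, 0.0, 1.0], size=(8, 12))
        base = select_segments(make_calls(values, samples), labels)
        perm = rng.permutation(12)
        shuffled = select_segments(
            make_calls(values[:, perm], [samples[i] for i in perm]), labels
        )
        for r1, r2 in zip(base, shuffled):
            assert r1.region == r2.region and r1.pathology == r2.pathology
            assert r1.p_value == pytest.approx(r2.p_value)
            assert r1.selected == r2.selected

    def test_degenerate_region_gets_p1_and_none(self, labels_pq):
        values = np.full((1, 4), np.nan)
        results = select_segments(make_calls(values, ["a", "b", "c", "d"]), labels_pq)
        assert all(r.p_value == 1.0 and r.test_used == "none" and not r.selected for r in results)

    def test_alpha_validated(self, labels_pq):
        with pytest.raises(ValueError):
            select_segments(make_calls(np.zeros((1, 4)), ["a", "b", "c", "d"]), labels_pq, alpha=1.5)

    def test_one_vs_rest_over_three_groups(self, rng):
        samples = [f"s{i}" for i in range(15)]
        labels = GroupLabels(
            {s: ["X", "Y", "Z"][i // 5] for i, s in enumerate(samples)}
        )
        values = rng.choice([-1.0, 0.0, 1.0], size=(4, 15))
        results = select_segments(make_calls(values, samples), labels)
        assert {r.pathology for r in results} == {"X", "Y", "Z"}
        assert len(results) == 12
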