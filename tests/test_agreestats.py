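"""Agreement statistics: kappa, Bland-Altman, ICC, t-tests, summaries."""

import numpy as np
import pytest

from airway2d.agreestats import (bland_altman, cohen_kappa, column_summary,
                                 icc, paired_t, proportion_below,
                                 table4_statistics, table5_statistics,
                                 two_sample_t)
from airway2d.imgio import load_table5


@pytest.fixture(scope="module")
def heights():
    recs = load_table5()
    return (np.array([r.h_t for r in recs], float),
            np.array([r.h1 for r in recs], float),
            np.array([r.h2 for r in recs], float))


class TestKappa:
    def test_segment_contingency(self):
        res = cohen_kappa(np.array([[27, 0], [1, 12]]))
        assert res.po == pytest.approx(0.975)
        assert res.pe == pytest.approx(0.570)
        assert res.kappa == pytest.approx(0.9419, abs=1e-4)

    def test_perfect_agreement(self):
        assert cohen_kappa(np.diag([20, 20])).kappa == 1.0

    def test_chance_level(self):
        assert cohen_kappa(np.ones((2, 2))).kappa == pytest.approx(0.0)

    def test_degenerate_marginals_rejected(self):
        with pytest.raises(ValueError, match="kappa undefined"):
            cohen_kappa(np.array([[5, 0], [0, 0]]))

    def test_invariant_to_empty_category(self):
        base = np.array([[27, 0], [1, 12]])
        padded = np.zeros((3, 3), dtype=int)
        padded[:2, :2] = base
        assert cohen_kappa(padded).kappa == pytest.approx(
            cohen_kappa(base).kappa)

    def test_matches_sklearn_on_raw_ratings(self, rng):
        """Cross-check the table formula against sklearn computed from the
        equivalent per-subject rating vectors."""
        from sklearn.metrics import cohen_kappa_score
        a = rng.integers(0, 3, 60)
        b = np.where(rng.random(60) < 0.7, a, rng.integers(0, 3, 60))
        table = np.zeros((3, 3), dtype=int)
        for x, y in zip(a, b):
            table[x, y] += 1
        assert cohen_kappa(table).kappa == pytest.approx(
            cohen_kappa_score(a, b))


class TestBlandAltman:
    def test_identical_series(self):
        res = bland_altman([1, 2, 3, 4.0], [1, 2, 3, 4.0])
        assert res.mean_diff == 0 and res.coverage_pct == 100.0

    def test_fixture_coverage(self, heights):
        h_t, h1, h2 = heights
        assert bland_altman(h_t, h1).n_within == 38
        assert bland_altman(h_t, h2).n_within == 36

    def test_shift_invariance(self, rng):
        a, b = rng.normal(size=30), rng.normal(size=30)
        r0, r1 = bland_altman(a, b), bland_altman(a + 100, b + 100)
        assert r0.n_within == r1.n_within
        assert r0.sd_diff == pytest.approx(r1.sd_diff)

    def test_limits_bracket_mean(self, rng):
        res = bland_altman(rng.normal(size=20), rng.normal(size=20))
        assert res.lower_limit <= res.mean_diff <= res.upper_limit

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bland_altman([1, 2, 3], [1, 2])


def icc_2_1_oracle(m):
    """Explicit two-way absolute-agreement single-measure mean squares."""
    n, k = m.shape
    grand = m.mean()
    msr = k * ((m.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((m.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((m - m.mean(axis=1, keepdims=True)
            - m.mean(axis=0, keepdims=True) + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_duplicate_raters_give_one(self):
        col = np.array([1.0, 2, 3, 5, 8])
        assert icc(np.column_stack([col, col])) == pytest.approx(1.0)

    def test_matches_mean_squares_oracle(self):
        m = np.array([[9, 2], [45, 50], [21, 25], [30, 28], [12, 9]],
                     dtype=float)
        assert icc(m) == pytest.approx(icc_2_1_oracle(m), abs=1e-6)

    def test_independent_raters_near_zero(self, rng):
        m = rng.normal(size=(200, 2))
        assert abs(icc(m)) < 0.2

    def test_constant_ratings_rejected(self):
        with pytest.raises(ValueError):
            icc(np.ones((5, 2)))


class TestTTests:
    def test_paired_identical_is_zero(self):
        t, dof, p = paired_t([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert t == 0 and dof == 3

    def test_paired_matches_direct_formula(self):
        a = np.array([3.0, 5, 1, 7])
        b = np.array([2.0, 6, 2, 4])
        d = a - b
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        t, dof, _ = paired_t(a, b)
        assert t == pytest.approx(expected)

    def test_two_sample_matches_pooled_formula(self):
        a = np.array([1.0, 2, 3])
        b = np.array([2.0, 4, 6, 8])
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) \
            / (len(a) + len(b) - 2)
        expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a)
                                                          + 1 / len(b)))
        t, dof, _ = two_sample_t(a, b)
        assert t == pytest.approx(expected) and dof == 5

    def test_fixture_heights_not_significantly_different(self, heights):
        h_t, h1, h2 = heights
        assert paired_t(h_t, h1)[2] > 0.05
        assert paired_t(h_t, h2)[2] > 0.05


class TestSummaries:
    def test_proportion_strictly_below(self):
        count, pct = proportion_below([1.0, 2.9, 3.0, 3.1], 3.0)
        assert count == 2 and pct == 50.0

    def test_all_below(self):
        assert proportion_below([0.1, 0.2], 1)[1] == 100.0

    def test_column_summary_sample_sd(self):
        mean, sd = column_summary([2.0, 4, 4, 4, 5, 5, 7, 9])
        assert mean == 5.0
        assert sd == pytest.approx(np.std([2, 4, 4, 4, 5, 5, 7, 9], ddof=1))

    def test_constant_column(self):
        assert column_summary([3.0, 3, 3])[1] == 0.0


def test_table5_statistics_match_printed_summary_rows():
    """Every recomputed mean/SD matches the printed summary row at its
    printed (2-dp, half-up) precision."""
    from tests_oracles import matches_printed

    s = table5_statistics()
    assert matches_printed(s["mean_h_t"][0], 625.13)
    assert matches_printed(s["mean_h_t"][1], 50.24)
    assert matches_printed(s["mean_h1"][0], 625.73)
    assert matches_printed(s["mean_h2"][0], 622.58)
    assert matches_printed(s["l1_px"][0], 8.85)
    assert matches_printed(s["l2_px"][0], 11.50)
    assert matches_printed(s["l1_px"][1], 10.07)
    assert matches_printed(s["l2_px"][1], 10.08)
    assert matches_printed(s["l1_mm"][0], 1.95)
    assert matches_printed(s["l2_mm"][0], 2.53)
    assert matches_printed(s["l1_mm"][1], 2.21)
    assert s["l1_range_mm"][0] == 0.0
    assert matches_printed(s["l1_range_mm"][1], 12.31)
    assert matches_printed(s["l2_range_mm"][1], 9.89)


def test_table4_statistics():
    s = table4_statistics()
    assert s["ai_retropalatal"] == 27
    assert s["ai_retropalatal_pct"] == 67.5
    assert s["disagreements"] == 1
    assert s["kappa"].kappa == pytest.approx(0.9419, abs=1e-4)
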