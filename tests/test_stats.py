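"""Statistical layer: t-tests, within-subject ANOVA, Holm, IQR fences."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from swayquest.stats import (
    eta_squared,
    holm_correct,
    iqr_exclude,
    one_sample_t,
    paired_t,
    rm_anova_3x2,
)


class TestOneSampleT:
    def test_symmetric_values_give_zero_t(self):
        res = one_sample_t([-1.0, 1.0], 0.0, "two")
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_textbook_example(self):
        # mean 2, sd 1, n 3: t = 2 / (1/sqrt(3))
        res = one_sample_t([1.0, 2.0, 3.0], 0.0, "two")
        assert res.statistic == pytest.approx(2 * np.sqrt(3), rel=1e-9)
        assert res.df == 2

    def test_one_sided_p_halves_two_sided(self):
        x = [0.8, 1.4, 0.3, 1.1, 0.9]
        two = one_sample_t(x, 0.0, "two")
        greater = one_sample_t(x, 0.0, "greater")
        assert greater.p == pytest.approx(two.p / 2, rel=1e-9)
        less = one_sample_t(x, 0.0, "less")
        assert less.p == pytest.approx(1 - two.p / 2, rel=1e-9)

    def test_statistic_reported_as_absolute_value(self):
        res = one_sample_t([-3.0, -2.0, -1.0], 0.0, "two")
        assert res.statistic > 0

    def test_zero_variance_away_from_mu_raises(self):
        with pytest.raises(ZeroDivisionError):
            one_sample_t([2.0, 2.0, 2.0], 0.0)

    def test_missing_values_reduce_df(self):
        res = one_sample_t([1.0, 2.0, np.nan, 3.0, np.nan], 0.0)
        assert res.df == 2 and res.n == 3

    def test_eta_squared_is_total_ss_ratio(self):
        x = np.array([1.0, 2.0, 3.0])
        res = one_sample_t(x, 0.0, "two")
        expect = 3 * x.mean() ** 2 / np.sum(x**2)
        assert res.eta_squared == pytest.approx(expect, rel=1e-12)


class TestPairedT:
    def test_identical_vectors_give_null_result(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_constant_shift_is_degenerate(self):
        with pytest.raises(ZeroDivisionError):
            paired_t([1.0, 2.0, 3.0], [0.5, 1.5, 2.5])

    def test_ten_pairs_have_nine_df(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        assert paired_t(a, b).df == 9

    def test_pairs_with_missing_member_dropped(self, rng):
        a = np.array([1.0, np.nan, 2.0, 3.0, 1.5])
        b = np.array([0.5, 1.0, np.nan, 1.0, 0.5])
        assert paired_t(a, b).n == 3


def brute_force_rm_anova(cells):
    """Loop-based sums-of-squares decomposition (independent oracle)."""
    n, a, b = cells.shape
    grand = cells.mean()
    ss = dict(total=0.0, subj=0.0, A=0.0, B=0.0, AB=0.0, AS=0.0, BS=0.0)
    for s in range(n):
        ss["subj"] += a * b * (cells[s].mean() - grand) ** 2
        for i in range(a):
            for j in range(b):
                ss["total"] += (cells[s, i, j] - grand) ** 2
    for i in range(a):
        ss["A"] += b * n * (cells[:, i, :].mean() - grand) ** 2
    for j in range(b):
        ss["B"] += a * n * (cells[:, :, j].mean() - grand) ** 2
    for i in range(a):
        for j in range(b):
            ss["AB"] += n * (
                cells[:, i, j].mean() - cells[:, i, :].mean()
                - cells[:, :, j].mean() + grand
            ) ** 2
    for s in range(n):
        for i in range(a):
            ss["AS"] += b * (
                cells[s, i, :].mean() - cells[:, i, :].mean()
                - cells[s].mean() + grand
            ) ** 2
        for j in range(b):
            ss["BS"] += a * (
                cells[s, :, j].mean() - cells[:, :, j].mean()
                - cells[s].mean() + grand
            ) ** 2
    ss["ABS"] = ss["total"] - sum(ss[k] for k in ("subj", "A", "B", "AB", "AS", "BS"))
    F_A = (ss["A"] / (a - 1)) / (ss["AS"] / ((a - 1) * (n - 1)))
    F_B = (ss["B"] / (b - 1)) / (ss["BS"] / ((b - 1) * (n - 1)))
    F_AB = (ss["AB"] / ((a - 1) * (b - 1))) / (ss["ABS"] / ((a - 1) * (b - 1) * (n - 1)))
    return ss, F_A, F_B, F_AB


class TestRmAnova:
    def test_subject_offsets_only_give_zero_f(self, rng):
        # each subject constant over all six cells: no within-subject effects
        cells = np.repeat(rng.normal(size=(6, 1, 1)), 6).reshape(6, 3, 2)
        res = rm_anova_3x2(cells)
        for r in res.values():
            assert r.statistic == pytest.approx(0.0, abs=1e-18)

    def test_matches_brute_force_decomposition(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 7))
            cells = rng.normal(size=(n, 3, 2))
            res = rm_anova_3x2(cells)
            _, F_A, F_B, F_AB = brute_force_rm_anova(cells)
            assert res["time"].statistic == pytest.approx(F_A, rel=1e-8)
            assert res["uncertainty"].statistic == pytest.approx(F_B, rel=1e-8)
            assert res["interaction"].statistic == pytest.approx(F_AB, rel=1e-8)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        cells = rng.normal(size=(8, 3, 2))
        rows = []
        for s in range(8):
            for i, t in enumerate(("early", "late", "after")):
                for j, u in enumerate(("low", "high")):
                    rows.append(dict(subject=s, time=t, unc=u, y=cells[s, i, j]))
        table = pg.rm_anova(
            data=pd.DataFrame(rows), dv="y", within=["time", "unc"],
            subject="subject", detailed=True,
        ).set_index("Source")
        res = rm_anova_3x2(cells)
        assert res["time"].statistic == pytest.approx(table.loc["time", "F"], rel=1e-6)
        assert res["uncertainty"].statistic == pytest.approx(table.loc["unc", "F"], rel=1e-6)
        assert res["interaction"].statistic == pytest.approx(
            table.loc["time * unc", "F"], rel=1e-6
        )
        assert res["time"].p == pytest.approx(table.loc["time", "p_unc"], rel=1e-6)

    def test_df_bookkeeping(self, rng):
        res = rm_anova_3x2(rng.normal(size=(15, 3, 2)))
        assert res["time"].df == (2, 28)
        assert res["uncertainty"].df == (1, 14)
        assert res["interaction"].df == (2, 28)

    def test_incomplete_subjects_dropped_listwise(self, rng):
        cells = rng.normal(size=(6, 3, 2))
        cells[0, 1, 0] = np.nan
        res = rm_anova_3x2(cells)
        assert res["time"].n == 5

    def test_too_few_complete_subjects_rejected(self, rng):
        cells = rng.normal(size=(3, 3, 2))
        cells[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova_3x2(cells)

    def test_effect_eta_squared_partition(self, rng):
        res = rm_anova_3x2(rng.normal(size=(10, 3, 2)))
        etas = [r.eta_squared for r in res.values()]
        assert all(0 <= e <= 1 for e in etas)
        assert sum(etas) <= 1.0


class TestHolm:
    def test_hand_computed_adjustment(self):
        np.testing.assert_allclose(
            holm_correct([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06], atol=1e-12
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_correct([0.2]), [0.2])

    def test_ties_all_scaled_by_m(self):
        np.testing.assert_allclose(holm_correct([0.02] * 3), [0.06] * 3, atol=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_adjusted_at_least_raw_and_capped(self, ps):
        adj = holm_correct(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0)
        # monotone in the raw ordering
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_correct([0.5, 1.2])


class TestIqrExclude:
    def test_gross_outlier_excluded(self):
        values = [0.0] * 19 + [100.0]
        retain, log = iqr_exclude(values)
        assert not retain[19] and retain[:19].all()
        assert log["n_excluded"] == 1

    def test_all_equal_values_kept(self):
        retain, log = iqr_exclude([5.0] * 10)
        assert retain.all() and log["n_excluded"] == 0

    def test_value_exactly_at_fence_retained(self):
        # sorted [1,2,3,4,11]: Q1=2, Q3=4, upper fence 4 + 3.5*2 = 11
        retain, _ = iqr_exclude([1.0, 2.0, 3.0, 4.0, 11.0])
        assert retain.all()
        retain, _ = iqr_exclude([1.0, 2.0, 3.0, 4.0, 11.01])
        assert not retain[-1]

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            iqr_exclude([1.0, 2.0, 3.0])

    def test_nan_passed_through_unretained(self):
        retain, log = iqr_exclude([1.0, 2.0, np.nan, 3.0, 4.0])
        assert not retain[2] and log["n_excluded"] == 0


class TestEtaSquared:
    def test_bounds_and_degenerate(self):
        assert eta_squared(5.0, 5.0) == 1.0
        assert eta_squared(0.0, 5.0) == 0.0
        with pytest.raises(ZeroDivisionError):
            eta_squared(0.0, 0.0)
        with pytest.raises(ValueError):
            eta_squared(-1.0, 5.0)
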