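"""Statistical battery vs. independent textbook / brute-force oracles."""

import math

import numpy as np
import pytest
import scipy.stats as sps

from rhizochron import (
    TraitRecord,
    correlate_m,
    one_way_anova_tukey,
    two_way_anova,
    welch_t,
)
from rhizochron.stats import CORRELATED_TRAITS, compact_letter_display


def brute_force_two_way(y, a, b):
    """Oracle: balanced two-way ANOVA by direct cell-mean decomposition."""
    y = np.asarray(y, float)
    a = np.asarray(a)
    b = np.asarray(b)
    grand = y.mean()
    lev_a, lev_b = np.unique(a), np.unique(b)
    n_per_cell = len(y) / (len(lev_a) * len(lev_b))
    ss_a = sum((y[a == la].mean() - grand) ** 2 * (a == la).sum() for la in lev_a)
    ss_b = sum((y[b == lb].mean() - grand) ** 2 * (b == lb).sum() for lb in lev_b)
    ss_cells = sum(
        (y[(a == la) & (b == lb)].mean() - grand) ** 2 * n_per_cell
        for la in lev_a for lb in lev_b
    )
    ss_ab = ss_cells - ss_a - ss_b
    ss_e = sum(
        ((y[(a == la) & (b == lb)] - y[(a == la) & (b == lb)].mean()) ** 2).sum()
        for la in lev_a for lb in lev_b
    )
    df_a, df_b = len(lev_a) - 1, len(lev_b) - 1
    df_ab = df_a * df_b
    df_e = len(y) - len(lev_a) * len(lev_b)
    mse = ss_e / df_e
    out = {}
    for name, ss, df in (("A", ss_a, df_a), ("B", ss_b, df_b), ("A:B", ss_ab, df_ab)):
        f = (ss / df) / mse
        out[name] = (ss, df, f, sps.f.sf(f, df, df_e))
    return out


class TestTwoWayAnova:
    def test_all_equal_values_give_null_result(self):
        y = [3.0] * 12
        a = ["g1", "g2"] * 6
        b = ["x"] * 6 + ["y"] * 6
        table = two_way_anova(y, a, b)
        for term in ("A", "B", "A:B"):
            assert table[term].F == 0.0
            assert table[term].p == 1.0

    def test_balanced_2x2_matches_brute_force_decomposition(self):
        rng = np.random.default_rng(123)
        a = np.repeat(["a1", "a2"], 6)
        b = np.tile(np.repeat(["b1", "b2"], 3), 2)
        y = rng.normal(0, 1, 12) + (a == "a2") * 1.5 + (b == "b2") * 0.5
        table = two_way_anova(y, a, b)
        oracle = brute_force_two_way(y, a, b)
        for term in ("A", "B", "A:B"):
            ss, df, f, p = oracle[term]
            assert table[term].sum_sq == pytest.approx(ss, rel=1e-8)
            assert table[term].df == df
            assert table[term].F == pytest.approx(f, rel=1e-8)
            assert table[term].p == pytest.approx(p, rel=1e-8)
        assert sum(t.df for t in table.terms) == len(y) - 1

    def test_balanced_15x3_matches_brute_force(self):
        rng = np.random.default_rng(7)
        a = np.repeat([f"acc{i}" for i in range(15)], 9)
        b = np.tile(np.repeat(["d8", "d10", "d12"], 3), 15)
        y = rng.normal(0, 1, a.size) + rng.normal(0, 0.3, 15)[
            np.repeat(np.arange(15), 9)]
        table = two_way_anova(y, a, b)
        oracle = brute_force_two_way(y, a, b)
        for term in ("A", "B", "A:B"):
            assert table[term].F == pytest.approx(oracle[term][2], rel=1e-8)
            assert table[term].p == pytest.approx(oracle[term][3], rel=1e-8)

    def test_empty_cell_raises_naming_the_cell(self):
        y = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        a = ["a1", "a1", "a1", "a2", "a2", "a2"]
        b = ["b1", "b2", "b1", "b1", "b1", "b1"]  # cell (a2, b2) empty
        with pytest.raises(ValueError, match=r"a2.*b2|b2.*a2"):
            two_way_anova(y, a, b)

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValueError, match="two levels"):
            two_way_anova([1, 2, 3, 4], ["a"] * 4, ["x", "x", "y", "y"])


class TestOneWayTukey:
    def test_identical_groups_share_one_letter(self):
        y = [2.0] * 9
        g = ["a", "b", "c"] * 3
        _, groups = one_way_anova_tukey(y, g)
        assert set(groups.letters.values()) == {"a"}
        assert all(p.p_adj == 1.0 for p in groups.pairs)

    def test_two_group_tukey_equals_pooled_t(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n1, n2 = rng.integers(3, 12, 2)
            x = rng.normal(0, 1, n1)
            y = rng.normal(0.8, 1, n2)
            _, groups = one_way_anova_tukey(
                np.concatenate([x, y]), ["x"] * n1 + ["y"] * n2
            )
            _, p_pooled = sps.ttest_ind(x, y, equal_var=True)
            assert groups.pairs[0].p_adj == pytest.approx(p_pooled, abs=1e-8)

    def test_adjusted_p_matches_scipy_tukey_hsd(self):
        rng = np.random.default_rng(31)
        samples = [rng.normal(mu, 1.0, n) for mu, n in ((0, 8), (0.5, 5), (1.5, 11), (0.2, 7))]
        y = np.concatenate(samples)
        g = sum(([f"g{i}"] * len(s) for i, s in enumerate(samples)), [])
        _, groups = one_way_anova_tukey(y, g)
        ref = sps.tukey_hsd(*samples)
        for pair in groups.pairs:
            i, j = int(pair.level_a[1]), int(pair.level_b[1])
            assert pair.p_adj == pytest.approx(ref.pvalue[i, j], abs=1e-8)

    def test_anova_f_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(8)
        samples = [rng.normal(m, 1, 6) for m in (0, 0.3, 1.0)]
        y = np.concatenate(samples)
        g = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        anova, _ = one_way_anova_tukey(y, g)
        f_ref, p_ref = sps.f_oneway(*samples)
        assert anova["factor"].F == pytest.approx(f_ref, rel=1e-10)
        assert anova["factor"].p == pytest.approx(p_ref, rel=1e-10)

    def test_singleton_level_raises_naming_it(self):
        with pytest.raises(ValueError, match="lonely"):
            one_way_anova_tukey([1.0, 2.0, 3.0], ["a", "a", "lonely"])

    def test_well_separated_means_get_distinct_letters(self):
        rng = np.random.default_rng(2)
        y = np.concatenate([rng.normal(m, 0.05, 10) for m in (0.0, 1.0, 2.0)])
        g = ["lo"] * 10 + ["mid"] * 10 + ["hi"] * 10
        _, groups = one_way_anova_tukey(y, g)
        assert groups.letters["lo"] == "a"
        assert groups.letters["mid"] == "b"
        assert groups.letters["hi"] == "c"

    def test_letter_invariant_on_random_unbalanced_panels(self):
        rng = np.random.default_rng(404)
        for _ in range(50):
            k = int(rng.integers(2, 7))
            sizes = rng.integers(2, 9, k)
            mus = rng.normal(0, 1, k)
            y = np.concatenate([rng.normal(mus[i], 0.5, sizes[i]) for i in range(k)])
            g = sum(([f"g{i}"] * sizes[i] for i in range(k)), [])
            _, groups = one_way_anova_tukey(y, g, alpha=0.05)
            for pair in groups.pairs:
                shares = bool(set(groups.letters[pair.level_a]) & set(groups.letters[pair.level_b]))
                assert shares == (pair.p_adj >= 0.05)
            assert all(groups.letters[lv] for lv in groups.letters)


class TestCompactLetterDisplay:
    def test_chain_structure_yields_overlapping_letters(self):
        # a < b < c with only a-c significant: b bridges both groups
        means = {"a": 0.0, "b": 1.0, "c": 2.0}
        letters = compact_letter_display(["a", "b", "c"], means, {frozenset({"a", "c"})})
        assert set(letters["b"]) >= {"a"} or set(letters["b"]) >= {"b"}
        assert not set(letters["a"]) & set(letters["c"])
        assert set(letters["a"]) & set(letters["b"])
        assert set(letters["b"]) & set(letters["c"])


class TestWelchT:
    def test_identical_samples(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_equal_n_equal_variance_gives_pooled_df(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2.5, 3.5, 4.5, 5.5]  # same spread, shifted
        _, df, _ = welch_t(x, y)
        assert df == pytest.approx(2 * 4 - 2)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(55)
        for _ in range(30):
            x = rng.normal(0, 1.0, int(rng.integers(3, 20)))
            y = rng.normal(0.5, 2.0, int(rng.integers(3, 20)))
            t, df, p = welch_t(x, y)
            vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
            t_ref = (x.mean() - y.mean()) / math.sqrt(vx + vy)
            df_ref = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
            p_ref = 2 * sps.t.sf(abs(t_ref), df_ref)
            assert t == pytest.approx(t_ref, rel=1e-10)
            assert df == pytest.approx(df_ref, rel=1e-10)
            assert p == pytest.approx(p_ref, rel=1e-10)

    def test_zero_variance_conventions(self):
        assert welch_t([2.0, 2.0], [2.0, 2.0])[2] == 1.0
        assert welch_t([2.0, 2.0], [3.0, 3.0])[2] == 0.0

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


def _records_from_arrays(m, **trait_arrays):
    records = []
    for i in range(len(m)):
        rec = TraitRecord(plant_id=f"p{i}", day=8, m=float(m[i]), b=0.0, r2=0.5)
        for name, arr in trait_arrays.items():
            setattr(rec, name, float(arr[i]))
        records.append(rec)
    return records


class TestCorrelateM:
    def test_self_correlation_is_perfect(self):
        rng = np.random.default_rng(3)
        m = rng.normal(-0.2, 0.1, 30)
        records = _records_from_arrays(m, TLRL=m)  # TLRL duplicates m
        rows = {r.trait: r for r in correlate_m(records)}
        assert rows["TLRL"].r2 == pytest.approx(1.0)
        assert rows["TLRL"].p < 1e-20

    def test_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(12)
        m = rng.normal(-0.2, 0.1, 40)
        trl = 2 * m + rng.normal(0, 0.1, 40)
        records = _records_from_arrays(m, TRL=trl)
        row = {r.trait: r for r in correlate_m(records)}["TRL"]
        r_ref, p_ref = sps.pearsonr(m, trl)
        assert row.r2 == pytest.approx(r_ref**2, rel=1e-12)
        assert row.p == pytest.approx(p_ref, rel=1e-12)
        assert row.n == 40

    def test_constructed_trait_outranks_independent_noise(self):
        rng = np.random.default_rng(9)
        m = rng.normal(-0.2, 0.1, 300)
        records = _records_from_arrays(
            m, TLRL=m * 5 + rng.normal(0, 0.2, 300), RD=rng.normal(0.5, 0.1, 300)
        )
        rows = {r.trait: r for r in correlate_m(records)}
        assert rows["TLRL"].r2 > rows["RD"].r2

    def test_day_filter_restricts_records(self):
        rng = np.random.default_rng(4)
        records = _records_from_arrays(rng.normal(0, 1, 10), TRL=rng.normal(0, 1, 10))
        for i, rec in enumerate(records):
            rec.day = 8 if i < 5 else 12
        rows = {r.trait: r for r in correlate_m(records, day_filter=8)}
        assert rows["TRL"].n == 5

    def test_trait_with_too_few_pairs_is_reported_missing(self):
        records = _records_from_arrays(np.array([0.1, 0.2, 0.3, 0.4]), TRL=np.ones(4))
        for rec in records:
            rec.RD = None
        rows = {r.trait: r for r in correlate_m(records)}
        assert rows["RD"].p is None and rows["RD"].r2 is None

    def test_discarded_records_are_excluded(self):
        records = _records_from_arrays(np.arange(6, dtype=float), TRL=np.arange(6, dtype=float))
        records[0].discarded = True
        records[0].m = None
        rows = {r.trait: r for r in correlate_m(records)}
        assert rows["TRL"].n == 5

    def test_reports_every_conventional_trait(self):
        records = _records_from_arrays(np.array([0.1, -0.2, 0.05, -0.3]))
        rows = correlate_m(records)
        assert tuple(r.trait for r in rows) == CORRELATED_TRAITS
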