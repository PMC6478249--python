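import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pitkit.stats import bonferroni, gg_epsilon, paired_t, rm_anova


def random_within_design(rng, n_subj, levels, effect=0.0):
    """Long-format balanced within-subject data with optional first-factor effect."""
    names = ["A", "B", "D"][: len(levels)]
    rows = []
    for s in range(n_subj):
        subj_eff = rng.normal(0, 1)
        for combo in itertools.product(*(range(l) for l in levels)):
            y = rng.normal(subj_eff + effect * combo[0], 1)
            rows.append((s, *[f"{n}{c}" for n, c in zip(names, combo)], y))
    return pd.DataFrame(rows, columns=["subject", *names, "y"]), names


def brute_force_rm_anova(df, names):
    """Independent sums-of-squares oracle: explicit textbook mean formulas,
    computed with nested Python loops over cells and subjects."""
    levels = [sorted(df[n].unique()) for n in names]
    subjects = sorted(df["subject"].unique())
    cell = {}
    for _, row in df.iterrows():
        cell[(row["subject"], *[row[n] for n in names])] = row["y"]
    grand = np.mean(list(cell.values()))

    def mean_of(subset_levels, subj=None):
        vals = [v for k, v in cell.items()
                if (subj is None or k[0] == subj)
                and all(k[1 + i] == lv for i, lv in subset_levels)]
        return np.mean(vals)

    results = {}
    for r in range(1, len(names) + 1):
        for axes in itertools.combinations(range(len(names)), r):
            ss_eff = 0.0
            n_per_cell = len(subjects) * int(np.prod(
                [len(levels[i]) for i in range(len(names)) if i not in axes]))
            for combo in itertools.product(*(levels[i] for i in axes)):
                dev = 0.0
                for k in range(len(axes) + 1):
                    for sub in itertools.combinations(range(len(axes)), k):
                        sign = (-1) ** (len(axes) - k)
                        sel = [(axes[i], combo[i]) for i in sub]
                        dev += sign * (mean_of(sel) if sel else grand)
                ss_eff += n_per_cell * dev ** 2
            # subject x effect interaction by full-cross residuals
            ss_err = 0.0
            mult = int(np.prod([len(levels[i]) for i in range(len(names))
                                if i not in axes]))
            for s in subjects:
                for combo in itertools.product(*(levels[i] for i in axes)):
                    dev = 0.0
                    items = list(range(len(axes)))
                    for k in range(len(axes) + 1):
                        for sub in itertools.combinations(items, k):
                            sel = [(axes[i], combo[i]) for i in sub]
                            # subject in / out of the marginal mean
                            sign = (-1) ** (len(axes) - k)
                            dev += sign * (mean_of(sel, subj=s) - mean_of(sel))
                    ss_err += mult * dev ** 2
            df_num = int(np.prod([len(levels[i]) - 1 for i in axes]))
            df_den = (len(subjects) - 1) * df_num
            name = ":".join(names[i] for i in axes)
            F = (ss_eff / df_num) / (ss_err / df_den)
            results[name] = (F, ss_eff, ss_err, df_num, df_den)
    return results


class TestRmAnova:
    @pytest.mark.parametrize("levels", [(2, 2), (2, 3), (2, 2, 2), (2, 3, 2)])
    def test_matches_brute_force_oracle(self, levels):
        rng = np.random.default_rng(hash(levels) % 2**31)
        df, names = random_within_design(rng, 5, levels, effect=0.4)
        got = {e.effect: e for e in rm_anova(df, "y", names)}
        expected = brute_force_rm_anova(df, names)
        assert set(got) == set(expected)
        for name, (F, ss_eff, ss_err, df_num, df_den) in expected.items():
            assert got[name].F == pytest.approx(F, abs=1e-10, rel=1e-10)
            assert got[name].ss_effect == pytest.approx(ss_eff, abs=1e-10)
            assert got[name].ss_error == pytest.approx(ss_err, abs=1e-10)
            assert (got[name].df_num, got[name].df_den) == (df_num, df_den)

    def test_matches_statsmodels(self):
        from statsmodels.stats.anova import AnovaRM
        rng = np.random.default_rng(11)
        df, names = random_within_design(rng, 7, (2, 3, 2), effect=0.3)
        got = {e.effect: e for e in rm_anova(df, "y", names)}
        table = AnovaRM(df, "y", "subject", within=names).fit().anova_table
        for name, row in table.iterrows():
            assert got[name].F == pytest.approx(row["F Value"], rel=1e-8)
            assert got[name].df_num == row["Num DF"]
            assert got[name].df_den == row["Den DF"]

    def test_main_effect_f_equals_squared_paired_t(self):
        rng = np.random.default_rng(3)
        df, names = random_within_design(rng, 9, (2, 2), effect=0.5)
        got = {e.effect: e for e in rm_anova(df, "y", names)}
        for factor in names:
            wide = df.groupby(["subject", factor])["y"].mean().unstack()
            t = paired_t(wide.iloc[:, 1], wide.iloc[:, 0]).t
            assert got[factor].F == pytest.approx(t ** 2, abs=1e-8)

    def test_flat_factor_gives_zero_f(self):
        rng = np.random.default_rng(4)
        df, names = random_within_design(rng, 6, (2, 2))
        # equalize the marginal cell means across A's levels while keeping
        # subject-level scatter (the error term stays positive)
        df["y"] = df["y"] - df.groupby("A")["y"].transform("mean")
        e = {x.effect: x for x in rm_anova(df, "y", ["A", "B"])}
        assert e["A"].F == pytest.approx(0.0, abs=1e-20)
        assert e["A"].ss_error > 0

    def test_two_level_factors_force_epsilon_one(self):
        rng = np.random.default_rng(5)
        df, names = random_within_design(rng, 6, (2, 2, 2))
        for e in rm_anova(df, "y", names):
            assert e.gg_epsilon == 1.0

    def test_ges_bounds_and_additivity(self):
        rng = np.random.default_rng(6)
        df, names = random_within_design(rng, 8, (2, 3), effect=0.8)
        effects = rm_anova(df, "y", names)
        assert all(0.0 <= e.ges <= 1.0 for e in effects)
        assert sum(e.ges for e in effects) <= 1.0

    def test_ges_and_epsilon_match_pingouin(self):
        import pingouin as pg
        rng = np.random.default_rng(12)
        rows = [(s, f"a{a}", rng.normal(0.3 * a, 1 + 0.2 * a))
                for s in range(10) for a in range(4)]
        df = pd.DataFrame(rows, columns=["subject", "A", "y"])
        mine = rm_anova(df, "y", ["A"])[0]
        ref = pg.rm_anova(data=df, dv="y", within="A", subject="subject",
                          detailed=True, effsize="ng2").iloc[0]
        assert mine.F == pytest.approx(ref["F"], rel=1e-8)
        assert mine.ges == pytest.approx(ref["ng2"], rel=1e-8)
        assert mine.gg_epsilon == pytest.approx(ref["eps"], rel=1e-6)

    def test_duplicate_rows_rejected(self):
        df = pd.DataFrame({"subject": [0, 0, 0], "A": ["a", "a", "b"],
                           "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            rm_anova(df, "y", ["A"])


class TestGgEpsilon:
    def test_compound_symmetry_gives_one(self):
        k = 4
        cov = np.full((k, k), 0.3) + np.eye(k) * 0.7
        assert gg_epsilon(cov) == pytest.approx(1.0)

    def test_two_levels_give_one(self):
        assert gg_epsilon(np.array([[1.0, 0.1], [0.1, 2.0]])) == 1.0

    def test_fixed_matrix_matches_eigenvalue_oracle(self):
        cov = np.array([[2.0, 0.5, 0.1], [0.5, 1.0, 0.3], [0.1, 0.3, 3.0]])
        k = 3
        C = np.eye(k) - np.full((k, k), 1 / k)
        lam = np.linalg.eigvalsh(C @ cov @ C)
        oracle = lam.sum() ** 2 / ((k - 1) * (lam ** 2).sum())
        assert gg_epsilon(cov) == pytest.approx(oracle, rel=1e-12)

    def test_bounds(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            a = rng.normal(size=(6, 4))
            cov = a.T @ a
            eps = gg_epsilon(cov)
            assert 1 / 3 <= eps <= 1.0

    def test_bad_input_rejected(self):
        with pytest.raises(ValueError):
            gg_epsilon(np.ones((2, 3)))
        with pytest.raises(ValueError):
            gg_epsilon(np.array([[1.0, 0.5], [0.2, 1.0]]))


class TestPairedT:
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=40),
           st.integers(0, 2**31 - 1))
    def test_d_equals_t_over_sqrt_n(self, base, seed):
        rng = np.random.default_rng(seed)
        x = np.asarray(base) + rng.normal(0, 1, len(base))
        y = rng.normal(0, 1, len(base))
        if np.std(x - y, ddof=1) == 0:
            return
        res = paired_t(x, y)
        assert res.cohens_d == pytest.approx(res.t / math.sqrt(res.n_pairs))

    def test_one_sided_halves_p_for_positive_t(self):
        x = np.array([1.0, 2.0, 3.0, 4.5])
        y = np.array([0.5, 1.0, 2.0, 3.0])
        two = paired_t(x, y, sided="two")
        one = paired_t(x, y, sided="one")
        assert one.p == pytest.approx(two.p / 2)
        assert one.df == len(x) - 1

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0], [0.0, 1.0])  # zero-variance differences
        with pytest.raises(ValueError):
            paired_t([1.0], [0.0])


class TestBonferroni:
    def test_scales_and_caps(self):
        assert bonferroni([0.017], m=2) == [0.034]
        assert bonferroni([0.6], m=2) == [1.0]
        assert bonferroni([0.03, 0.2]) == [0.06, 0.4]
        assert bonferroni([0.03], m=1) == [0.03]

    def test_m_too_small_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.01, 0.02, 0.03], m=2)
        with pytest.raises(ValueError):
            bonferroni([1.5])
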