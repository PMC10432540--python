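import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tactovoc import (
    SummaryStats,
    holm_correction,
    mauchly_sphericity,
    paired_t,
    paired_t_from_summary,
    percent_correct,
    rm_anova,
    spearman,
)


class TestPercentCorrect:
    def _trials(self, corrects, **cols):
        base = dict(condition="8FB8T")
        base.update(cols)
        return pd.DataFrame([{**base, "correct": c} for c in corrects])

    def test_all_correct_is_100(self):
        out = percent_correct(self._trials([True] * 8))
        assert out["percent_correct"].iloc[0] == 100.0

    def test_one_of_four(self):
        out = percent_correct(self._trials([True, False, False, False]))
        assert out["percent_correct"].iloc[0] == 25.0

    def test_random_responses_near_chance(self, rng):
        trials = self._trials(rng.integers(3, size=20000) == 0)
        out = percent_correct(trials)
        assert out["percent_correct"].iloc[0] == pytest.approx(33.3, abs=1.5)

    def test_grouped_by_condition_and_talker(self):
        df = pd.concat(
            [
                self._trials([True, True], condition="A", talker="male"),
                self._trials([False, True], condition="A", talker="female"),
            ]
        )
        out = percent_correct(df, by=("condition", "talker"))
        assert len(out) == 2
        assert set(out["percent_correct"]) == {100.0, 50.0}

    def test_missing_responses_rejected(self):
        df = self._trials([True, None])
        with pytest.raises(ValueError):
            percent_correct(df)
        with pytest.raises(ValueError):
            percent_correct(df.iloc[:0])


class TestPairedTFromSummary:
    # printed-results worked examples: t = mean / (sd / sqrt(n)), n = 26
    @pytest.mark.parametrize(
        "mean,sd,expected_t",
        [(5.9, 5.0, 6.0), (8.4, 3.0, 14.3), (2.5, 5.7, 2.2)],
    )
    def test_primary_comparison_t_values(self, mean, sd, expected_t):
        res = paired_t_from_summary(SummaryStats(mean, sd, 26))
        assert round(res.t, 1) == expected_t
        assert res.df == 25

    def test_zero_mean_gives_t_zero_p_one(self):
        res = paired_t_from_summary(SummaryStats(0.0, 3.0, 10))
        assert res.t == 0.0 and res.p_two_tailed == 1.0

    def test_zero_sd_flags_infinite_t(self):
        res = paired_t_from_summary(SummaryStats(2.0, 0.0, 10))
        assert np.isinf(res.t) and res.p_two_tailed == 0.0

    def test_agrees_with_raw_data_paired_t(self, rng):
        x = rng.normal(50, 5, 26)
        y = rng.normal(45, 5, 26)
        d = x - y
        summary = SummaryStats(float(np.mean(d)), float(np.std(d, ddof=1)), 26)
        assert paired_t_from_summary(summary).t == pytest.approx(paired_t(x, y).t, abs=1e-9)

    def test_invalid_summary_rejected(self):
        with pytest.raises(ValueError):
            SummaryStats(1.0, -1.0, 26)
        with pytest.raises(ValueError):
            SummaryStats(1.0, 1.0, 1)


class TestHolmCorrection:
    def test_single_p_unchanged(self):
        assert holm_correction([0.04], m=1)[0] == pytest.approx(0.04)

    def test_hand_worked_step_down(self):
        out = holm_correction([0.01, 0.02, 0.04], m=3)
        assert np.allclose(out, [0.03, 0.04, 0.04])

    def test_all_ones_stay_one(self):
        assert np.all(holm_correction([1.0, 1.0, 1.0]) == 1.0)

    def test_family_larger_than_supplied(self):
        # the 51-test family applied to three primary p-values
        out = holm_correction([0.001, 0.01, 0.04], m=51)
        assert np.allclose(out, [0.051, 0.5, 1.0])

    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=8)
    )
    def test_monotone_and_bounded(self, pvals):
        out = holm_correction(pvals)
        p = np.asarray(pvals)
        assert np.all(out >= p - 1e-15)  # never below raw
        assert np.all(out <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(out[order]) >= -1e-15)  # monotone in rank
        # never below Bonferroni divided by the rank factor
        bonf = np.minimum(p * p.size, 1.0)
        assert np.all(out <= bonf + 1e-12)

    def test_agrees_with_statsmodels_when_family_matches(self):
        from statsmodels.stats.multitest import multipletests

        pvals = [0.003, 0.04, 0.2, 0.011]
        ours = holm_correction(pvals)
        theirs = multipletests(pvals, method="holm")[1]
        assert np.allclose(ours, theirs)

    def test_nan_pvalues_propagate_without_breaking_family(self):
        out = holm_correction([0.01, np.nan, 0.04], m=3)
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2]], [0.03, 0.08])

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            holm_correction([0.0])
        with pytest.raises(ValueError):
            holm_correction([0.1, 0.2], m=1)


def _long_table(values, subjects, factors):
    """values indexed [subject, level_a, level_b, ...] -> long DataFrame."""
    rows = []
    shape = values.shape
    for idx in itertools.product(*(range(s) for s in shape)):
        row = {"subject": subjects[idx[0]], "score": values[idx]}
        for name, lev in zip(factors, idx[1:]):
            row[name] = f"{name}{lev}"
        rows.append(row)
    return pd.DataFrame(rows)


def _brute_force_within_ss(values):
    """Independent SS decomposition for a (subject x A x B) table.

    Inclusion-exclusion over marginal means; returns dict of
    effect -> (ss_effect, ss_error, df_effect, df_error).
    """
    n, a, b = values.shape
    grand = values.mean()
    m_s = values.mean(axis=(1, 2))
    m_a = values.mean(axis=(0, 2))
    m_b = values.mean(axis=(0, 1))
    m_sa = values.mean(axis=2)
    m_sb = values.mean(axis=1)
    m_ab = values.mean(axis=0)
    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_sa = b * np.sum(
        (m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2
    )
    ss_sb = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_ab = n * np.sum(
        (m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2
    )
    resid = (
        values
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - grand
    )
    ss_sab = np.sum(resid**2)
    return {
        "A": (ss_a, ss_sa, a - 1, (a - 1) * (n - 1)),
        "B": (ss_b, ss_sb, b - 1, (b - 1) * (n - 1)),
        "A x B": (ss_ab, ss_sab, (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1)),
    }


class TestRmAnova:
    def test_no_condition_differences_gives_f_near_zero(self):
        rng = np.random.default_rng(1)
        values = rng.normal(50, 3, size=(10, 4))
        # remove every between-condition difference, keep subject variation
        values = values - values.mean(axis=0, keepdims=True) + values.mean()
        df = _long_table(values, list(range(10)), ["cond"])
        out = rm_anova(df, "score", "subject", ["cond"])
        assert out["F"].iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_two_level_factor_f_equals_t_squared(self, rng):
        x = rng.normal(50, 5, 12)
        y = x + rng.normal(2, 3, 12)
        df = pd.DataFrame(
            {
                "subject": list(range(12)) * 2,
                "cond": ["a"] * 12 + ["b"] * 12,
                "score": np.concatenate([x, y]),
            }
        )
        f = rm_anova(df, "score", "subject", ["cond"])["F"].iloc[0]
        t = paired_t(x, y).t
        assert f == pytest.approx(t**2, rel=1e-6)

    def test_matches_brute_force_two_way_decomposition(self):
        # 4-subject toy table, 2x3 within design
        rng = np.random.default_rng(3)
        values = rng.normal(50, 5, size=(4, 2, 3))
        df = _long_table(values, list(range(4)), ["A", "B"])
        out = rm_anova(df, "score", "subject", ["A", "B"]).set_index("effect")
        oracle = _brute_force_within_ss(values)
        for effect, (ss_e, ss_err, df_e, df_err) in oracle.items():
            f_oracle = (ss_e / df_e) / (ss_err / df_err)
            assert out.loc[effect, "F"] == pytest.approx(f_oracle, rel=1e-6)
            assert out.loc[effect, "df_num"] == df_e
            assert out.loc[effect, "df_den"] == df_err

    def test_three_way_runs_and_detects_planted_effect(self):
        rng = np.random.default_rng(4)
        n = 12
        values = np.zeros((n, 3, 2, 2))
        values += rng.normal(0, 3, (n, 1, 1, 1))  # subject offsets
        values += np.array([0.0, 4.0, 8.0])[None, :, None, None]  # factor A effect
        values += rng.normal(0, 2, values.shape)
        df = _long_table(values, list(range(n)), ["A", "B", "C"])
        out = rm_anova(df, "score", "subject", ["A", "B", "C"]).set_index("effect")
        assert out.loc["A", "p"] < 0.01
        assert out.loc["B", "p"] > 0.01

    def test_planted_effect_power(self):
        # paired design, delta=5, sigma_subject=3, sigma_resid=2, n=26:
        # detected at p < 0.01 in >= 95% of 200 replicates
        rng = np.random.default_rng(5)
        detected = 0
        n_rep = 200
        for _ in range(n_rep):
            subj = rng.normal(0, 3, 26)
            a = 50 + subj + rng.normal(0, 2, 26)
            b = 55 + subj + rng.normal(0, 2, 26)
            res = paired_t(b, a)
            detected += res.p_two_tailed < 0.01
        assert detected / n_rep >= 0.95

    def test_missing_cells_rejected(self):
        df = pd.DataFrame(
            {
                "subject": [0, 0, 1],
                "cond": ["a", "b", "a"],
                "score": [1.0, 2.0, 3.0],
            }
        )
        with pytest.raises(ValueError):
            rm_anova(df, "score", "subject", ["cond"])


class TestMauchly:
    def _table(self, values):
        n, k = values.shape
        return pd.DataFrame(
            {
                "subject": np.repeat(range(n), k),
                "cond": list(range(k)) * n,
                "score": values.ravel(),
            }
        )

    def test_two_level_factor_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            mauchly_sphericity(self._table(rng.normal(size=(10, 2))), "score", "subject", "cond")

    def test_null_rejection_rate_near_alpha(self):
        # compound-symmetric data satisfy sphericity: rejection ~ alpha
        rng = np.random.default_rng(7)
        alpha = 0.05
        rejections = 0
        n_sim = 500
        for _ in range(n_sim):
            subj = rng.normal(0, 2, (26, 1))
            x = subj + rng.normal(0, 1, (26, 3))
            res = mauchly_sphericity(self._table(x), "score", "subject", "cond")
            rejections += res.p < alpha
        rate = rejections / n_sim
        assert 0.02 <= rate <= 0.09

    def test_heteroscedastic_levels_detected(self):
        rng = np.random.default_rng(8)
        rejections = 0
        n_sim = 100
        for _ in range(n_sim):
            x = np.column_stack(
                [
                    rng.normal(0, np.sqrt(10), 26),
                    rng.normal(0, 1, 26),
                    rng.normal(0, 1, 26),
                ]
            )
            res = mauchly_sphericity(self._table(x), "score", "subject", "cond")
            rejections += res.p < 0.05
        assert rejections / n_sim > 0.5

    def test_agrees_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        x = rng.normal(size=(12, 4)) * np.array([1.0, 1.5, 2.0, 1.0])
        df = self._table(x)
        ours = mauchly_sphericity(df, "score", "subject", "cond")
        theirs = pg.sphericity(df, dv="score", subject="subject", within="cond")
        assert ours.w == pytest.approx(theirs.W, rel=1e-6)
        # chi-square small-sample correction differs slightly across
        # implementations; p must agree closely but not bit-exactly
        assert ours.p == pytest.approx(theirs.pval, rel=0.05)


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [10, 20, 40, 80, 160])
        assert rho == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        rho, _ = spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_hand_computed_rank_example(self):
        # sum of squared rank differences is 4: rho = 1 - 6*4/(5*24) = 0.8
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])
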