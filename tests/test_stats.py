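"""RM-AN(C)OVA, paired t, Holm step-down, correlation screens."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

from sleepmem import (holm_bonferroni, paired_t, rm_anova_2x2x2,
                      sleep_memory_screen)

CONDS = ("placebo", "zolpidem")
VALS = ("negative", "neutral")


def _long(values_by_subject):
    """values_by_subject: n x 8 array ordered (cond, test, valence)."""
    rows = []
    for s, vals in enumerate(values_by_subject):
        k = 0
        for c in CONDS:
            for t in (1, 2):
                for v in VALS:
                    rows.append(dict(subject=s, condition=c, test=t,
                                     valence=v, dprime=vals[k]))
                    k += 1
    return pd.DataFrame(rows)


class TestPairedT:
    def test_identical_vectors(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p == 1.0
        assert res.degenerate

    def test_hand_computed_example(self):
        # differences 1,2,3,4: mean 2.5, sd 1.2910 -> t = 2.5/(1.2910/2)
        res = paired_t([2.0, 3.0, 4.0, 5.0], [1.0, 1.0, 1.0, 1.0])
        assert res.t == pytest.approx(3.873, abs=1e-3)
        assert res.df == 3

    def test_antisymmetry(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        a = paired_t(x, y)
        b = paired_t(y, x)
        assert a.t == pytest.approx(-b.t)
        assert a.p == pytest.approx(b.p)

    def test_constant_nonzero_difference_degenerate(self):
        res = paired_t([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
        assert res.degenerate
        assert np.isinf(res.t)


def brute_force_holm(p, alpha):
    """Reject the i-th smallest p iff every prefix step passes."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    out = np.zeros(m, dtype=bool)
    for i in range(m):
        ok = all(p[order[j]] <= alpha / (m - j) for j in range(i + 1))
        out[order[i]] = ok
    return out


class TestHolm:
    def test_single_p_reduces_to_plain_test(self):
        assert holm_bonferroni([0.04], alpha=0.05).tolist() == [True]

    def test_step_down_schedule(self):
        # sorted: 0.01 <= .05/3; 0.03 > .05/2 stops the procedure
        got = holm_bonferroni([0.01, 0.04, 0.03], alpha=0.05)
        assert got.tolist() == [True, False, False]

    def test_all_ones_rejected_nothing(self):
        assert not holm_bonferroni([1.0, 1.0, 1.0]).any()

    def test_empty_input(self):
        assert holm_bonferroni([]).size == 0

    def test_brute_force_equivalence_1000_vectors(self, rng):
        for i in range(1000):
            m = rng.integers(1, 12)
            p = rng.uniform(size=m)
            if rng.random() < 0.3:  # inject ties
                p[: m // 2] = p[0]
            alpha = rng.choice([0.01, 0.05, 0.1])
            got = holm_bonferroni(p, alpha)
            np.testing.assert_array_equal(got, brute_force_holm(p, alpha))
            if i < 100:  # statsmodels as a second, library oracle
                np.testing.assert_array_equal(
                    got, multipletests(p, alpha, method="holm")[0])

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.5])


class TestRmAnova:
    def test_null_data_all_f_zero(self):
        # identical cell values per subject -> every contrast is zero
        base = np.arange(6, dtype=float)[:, None] * np.ones(8)
        res = rm_anova_2x2x2(_long(base))
        for r in res:
            assert r.F == pytest.approx(0.0, abs=1e-20)
            assert r.p == pytest.approx(1.0)

    def test_matches_statsmodels_anovarm(self, rng):
        df = _long(rng.normal(size=(12, 8)))
        mine = {r.effect: r for r in rm_anova_2x2x2(df)}
        ref = AnovaRM(df, "dprime", "subject",
                      within=["condition", "test", "valence"]).fit().anova_table
        name_map = {"condition": "drug", "test": "test", "valence": "emotion",
                    "condition:test": "drug:test",
                    "condition:valence": "drug:emotion",
                    "test:valence": "test:emotion",
                    "condition:test:valence": "drug:test:emotion"}
        for sm_name, my_name in name_map.items():
            assert mine[my_name].F == pytest.approx(
                ref.loc[sm_name, "F Value"], rel=1e-8)
            assert mine[my_name].p == pytest.approx(
                ref.loc[sm_name, "Pr > F"], rel=1e-8)
            assert mine[my_name].df_den == int(ref.loc[sm_name, "Den DF"])

    def test_four_subject_hand_decomposition(self):
        """Main-effect F equals the explicit sums-of-squares ratio."""
        Y = np.array([
            [2.0, 1.5, 1.8, 1.2, 2.4, 1.9, 2.1, 1.6],
            [1.1, 0.9, 1.0, 0.7, 1.5, 1.2, 1.4, 1.0],
            [2.5, 2.0, 2.2, 1.7, 2.9, 2.2, 2.6, 2.1],
            [0.8, 0.5, 0.9, 0.4, 1.2, 0.8, 1.1, 0.6],
        ])
        # drug contrast: mean(zolpidem cells) - mean(placebo cells)
        contrast = Y[:, 4:].mean(axis=1) - Y[:, :4].mean(axis=1)
        n = len(contrast)
        ss_effect = n * contrast.mean() ** 2
        ss_error = ((contrast - contrast.mean()) ** 2).sum()
        f_expected = ss_effect / (ss_error / (n - 1))
        res = {r.effect: r for r in rm_anova_2x2x2(_long(Y))}
        assert res["drug"].F == pytest.approx(f_expected, rel=1e-10)
        assert res["drug"].df_den == n - 1

    def test_constant_covariate_equals_no_covariate(self, rng):
        df = _long(rng.normal(size=(10, 8)))
        cov = pd.Series(70.0, index=range(10))
        with_c = rm_anova_2x2x2(df, covariate=cov)
        without = rm_anova_2x2x2(df)
        a = {r.effect: (r.F, r.df_den, r.p) for r in with_c}
        b = {r.effect: (r.F, r.df_den, r.p) for r in without}
        assert a == b

    def test_covariate_changes_error_df(self, rng):
        df = _long(rng.normal(size=(10, 8)))
        cov = pd.Series(rng.normal(75, 10, 10), index=range(10))
        res = {r.effect: r for r in rm_anova_2x2x2(df, covariate=cov)}
        assert res["drug"].df_den == 8  # n - 2
        assert "drug:weight" in res
        assert "weight" in res

    def test_incomplete_subject_listwise_deleted(self, rng):
        df = _long(rng.normal(size=(8, 8)))
        df = df.drop(df[(df.subject == 0) & (df.test == 2)].index)
        with pytest.warns(UserWarning, match="listwise"):
            res = rm_anova_2x2x2(df)
        assert res[0].n_subjects == 7


class TestScreen:
    def _frames(self, x, y, n=None):
        n = n or len(x)
        feats = pd.DataFrame({"subject": range(n), "condition": "placebo",
                              "feat": x})
        mem = pd.DataFrame({"subject": range(n), "condition": "placebo",
                            "mem": y})
        return feats, mem

    def test_perfect_correlation(self):
        x = np.arange(10.0)
        feats, mem = self._frames(x, x)
        out = sleep_memory_screen(feats, mem, alpha_corrected=0.0025)
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["significant"].iloc[0]

    def test_negative_limit(self, rng):
        x = np.arange(20.0)
        y = -2 * x + rng.normal(0, 1e-9, 20)
        feats, mem = self._frames(x, y)
        out = sleep_memory_screen(feats, mem, alpha_corrected=0.0025)
        assert out["r"].iloc[0] == pytest.approx(-1.0, abs=1e-6)

    def test_constant_vector_flagged(self):
        feats, mem = self._frames(np.ones(8), np.arange(8.0))
        out = sleep_memory_screen(feats, mem, alpha_corrected=0.004)
        assert not out["valid"].iloc[0]
        assert np.isnan(out["r"].iloc[0])

    def test_population_correlation_recovered(self, rng):
        # feature = a*score + noise at known a -> r within CI of rho
        n, a = 26, 0.8
        score = rng.normal(0, 1, n)
        noise_sd = 1.0
        feat = a * score + rng.normal(0, noise_sd, n)
        rho = a / np.sqrt(a ** 2 + noise_sd ** 2)
        feats, mem = self._frames(feat, score)
        out = sleep_memory_screen(feats, mem, alpha_corrected=0.004)
        # Fisher-z 95% half-width at n=26 ~ 0.41
        z = np.arctanh(out["r"].iloc[0])
        assert abs(z - np.arctanh(rho)) < 2.5 / np.sqrt(n - 3)

    def test_separate_per_condition(self, rng):
        feats = pd.DataFrame({
            "subject": list(range(8)) * 2,
            "condition": ["placebo"] * 8 + ["zolpidem"] * 8,
            "feat": np.r_[np.arange(8.0), rng.normal(size=8)],
        })
        mem = feats.rename(columns={"feat": "mem"}).copy()
        mem["mem"] = np.r_[np.arange(8.0), rng.normal(size=8)]
        out = sleep_memory_screen(feats, mem, alpha_corrected=0.0025)
        assert set(out["condition"]) == {"placebo", "zolpidem"}
        pb = out[out["condition"] == "placebo"]
        assert pb["r"].iloc[0] == pytest.approx(1.0)
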