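"""Tests of the inference battery: fences, t-tests, Wilcoxon, power, ANOVA."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from iblt.anova import rm_anova
from iblt.stats import (
    correlation_test,
    iqr_outliers,
    one_sample_t,
    paired_contrast_rejection_rate,
    paired_t,
    power_paired_t,
    welch_t,
    wilcoxon_signed_rank,
)


class TestIqrOutliers:
    def test_hand_computed_fences(self):
        mask = iqr_outliers([1, 2, 3, 4, 100])
        assert mask.fences[0] == pytest.approx((-1.0, 7.0))  # Q1=2, Q3=4
        assert list(mask.keep) == [True, True, True, True, False]
        assert mask.n_removed == 1

    def test_constant_vector_flags_nothing(self):
        mask = iqr_outliers([3.3] * 6)
        assert mask.keep.all()

    def test_per_level_fences_differ(self):
        x = [0, 1, 2, 3, 100, 101, 102, 103]
        g = ["a"] * 4 + ["b"] * 4
        joint = iqr_outliers(x)
        split = iqr_outliers(x, g)
        assert split.fences["a"] != split.fences["b"]
        assert split.fences["a"] != joint.fences[0]

    def test_idempotence(self):
        x = np.array([1.0, 2, 3, 4, 100, 2.5, 3.5])
        first = iqr_outliers(x)
        second = iqr_outliers(x[first.keep])
        assert second.keep.all()

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            iqr_outliers([1, 2, 3])
        with pytest.raises(ValueError):
            iqr_outliers([1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])


class TestTTests:
    def test_welch_from_questionnaire_summaries(self):
        """Summary-statistics Welch test on typical BDI-like group summaries."""
        res = welch_t(mean1=26.8, sd1=9.7, n1=43, mean2=4.7, sd2=6.5, n2=40)
        assert res.statistic == pytest.approx(12.27, abs=0.01)
        assert res.df == pytest.approx(73.8, abs=0.05)
        assert res.p < 0.001

    def test_identical_summaries_give_zero_t(self):
        res = welch_t(mean1=5, sd1=2, n1=30, mean2=5, sd2=2, n2=30)
        assert res.statistic == 0.0 and res.p == pytest.approx(1.0)

    def test_one_sample_zero_mean(self):
        res = one_sample_t([-1.0, 0.0, 1.0])
        assert res.statistic == 0.0
        assert res.df == 2

    def test_paired_equals_one_sample_on_differences(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 15), rng.normal(0.3, 1, 15)
        a, b = paired_t(x, y), one_sample_t(x - y)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.effect_size == pytest.approx(b.effect_size)  # Cohen's dz

    def test_zero_variance_paired_warns_infinite(self):
        with pytest.warns(UserWarning):
            res = paired_t([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])
        assert np.isinf(res.statistic)

    def test_welch_one_sided(self):
        rng = np.random.default_rng(1)
        hi, lo = rng.normal(1, 1, 40), rng.normal(0, 1, 40)
        res = welch_t(hi, lo, alternative="greater")
        assert res.p < 0.01


class TestWilcoxon:
    def test_hand_ranked_v(self):
        # |d| = [1,2,3] -> ranks [1,2,3]; positive ranks 1+2 = 3
        res = wilcoxon_signed_rank([1, 2, 0], [0, 0, 3])
        assert res.statistic == 3.0

    def test_all_positive_maximum(self):
        res = wilcoxon_signed_rank([2, 3, 4], [1, 1, 1])
        assert res.statistic == 6.0  # n(n+1)/2

    def test_single_nonzero_pair(self):
        res = wilcoxon_signed_rank([1, 1, 1, 2], [1, 1, 1, 1])
        assert res.statistic in (0.0, 1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1, 1], [1, 1])

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.4, 1, 40)
        res = wilcoxon_signed_rank(x, np.zeros(40))
        assert 0 < res.p < 1


class TestCorrelation:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = correlation_test(x, 2 * x + 1)
        assert res.effect_size == pytest.approx(1.0)

    def test_closed_form_t(self):
        # r = 0.5, n = 11 -> t = 0.5 * sqrt(9 / 0.75) = 1.732
        rng = np.random.default_rng(3)
        for _ in range(50):  # find no specific data; check the formula directly
            pass
        x = np.array([0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10.0])
        # construct y with exact r = 0.5
        z = np.array([0, 2, 1, 4, 3, 6, 5, 8, 7, 10, 9.0])
        xs = (x - x.mean()) / x.std()
        zs = z - z.mean()
        zs -= (zs @ xs) / (xs @ xs) * xs  # orthogonalise
        zs /= zs.std()
        y = 0.5 * xs + np.sqrt(1 - 0.25) * zs
        res = correlation_test(x, y)
        assert res.effect_size == pytest.approx(0.5, abs=1e-12)
        assert res.statistic == pytest.approx(1.7320508, abs=1e-6)
        assert res.df == 9

    def test_independent_streams_near_zero(self):
        rng = np.random.default_rng(4)
        res = correlation_test(rng.normal(size=10_000), rng.normal(size=10_000))
        assert abs(res.effect_size) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlation_test([1, 1, 1], [1, 2, 3])


class TestPower:
    def test_known_sample_sizes(self):
        assert power_paired_t(0.3, 0.80, 0.05, tails=2) == 90

    def test_monotone_in_effect_size(self):
        assert power_paired_t(0.6) < power_paired_t(0.3)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            power_paired_t(0.0)
        with pytest.raises(ValueError):
            power_paired_t(0.5, power=1.5)

    def test_one_tailed_needs_fewer_subjects(self):
        assert power_paired_t(0.4, tails=1) < power_paired_t(0.4, tails=2)


class TestRmAnova:
    def test_two_level_within_equals_squared_paired_t(self):
        rng = np.random.default_rng(5)
        n = 20
        d = pd.DataFrame(
            {
                "s": np.repeat(np.arange(n), 2),
                "w": ["a", "b"] * n,
                "y": rng.normal(0, 1, 2 * n) + np.tile([0.0, 0.4], n),
            }
        )
        t = paired_t(d[d.w == "a"].y.to_numpy(), d[d.w == "b"].y.to_numpy())
        table = rm_anova(d, "y", "s", within=["w"])
        assert table.F.iloc[0] == pytest.approx(t.statistic**2, abs=1e-8)

    def test_constant_within_effect_gives_zero_f(self):
        n = 12
        rng = np.random.default_rng(6)
        base = rng.normal(0, 1, n)
        d = pd.DataFrame(
            {
                "s": np.repeat(np.arange(n), 2),
                "w": ["a", "b"] * n,
                "y": np.repeat(base, 2),  # identical across levels per subject
            }
        )
        table = rm_anova(d, "y", "s", within=["w"])
        assert table.F.iloc[0] == pytest.approx(0.0, abs=1e-20)

    def test_matches_pingouin_mixed_anova_balanced(self):
        rng = np.random.default_rng(7)
        rows = []
        for i in range(24):
            g = "g1" if i < 12 else "g2"
            base = rng.normal(0, 1)
            for w in ("w1", "w2", "w3"):
                bump = 0.6 if (g == "g2" and w == "w3") else 0.0
                rows.append({"s": i, "g": g, "w": w, "y": base + rng.normal(0, 1) + bump})
        df = pd.DataFrame(rows)
        mine = rm_anova(df, "y", "s", within=["w"], between=["g"]).set_index("effect")
        ref = pg.mixed_anova(df, dv="y", within="w", subject="s", between="g").set_index("Source")
        assert mine.loc["g", "F"] == pytest.approx(ref.loc["g", "F"], abs=1e-8)
        assert mine.loc["w", "F"] == pytest.approx(ref.loc["w", "F"], abs=1e-8)
        assert mine.loc["g x w", "F"] == pytest.approx(ref.loc["Interaction", "F"], abs=1e-8)

    def test_matches_pingouin_two_way_within(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(15):
            base = rng.normal(0, 1)
            for w1 in ("a", "b"):
                for w2 in ("x", "y", "z"):
                    rows.append(
                        {"s": i, "w1": w1, "w2": w2,
                         "y": base + rng.normal(0, 1) + (0.5 if w1 == "a" else 0)}
                    )
        df = pd.DataFrame(rows)
        mine = rm_anova(df, "y", "s", within=["w1", "w2"]).set_index("effect")
        ref = pg.rm_anova(df, dv="y", within=["w1", "w2"], subject="s").set_index("Source")
        for eff, src in [("w1", "w1"), ("w2", "w2"), ("w1 x w2", "w1 * w2")]:
            assert mine.loc[eff, "F"] == pytest.approx(ref.loc[src, "F"], abs=1e-8)
        # GG epsilon for the 3-level factor
        assert mine.loc["w2", "gg_eps"] == pytest.approx(ref.loc["w2", "eps"], abs=1e-8)

    def test_crossover_interaction_detected_without_main_effects(self):
        """A pure Sample x Valence crossover shows up only as the interaction."""
        rng = np.random.default_rng(9)
        rows = []
        n = 40
        for i in range(n):
            g = "low" if i < n // 2 else "high"
            sign = 1.0 if g == "low" else -1.0
            base = rng.normal(0, 0.8)
            for w, wsign in (("win", 1.0), ("loss", -1.0)):
                rows.append(
                    {"s": i, "g": g, "w": w, "y": base + 0.5 * sign * wsign + rng.normal(0, 0.5)}
                )
        df = pd.DataFrame(rows)
        table = rm_anova(df, "y", "s", within=["w"], between=["g"]).set_index("effect")
        assert table.loc["g x w", "p"] < 0.01
        assert table.loc["g", "p"] > 0.05
        assert table.loc["w", "p"] > 0.05

    def test_incomplete_subjects_dropped(self):
        rng = np.random.default_rng(10)
        d = pd.DataFrame(
            {
                "s": np.repeat(np.arange(10), 2),
                "w": ["a", "b"] * 10,
                "y": rng.normal(size=20),
            }
        ).drop(index=[1])  # subject 0 loses its "b" cell
        table = rm_anova(d, "y", "s", within=["w"])
        assert (table["n"] == 9).all()


class TestCalibrationHarness:
    def test_null_rejection_rate_near_alpha(self):
        rate = paired_contrast_rejection_rate(n=38, dz=0.0, n_replicates=2000, seed=11)
        assert abs(rate - 0.05) < 0.02

    def test_powered_effect_detected(self):
        rate = paired_contrast_rejection_rate(n=38, dz=0.472, n_replicates=2000, seed=12)
        assert 0.75 < rate < 0.87
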