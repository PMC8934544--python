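"""Statistical-layer tests: the balanced compound-symmetry fit against its
closed-form oracles, Welch's ANOVA against independent implementations, the
body-length matching rule and Monte-Carlo power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from danioeye.stats_mixed import (
    fit_cs_mixed,
    p_to_stars,
    power_sim,
    size_match_filter,
    welch_anova,
)


def simulate_table(rng, n_fish=10, effect=0.0, sigma_fish=10.0, sigma_eye=4.0,
                   genotypes=("wt", "mut"), drop_one_eye=False):
    rows = []
    for g in genotypes:
        offset = effect if g != genotypes[0] else 0.0
        for i in range(n_fish):
            fish_mean = offset + rng.normal(0, sigma_fish)
            for eye in ("L", "R"):
                rows.append({
                    "fish_id": f"{g}_{i}",
                    "eye": eye,
                    "genotype": g,
                    "value": fish_mean + rng.normal(0, sigma_eye),
                })
    df = pd.DataFrame(rows)
    if drop_one_eye:
        df = df.drop(df.index[0])
    return df


class TestCsMixedModel:
    def test_matches_fish_means_t_test(self, rng):
        """On balanced data the CS mixed-model genotype effect and p value
        equal the pooled two-sample t-test on per-fish eye means."""
        df = simulate_table(rng, effect=5.0)
        fit = fit_cs_mixed(df, "value", "wt")
        means = df.groupby(["fish_id", "genotype"])["value"].mean().reset_index()
        a = means.loc[means.genotype == "wt", "value"]
        b = means.loc[means.genotype == "mut", "value"]
        t, p = sps.ttest_ind(b, a, equal_var=True)
        assert fit.effect_size == pytest.approx(b.mean() - a.mean(), rel=1e-12)
        assert fit.p_value == pytest.approx(p, rel=1e-9)
        assert fit.df == 18

    def test_zero_within_fish_variance_reduces_to_t_test(self, rng):
        df = simulate_table(rng, effect=3.0, sigma_eye=1e-12)
        fit = fit_cs_mixed(df, "value", "wt")
        means = df.groupby(["fish_id", "genotype"])["value"].mean().reset_index()
        a = means.loc[means.genotype == "wt", "value"]
        b = means.loc[means.genotype == "mut", "value"]
        _, p = sps.ttest_ind(b, a, equal_var=True)
        assert fit.p_value == pytest.approx(p, rel=1e-6)
        assert fit.sigma_eye_sq == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_statsmodels_mixedlm(self, rng):
        """Independent cross-check: REML random-intercept fit from
        statsmodels gives the same effect, SE and variance components."""
        import warnings
        import statsmodels.formula.api as smf

        df = simulate_table(rng, effect=4.0)
        fit = fit_cs_mixed(df, "value", "wt")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = smf.mixedlm(
                'value ~ C(genotype, Treatment("wt"))', df, groups=df["fish_id"]
            ).fit(reml=True)
        assert fit.effect_size == pytest.approx(float(m.params.iloc[1]), rel=1e-6)
        assert fit.se == pytest.approx(float(m.bse.iloc[1]), rel=1e-3)
        assert fit.sigma_eye_sq == pytest.approx(float(m.scale), rel=1e-3)
        assert fit.sigma_fish_sq == pytest.approx(
            float(np.asarray(m.cov_re)[0, 0]), rel=1e-2, abs=0.5
        )

    def test_unbalanced_table_uses_reml_path(self, rng):
        df = simulate_table(rng, effect=6.0, drop_one_eye=True)
        fit = fit_cs_mixed(df, "value", "wt")
        assert fit.converged
        assert fit.n_eyes == 39
        assert fit.effect_size == pytest.approx(6.0, abs=10.0)

    def test_identical_values_collapse(self):
        rows = [
            {"fish_id": f"{g}{i}", "eye": e, "genotype": g, "value": 7.0}
            for g in ("wt", "mut") for i in range(5) for e in ("L", "R")
        ]
        fit = fit_cs_mixed(pd.DataFrame(rows), "value", "wt")
        assert fit.effect_size == 0.0
        assert fit.sigma_fish_sq == 0.0 and fit.sigma_eye_sq == 0.0
        assert fit.p_value == 1.0

    def test_effect_equivariance(self, rng):
        df = simulate_table(rng, effect=2.0)
        fit1 = fit_cs_mixed(df, "value", "wt")
        df2 = df.copy()
        df2.loc[df2.genotype == "mut", "value"] += 11.5
        fit2 = fit_cs_mixed(df2, "value", "wt")
        assert fit2.effect_size - fit1.effect_size == pytest.approx(11.5, rel=1e-9)

    def test_icc_bounds_and_variances(self, rng):
        df = simulate_table(rng, sigma_fish=12.0, sigma_eye=3.0)
        fit = fit_cs_mixed(df, "value", "wt")
        assert 0.0 <= fit.icc <= 1.0
        assert fit.sigma_fish_sq >= 0 and fit.sigma_eye_sq >= 0
        assert fit.icc > 0.5  # fish variance dominates by construction

    def test_input_validation(self, rng):
        df = simulate_table(rng)
        with pytest.raises(ValueError, match="reference"):
            fit_cs_mixed(df, "value", "nope")
        with pytest.raises(ValueError, match="3 fish"):
            fit_cs_mixed(df[df.fish_id.isin(["wt_0", "wt_1", "mut_0", "mut_1"])],
                         "value", "wt")
        with pytest.raises(KeyError):
            fit_cs_mixed(df, "missing_metric", "wt")

    def test_type_i_error_calibrated(self):
        """Under the null the CS fit rejects at alpha = 0.05 between 3% and
        7% of the time (2000 simulated null cohorts)."""
        rng = np.random.default_rng(2024)
        n_reps, hits = 2000, 0
        template = pd.DataFrame({
            "fish_id": np.repeat([f"{g}_{i}" for g in "ab" for i in range(10)], 2),
            "eye": ["L", "R"] * 20,
            "genotype": np.repeat(["wt", "mut"], 20),
        })
        for _ in range(n_reps):
            fish = np.repeat(rng.normal(0, 10, size=20), 2)
            df = template.assign(value=fish + rng.normal(0, 4, size=40))
            hits += fit_cs_mixed(df, "value", "wt").p_value < 0.05
        assert 0.03 <= hits / n_reps <= 0.07


class TestWelchAnova:
    def test_identical_group_means(self, rng):
        base = rng.normal(0, 1, 12)
        res = welch_anova([base, base + rng.normal(0, 1e-9, 12)])
        assert res.F == pytest.approx(0.0, abs=1e-6)
        assert res.p_value == pytest.approx(1.0, abs=1e-3)

    def test_two_group_F_equals_t_squared(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(1, 3, 15)
        res = welch_anova([a, b])
        t, p = sps.ttest_ind(a, b, equal_var=False)
        assert res.F == pytest.approx(t**2, abs=1e-9)
        assert res.p_value == pytest.approx(p, abs=1e-9)

    def test_three_group_example_matches_direct_formula(self):
        groups = [
            np.array([27.5, 21.0, 19.0, 23.6, 17.0, 17.9, 16.9, 20.1, 21.9, 22.6]),
            np.array([24.5, 23.4, 21.1, 25.3, 22.8, 23.7, 24.8, 25.1]),
            np.array([31.2, 24.0, 24.1, 25.0, 24.1, 26.7, 27.9, 33.5]),
        ]
        # independent hand computation of Welch's statistic
        n = np.array([len(g) for g in groups], float)
        m = np.array([g.mean() for g in groups])
        v = np.array([g.var(ddof=1) for g in groups])
        w = n / v
        mw = (w * m).sum() / w.sum()
        k = 3
        A = (w * (m - mw) ** 2).sum() / (k - 1)
        lam = (((1 - w / w.sum()) ** 2) / (n - 1)).sum()
        F_expected = A / (1 + 2 * (k - 2) / (k**2 - 1) * lam)
        res = welch_anova(groups)
        assert res.F == pytest.approx(F_expected, abs=1e-6)

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        groups = [rng.normal(0, 1, 8), rng.normal(0.5, 2, 12), rng.normal(1, 0.5, 6)]
        res = welch_anova(groups)
        df = pd.DataFrame({
            "v": np.concatenate(groups),
            "g": np.repeat([0, 1, 2], [len(g) for g in groups]),
        })
        ref = pg.welch_anova(df, dv="v", between="g")
        assert res.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert res.df2 == pytest.approx(float(ref["ddof2"].iloc[0]), rel=1e-9)
        assert res.p_value == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-9)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_anova([[1.0], [2.0, 3.0]])
        with pytest.raises(ValueError):
            welch_anova([[1.0, 1.0], [2.0, 3.0]])


class TestSizeMatch:
    def _table(self, wt_mean, mut_mean, n=10, sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, mean in (("wt", wt_mean), ("mut", mut_mean)):
            for i in range(n):
                rows.append({"fish_id": f"{g}{i}", "genotype": g,
                             "body_length": mean + rng.normal(0, sd)})
        return pd.DataFrame(rows)

    def test_equal_means_pass(self):
        passed, _ = size_match_filter(self._table(28.0, 28.0), "wt")
        assert passed

    def test_1p5_percent_fails(self):
        passed, report = size_match_filter(self._table(28.0, 28.0 * 1.015), "wt")
        assert not passed
        assert report["relative_difference"].iloc[0] == pytest.approx(0.015)

    def test_exact_1_percent_inclusive(self):
        passed, _ = size_match_filter(self._table(28.0, 28.0 * 1.01), "wt")
        assert passed

    def test_missing_reference_errors(self):
        with pytest.raises(ValueError):
            size_match_filter(self._table(28.0, 28.0), "other")


class TestPowerSim:
    def test_null_power_near_alpha(self):
        res = power_sim(0.0, sigma_fish=10.0, sigma_eye=4.0, n_reps=2000, seed=3)
        assert res.power == pytest.approx(0.05, abs=0.015)

    def test_large_effect_saturates(self):
        res = power_sim(100.0, sigma_fish=10.0, sigma_eye=4.0, n_reps=200, seed=3)
        assert res.power == 1.0

    def test_monotone_in_n_and_effect(self):
        p_small = power_sim(8.0, 10.0, 4.0, n_fish_per_group=5, n_reps=800, seed=7).power
        p_big_n = power_sim(8.0, 10.0, 4.0, n_fish_per_group=20, n_reps=800, seed=7).power
        p_big_eff = power_sim(16.0, 10.0, 4.0, n_fish_per_group=5, n_reps=800, seed=7).power
        assert p_big_n >= p_small
        assert p_big_eff >= p_small

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            power_sim(1.0, 0.0, 4.0)
        with pytest.raises(ValueError):
            power_sim(1.0, 10.0, 4.0, n_reps=50)


def test_star_mapping():
    assert p_to_stars(0.0005) == "***"
    assert p_to_stars(0.005) == "**"
    assert p_to_stars(0.04) == "*"
    assert p_to_stars(0.2) == "ns"
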