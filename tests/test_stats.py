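"""Statistical battery against independent oracles.

ANOVA/eta-squared against a raw-data ANOVA, Games-Howell against an
explicit studentized-range quadrature and against an independent
raw-data implementation, Spearman against the hand rank formula,
chi-squared against the textbook sum, ANCOVA against statsmodels.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy import stats as sps

from shankgait.stats import (
    AnovaResult,
    GroupSummary,
    ancova_group_effect,
    anova_eta2,
    chi2_pairwise,
    cohens_d,
    cohens_d_label,
    eta_squared_label,
    games_howell,
    percent_difference,
    spearman,
    stat_report,
)


def _raw_with_summary(n, mean, sd, rng):
    """A sample whose mean/SD equal the requested values exactly."""
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


def _sr_sf_quadrature(q, k, df):
    """Studentized-range survival function by direct numerical quadrature."""

    def p_inf(qq):
        f = lambda z: sps.norm.pdf(z) * (
            sps.norm.cdf(z) - sps.norm.cdf(z - qq)
        ) ** (k - 1)
        val, _ = integrate.quad(f, -9, 9, limit=300, epsabs=1e-12)
        return k * val

    chi = sps.chi(df)
    g = lambda x: chi.pdf(x) * p_inf(q * x / np.sqrt(df))
    val, _ = integrate.quad(g, chi.ppf(1e-13), chi.ppf(1 - 1e-13),
                            limit=300, epsabs=1e-12)
    return 1 - val


class TestAnova:
    def test_summary_anova_equals_raw_anova(self, rng):
        groups, raw = [], []
        for n, m, s in [(12, 5.0, 1.1), (20, 6.2, 2.3), (8, 4.1, 0.7)]:
            x = _raw_with_summary(n, m, s, rng)
            raw.append(x)
            groups.append(GroupSummary.from_data(str(n), x))
        res = anova_eta2(groups)
        F, p = sps.f_oneway(*raw)
        assert res.F == pytest.approx(F, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-10)
        grand = np.concatenate(raw)
        ss_tot = ((grand - grand.mean()) ** 2).sum()
        ss_w = sum(((x - x.mean()) ** 2).sum() for x in raw)
        assert res.eta_squared == pytest.approx(1 - ss_w / ss_tot, rel=1e-10)

    def test_identical_groups_give_zero_effect(self):
        g = [GroupSummary("a", 10, 5.0, 1.0), GroupSummary("b", 10, 5.0, 1.0)]
        res = anova_eta2(g)
        assert res.F == 0.0 and res.eta_squared == 0.0

    def test_zero_variance_convention(self):
        g = [GroupSummary("a", 10, 5.0, 0.0), GroupSummary("b", 10, 5.0, 0.0)]
        assert anova_eta2(g) == AnovaResult(0.0, 1.0, 0.0, 1, 18)

    def test_affine_invariance_of_eta2(self, rng):
        gs = [GroupSummary("a", 15, 3.0, 1.0), GroupSummary("b", 25, 4.5, 2.0)]
        scaled = [GroupSummary(g.label, g.n, 7 * g.mean - 2, 7 * g.sd) for g in gs]
        assert anova_eta2(gs).eta_squared == pytest.approx(
            anova_eta2(scaled).eta_squared, rel=1e-12
        )


class TestCohensD:
    def test_equal_means_zero(self):
        assert cohens_d(5.0, 1.0, 10, 5.0, 2.0, 12) == 0.0

    def test_zero_pooled_sd_surfaces(self):
        with pytest.raises(ZeroDivisionError):
            cohens_d(5.0, 0.0, 10, 6.0, 0.0, 12)

    def test_affine_invariance(self):
        d1 = cohens_d(3.0, 1.2, 20, 4.0, 0.8, 15)
        d2 = cohens_d(3 * 3.0 + 1, 3 * 1.2, 20, 3 * 4.0 + 1, 3 * 0.8, 15)
        assert d1 == pytest.approx(d2, rel=1e-12)


class TestGamesHowell:
    SUMMARIES = [
        GroupSummary("non-frail", 49, 0.70, 0.11),
        GroupSummary("pre-frail", 92, 0.83, 0.23),
        GroupSummary("frail", 20, 1.11, 0.46),
    ]

    def test_p_within_1e6_of_quadrature_oracle(self):
        res = games_howell(self.SUMMARIES)
        for pr in res:
            a = next(g for g in self.SUMMARIES if g.label == pr.pair[0])
            b = next(g for g in self.SUMMARIES if g.label == pr.pair[1])
            se = np.sqrt(a.sd**2 / a.n + b.sd**2 / b.n)
            q = abs(a.mean - b.mean) * np.sqrt(2) / se
            oracle = _sr_sf_quadrature(q, 3, pr.df)
            assert pr.p == pytest.approx(oracle, abs=1e-6)

    def test_identical_groups_p_near_one(self):
        g = [GroupSummary("a", 30, 5.0, 1.0), GroupSummary("b", 30, 5.0, 1.0)]
        (pr,) = games_howell(g)
        assert pr.p > 0.999
        assert pr.ci_lower <= 0 <= pr.ci_upper

    def test_matches_raw_data_reference_implementation(self, rng):
        pingouin = pytest.importorskip("pingouin")
        raw = {
            "a": _raw_with_summary(18, 10.0, 2.0, rng),
            "b": _raw_with_summary(25, 12.5, 3.5, rng),
            "c": _raw_with_summary(11, 9.0, 1.2, rng),
        }
        df = pd.DataFrame(
            {
                "y": np.concatenate(list(raw.values())),
                "g": np.repeat(list(raw), [len(v) for v in raw.values()]),
            }
        )
        ref = pingouin.pairwise_gameshowell(data=df, dv="y", between="g")
        mine = games_howell(
            [GroupSummary.from_data(k, v) for k, v in raw.items()]
        )
        for pr in mine:
            row = ref[(ref["A"] == pr.pair[0]) & (ref["B"] == pr.pair[1])]
            assert len(row) == 1
            assert pr.p == pytest.approx(float(row["pval"].iloc[0]), abs=1e-6)
            assert pr.df == pytest.approx(float(row["df"].iloc[0]), rel=1e-9)

    def test_reduces_to_tukey_for_equal_n_and_variance(self, rng):
        statsmodels = pytest.importorskip("statsmodels.stats.multicomp")
        n, sd = 200, 2.0
        means = {"a": 10.0, "b": 10.4, "c": 10.8}
        raw = {k: _raw_with_summary(n, m, sd, rng) for k, m in means.items()}
        tuk = statsmodels.pairwise_tukeyhsd(
            np.concatenate(list(raw.values())),
            np.repeat(list(raw), n),
        )
        mine = games_howell([GroupSummary.from_data(k, v) for k, v in raw.items()])
        for pr, p_tuk in zip(mine, tuk.pvalues):
            assert pr.p == pytest.approx(p_tuk, abs=0.005)

    def test_minimal_groups_df_edge(self):
        # Welch df reaches its lower bound of 1 when n=2 and one group's
        # variance dominates; the p-value must still be defined.
        (pr,) = games_howell(
            [GroupSummary("a", 2, 1.0, 5.0), GroupSummary("b", 2, 2.0, 1e-6)]
        )
        assert pr.df == pytest.approx(1.0, abs=0.01)
        assert 0.0 <= pr.p <= 1.0


def test_percent_difference():
    assert percent_difference(1.11, 0.83) == pytest.approx(33.7, abs=0.05)
    assert percent_difference(5.0, 5.0) == 0.0
    with pytest.raises(ZeroDivisionError):
        percent_difference(1.0, 0.0)


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.arange(10.0)
        assert spearman(x, x**3)[0] == pytest.approx(1.0)
        assert spearman(x, -x - 5)[0] == pytest.approx(-1.0)

    def test_tie_laden_fixture_matches_rank_formula(self, rng):
        x = rng.integers(0, 5, size=20).astype(float)
        y = rng.integers(0, 4, size=20).astype(float)
        rho, _ = spearman(x, y)
        rx = sps.rankdata(x)  # average ranks
        ry = sps.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, rel=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman(np.ones(5), np.arange(5.0))


class TestChi2:
    def test_gender_counts_fixture(self):
        chi2, p = chi2_pairwise([[17, 32], [7, 13]])
        assert p == pytest.approx(0.981, abs=0.001)

    def test_proportional_table_is_null(self):
        chi2, p = chi2_pairwise([[10, 20], [30, 60]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_formula(self, rng):
        table = rng.integers(5, 40, size=(2, 2)).astype(float)
        chi2, p = chi2_pairwise(table)
        colsum, rowsum, n = table.sum(0), table.sum(1), table.sum()
        expected = np.outer(rowsum, colsum) / n
        oracle = ((table - expected) ** 2 / expected).sum()
        assert chi2 == pytest.approx(oracle, rel=1e-12)
        assert p == pytest.approx(sps.chi2.sf(oracle, 1), rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi2_pairwise([[0, 0], [5, 3]])


class TestAncova:
    @staticmethod
    def _cohort(rng, n_per=40, effect=(0.0, 1.0, 2.0), confound=0.0):
        rows = []
        for gi, g in enumerate("abc"):
            for _ in range(n_per):
                age = rng.normal(70 + confound * gi, 8)
                sex = rng.choice(["M", "F"])
                bmi = rng.normal(27, 4)
                y = effect[gi] + 0.05 * confound * age + rng.normal()
                rows.append(dict(stage=g, age=age, sex=sex, bmi=bmi, y=y))
        return pd.DataFrame(rows)

    def test_orthogonal_covariates_reduce_to_anova(self, rng):
        df = self._cohort(rng, effect=(0.0, 0.6, 1.2))
        # orthogonalise covariates against group and outcome
        G = pd.get_dummies(df["stage"]).to_numpy(float)
        basis = np.hstack([G, df[["y"]].to_numpy()])
        for c in ("age", "bmi"):
            x = df[c].to_numpy()
            beta, *_ = np.linalg.lstsq(basis, x, rcond=None)
            df[c] = x - basis @ beta
        res = ancova_group_effect(df, "y", covariates=("age", "bmi"))
        F, _ = sps.f_oneway(*[df[df["stage"] == g]["y"] for g in "abc"])
        assert res.F == pytest.approx(F, rel=0.02)

    def test_matches_statsmodels_partial_f(self, rng):
        smf = pytest.importorskip("statsmodels.formula.api")
        sm_api = pytest.importorskip("statsmodels.api")
        df = self._cohort(rng, confound=1.0)
        res = ancova_group_effect(df, "y")
        full = smf.ols("y ~ C(stage) + age + C(sex) + bmi", df).fit()
        aov = sm_api.stats.anova_lm(full, typ=3)
        assert res.F == pytest.approx(float(aov.loc["C(stage)", "F"]), rel=1e-8)
        assert res.p == pytest.approx(float(aov.loc["C(stage)", "PR(>F)"]), rel=1e-6)

    def test_recovers_injected_group_effect_direction(self, rng):
        df = self._cohort(rng, effect=(0.0, 0.5, 1.5), confound=1.0)
        res = ancova_group_effect(df, "y")
        assert res.p < 0.001
        adj = res.adjusted_means
        assert adj["a"] < adj["b"] < adj["c"]

    def test_rank_deficiency_rejected(self, rng):
        df = self._cohort(rng)
        df["dup"] = df["age"]
        with pytest.raises(ValueError):
            ancova_group_effect(df, "y", covariates=("age", "dup", "sex"))


def test_effect_size_bands():
    assert eta_squared_label(0.005) == "negligible"
    assert eta_squared_label(0.01) == "small"
    assert eta_squared_label(0.06) == "medium"
    assert eta_squared_label(0.14) == "large"
    assert cohens_d_label(0.1) == "negligible"
    assert cohens_d_label(0.2) == "small"
    assert cohens_d_label(0.5) == "medium"
    assert cohens_d_label(0.8) == "large"


def test_stat_report_structure():
    report = stat_report(
        {"propulsion_duration": TestGamesHowell.SUMMARIES}
    )
    block = report["propulsion_duration"]
    assert block["anova"]["effect_band"] == "large"
    assert len(block["pairwise"]) == 3
    for pw in block["pairwise"]:
        assert pw["ci"][0] <= pw["ci"][1]
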