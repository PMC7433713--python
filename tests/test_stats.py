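"""Jonckheere-Terpstra trend test (exact vs asymptotic), Holm-adjusted
pairwise Wilcoxon, and the two-factor composite x carrier analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tacpgx.stats import (
    combined_two_factor,
    holm_adjust,
    jonckheere_terpstra,
    pairwise_wilcoxon_holm,
)


class TestJonckheereTerpstra:
    def test_maximal_separation_exact_p(self):
        # groups [1,2] < [3,4] < [5,6]: statistic at its maximum 12, which a
        # single split of the 90 attains, so the two-sided permutation p is
        # 2 * (1/90)
        res = jonckheere_terpstra([[1, 2], [3, 4], [5, 6]], method="exact")
        assert res.statistic == 12
        assert res.p_two_sided == pytest.approx(2 / 90)

    def test_complete_ties(self):
        res = jonckheere_terpstra([[1, 1], [1, 1], [1, 1]], method="asymptotic")
        assert res.statistic == 6.0  # half the maximum of 12
        assert res.p_two_sided == 1.0

    def test_two_groups_reduces_to_wilcoxon(self, rng):
        x = rng.normal(0, 1, 15)
        y = rng.normal(0.8, 1, 12)
        jt = jonckheere_terpstra([x, y], method="asymptotic")
        mw = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=True)
        assert jt.p_two_sided == pytest.approx(mw.pvalue, abs=1e-9)

    def test_exact_agrees_with_asymptotic_small_n(self, rng):
        # no-tie configurations with groups of 4: the continuity-corrected
        # normal approximation tracks the exact permutation p closely
        for _ in range(8):
            groups = [rng.normal(loc, 1, 4) for loc in (0.0, 0.5, 1.0)]
            pe = jonckheere_terpstra(groups, method="exact").p_two_sided
            pa = jonckheere_terpstra(groups, method="asymptotic").p_two_sided
            assert abs(pe - pa) < 0.02

    def test_exact_is_permutation_distribution(self):
        # independent oracle: recompute the exact p by explicit enumeration
        groups = [[1.0, 4.0], [2.0, 5.0], [3.0]]
        res = jonckheere_terpstra(groups, method="exact")
        pooled = [1.0, 4.0, 2.0, 5.0, 3.0]

        def jt_stat(gs):
            t = 0.0
            for a, b in itertools.combinations(gs, 2):
                for x in a:
                    for y in b:
                        t += (y > x) + 0.5 * (y == x)
            return t

        stats = []
        for perm in itertools.permutations(pooled):
            stats.append(jt_stat([perm[:2], perm[2:4], perm[4:]]))
        stats = np.array(stats)
        lower = np.mean(stats <= res.statistic + 1e-9)
        upper = np.mean(stats >= res.statistic - 1e-9)
        assert res.p_two_sided == pytest.approx(min(1.0, 2 * min(lower, upper)))

    def test_null_superuniform(self):
        rng = np.random.default_rng(99)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            groups = [rng.normal(0, 1, 10) for _ in range(3)]
            if jonckheere_terpstra(groups, method="asymptotic").p_two_sided < 0.05 - 1e-12:
                rejections += 1
        se = np.sqrt(0.05 * 0.95 / reps)
        assert rejections / reps <= 0.05 + 3 * se

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            jonckheere_terpstra([[1, 2], []])


class TestHolmWilcoxon:
    def test_hand_worked_holm(self):
        adj = holm_adjust([0.01, 0.03, 0.04])
        assert adj == pytest.approx([0.03, 0.06, 0.06])

    def test_single_pair_unchanged(self):
        assert holm_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert holm_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_monotone_and_never_smaller(self, rng):
        raw = rng.uniform(0, 1, 6)
        adj = holm_adjust(raw)
        assert np.all(adj >= raw)
        order = np.argsort(raw)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_pairwise_structure(self, rng):
        groups = {
            "Poor": rng.normal(0, 1, 20),
            "Intermediate": rng.normal(1, 1, 15),
            "Extensive": rng.normal(2, 1, 8),
        }
        results = pairwise_wilcoxon_holm(groups)
        assert len(results) == 3
        for r in results:
            assert r.holm_adjusted_p >= r.raw_p - 1e-12
            assert 0 < r.holm_adjusted_p <= 1


def _balanced_frame(rng, n_per_cell=50, comp_step=10.0, carrier_effect=-5.0, sd=4.0):
    rows = []
    for ci, comp in enumerate(("Poor", "Intermediate", "Extensive")):
        for carr, ce in (("CC", 0.0), ("T-carrier", carrier_effect)):
            y = 20.0 + comp_step * ci + ce + rng.normal(0, sd, n_per_cell)
            rows += [
                {"composite_class": comp, "abcb1_3435_carrier": carr, "y": v}
                for v in y
            ]
    return pd.DataFrame(rows)


class TestCombinedTwoFactor:
    def test_constant_phenotype(self, rng):
        df = _balanced_frame(rng, n_per_cell=5)
        df["y"] = 7.0
        res = combined_two_factor(df, ["y"])[0]
        assert res.p_abcb1 == 1.0 and res.p_composite == 1.0
        assert np.allclose(res.cell_means.to_numpy(float), 7.0)

    def test_recovers_additive_effects(self, rng):
        df = _balanced_frame(rng)
        res = combined_two_factor(df, ["y"])[0]
        assert res.p_composite < 0.05 and res.p_abcb1 < 0.05
        for ci, comp in enumerate(("Poor", "Intermediate", "Extensive")):
            for carr, ce in (("CC", 0.0), ("T-carrier", -5.0)):
                truth = 20.0 + 10.0 * ci + ce
                se = 3 * 4.0 / np.sqrt(50)
                assert abs(res.cell_means.loc[comp, carr] - truth) < 3 * se

    def test_balanced_design_matches_closed_form_anova(self, rng):
        # on a balanced design Type-II SS equal textbook two-way main-effect
        # sums of squares; compare F p-values against the closed form
        df = _balanced_frame(rng, n_per_cell=12)
        res = combined_two_factor(df, ["y"])[0]
        piv = df.pivot_table(index="composite_class", columns="abcb1_3435_carrier", values="y", aggfunc="mean")
        n = 12
        grand = df["y"].mean()
        ss_a = 2 * n * ((piv.mean(axis=1) - grand) ** 2).sum()  # composite
        ss_b = 3 * n * ((piv.mean(axis=0) - grand) ** 2).sum()  # carrier
        # residual from the main-effects model
        import statsmodels.formula.api as smf

        fit = smf.ols("y ~ C(composite_class) + C(abcb1_3435_carrier)", data=df).fit()
        ss_e, df_e = fit.ssr, fit.df_resid
        f_a = (ss_a / 2) / (ss_e / df_e)
        f_b = (ss_b / 1) / (ss_e / df_e)
        assert res.p_composite == pytest.approx(float(sps.f.sf(f_a, 2, df_e)), abs=1e-8)
        assert res.p_abcb1 == pytest.approx(float(sps.f.sf(f_b, 1, df_e)), abs=1e-8)

    def test_single_factor_degenerate_equals_oneway_anova(self, rng):
        df = _balanced_frame(rng, n_per_cell=15)
        df = df[df["abcb1_3435_carrier"] == "CC"]
        res = combined_two_factor(df, ["y"])[0]
        samples = [g["y"].to_numpy() for _, g in df.groupby("composite_class", observed=True)]
        assert res.p_composite == pytest.approx(sps.f_oneway(*samples).pvalue, abs=1e-8)
        assert np.isnan(res.p_abcb1)

    def test_empty_cell_warns_with_name(self, rng):
        df = _balanced_frame(rng, n_per_cell=8)
        df = df[~((df["composite_class"] == "Extensive") & (df["abcb1_3435_carrier"] == "CC"))]
        with pytest.warns(UserWarning, match="Extensive"):
            combined_two_factor(df, ["y"])
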