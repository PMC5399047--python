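"""Screening statistics against independent oracles: scipy's ANOVA, a
brute-force Benjamini-Hochberg step-up, t-squared identity, permutation
floors, and null calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from txpod.screen import (
    bh_adjust,
    filter_genes,
    fs_statistic,
    ls_mean_fold_changes,
    one_way_anova,
    screen_genes,
)

GROUPS = np.repeat([0, 1, 2], 3)


class TestOneWayAnova:
    def test_constant_rows_give_f0_p1(self):
        F, p = one_way_anova(np.full((2, 9), 3.14), GROUPS)
        np.testing.assert_array_equal(F, [0.0, 0.0])
        np.testing.assert_array_equal(p, [1.0, 1.0])

    def test_matches_scipy_f_oneway(self, rng):
        X = rng.normal(size=(50, 9))
        F, p = one_way_anova(X, GROUPS)
        for i in range(50):
            ref = stats.f_oneway(X[i, :3], X[i, 3:6], X[i, 6:])
            assert F[i] == pytest.approx(ref.statistic, rel=1e-10)
            assert p[i] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_sums_of_squares_decomposition(self):
        X = np.array([[1, 2, 3, 2, 3, 4, 3, 4, 5.0]])
        F, _ = one_way_anova(X, GROUPS)
        # brute force: SSB/(k-1) over SSW/(n-k)
        g = [X[0, :3], X[0, 3:6], X[0, 6:]]
        grand = X.mean()
        ssb = sum(3 * (np.mean(gi) - grand) ** 2 for gi in g)
        ssw = sum(np.sum((gi - np.mean(gi)) ** 2) for gi in g)
        assert F[0] == pytest.approx((ssb / 2) / (ssw / 6))

    def test_two_groups_equals_t_squared(self, rng):
        X = rng.normal(size=(10, 8))
        groups = np.repeat([0, 1], 4)
        F, p = one_way_anova(X, groups)
        for i in range(10):
            t = stats.ttest_ind(X[i, :4], X[i, 4:], equal_var=True)
            assert F[i] == pytest.approx(t.statistic**2, rel=1e-10)
            assert p[i] == pytest.approx(t.pvalue, rel=1e-10)

    def test_single_replicate_per_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova(np.zeros((2, 3)), [0, 1, 2])


class TestFsStatistic:
    def test_equal_residual_variances_reduce_to_f(self, rng):
        # same residual pattern per gene -> identical residual variances ->
        # the shrinkage target equals each variance and Fs == F
        resid = rng.normal(size=9)
        resid = resid - np.array([resid[:3].mean()] * 3 + [resid[3:6].mean()] * 3
                                 + [resid[6:].mean()] * 3)
        X = np.stack([resid + np.repeat([0, d, 2 * d], 3) for d in (0.0, 0.5, 1.0)])
        fs, _ = fs_statistic(X, GROUPS, n_permutations=100, rng=rng)
        F, _ = one_way_anova(X, GROUPS)
        np.testing.assert_allclose(fs, F, rtol=1e-10)

    def test_permutation_floor_for_extreme_gene(self, rng):
        B = 200
        X = rng.normal(size=(40, 9)) * 0.1
        X[0] += np.repeat([0.0, 3.0, 6.0], 3)  # one hugely responsive gene
        _, p = fs_statistic(X, GROUPS, n_permutations=B, rng=rng)
        assert p[0] == pytest.approx(1.0 / (1 + B))

    def test_null_calibration(self):
        rng = np.random.default_rng(2024)
        X = rng.normal(size=(1000, 9))
        _, p = fs_statistic(X, GROUPS, n_permutations=500, rng=rng)
        frac = np.mean(p <= 0.05)
        # binomial 99% bounds around 0.05 for 1000 genes
        bound = 2.576 * np.sqrt(0.05 * 0.95 / 1000)
        assert abs(frac - 0.05) < bound + 0.01  # permutations shared across genes

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            fs_statistic(np.zeros((5, 9)), GROUPS, n_permutations=10, rng=rng)


def _bh_oracle(p):
    """Brute force: adjusted_i = min_{j: p_(j) >= p_(i)} (m * p_(j) / rank_j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        adj[idx] = min(running, 1.0)
    return adj


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_adjust([0.5]), [0.5])

    def test_empty_input(self):
        assert len(bh_adjust([])) == 0

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60)
    )
    def test_matches_brute_force_oracle(self, p):
        np.testing.assert_allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestLsMeanFoldChanges:
    def test_fold_change_of_1p5(self):
        X = np.array([[5.0] * 3 + [5.585] * 3])
        fc = ls_mean_fold_changes(X, np.repeat([0, 1], 3))
        assert fc.iloc[0, 0] == pytest.approx(0.585)
        assert 2 ** fc.iloc[0, 0] == pytest.approx(1.5, abs=0.001)

    def test_no_change_gives_unit_fc(self):
        X = np.array([[4.0] * 6])
        fc = ls_mean_fold_changes(X, np.repeat([0, 1], 3))
        assert fc.iloc[0, 0] == 0.0

    def test_unbalanced_equals_normal_equations(self, rng):
        groups = np.array([0, 0, 0, 0, 1, 1, 2, 2, 2])
        X = rng.normal(size=(1, 9))
        fc = ls_mean_fold_changes(X, groups)
        # one-factor normal equations: cell means are the LS means
        for j, g in enumerate([1, 2]):
            expected = X[0, groups == g].mean() - X[0, groups == 0].mean()
            assert fc.iloc[0, j] == pytest.approx(expected)

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError):
            ls_mean_fold_changes(np.zeros((1, 4)), [1, 1, 2, 2], control=0)


class TestFilterGenes:
    def _screen(self):
        return pd.DataFrame(
            {
                "gene": ["a", "b", "c"],
                "p_anova": [0.01, 0.2, 0.04],
                "fdr_p": [0.01, 0.01, 0.2],
                "max_fc": [1.6, 1.4, 1.6],
                "pass_conservative": [True, False, False],
                "pass_liberal": [True, False, True],
            }
        )

    def test_conservative_needs_both_thresholds(self):
        assert filter_genes(self._screen(), "conservative") == {"a"}

    def test_liberal_uses_anova_p(self):
        assert filter_genes(self._screen(), "liberal") == {"a", "c"}

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            filter_genes(self._screen(), "strict")


class TestScreenGenes:
    def test_strong_signal_retained_by_both_modes(self):
        from txpod.simulate import SimConfig, simulate_study

        cfg = SimConfig(n_genes=150, frac_responsive=0.3, sigma=0.15,
                        effect_size=1.5, seed=21)
        study = simulate_study(cfg)
        table = screen_genes(study.expression, study.doses,
                             n_permutations=300, seed=21)
        truth = study.truth.set_index("gene")
        # genes whose asymptotic effect is >= 4 sigma
        strong = [
            g for g in truth.index
            if truth.loc[g, "family"] != "null"
        ]
        sub = table.set_index("gene").loc[strong]
        assert sub["pass_conservative"].mean() >= 0.9
        assert sub["pass_liberal"].mean() >= 0.9

    def test_null_study_liberal_retains_about_5pct(self):
        from txpod.simulate import SimConfig, simulate_study

        cfg = SimConfig(n_genes=600, frac_responsive=0.0, seed=31)
        study = simulate_study(cfg)
        table = screen_genes(study.expression, study.doses,
                             n_permutations=150, seed=31)
        frac = table["pass_liberal"].mean()
        assert 0.02 < frac < 0.09
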