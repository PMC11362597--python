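import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from apmstools.core import DesignError
from apmstools.enrichment import (
    DifferentialEnrichment,
    EBayesPrior,
    bh_adjust,
    estimate_ebayes_prior,
    fit_group_contrast,
    moderated_t,
    select_candidates,
)

from conftest import make_table, make_two_group_design


def _contrast(values, n_a, n_b):
    t = make_table(values)
    design = make_two_group_design(n_a, n_b)
    return fit_group_contrast(t, design, "BAIT_INTACT", "GST_CTRL")


class TestGroupContrast:
    def test_constant_groups(self):
        c = _contrast([[3.0, 3.0, 3.0, 5.0, 5.0, 5.0]], 3, 3)
        assert c.log2fc[0] == 2.0
        assert c.s2[0] == 0.0
        assert c.df_resid[0] == 4.0

    def test_identical_groups_have_zero_fc(self, rng):
        half = rng.normal(25, 1, size=(20, 3))
        c = _contrast(np.hstack([half, half]), 3, 3)
        np.testing.assert_allclose(c.log2fc, 0.0, atol=1e-12)

    def test_hand_computed_pooled_variance(self):
        # bait (4, 6) vs ctrl (1, 3): fc 3, pooled s2 = (2 + 2)/2 = 2, df 2
        c = _contrast([[1.0, 3.0, 4.0, 6.0]], 2, 2)
        assert c.log2fc[0] == 3.0
        assert c.s2[0] == pytest.approx(2.0)
        assert c.df_resid[0] == 2.0
        assert c.avg_expr[0] == pytest.approx(3.5)

    def test_absent_condition_is_an_error(self):
        t = make_table([[1.0, 2.0, 3.0, 4.0]])
        design = make_two_group_design(2, 2)
        with pytest.raises(DesignError):
            fit_group_contrast(t, design, "COIP_BAIT", "GST_CTRL")


class TestPriorEstimation:
    def test_equal_variances_give_infinite_d0(self):
        prior = estimate_ebayes_prior([1.0, 1.0, 1.0], 4.0)
        assert math.isinf(prior.d0)
        assert prior.s0sq == pytest.approx(1.0)

    def test_two_equal_variances(self):
        prior = estimate_ebayes_prior([1.0, 1.0], 4.0)
        assert prior.s0sq == pytest.approx(1.0)

    def test_recovers_known_hyperparameters(self):
        rng = np.random.default_rng(2024)
        d0_true, s0_true, d = 4.0, 1.0, 10
        true_var = s0_true * d0_true / rng.chisquare(d0_true, size=5000)
        s2 = true_var * rng.chisquare(d, size=5000) / d
        prior = estimate_ebayes_prior(s2, float(d))
        assert prior.d0 == pytest.approx(d0_true, rel=0.15)
        assert prior.s0sq == pytest.approx(s0_true, rel=0.05)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError):
            estimate_ebayes_prior([0.0, 0.0], 4.0)


class TestModeratedT:
    def test_no_shrinkage_limit_is_ordinary_t(self, rng):
        values = rng.normal(25, 1, size=(15, 8))
        c = _contrast(values, 4, 4)
        res = moderated_t(c, EBayesPrior(d0=1e-12, s0sq=1.0))
        ref = stats.ttest_ind(values[:, 4:], values[:, :4], axis=1)
        np.testing.assert_allclose(res.t_mod, ref.statistic, rtol=1e-6)
        np.testing.assert_allclose(res.p_value, ref.pvalue, rtol=1e-6)

    def test_full_shrinkage_limit_uses_prior_variance(self, rng):
        c = _contrast(rng.normal(25, 1, size=(10, 8)), 4, 4)
        res = moderated_t(c, EBayesPrior(d0=math.inf, s0sq=0.7))
        np.testing.assert_allclose(res.s2_post, 0.7)
        se = math.sqrt(0.7 * (1 / 4 + 1 / 4))
        np.testing.assert_allclose(res.t_mod, c.log2fc / se, rtol=1e-12)

    def test_matches_limma_reference_fixture(self):
        """Frozen reference values computed with R bioconductor-limma 3.58.1
        (lmFit + eBayes) on this exact generated matrix."""
        rng = np.random.default_rng(20240601)
        X = rng.normal(25, 1, size=(10, 8))
        X[:3, 4:] += np.array([3.0, 1.5, 0.5])[:, None]
        c = _contrast(X, 4, 4)
        prior = estimate_ebayes_prior(c.s2.to_numpy(), c.df_resid.to_numpy())
        assert prior.d0 == pytest.approx(16.0909653057, rel=1e-9)
        assert prior.s0sq == pytest.approx(0.858398053224, rel=1e-9)
        res = moderated_t(c, prior)
        ref_t = np.array([
            6.361300276655919, 0.748681450811828, 0.337673610048105,
            1.052341827987358, 1.028008061748619, -0.366711508057025,
            -0.605874487218179, 1.256124507470860, -0.321149260716647,
            0.852147241492708,
        ])
        ref_p = np.array([
            2.07439741656216e-06, 4.61946865307416e-01, 7.38796839794795e-01,
            3.04018204815942e-01, 3.15071245645726e-01, 7.17323329170596e-01,
            5.50773229069596e-01, 2.22193314347488e-01, 7.51115893519487e-01,
            4.03276474643585e-01,
        ])
        np.testing.assert_allclose(res.t_mod, ref_t, atol=1e-6)
        np.testing.assert_allclose(res.p_value, ref_p, atol=1e-6)

    def test_continuity_in_d0(self, rng):
        c = _contrast(rng.normal(25, 1, size=(12, 8)), 4, 4)
        prev = moderated_t(c, EBayesPrior(d0=1e-9, s0sq=1.0)).t_mod.to_numpy()
        for d0 in (0.01, 1.0, 100.0, 1e6):
            cur = moderated_t(c, EBayesPrior(d0=d0, s0sq=1.0)).t_mod.to_numpy()
            assert np.all(np.isfinite(cur))
            prev = cur
        z = moderated_t(c, EBayesPrior(d0=math.inf, s0sq=1.0)).t_mod.to_numpy()
        np.testing.assert_allclose(cur, z, rtol=1e-4)


def brute_force_bh(p):
    """Literal step-up: adj_(i) = min_{j >= i} p_(j) * n / j, capped at 1."""
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    for rank, i in enumerate(order, start=1):
        best = min(
            p[order[j - 1]] * n / j for j in range(rank, n + 1)
        )
        adj[i] = min(best, 1.0)
    return adj


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ((0.01, 0.02, 0.03, 0.04), (0.04, 0.04, 0.04, 0.04)),
            ((0.005, 0.1), (0.01, 0.1)),
            ((0.5,), (0.5,)),
        ],
    )
    def test_hand_computed_cases(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected)

    def test_matches_brute_force_on_small_grids(self):
        grid = [0.001, 0.01, 0.04, 0.2, 0.5, 1.0]
        rng = np.random.default_rng(0)
        for n in range(1, 6):
            for _ in range(40):
                p = rng.choice(grid, size=n).tolist()
                np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), rtol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=20))
    def test_properties_and_statsmodels_agreement(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)
        # order statistics of adjusted values are monotone in those of p
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        sm = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(adj, sm, rtol=1e-10)

    def test_rejects_out_of_range(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [np.nan]):
            with pytest.raises(ValueError):
                bh_adjust(bad)


class TestSelectCandidates:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["protein_id", "log2fc", "adj_p"])

    @pytest.mark.parametrize(
        "log2fc, adj_p, selected",
        [
            (3.08, 1e-4, True),   # strong, significant enrichment
            (1.9, 1e-4, False),   # below the fold-change cut
            (4.0, 0.02, False),   # above alpha
            (-4.0, 1e-4, False),  # depleted, one-directional default
        ],
    )
    def test_default_thresholds(self, log2fc, adj_p, selected):
        out = select_candidates(self._frame([("P1", log2fc, adj_p)]))
        assert (len(out) == 1) is selected

    def test_both_directions_mode(self):
        out = select_candidates(
            self._frame([("P1", -4.0, 1e-4)]), direction="both"
        )
        assert len(out) == 1


class TestModelInterface:
    def test_fit_produces_consistent_results_object(self, rng):
        values = rng.normal(25, 0.5, size=(60, 12))
        values[:5, 6:] += 4.0
        t = make_table(values)
        design = make_two_group_design(6, 6)
        res = DifferentialEnrichment(t, design, "BAIT_INTACT", "GST_CTRL").fit()
        assert set(res.candidates["protein_id"]) == {f"P{i}" for i in range(5)}
        assert (res.frame["adj_p"] >= res.frame["p_value"] - 1e-15).all()
        sig = res.frame["significant"]
        manual = (res.frame["adj_p"] < 0.01) & (res.frame["log2fc"] >= 2.0)
        assert sig.equals(manual)
        assert "candidates:      5" in res.summary()
        vol = res.volcano_coords()
        assert len(vol) == 60 and {"log2fc", "neg_log10_adj_p"} <= set(vol.columns)
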