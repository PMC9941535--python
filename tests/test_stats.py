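"""Statistical core: Pearson/t tests vs permutation oracles, BH-FDR vs
hand enumeration and statsmodels, screening behavior."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from uafc.connectivity import ROITimeSeries, fc_fisher_z
from uafc.stats import (
    bh_fdr,
    edge_group_test,
    pearson_test,
    pearson_p_from_r,
    screen_rois,
    t_test_p_from_t,
    two_sample_t,
)


class TestPearson:
    @pytest.mark.parametrize(
        "r,n,expected_p",
        [
            (0.444, 32, 0.011),   # published screening example
            (-0.431, 32, 0.014),  # published screening example
            (0.425, 32, 0.015),
            (-0.350, 32, 0.049),
        ],
    )
    def test_reported_r_reproduces_reported_p(self, r, n, expected_p):
        """The analytic t transform of a published correlation reproduces
        its published p-value to within one unit of printed precision."""
        assert pearson_p_from_r(r, n) == pytest.approx(expected_p, abs=1e-3)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 25))
        r, t, p = pearson_test(x, y)
        ref = sps.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_perfect_correlation_limits(self):
        x = np.arange(10.0)
        r, t, p = pearson_test(x, x)
        assert (r, p) == (1.0, 0.0)
        r2, _, p2 = pearson_test(x, -2 * x + 3)
        assert (r2, p2) == (-1.0, 0.0)

    def test_analytic_p_within_permutation_oracle_error(self):
        """Two-tailed analytic p agrees with a 10^5-permutation null at n=20."""
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal((2, 20))
        r_obs, _, p_analytic = pearson_test(x, y)
        n_perm = 100_000
        perm_r = np.empty(n_perm)
        yc = y - y.mean()
        xc = x - x.mean()
        xn = xc / np.linalg.norm(xc)
        for i in range(n_perm):
            yp = yc[rng.permutation(20)]
            perm_r[i] = xn @ yp / np.linalg.norm(yp)
        p_perm = (np.sum(np.abs(perm_r) >= abs(r_obs) - 1e-12) + 1) / (n_perm + 1)
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p_analytic - p_perm) < max(4 * se, 0.01)

    @pytest.mark.parametrize("bad", [np.ones(5), np.zeros(5)])
    def test_constant_input_errors(self, bad):
        with pytest.raises(ValueError, match="constant"):
            pearson_test(bad, np.arange(5.0))

    def test_short_input_errors(self):
        with pytest.raises(ValueError):
            pearson_test([1.0, 2.0], [3.0, 4.0])


class TestTwoSampleT:
    def test_reported_t_reproduces_reported_p_at_df61(self):
        """t = -3.402 at 32+31-2 = 61 df gives two-tailed p = 0.001."""
        assert t_test_p_from_t(-3.402, 61) == pytest.approx(0.001, abs=5e-4)
        for t in (-3.745, -3.704, -3.473):
            assert t_test_p_from_t(t, 61) < 0.001

    def test_matches_scipy_pooled(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal(12), rng.standard_normal(15) + 0.4
        t, p = two_sample_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_identical_samples_give_t0_p1(self):
        a = np.array([1.0, 2.0, 3.5, 4.0])
        t, p = two_sample_t(a, a.copy())
        assert t == 0.0
        assert p == 1.0

    def test_within_permutation_oracle_error(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(12)
        b = rng.standard_normal(12) + 0.5
        t_obs, p_analytic = two_sample_t(a, b)
        pooled = np.r_[a, b]
        n_perm = 50_000
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(24)
            t_p, _ = two_sample_t(pooled[perm[:12]], pooled[perm[12:]])
            count += abs(t_p) >= abs(t_obs) - 1e-12
        p_perm = (count + 1) / (n_perm + 1)
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p_analytic - p_perm) < max(4 * se, 0.012)

    def test_zero_pooled_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            two_sample_t([1.0, 1.0], [1.0, 1.0])


def _bh_oracle(pvals, q):
    """Textbook step-up enumeration: find the largest k with
    p_(k) <= k*q/m; reject the k smallest p-values."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if pvals[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, bool)
    reject[order[:k_star]] = True
    return reject


class TestBHFDR:
    def test_single_p_below_q_rejected(self):
        adj, rej = bh_fdr(np.array([0.04]), q=0.05)
        assert adj[0] == pytest.approx(0.04)
        assert rej[0]

    def test_hand_worked_step_up(self):
        """m=4, p=(.01,.02,.03,.04): adjusted all 0.04, all rejected."""
        adj, rej = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]), q=0.05)
        np.testing.assert_allclose(adj, 0.04, atol=1e-12)
        assert rej.all()

    def test_all_ones_rejects_none(self):
        _, rej = bh_fdr(np.ones(7), q=0.05)
        assert not rej.any()

    def test_exhaustive_small_grid_matches_enumeration_oracle(self):
        """Every p-vector of length <= 6 over a 0.1 grid matches the
        step-up enumeration exactly."""
        grid = np.array([0.001, 0.02, 0.04, 0.051, 0.2, 1.0])
        for m in range(1, 7):
            for combo in itertools.combinations_with_replacement(grid, m):
                p = np.array(combo)
                _, rej = bh_fdr(p, q=0.05)
                np.testing.assert_array_equal(rej, _bh_oracle(p, 0.05), err_msg=str(p))

    def test_matches_statsmodels_on_random_inputs(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            adj, rej = bh_fdr(p, q=0.05)
            ref_rej, ref_adj, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_allclose(adj, ref_adj, atol=1e-12)
            # statsmodels rejects at <=, we at <; differences only at exact ties
            disagree = rej != ref_rej
            assert np.all(np.isclose(adj[disagree], 0.05)) if disagree.any() else True

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 15)
        perm = rng.permutation(15)
        adj, rej = bh_fdr(p)
        adj_p, rej_p = bh_fdr(p[perm])
        np.testing.assert_allclose(adj_p, adj[perm], atol=1e-15)
        np.testing.assert_array_equal(rej_p, rej[perm])

    def test_out_of_range_p_errors(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))


class TestScreenRois:
    def _table(self, n=32, n_rois=10, seed=6, planted=None):
        rng = np.random.default_rng(seed)
        ua = rng.normal(300, 80, n)
        cols = {}
        for roi in range(1, n_rois + 1):
            noise = rng.standard_normal(n)
            if planted and roi in planted:
                z = (ua - ua.mean()) / ua.std()
                cols[roi] = 0.7 * z + 0.7 * noise
            else:
                cols[roi] = noise
        return pd.DataFrame(cols), ua

    def test_planted_rois_selected(self):
        table, ua = self._table(planted={2, 5})
        out = screen_rois(table, ua)
        assert set(out.loc[out.selected, "roi_id"]) >= {2, 5}

    def test_reported_r_fixture_selects_all_15(self):
        """A cohort whose per-ROI correlations equal the 15 published r
        values at n=32 yields 15 selected ROIs at uncorrected p<0.05."""
        from uafc.reference import ROI_SCREEN_ROWS

        rng = np.random.default_rng(7)
        n = 32
        ua = rng.normal(300, 80, n)
        z = (ua - ua.mean()) / ua.std(ddof=0)
        cols = {}
        for idx, _, r in ROI_SCREEN_ROWS:
            noise = rng.standard_normal(n)
            noise -= noise @ z / (z @ z) * z  # exact orthogonalization
            noise /= noise.std()
            cols[idx] = r * z + np.sqrt(1 - r**2) * noise
        out = screen_rois(pd.DataFrame(cols), ua)
        assert int(out.selected.sum()) == 15
        got = dict(zip(out.roi_id, out.r))
        for idx, _, r in ROI_SCREEN_ROWS:
            assert got[idx] == pytest.approx(r, abs=1e-9)

    def test_alpha_zero_selects_none(self):
        table, ua = self._table(planted={2})
        out = screen_rois(table, ua, alpha=0.0)
        assert not out.selected.any()

    def test_null_false_positive_rate_near_alpha(self):
        """Shuffled UA: expected selections ~ alpha * n_rois."""
        hits, trials, n_rois = 0, 40, 20
        for seed in range(trials):
            table, ua = self._table(n_rois=n_rois, seed=100 + seed)
            out = screen_rois(table, ua, alpha=0.05)
            hits += int(out.selected.sum())
        rate = hits / (trials * n_rois)
        assert 0.01 < rate < 0.10  # 0.05 +- Monte-Carlo error

    def test_bh_mode_is_more_conservative(self):
        table, ua = self._table(planted={2, 5})
        raw = screen_rois(table, ua, correction="none")
        bh = screen_rois(table, ua, correction="bh")
        assert bh.selected.sum() <= raw.selected.sum()

    def test_column_order_invariance(self):
        table, ua = self._table(planted={3})
        shuffled = table[list(reversed(table.columns))]
        a = screen_rois(table, ua)
        b = screen_rois(shuffled, ua)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_values_error(self):
        table, ua = self._table()
        table.iloc[3, 2] = np.nan
        with pytest.raises(ValueError, match="imputation"):
            screen_rois(table, ua)


def _zfc_group(rng, n_subjects, k=6, offset_edges=(), offset=0.0, t_len=60):
    out = []
    for _ in range(n_subjects):
        data = rng.standard_normal((k, t_len))
        for i, j in offset_edges:
            shared = rng.standard_normal(t_len)
            data[i] = data[i] + offset * shared
            data[j] = data[j] + offset * shared
        out.append(fc_fisher_z(ROITimeSeries(list(range(1, k + 1)), data)))
    return out


class TestEdgeGroupTest:
    def test_edge_count_is_k_choose_2(self):
        rng = np.random.default_rng(8)
        res = edge_group_test(_zfc_group(rng, 4, k=15), _zfc_group(rng, 4, k=15))
        assert res.n_edges == 105

    def test_null_groups_rarely_select(self):
        rng = np.random.default_rng(9)
        any_hits = 0
        for _ in range(10):
            res = edge_group_test(_zfc_group(rng, 10), _zfc_group(rng, 10))
            any_hits += bool(res.selected_edges)
        assert any_hits <= 2

    def test_planted_offset_edges_selected(self):
        rng = np.random.default_rng(10)
        hc = _zfc_group(rng, 16, offset_edges=[(0, 1), (2, 3)], offset=1.2, t_len=120)
        pd_ = _zfc_group(rng, 16, t_len=120)
        res = edge_group_test(pd_, hc)
        assert set(res.selected_edges) == {(2, 1), (4, 3)}
        # planted PD<HC direction gives negative t
        sel = res.table[res.table.selected]
        assert (sel.t < 0).all()

    def test_t_matrix_is_symmetric_with_zero_diagonal(self):
        rng = np.random.default_rng(11)
        res = edge_group_test(_zfc_group(rng, 5), _zfc_group(rng, 5))
        tm = res.t_matrix.to_numpy()
        np.testing.assert_allclose(tm, tm.T, atol=0)
        np.testing.assert_allclose(np.diag(tm), 0.0)

    def test_roi_order_mismatch_errors(self):
        rng = np.random.default_rng(12)
        a = _zfc_group(rng, 3)
        b = _zfc_group(rng, 3)
        b[0].roi_ids = list(reversed(b[0].roi_ids))
        with pytest.raises(ValueError, match="mismatch"):
            edge_group_test(a, b)

    def test_welch_option_runs(self):
        rng = np.random.default_rng(13)
        res = edge_group_test(_zfc_group(rng, 6), _zfc_group(rng, 6), method="welch")
        assert res.n_edges == 15
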