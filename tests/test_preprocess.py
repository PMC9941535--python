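"""Denoising chain: QC, Friston-24, smoothing, band-pass, nuisance regression."""

import numpy as np
import pytest

from uafc.io import SubjectRecord, Volume4D
from uafc.preprocess import (
    MotionParams,
    detrend_bandpass,
    friston24_expand,
    gaussian_smooth,
    load_motion,
    nuisance_regress,
    preprocess_subject,
    qc_exclude,
)


def _records(n, group="HC"):
    return [
        SubjectRecord(subject_id=f"s{i}", group=group, ua_umol_l=300.0)
        for i in range(n)
    ]


class TestQC:
    def test_planted_spike_excludes_exactly_one(self):
        """32 controls with one 3.5 mm spike -> 31 retained."""
        recs = _records(32)
        motion = {f"s{i}": MotionParams(np.zeros((50, 6))) for i in range(32)}
        spiked = np.zeros((50, 6))
        spiked[20, 1] = 3.5
        motion["s7"] = MotionParams(spiked)
        kept, report = qc_exclude(recs, motion)
        assert len(kept) == 31
        assert [e for e in report["subjects"] if e.get("excluded")][0]["subject_id"] == "s7"

    def test_all_zero_motion_retains_all(self):
        recs = _records(5)
        motion = {r.subject_id: MotionParams(np.zeros((10, 6))) for r in recs}
        kept, _ = qc_exclude(recs, motion)
        assert len(kept) == 5

    @pytest.mark.parametrize(
        "peak,expect_kept", [(3.0, True), (3.0000001, False), (2.999, True)]
    )
    def test_threshold_is_strict_inequality(self, peak, expect_kept):
        """Exactly 3.0 mm is retained; only motion *exceeding* 3.0 excludes."""
        recs = _records(1)
        m = np.zeros((10, 6))
        m[4, 0] = peak
        kept, _ = qc_exclude(recs, {"s0": MotionParams(m)})
        assert bool(kept) is expect_kept

    def test_rotation_threshold_applies_too(self):
        recs = _records(1)
        m = np.zeros((10, 6))
        m[4, 5] = 3.2  # degrees
        kept, _ = qc_exclude(recs, {"s0": MotionParams(m)})
        assert not kept

    def test_missing_motion_excludes_with_reason(self):
        recs = _records(2)
        motion = {"s0": MotionParams(np.zeros((10, 6)))}
        kept, report = qc_exclude(recs, motion)
        assert len(kept) == 1
        missing = [e for e in report["subjects"] if e["subject_id"] == "s1"][0]
        assert missing["reason"] == "no_motion"


class TestFriston24:
    def test_shape_and_names(self):
        cols, names = friston24_expand(MotionParams(np.random.default_rng(0).normal(size=(20, 6))))
        assert cols.shape == (20, 24)
        assert len(names) == 24

    def test_zero_motion_gives_zero_block(self):
        cols, _ = friston24_expand(MotionParams(np.zeros((10, 6))))
        assert not cols.any()

    def test_single_impulse_enumeration_oracle(self):
        """An impulse at frame k appears lagged at k+1 and squared in both."""
        m = np.zeros((8, 6))
        k, val = 3, 0.7
        m[k, 2] = val
        cols, names = friston24_expand(MotionParams(m))
        expected = np.zeros((8, 24))
        expected[k, 2] = val          # R_t
        expected[k + 1, 8] = val      # R_{t-1} (lag block cols 6..11)
        expected[k, 14] = val**2      # R_t^2 (cols 12..17)
        expected[k + 1, 20] = val**2  # R_{t-1}^2 (cols 18..23)
        np.testing.assert_allclose(cols, expected)

    def test_lag_at_first_frame_is_zero(self):
        m = np.random.default_rng(1).normal(size=(12, 6))
        cols, _ = friston24_expand(MotionParams(m))
        assert not cols[0, 6:12].any()
        assert not cols[0, 18:24].any()


class TestGaussianSmooth:
    def test_fwhm_zero_is_identity(self, random_volume):
        out = gaussian_smooth(random_volume, 0.0)
        np.testing.assert_array_equal(out.data, random_volume.data)

    def test_constant_image_unchanged_in_mask(self, random_volume):
        vol = random_volume.with_data(np.full_like(random_volume.data, 5.0))
        vol.data[~vol.mask] = 0.0
        out = gaussian_smooth(vol, 6.0)
        np.testing.assert_allclose(out.data[vol.mask], 5.0, atol=1e-6)

    def test_impulse_matches_bruteforce_convolution(self):
        """6 mm FWHM at 3 mm voxels: sigma ~ 0.849 voxels; compare against a
        direct discrete Gaussian convolution on a full mask."""
        shape = (9, 9, 9)
        data = np.zeros((*shape, 2))
        data[4, 4, 4, :] = 1.0
        vol = Volume4D(
            data, np.diag([3.0, 3.0, 3.0, 1.0]), (3.0, 3.0, 3.0), 2.0,
            np.ones(shape, bool),
        )
        out = gaussian_smooth(vol, 6.0)
        sigma = 6.0 / (2 * np.sqrt(2 * np.log(2))) / 3.0
        assert sigma == pytest.approx(0.8493, abs=1e-3)
        ax = np.arange(-15, 16)
        g1 = np.exp(-(ax**2) / (2 * sigma**2))
        g1 /= g1.sum()
        brute = np.zeros(shape)
        for i, gi in zip(ax, g1):
            for j, gj in zip(ax, g1):
                for k, gk in zip(ax, g1):
                    x, y, z = 4 + i, 4 + j, 4 + k
                    if 0 <= x < 9 and 0 <= y < 9 and 0 <= z < 9:
                        brute[x, y, z] += gi * gj * gk
        # interior normalization differs only at the (truncated) borders
        np.testing.assert_allclose(out.data[2:7, 2:7, 2:7, 0], brute[2:7, 2:7, 2:7], atol=2e-4)

    def test_negative_fwhm_errors(self, random_volume):
        with pytest.raises(ValueError):
            gaussian_smooth(random_volume, -1.0)

    def test_out_of_mask_zeros_do_not_bleed_in(self):
        shape = (7, 7, 7)
        data = np.full((*shape, 2), 3.0)
        mask = np.zeros(shape, bool)
        mask[2:5, 2:5, 2:5] = True
        data[~mask] = 0.0
        vol = Volume4D(data, np.eye(4), (3.0, 3.0, 3.0), 2.0, mask)
        out = gaussian_smooth(vol, 8.0)
        np.testing.assert_allclose(out.data[mask], 3.0, atol=1e-6)


class TestDetrendBandpass:
    tr = 2.0

    def _sine(self, f, n=232):
        t = np.arange(n) * self.tr
        return np.sin(2 * np.pi * f * t)[None, :]

    def test_in_band_sinusoid_preserved(self):
        """0.04 Hz lies mid-band; amplitude must survive at >= 99%."""
        x = self._sine(0.04)
        y = detrend_bandpass(x, self.tr)
        assert np.ptp(y) >= 0.99 * np.ptp(x)

    def test_below_band_sinusoid_removed(self):
        """A 0.005 Hz probe is attenuated to ~0: its best-fit amplitude in
        the output is < 10% (the residual is finite-window leakage into the
        pass band, which any ideal frequency-domain filter shares)."""
        x = self._sine(0.005)
        y = detrend_bandpass(x, self.tr)
        t = np.arange(x.shape[1]) * self.tr
        D = np.column_stack([np.sin(2 * np.pi * 0.005 * t), np.cos(2 * np.pi * 0.005 * t)])
        beta, *_ = np.linalg.lstsq(D, y.ravel(), rcond=None)
        assert np.hypot(*beta) < 0.1
        assert np.sqrt((y**2).mean()) < 0.25 * np.sqrt((x**2).mean())

    def test_on_bin_stopband_sinusoid_vanishes(self):
        """A sub-band sinusoid on an exact Fourier bin leaves no residual."""
        n = 232
        k = 2  # f = k / (n * tr) ~ 0.0043 Hz, well below the 0.01 Hz edge
        t = np.arange(n)
        x = np.sin(2 * np.pi * k * t / n)[None, :]
        y = detrend_bandpass(x, self.tr)
        assert np.abs(y).max() < 1e-8

    def test_constant_series_becomes_zero(self):
        y = detrend_bandpass(np.full((1, 64), 9.0), self.tr)
        np.testing.assert_allclose(y, 0.0, atol=1e-10)

    def test_output_mean_is_zero(self):
        rng = np.random.default_rng(3)
        y = detrend_bandpass(rng.standard_normal((5, 100)), self.tr)
        np.testing.assert_allclose(y.mean(axis=1), 0.0, atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        once = detrend_bandpass(rng.standard_normal((3, 120)), self.tr)
        twice = detrend_bandpass(once, self.tr)
        np.testing.assert_allclose(twice, once, atol=1e-10)

    @pytest.mark.parametrize("low,high", [(0.0, 0.08), (0.01, 0.3), (0.08, 0.01)])
    def test_invalid_band_errors(self, low, high):
        with pytest.raises(ValueError):
            detrend_bandpass(np.zeros((1, 64)), self.tr, low, high)

    def test_too_few_frames_errors(self):
        with pytest.raises(ValueError, match="8 frames"):
            detrend_bandpass(np.zeros((1, 5)), self.tr)


class TestNuisanceRegress:
    def test_residuals_match_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        ts = rng.standard_normal((7, 50))
        C = np.column_stack([rng.standard_normal((50, 3)), np.ones(50)])
        resid = nuisance_regress(ts, C)
        oracle = ts.T - C @ np.linalg.solve(C.T @ C, C.T @ ts.T)
        np.testing.assert_allclose(resid, oracle.T, atol=1e-8)

    def test_residuals_orthogonal_to_confounds(self):
        rng = np.random.default_rng(6)
        ts = rng.standard_normal((10, 60))
        C = np.column_stack([rng.standard_normal((60, 5)), np.ones(60)])
        resid = nuisance_regress(ts, C)
        proj = np.abs(resid @ C) / (
            np.linalg.norm(resid, axis=1, keepdims=True) * np.linalg.norm(C, axis=0)
        )
        assert proj.max() < 1e-8

    def test_ts_equal_to_confound_column_gives_zero(self):
        rng = np.random.default_rng(7)
        col = rng.standard_normal(40)
        C = np.column_stack([col, np.ones(40)])
        resid = nuisance_regress(col[None, :], C)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_constant_only_confound_mean_centers(self):
        rng = np.random.default_rng(8)
        ts = rng.standard_normal((4, 30)) + 5.0
        resid = nuisance_regress(ts, np.ones((30, 1)))
        np.testing.assert_allclose(resid, ts - ts.mean(axis=1, keepdims=True), atol=1e-10)

    def test_rank_deficient_design_names_columns(self):
        rng = np.random.default_rng(9)
        a = rng.standard_normal(30)
        C = np.column_stack([a, 2 * a, np.ones(30)])
        with pytest.raises(ValueError, match="dup"):
            nuisance_regress(rng.standard_normal((2, 30)), C, names=["a", "dup", "const"])


class TestPreprocessSubject:
    # 200 frames: the 0.01-0.08 Hz subspace (~57 dims) must exceed the 26
    # confound columns, otherwise regression absorbs the whole band
    n_t = 200

    def _inputs(self):
        rng = np.random.default_rng(10)
        shape = (6, 6, 4)
        data = rng.standard_normal((*shape, self.n_t)).astype(float) + 100
        mask = np.ones(shape, bool)
        vol = Volume4D(data, np.eye(4), (3.0, 3.0, 3.0), 2.0, mask)
        motion = MotionParams(np.cumsum(rng.normal(0, 0.01, size=(self.n_t, 6)), axis=0))
        return vol, motion

    def test_residuals_orthogonal_to_motion(self):
        vol, motion = self._inputs()
        ts = preprocess_subject(vol, motion, fwhm_mm=0.0)
        assert np.linalg.norm(ts, axis=1).min() > 1e-6  # nondegenerate residuals
        f24 = np.column_stack([motion.values, motion.values**2])
        # residuals orthogonal to the filtered confound space implies near-
        # zero correlation with the raw in-band motion content
        from uafc.preprocess import detrend_bandpass

        filt = detrend_bandpass(f24.T, 2.0).T
        proj = np.abs(ts @ filt) / (
            np.linalg.norm(ts, axis=1, keepdims=True) * np.linalg.norm(filt, axis=0) + 1e-30
        )
        assert proj.max() < 1e-7

    def test_order_must_be_permutation(self):
        vol, motion = self._inputs()
        with pytest.raises(ValueError, match="order"):
            preprocess_subject(vol, motion, order=("smooth", "filter"))

    def test_zero_motion_is_handled(self):
        vol, _ = self._inputs()
        ts = preprocess_subject(vol, MotionParams(np.zeros((self.n_t, 6))), fwhm_mm=0.0)
        assert ts.shape == (vol.mask.sum(), self.n_t)

    def test_frame_mismatch_errors(self):
        vol, _ = self._inputs()
        with pytest.raises(ValueError, match="frames"):
            preprocess_subject(vol, MotionParams(np.zeros((self.n_t - 1, 6))))


def test_load_motion_discards_leading_rows(tmp_path):
    vals = np.arange(60.0).reshape(10, 6)
    path = tmp_path / "m.txt"
    np.savetxt(path, vals)
    m = load_motion(path, discard_leading=3)
    assert m.n_frames == 7
    np.testing.assert_allclose(m.values[0], vals[3])
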