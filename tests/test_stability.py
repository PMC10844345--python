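import numpy as np
import pytest
from scipy.stats import rankdata

from surfstab.stability import (BoldSeries, DfcStack, WindowSpec, bandpass,
                                discard_initial, friston24, kendalls_w,
                                make_windows, qc_motion, regress_confounds,
                                stability_map, windowed_fc, zscore_map)
from surfstab.synthetic import MotionTrace

from oracles import brute_force_w, naive_vertex_stability


def make_bold(data, tr=2.0):
    return BoldSeries(np.asarray(data, float), tr)


class TestQcMotion:
    def test_still_subject_passes(self):
        assert qc_motion(MotionTrace(np.zeros((10, 6))))

    def test_translation_beyond_limit_fails(self):
        p = np.zeros((10, 6))
        p[4, 1] = 2.6
        res = qc_motion(MotionTrace(p))
        assert not res and "translation" in res.reason

    def test_boundary_is_strict(self):
        p = np.zeros((10, 6))
        p[4, 4] = 2.5
        assert qc_motion(MotionTrace(p))


class TestDiscardInitial:
    def test_drops_requested_volumes(self):
        b = make_bold(np.arange(2 * 180).reshape(2, 180))
        out = discard_initial(b, 10)
        assert out.n_timepoints == 170
        np.testing.assert_array_equal(out.data[0], np.arange(10, 180))

    def test_zero_is_identity(self):
        b = make_bold(np.random.default_rng(0).normal(size=(3, 20)))
        np.testing.assert_array_equal(discard_initial(b, 0).data, b.data)

    def test_too_many_rejected(self):
        with pytest.raises(ValueError):
            discard_initial(make_bold(np.ones((2, 5))), 10)


class TestFriston24:
    def test_zero_trace_gives_zero_table(self):
        assert not friston24(MotionTrace(np.zeros((12, 6)))).any()

    def test_shape_and_structure(self, rng):
        p = rng.standard_normal((30, 6))
        f = friston24(MotionTrace(p))
        assert f.shape == (30, 24)
        np.testing.assert_array_equal(f[:, :6], p)
        np.testing.assert_array_equal(f[0, 6:12], 0.0)
        np.testing.assert_array_equal(f[1:, 6:12], p[:-1])  # one-volume lag
        np.testing.assert_array_equal(f[:, 12:18], p ** 2)
        np.testing.assert_array_equal(f[1:, 18:24], p[:-1] ** 2)


class TestRegressConfounds:
    def test_linear_ramp_fully_removed(self):
        t = np.arange(50, dtype=float)
        b = make_bold(np.vstack([2 * t + 1, -t + 3]))
        out = regress_confounds(b, t[:, None])
        np.testing.assert_allclose(out.data, 0.0, atol=1e-9)

    def test_empty_confounds_mean_center(self, rng):
        b = make_bold(rng.standard_normal((4, 30)) + 5)
        out = regress_confounds(b, None)
        np.testing.assert_allclose(out.data.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.data, b.data - b.data.mean(1, keepdims=True))

    def test_residuals_orthogonal_to_confounds(self, rng):
        conf = rng.standard_normal((60, 5))
        signal = rng.standard_normal((8, 60)) + conf[:, 0] * 2.0
        out = regress_confounds(make_bold(signal), conf)
        for j in range(5):
            r = np.abs([np.corrcoef(row, conf[:, j])[0, 1]
                        for row in out.data])
            assert (r < 1e-10).all()

    def test_collinear_design_rejected_with_columns(self, rng):
        c = rng.standard_normal((30, 2))
        conf = np.hstack([c, c[:, :1] * 2.0])
        with pytest.raises(ValueError, match="collinear"):
            regress_confounds(make_bold(rng.standard_normal((2, 30))), conf)


class TestBandpass:
    def test_in_band_sinusoid_preserved(self):
        t = np.arange(200) * 2.0
        sig = np.sin(2 * np.pi * 0.05 * t)
        out = bandpass(make_bold(sig[None, :]), 0.01, 0.1)
        assert abs(out.data.std() / sig.std() - 1.0) < 0.01

    def test_out_of_band_sinusoid_rejected(self):
        t = np.arange(200) * 2.0
        sig = np.sin(2 * np.pi * 0.2 * t)
        out = bandpass(make_bold(sig[None, :]), 0.01, 0.1)
        assert out.data.std() < 0.01 * sig.std()

    def test_constant_signal_zeroed(self):
        out = bandpass(make_bold(np.full((2, 64), 7.0)), 0.01, 0.1)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-10)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(make_bold(np.ones((1, 64))), 0.01, 0.4)  # Nyquist 0.25


class TestMakeWindows:
    def test_default_geometry(self):
        wins = make_windows(170, 2.0, WindowSpec(64, 4))
        assert len(wins) == 70
        assert all(b - a == 32 for a, b in wins)
        assert [a for a, _ in wins] == list(range(0, 139, 2))

    @pytest.mark.parametrize("window_s,step_s", [(50, 2), (50, 4), (64, 2),
                                                 (64, 4), (100, 2), (100, 4)])
    def test_counts_match_enumeration(self, window_s, step_s):
        spec = WindowSpec(window_s, step_s)
        w, s = spec.window_vols(2.0), spec.step_vols(2.0)
        expected = [a for a in range(0, 171, 1) if a % s == 0 and a + w <= 170]
        wins = make_windows(170, 2.0, spec)
        assert [a for a, _ in wins] == expected

    def test_single_window_when_exact_fit(self):
        assert make_windows(32, 2.0, WindowSpec(64, 4)) == [(0, 32)]

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            make_windows(20, 2.0, WindowSpec(64, 4))

    def test_non_integer_multiple_of_tr_rejected(self):
        with pytest.raises(ValueError):
            make_windows(170, 2.0, WindowSpec(63, 4))


class TestWindowedFc:
    def test_identical_target_correlates_one(self, rng):
        x = rng.standard_normal(40)
        b = make_bold(np.vstack([x, x, rng.standard_normal(40)]))
        stack = windowed_fc(b, 0, np.array([1, 2]), [(0, 20), (20, 40)])
        np.testing.assert_allclose(stack.corr[:, 0], 1.0, atol=1e-12)

    def test_negated_target_correlates_minus_one(self, rng):
        x = rng.standard_normal(40)
        b = make_bold(np.vstack([x, -x, rng.standard_normal(40)]))
        stack = windowed_fc(b, 0, np.array([1, 2]), [(0, 20), (20, 40)])
        np.testing.assert_allclose(stack.corr[:, 0], -1.0, atol=1e-12)

    def test_toy_window_pearson_value(self):
        b = make_bold(np.array([[1, 2, 3, 4], [1, 3, 2, 4], [4, 3, 2, 1]]))
        stack = windowed_fc(b, 0, np.array([1, 2]), [(0, 4)])
        np.testing.assert_allclose(stack.corr[0], [0.8, -1.0], atol=1e-12)

    def test_flat_window_marked_undefined(self, rng):
        b = make_bold(np.vstack([rng.standard_normal(10),
                                 np.zeros(10), rng.standard_normal(10)]))
        stack = windowed_fc(b, 0, np.array([1, 2]), [(0, 5), (5, 10)])
        assert np.isnan(stack.corr[:, 0]).all()
        assert np.isfinite(stack.corr[:, 1]).all()


class TestKendallsW:
    def test_perfect_concordance(self):
        m = np.tile([0.1, 0.5, 0.9, 0.3], (5, 1)) + \
            np.arange(5)[:, None] * 0.0
        assert kendalls_w(m) == pytest.approx(1.0, abs=1e-12)

    def test_two_reversed_judges_give_zero(self):
        m = np.array([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]])
        assert kendalls_w(m) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("trial", range(40))
    def test_matches_brute_force_with_and_without_ties(self, trial):
        rng = np.random.default_rng(trial)
        k = rng.integers(2, 11)
        n = rng.integers(2, 13)
        m = rng.standard_normal((int(k), int(n)))
        if trial % 2:
            m = np.round(m)          # force ties
        expected = np.clip(brute_force_w(m), 0, 1)
        if np.isnan(expected):
            return
        assert kendalls_w(m) == pytest.approx(expected, abs=1e-12)

    def test_rank_invariance_under_fisher_z(self, rng):
        m = rng.uniform(-0.95, 0.95, size=(8, 10))
        assert kendalls_w(np.arctanh(m)) == kendalls_w(m)

    def test_permutation_invariance(self, rng):
        m = rng.standard_normal((6, 9))
        w = kendalls_w(m)
        assert kendalls_w(m[:, rng.permutation(9)]) == pytest.approx(w, abs=1e-12)
        assert kendalls_w(m[rng.permutation(6), :]) == pytest.approx(w, abs=1e-12)

    def test_bounds(self, rng):
        for _ in range(50):
            m = rng.standard_normal((3, 4))
            assert 0.0 <= kendalls_w(m) <= 1.0

    def test_all_tied_everywhere_undefined(self):
        with pytest.warns(RuntimeWarning):
            assert np.isnan(kendalls_w(np.ones((3, 4))))

    def test_nan_target_dropped_from_all_judges(self, rng):
        m = rng.standard_normal((5, 6))
        m_with_nan = m.copy()
        m_with_nan[2, 3] = np.nan
        assert kendalls_w(m_with_nan) == pytest.approx(
            kendalls_w(np.delete(m, 3, axis=1)), abs=1e-12)


class TestStabilityMap:
    def test_vertex_mode_matches_naive_reference(self, rng):
        # small mesh keeps the quadratic reference fast; the full-scale
        # equivalence is exercised by the acceptance suite
        data = rng.standard_normal((30, 80))
        b = make_bold(data)
        spec = WindowSpec(40, 8)
        got = stability_map(b, np.ones(30, bool), None, spec,
                            "vertex_by_vertex")
        expected = naive_vertex_stability(data, 2.0, spec.window_s, spec.step_s)
        np.testing.assert_allclose(got.values, expected, atol=1e-10)

    def test_unmasked_vertices_are_nan(self, rng):
        data = rng.standard_normal((20, 80))
        mask = np.ones(20, bool)
        mask[[3, 7]] = False
        got = stability_map(make_bold(data), mask, None, WindowSpec(40, 8),
                            "vertex_by_vertex")
        assert np.isnan(got.values[[3, 7]]).all()
        assert np.isfinite(np.delete(got.values, [3, 7])).all()

    def test_iid_noise_yields_low_stability(self, rng):
        data = rng.standard_normal((40, 170))
        got = stability_map(make_bold(data), np.ones(40, bool), None,
                            WindowSpec(64, 4), "vertex_by_vertex")
        # with no coupling, W concentrates near its small-sample null level,
        # far below the stationary-coupling regime
        assert np.nanmedian(got.values) < 0.35

    def test_atlas_mode_requires_two_parcels(self, mesh162, rng):
        from surfstab.surface import ParcellationAtlas
        atlas = ParcellationAtlas(np.ones(162, dtype=int))
        b = make_bold(rng.standard_normal((162, 80)))
        with pytest.raises(ValueError, match="parcels"):
            stability_map(b, np.ones(162, bool), atlas, WindowSpec(40, 8),
                          "vertex_by_atlas")

    def test_atlas_mode_seed_exclusion_changes_own_parcel_target(
            self, mesh162, atlas12, rng):
        b = make_bold(rng.standard_normal((162, 100)))
        mask = np.ones(162, bool)
        inc = stability_map(b, mask, atlas12, WindowSpec(40, 8),
                            "vertex_by_atlas", seed_policy="include")
        exc = stability_map(b, mask, atlas12, WindowSpec(40, 8),
                            "vertex_by_atlas", seed_policy="exclude")
        assert not np.allclose(inc.values, exc.values)

    def test_modulated_parcel_falls_below_map_median(
            self, mesh162, atlas12, regime_config):
        from surfstab.synthetic import simulate_subject_bold
        b = simulate_subject_bold(mesh162, atlas12,
                                  regime_config.with_amplitude(2, 0.9),
                                  180, 2.0, 4)
        got = stability_map(b, np.ones(162, bool), atlas12, WindowSpec(64, 4))
        lab = atlas12.labels
        med = np.nanmedian(got.values)
        assert np.nanmean(got.values[lab == 2]) < med
        # a stationary parcel far from the modulated one sits above it
        assert np.nanmean(got.values[lab == 7]) > \
            np.nanmean(got.values[lab == 2])


class TestZscoreMap:
    def _smap(self, values):
        from surfstab.stability import StabilityMap
        return StabilityMap(np.asarray(values, float))

    def test_three_values_standardise(self):
        out = zscore_map(self._smap([1.0, 2.0, 3.0]), np.ones(3, bool))
        np.testing.assert_allclose(out.values, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_mask_moments(self, rng):
        v = rng.uniform(0, 1, size=50)
        mask = np.zeros(50, bool)
        mask[:30] = True
        out = zscore_map(self._smap(v), mask)
        assert abs(out.values[mask].mean()) < 1e-10
        assert abs(out.values[mask].std(ddof=1) - 1.0) < 1e-10

    def test_idempotent(self, rng):
        v = rng.standard_normal(40)
        m1 = zscore_map(self._smap(v), np.ones(40, bool))
        m2 = zscore_map(m1, np.ones(40, bool))
        np.testing.assert_allclose(m1.values, m2.values, atol=1e-12)

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError):
            zscore_map(self._smap(np.ones(10)), np.ones(10, bool))

    def test_pooled_hemisphere_moments(self, rng):
        from surfstab.stability import zscore_maps_pooled
        left = self._smap(rng.uniform(0, 1, 30) + 0.2)
        right = self._smap(rng.uniform(0, 1, 40))
        masks = [np.ones(30, bool), np.ones(40, bool)]
        zl, zr = zscore_maps_pooled([left, right], masks)
        pooled = np.concatenate([zl.values, zr.values])
        assert abs(pooled.mean()) < 1e-10
        assert abs(pooled.std(ddof=1) - 1.0) < 1e-10
        # hemisphere offsets survive joint standardisation
        assert zl.values.mean() > zr.values.mean()
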