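"""TIC features: peak detection, trapezoidal decomposition, histograms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from nbceus.datatypes import TIC, AcquisitionSeries, CineLoop
from nbceus.synthetic import gamma_variate
from nbceus.tic import (
    map_histogram,
    parametric_maps,
    smooth_tic,
    tic_features,
    whole_organ_tic,
)


def _series_from_stack(stack, mask, dt=0.2):
    loop = CineLoop(frames=stack, frame_interval_s=dt)
    return AcquisitionSeries(loops=[loop], mask=mask)


class TestWholeOrganTIC:
    def test_uniform_frames_give_constant_tic(self):
        stack = np.full((10, 8, 8), 3.0)
        mask = np.ones((8, 8), bool)
        tic = whole_organ_tic(_series_from_stack(stack, mask))
        assert np.all(tic.values == 3.0)

    def test_single_pixel_mask_is_identity(self, rng):
        stack = rng.uniform(0, 5, size=(30, 6, 6))
        mask = np.zeros((6, 6), bool)
        mask[2, 3] = True
        tic = whole_organ_tic(_series_from_stack(stack, mask))
        np.testing.assert_array_equal(tic.values, stack[:, 2, 3])

    def test_invariant_to_outside_mask_changes(self, rng):
        stack = rng.uniform(0, 5, size=(20, 6, 6))
        mask = np.zeros((6, 6), bool)
        mask[1:4, 1:4] = True
        tic_a = whole_organ_tic(_series_from_stack(stack, mask))
        stack2 = stack.copy()
        stack2[:, ~mask] = rng.uniform(0, 100, size=(20, int((~mask).sum())))
        tic_b = whole_organ_tic(_series_from_stack(stack2, mask))
        np.testing.assert_array_equal(tic_a.values, tic_b.values)

    def test_empty_mask_rejected(self):
        stack = np.ones((5, 4, 4))
        with pytest.raises(ValueError):
            whole_organ_tic(_series_from_stack(stack, np.zeros((4, 4), bool)))


class TestSmoothTIC:
    def test_window_one_is_identity(self, rng):
        tic = TIC(np.arange(10.0), rng.uniform(0, 1, 10))
        out = smooth_tic(tic, 1)
        np.testing.assert_array_equal(out.values, tic.values)

    def test_edge_truncated_means_hand_example(self):
        tic = TIC(np.arange(3.0), np.array([0.0, 3.0, 0.0]))
        out = smooth_tic(tic, 3)
        np.testing.assert_allclose(out.values, [1.5, 1.0, 1.5])

    def test_constant_series_unchanged(self):
        tic = TIC(np.arange(9.0), np.full(9, 4.2))
        np.testing.assert_allclose(smooth_tic(tic, 5).values, 4.2)

    @pytest.mark.parametrize("window", [0, 2, 4, 99])
    def test_bad_windows_rejected(self, window):
        tic = TIC(np.arange(10.0), np.ones(10))
        with pytest.raises(ValueError):
            smooth_tic(tic, window)


class TestTICFeatures:
    def test_symmetric_triangle(self):
        t = np.linspace(0, 2, 2001)
        v = np.where(t <= 1, t, 2 - t)
        f = tic_features(TIC(t, v), smooth_window=1)
        assert f.ttp_s == pytest.approx(1.0)
        assert f.pi == pytest.approx(1.0)
        assert f.auc == pytest.approx(1.0, rel=1e-6)
        assert f.aurc == pytest.approx(0.5, rel=1e-6)
        assert f.aufc == pytest.approx(0.5, rel=1e-6)

    def test_constant_tic_first_occurrence_tie_break(self):
        t = np.linspace(0, 7, 71)
        f = tic_features(TIC(t, np.full(71, 2.0)), smooth_window=1)
        assert f.ttp_s == 0.0
        assert f.pi == 2.0
        assert f.auc == pytest.approx(14.0)
        assert f.aurc == 0.0
        assert f.aufc == pytest.approx(14.0)

    def test_gamma_variate_closed_form(self):
        # AUC of A (t/tp)^a e^{a(1-t/tp)} over [0, inf) = A e^a Gamma(a+1) tp / a^(a+1)
        A, tp, alpha = 40.0, 10.0, 2.0
        t = np.arange(0, 200.0001, 0.2)
        f = tic_features(TIC(t, gamma_variate(t, A, tp, alpha)), smooth_window=1)
        closed_form = 100 * np.e**2  # = 738.906 for these parameters
        assert f.ttp_s == pytest.approx(tp, abs=0.2)
        assert f.pi == pytest.approx(A, rel=1e-9)  # peak lies on the sample grid
        assert f.auc == pytest.approx(closed_form, rel=0.005)
        # independent adaptive-quadrature oracle
        oracle, _ = quad(lambda x: gamma_variate(np.array([x]), A, tp, alpha)[0], 0, 200)
        assert f.auc == pytest.approx(oracle, rel=1e-4)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        n=st.integers(5, 120),
        seed=st.integers(0, 2**31 - 1),
        window=st.sampled_from([1, 3, 5]),
    )
    def test_decomposition_and_bounds_properties(self, n, seed, window):
        """AUrC + AUfC = AUC exactly; TTP within span; PI >= smoothed samples."""
        r = np.random.default_rng(seed)
        t = np.cumsum(r.uniform(0.05, 0.4, n))
        v = r.uniform(0, 10, n)
        window = min(window, n if n % 2 else n - 1)
        f = tic_features(TIC(t, v), smooth_window=window)
        assert f.aurc + f.aufc == pytest.approx(f.auc, rel=1e-12, abs=1e-12)
        assert 0 <= f.ttp_s <= t[-1] - t[0]
        assert f.pi >= smooth_tic(TIC(t, v), window).values.max() - 1e-12


class TestParametricMaps:
    def test_noise_free_recovery_of_peak_parameters(self, noise_free_series):
        """TTP within one frame; PI exact when the peak lies on the grid."""
        series, truth = noise_free_series
        maps = parametric_maps(series, smooth_window=1)
        m = series.mask
        assert np.nanmax(np.abs(maps.ttp_s[m] - 10.0)) <= series.loops[0].frame_interval_s
        np.testing.assert_allclose(maps.pi[m], truth.amplitude[m], rtol=1e-6)

    def test_constant_cine_gives_zero_ttp_and_aurc(self):
        stack = np.full((12, 5, 5), 7.0)
        mask = np.ones((5, 5), bool)
        maps = parametric_maps(_series_from_stack(stack, mask), smooth_window=1)
        assert np.all(maps.ttp_s[mask] == 0.0)
        assert np.all(maps.aurc[mask] == 0.0)

    def test_outside_mask_is_nan_and_ignored(self, rng):
        stack = rng.uniform(0, 5, size=(20, 8, 8))
        mask = np.zeros((8, 8), bool)
        mask[2:6, 2:6] = True
        maps_a = parametric_maps(_series_from_stack(stack, mask))
        stack2 = stack.copy()
        stack2[:, ~mask] += 50
        maps_b = parametric_maps(_series_from_stack(stack2, mask))
        for name, arr in maps_a.items():
            assert np.all(np.isnan(arr[~mask]))
            np.testing.assert_array_equal(arr, maps_b[name])

    def test_matches_per_pixel_tic_features(self, rng):
        """The vectorized maps equal the scalar path pixel by pixel."""
        stack = rng.uniform(0, 5, size=(40, 4, 4))
        mask = np.ones((4, 4), bool)
        series = _series_from_stack(stack, mask)
        maps = parametric_maps(series, smooth_window=3)
        t = series.loops[0].times_s
        for rr in range(4):
            for cc in range(4):
                f = tic_features(TIC(t, stack[:, rr, cc]), smooth_window=3)
                assert maps.ttp_s[rr, cc] == pytest.approx(f.ttp_s)
                assert maps.auc[rr, cc] == pytest.approx(f.auc, rel=1e-12)
                assert maps.aurc[rr, cc] == pytest.approx(f.aurc, rel=1e-12)
                assert maps.pi[rr, cc] == pytest.approx(f.pi, rel=1e-12)


class TestMapHistogram:
    def test_hand_example_moments(self):
        s = map_histogram(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert s.mean == pytest.approx(2.5)
        assert s.variance == pytest.approx(5.0 / 3.0)
        assert s.n == 4

    def test_symmetric_values_have_zero_skewness(self):
        s = map_histogram(np.array([[-3.0, 0.0, 3.0]]))
        assert s.skewness == pytest.approx(0.0, abs=1e-12)

    def test_constant_map_degenerate(self):
        s = map_histogram(np.full((3, 3), 2.0))
        assert s.variance == 0.0
        assert np.isnan(s.skewness)

    def test_counts_sum_to_masked_pixels(self, rng):
        arr = rng.uniform(0, 1, (10, 10))
        mask = rng.uniform(0, 1, (10, 10)) > 0.4
        s = map_histogram(arr, mask, n_bins=7)
        assert s.counts.sum() == mask.sum() == s.n

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            map_histogram(np.full((4, 4), np.nan))

    def test_iri_maps_skewed_versus_sham(self, desk_cohort):
        """Injury shifts mass into the low tail of PI and AUrC histograms
        (hypoperfused patches) and into the high tail of AUfC (retention
        patches) — the leftward/rightward skewing the analysis looks for."""
        from nbceus.tic import parametric_maps as pm

        def tail_fractions(series):
            maps = pm(series)
            out = {}
            for name in ("pi", "aurc"):
                vals = maps[name][series.mask]
                out[name] = np.mean(vals < 0.7 * np.nanmedian(vals))
            vals = maps.aufc[series.mask]
            out["aufc"] = np.mean(vals > 2.0 * np.nanmedian(vals))
            return out

        frac = {"sham": [], "iri": []}
        for series, _ in desk_cohort:
            frac[series.group_label].append(tail_fractions(series))
        for name in ("pi", "aurc", "aufc"):
            iri = np.mean([f[name] for f in frac["iri"]])
            sham = np.mean([f[name] for f in frac["sham"]])
            assert iri > sham, f"{name}: IRI tail {iri:.3f} !> sham {sham:.3f}"
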