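"""Allan-factor variance, AF functions, and log-log shape fits."""

import numpy as np
import pytest

import rhythmkit as rk


class TestAFVariance:
    def test_hand_oracle_two_windows(self):
        # counts (3,1) on [0,1) at T=0.5: A = (3-1)^2 / (2*2) = 1
        e = rk.EventSeries([0.1, 0.3, 0.4, 0.9], t_start=0.0, t_end=1.0)
        assert rk.af_variance(e, 0.5) == 1.0

    @pytest.mark.parametrize("k", [1, 2, 5])
    def test_aligned_isochronous_grid_has_zero_af(self, iso_clean, k):
        assert rk.af_variance(iso_clean, k * 0.2) == 0.0

    def test_poisson_af_is_one_within_replication_error(self):
        vals = [
            rk.af_variance(rk.gen_poisson(rk.PoissonSpec(12.0, 100.0, s)), 0.5)
            for s in range(12)
        ]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 1.0) <= 3 * se + 0.02

    def test_out_of_range_timescale_rejected(self, iso_clean):
        with pytest.raises(ValueError):
            rk.af_variance(iso_clean, 6.0)  # > span/2
        with pytest.raises(ValueError):
            rk.af_variance(iso_clean, 0.0)

    def test_time_shift_invariance(self, poisson_10s):
        shifted = poisson_10s.shifted(3.0)
        for T in (0.25, 0.5, 1.0):
            assert rk.af_variance(shifted, T) == pytest.approx(
                rk.af_variance(poisson_10s, T), abs=1e-12
            )

    def test_time_reversal_invariance_on_commensurate_window(self):
        e = rk.EventSeries([0.1, 0.3, 0.4, 0.9, 1.2, 1.7], 0.0, 2.0)
        rev = rk.EventSeries(np.sort(2.0 - e.times), 0.0, 2.0)
        for T in (0.5, 1.0):
            assert rk.af_variance(rev, T) == pytest.approx(rk.af_variance(e, T), abs=1e-12)

    def test_superposed_poisson_processes_stay_poisson_flat(self):
        a = rk.gen_poisson(rk.PoissonSpec(6.0, 100.0, 1))
        b = rk.gen_poisson(rk.PoissonSpec(6.0, 100.0, 2))
        merged = rk.EventSeries(
            np.unique(np.concatenate([a.times, b.times])), 0.0, 100.0
        )
        vals = [rk.af_variance(merged, T) for T in (0.25, 0.5, 1.0, 2.0)]
        assert all(abs(v - 1.0) < 0.5 for v in vals)


class TestAFFunction:
    def test_dyadic_ladder_and_window_counts(self, poisson_10s):
        fn = rk.af_function(poisson_10s, 0.05, 2.5)
        np.testing.assert_allclose(fn.timescales, 0.05 * 2.0 ** np.arange(6))
        assert np.all(fn.window_counts >= 2)
        assert np.all(np.diff(fn.timescales) > 0)

    def test_single_timescale_ladder(self, poisson_10s):
        fn = rk.af_function(poisson_10s, 0.5, 0.9)
        assert len(fn) == 1

    def test_scales_without_two_windows_dropped(self):
        e = rk.EventSeries(np.arange(0, 4, 0.1), 0.0, 4.0)
        fn = rk.af_function(e, 0.5, 2.0)
        assert np.all(fn.window_counts >= 2)

    def test_invalid_range_rejected(self, poisson_10s):
        with pytest.raises(ValueError):
            rk.af_function(poisson_10s, 2.0, 1.0)


class TestAFShape:
    def _fn(self, timescales, af_values):
        return rk.AFFunction(
            np.asarray(timescales), np.asarray(af_values),
            np.full(len(timescales), 10), n_events=100,
        )

    def test_flat_unit_af_gives_zero_slope_and_curvature(self):
        sh = rk.af_shape(self._fn([0.1, 0.2, 0.4, 0.8], [1, 1, 1, 1]))
        assert sh.slope == pytest.approx(0.0, abs=1e-9)
        assert sh.curvature == pytest.approx(0.0, abs=1e-9)

    def test_identity_on_loglog_gives_unit_slope(self):
        ts = np.array([0.1, 0.2, 0.4, 0.8, 1.6])
        sh = rk.af_shape(self._fn(ts, ts))
        assert sh.slope == pytest.approx(1.0, abs=1e-9)
        assert sh.curvature == pytest.approx(0.0, abs=1e-9)
        assert sh.fit_residual == pytest.approx(0.0, abs=1e-9)

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(ValueError):
            rk.af_shape(self._fn([0.1, 0.2], [1.0, 1.0]))

    def test_poisson_slope_flat_in_seed_aggregate(self):
        # mean AF function over seeds, then fit: sampling noise at the
        # coarsest scales (few windows) averages out across replicates
        per_scale = []
        for s in range(20):
            fn = rk.af_function(rk.gen_poisson(rk.PoissonSpec(12.0, 100.0, s)), 0.05, 12.8)
            per_scale.append(fn.af_values)
        mean_fn = rk.AFFunction(
            fn.timescales, np.mean(per_scale, axis=0), fn.window_counts, fn.n_events
        )
        sh = rk.af_shape(mean_fn)
        assert abs(sh.slope) <= 0.15
        assert abs(sh.curvature) <= 0.1

    @staticmethod
    def _nested_cluster_cascade(seed, duration=100.0):
        # Poisson cluster centers, each spawning a triplet-of-double-pulses
        # motif: random nesting at three scales without global periodicity
        parents = rk.gen_poisson(rk.PoissonSpec(0.8, duration, seed)).times
        offsets = np.array([0.0, 0.05, 0.25, 0.30, 0.50, 0.55])
        times = np.unique(
            np.round((parents[:, None] + offsets[None, :]).ravel(), 3)
        )
        times = times[times < duration]
        return rk.EventSeries(times, 0.0, duration)

    def test_nested_cluster_slope_exceeds_rate_matched_poisson(self):
        wins = 0
        for s in range(20):
            cascade = self._nested_cluster_cascade(s)
            rate = cascade.n_events / cascade.span
            pois = rk.gen_poisson(rk.PoissonSpec(rate, 100.0, 1000 + s))
            s_c = rk.af_shape(rk.af_function(cascade, 0.05, 12.8)).slope
            s_p = rk.af_shape(rk.af_function(pois, 0.05, 12.8)).slope
            wins += s_c > s_p
        assert wins >= 19

    def test_cascade_af_rises_over_cluster_octaves(self):
        cascade = self._nested_cluster_cascade(5)
        fn = rk.af_function(cascade, 0.05, 12.8)
        # clustering inflates count variance: AF well above Poisson unity
        # at the scales bracketing the motif structure (0.4-3.2 s)
        sel = (fn.timescales >= 0.4) & (fn.timescales <= 3.2)
        assert np.all(fn.af_values[sel] > 1.5)
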