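import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from v1l4sim import analysis, connectome
from v1l4sim.analysis import (amplification_fit, cv_isi, dsi, f0_f1,
                              fano_factor, flash_psth, lgn_convergence,
                              lgn_fraction, mua_spectrum, omi, osi,
                              signal_noise_correlations, skewness, sparsity,
                              spont_rate)
from v1l4sim.netsim import SpikeData

DIRS8 = np.arange(0.0, 360.0, 45.0)


def spikes_from(times_by_cell, t_max=1000.0, trial=0, acc=None):
    ids, ts = [], []
    for c, tt in enumerate(times_by_cell):
        ids.extend([c] * len(tt))
        ts.extend(tt)
    order = np.argsort(ts) if ts else []
    return SpikeData(np.asarray(ids, dtype=np.int32)[order],
                     np.asarray(ts, dtype=float)[order],
                     len(times_by_cell), t_max, trial, acc=acc or {})


class TestSpontRate:
    def test_single_spike_in_twenty_windows_gives_point_one_hz(self):
        trials = [spikes_from([[700.0]] if t == 0 else [[]])
                  for t in range(20)]
        assert spont_rate(trials, 1)[0] == pytest.approx(0.1)

    def test_no_spikes_zero(self):
        trials = [spikes_from([[]]) for _ in range(20)]
        assert spont_rate(trials, 1)[0] == 0.0

    def test_one_spike_per_window_two_hz(self):
        trials = [spikes_from([[750.0]]) for _ in range(20)]
        assert spont_rate(trials, 1)[0] == pytest.approx(2.0)

    def test_first_half_second_ignored(self):
        trials = [spikes_from([[100.0, 499.9]]) for _ in range(20)]
        assert spont_rate(trials, 1)[0] == 0.0

    def test_no_trials_rejected(self):
        with pytest.raises(ValueError):
            spont_rate([], 1)


class TestOsiDsi:
    def test_flat_curve_osi_zero(self):
        assert osi(DIRS8, np.full(8, 3.0)) == pytest.approx(0.0, abs=1e-12)

    def test_single_direction_osi_one(self):
        f = np.zeros(8)
        f[2] = 5.0
        assert osi(DIRS8, f) == pytest.approx(1.0)

    def test_structured_curves_match_complex_sum_oracle(self):
        # brute-force oracle: direct complex arithmetic.  A curve with a
        # 90-degree period cancels exactly in orientation space; breaking
        # the symmetry at one direction leaves |extra| / sum f.
        sym = np.array([2.0, 1, 2, 1, 2, 1, 2, 1])
        assert abs((sym * np.exp(2j * np.deg2rad(DIRS8))).sum()) < 1e-12
        assert osi(DIRS8, sym) == pytest.approx(0.0, abs=1e-12)
        f = sym.copy()
        f[0] += 1.0
        oracle = abs((f * np.exp(2j * np.deg2rad(DIRS8))).sum()) / f.sum()
        assert oracle == pytest.approx(1.0 / 13.0)
        assert osi(DIRS8, f) == pytest.approx(oracle)

    def test_zero_curve_undefined(self):
        assert np.isnan(osi(DIRS8, np.zeros(8)))
        assert np.isnan(dsi(DIRS8, np.zeros(8)))

    def test_dsi_examples(self):
        f = np.zeros(8)
        f[1], f[5] = 3.0, 1.0          # preferred 45, null 225
        assert dsi(DIRS8, f) == pytest.approx(0.5)
        f[5] = 3.0
        assert dsi(DIRS8, f) == pytest.approx(0.0)
        f[5] = 0.0
        assert dsi(DIRS8, f) == pytest.approx(1.0)

    @settings(max_examples=60, deadline=None)
    @given(hnp.arrays(float, 8, elements=st.floats(0, 100)))
    def test_bounded_and_scale_invariant(self, f):
        v = osi(DIRS8, f)
        d = dsi(DIRS8, f)
        if f.sum() > 0:
            assert 0.0 <= v <= 1.0 + 1e-9
            assert osi(DIRS8, 3.7 * f) == pytest.approx(v, abs=1e-9)
        if not np.isnan(d):
            assert -1.0 - 1e-9 <= d <= 1.0 + 1e-9
            assert dsi(DIRS8, 3.7 * f) == pytest.approx(d, abs=1e-9)

    @settings(max_examples=40, deadline=None)
    @given(hnp.arrays(float, 8, elements=st.floats(0.1, 50)),
           st.integers(1, 7))
    def test_osi_rotation_invariance(self, f, shift):
        rolled = np.roll(f, shift)
        assert osi(DIRS8, rolled) == pytest.approx(osi(DIRS8, f), abs=1e-9)


class TestF0F1:
    def _sine(self, a, b, freq=4.0, seconds=2.0):
        t = np.arange(int(seconds * 1000)) / 1000.0
        return a + b * np.sin(2 * np.pi * freq * t)

    def test_fourier_abs_convention(self):
        f0, f1 = f0_f1(self._sine(5.0, 2.0), 4.0, convention="fourier_abs")
        assert f0 == pytest.approx(5.0, rel=1e-3)
        assert f1 == pytest.approx(2.0, rel=1e-2)

    def test_fit_2b_convention_doubles(self):
        f0, f1 = f0_f1(self._sine(5.0, 2.0), 4.0, convention="fit_2b")
        assert f0 == pytest.approx(5.0, rel=1e-3)
        assert f1 == pytest.approx(4.0, rel=1e-2)

    def test_constant_signal_f1_zero(self):
        f0, f1 = f0_f1(np.full(2000, 3.3), 4.0)
        assert f0 == pytest.approx(3.3)
        assert f1 == pytest.approx(0.0, abs=1e-9)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            f0_f1(np.ones(100), 4.0)
        with pytest.raises(ValueError):
            f0_f1(np.ones(2000), 4.0, convention="rms")


class TestSparsity:
    def test_uniform_bins_zero(self):
        assert sparsity(np.full(10, 2.5)) == pytest.approx(0.0, abs=1e-12)

    def test_single_active_bin_one(self):
        f = np.zeros(10)
        f[3] = 7.0
        assert sparsity(f) == pytest.approx(1.0)

    def test_two_bin_worked_example(self):
        assert sparsity(np.array([1.0, 3.0])) == pytest.approx(0.4)

    def test_all_zero_undefined(self):
        assert np.isnan(sparsity(np.zeros(10)))

    @settings(max_examples=50, deadline=None)
    @given(hnp.arrays(float, 12, elements=st.floats(0, 100)))
    def test_bounded_and_scale_invariant(self, f):
        s = sparsity(f)
        if not np.isnan(s):
            assert -1e-9 <= s <= 1.0 + 1e-9
            assert sparsity(2.5 * f) == pytest.approx(s, abs=1e-9)

    def test_concentration_increases_sparsity(self):
        spread = np.array([2.0, 2, 2, 2])
        tight = np.array([8.0, 0, 0, 0])
        mid = np.array([4.0, 4, 0, 0])
        assert sparsity(spread) < sparsity(mid) < sparsity(tight)


class TestVariability:
    def test_regular_train_cv_zero(self):
        assert cv_isi(np.arange(0, 1000, 10.0)) == pytest.approx(0.0)

    def test_cv_squared_versus_plain_convention(self):
        rng = np.random.default_rng(0)
        t = np.cumsum(rng.exponential(20.0, 500))
        assert cv_isi(t, squared=True) == \
            pytest.approx(cv_isi(t, squared=False) ** 2)
        assert cv_isi(t, squared=False) == pytest.approx(1.0, rel=0.15)

    def test_too_few_intervals_undefined(self):
        assert np.isnan(cv_isi([5.0]))

    def test_fano_near_one_for_poisson_trains(self):
        # regression oracle: homogeneous Poisson variance equals mean
        rng = np.random.default_rng(1)
        trials = []
        for tr in range(60):
            cells = [(np.nonzero(rng.random(3000) < 0.02)[0] + 0.5)
                     for _ in range(3)]
            trials.append(spikes_from(cells, t_max=3000.0, trial=tr))
        fano = fano_factor(trials, 3)
        assert np.all(np.abs(fano - 1.0) < 0.25)

    def test_signal_correlation_identical_tuning_is_one(self):
        counts = np.zeros((8, 4, 2))
        base = np.array([1, 5, 2, 7, 1, 0, 3, 4], dtype=float)
        counts[:, :, 0] = base[:, None]
        counts[:, :, 1] = (2 * base)[:, None]
        counts += np.random.default_rng(2).normal(0, 1e-6, counts.shape)
        sig, _ = signal_noise_correlations(counts)
        assert sig[0, 1] == pytest.approx(1.0, abs=1e-3)

    def test_noise_correlation_independent_near_zero(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(5.0, size=(8, 200, 2)).astype(float)
        _, noise = signal_noise_correlations(counts)
        assert abs(noise[0, 1]) < 0.1


class TestOmiSkewness:
    @pytest.mark.parametrize("fp,fc,expected", [
        (0.0, 4.0, -1.0), (3.0, 3.0, 0.0), (3.0, 1.0, 0.5),
    ])
    def test_omi_values(self, fp, fc, expected):
        assert omi(fp, fc) == pytest.approx(expected)

    def test_omi_undefined_when_both_zero(self):
        assert np.isnan(omi(0.0, 0.0))

    def test_skewness_symmetric_zero(self):
        assert skewness([1.0, 2.0, 3.0, 4.0, 5.0]) == pytest.approx(0.0,
                                                                    abs=1e-12)

    def test_skewness_worked_example(self):
        # brute force: [0,0,0,9] -> third standardised moment = 2/sqrt(3)
        v = np.array([0.0, 0, 0, 9])
        z = (v - v.mean()) / v.std()
        assert np.mean(z ** 3) == pytest.approx(2.0 / np.sqrt(3.0))
        assert skewness(v) == pytest.approx(2.0 / np.sqrt(3.0))

    def test_skewness_normal_sample_near_zero(self):
        rng = np.random.default_rng(4)
        assert abs(skewness(rng.normal(5, 2, 200_000))) < 0.02

    def test_skewness_degenerate_undefined(self):
        assert np.isnan(skewness([2.0, 2.0, 2.0, 2.0]))


class TestMuaSpectrum:
    def _cells(self, n):
        return pd.DataFrame({"x": np.linspace(10, 400, n),
                             "y": np.zeros(n)})

    def test_no_spikes_flat_zero(self):
        cells = self._cells(3)
        trials = [spikes_from([[], [], []], t_max=2548.0)]
        f, p = mua_spectrum(trials, cells)
        assert np.all(p == 0.0)

    def test_common_periodic_pattern_peaks_at_its_frequency(self):
        # Fourier identity oracle: a jittered 20 Hz population rhythm puts
        # its dominant spectral mass at 20 Hz
        cells = self._cells(5)
        rng = np.random.default_rng(11)
        trials = [spikes_from(
            [np.sort(np.arange(550.0, 2500.0, 50.0)
                     + rng.normal(0, 6.0, 39)) for _ in range(5)],
            t_max=2548.0)]
        f, p = mua_spectrum(trials, cells)
        peak_f = f[1:][np.argmax(p[1:])]
        assert peak_f == pytest.approx(20.0, abs=1.0)

    def test_power_scales_quadratically_with_weights(self):
        cells = self._cells(4)
        rng = np.random.default_rng(5)
        times = [list(np.sort(rng.uniform(500, 2500, 60))) for _ in range(4)]
        t1 = [spikes_from(times, t_max=2548.0)]
        f, p1 = mua_spectrum(t1, cells, min_r_um=1.0)
        # doubling every weight is the same as halving all the distances
        cells2 = cells.copy()
        cells2["x"] /= 2.0
        _, p2 = mua_spectrum(t1, cells2, min_r_um=1.0)
        assert np.allclose(p2, 4.0 * p1, rtol=1e-6)


class TestInputAccounting:
    def test_feedforward_only_fraction_is_one(self):
        sd = spikes_from([[]], acc={"lgn_exc": np.array([5.0]),
                                    "all_exc": np.array([5.0])})
        assert lgn_fraction([sd])[0] == pytest.approx(1.0)

    def test_silenced_lgn_fraction_zero(self):
        sd = spikes_from([[]], acc={"lgn_exc": np.array([0.0]),
                                    "all_exc": np.array([5.0])})
        assert lgn_fraction([sd])[0] == pytest.approx(0.0)

    def test_no_input_undefined(self):
        sd = spikes_from([[]], acc={"lgn_exc": np.array([0.0]),
                                    "all_exc": np.array([0.0])})
        assert np.isnan(lgn_fraction([sd])[0])


class TestConvergence:
    def _ff(self, edges):
        src, tgt = zip(*edges)
        return connectome.ConnectionSet(
            np.asarray(src, dtype=np.int32), np.asarray(tgt, dtype=np.int32),
            np.full(len(edges), 30, dtype=np.int16),
            np.ones(len(edges), dtype=np.float32), kind="lgn")

    def test_identical_source_sets_give_half(self):
        ff = self._ff([(0, 0), (1, 0), (2, 0), (0, 1), (1, 1), (2, 1)])
        rec = self._ff([(0, 1)])
        out = lgn_convergence([(0, 1)], ff, rec, 2)
        assert out["convergence"].iloc[0] == pytest.approx(0.5)
        assert out["coupling"].iloc[0] == "one_way"

    def test_disjoint_source_sets_zero_and_reciprocal_label(self):
        ff = self._ff([(0, 0), (1, 0), (2, 1), (3, 1)])
        rec = self._ff([(0, 1), (1, 0)])
        out = lgn_convergence([(0, 1)], ff, rec, 2)
        assert out["convergence"].iloc[0] == pytest.approx(0.0)
        assert out["coupling"].iloc[0] == "reciprocal"

    def test_no_lgn_input_pair_undefined(self):
        ff = self._ff([(0, 2)])
        rec = self._ff([(0, 1)])
        out = lgn_convergence([(0, 1)], ff, rec, 3)
        assert np.isnan(out["convergence"].iloc[0])


class TestFits:
    def test_exact_linear_data(self):
        x = np.arange(1.0, 8)
        a, b, r2 = amplification_fit(x, 2.0 * x)
        assert (a, b, r2) == (pytest.approx(2.0), pytest.approx(0.0),
                              pytest.approx(1.0))
        a, b, r2 = amplification_fit(x, x)
        assert a == pytest.approx(1.0)

    def test_noisy_slope_recovered(self):
        rng = np.random.default_rng(6)
        x = np.linspace(0, 10, 200)
        y = 2.0 * x + rng.normal(0, 0.5, 200)
        a, b, r2 = amplification_fit(x, y)
        assert a == pytest.approx(2.0, abs=0.1)
        assert r2 > 0.9

    def test_degenerate_x_undefined(self):
        a, b, r2 = amplification_fit([1.0, 1.0], [2.0, 3.0])
        assert np.isnan(a)


class TestFlashPsth:
    def test_two_injected_bumps_recovered(self):
        rng = np.random.default_rng(7)
        trials = []
        for tr in range(10):
            times = []
            for mu in (650.0, 750.0):
                times.extend(rng.normal(mu, 4.0, 40))
            trials.append(spikes_from([sorted(times), []], t_max=1500.0,
                                      trial=tr))
        t, psth, peaks = flash_psth(trials, [0], onset_ms=600.0)
        assert len(peaks) == 2
        assert peaks[0][0] == pytest.approx(50.0, abs=6.0)
        assert peaks[1][0] == pytest.approx(150.0, abs=6.0)

    def test_flat_psth_no_peaks(self):
        trials = [spikes_from([[], []], t_max=1500.0)]
        _, _, peaks = flash_psth(trials, [0, 1], onset_ms=600.0)
        assert peaks == []
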