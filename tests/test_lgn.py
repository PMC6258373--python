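import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from v1l4sim import lgn
from v1l4sim.lgn import (DEFAULT_PARAM_RANGES, FilterParamRanges,
                         bank_rates, discrete_temporal_kernel,
                         filter_response, generate_spikes, place_filters,
                         retinotopy_map, spatial_kernel, subfield_table,
                         temporal_kernel, wire_lgn_to_l4)
from v1l4sim.stimuli import make_gray, make_grating
from conftest import make_cells


def single_filter(ftype="ON", x0=0.0, y0=0.0, sigma_c=2.5, a_c=0.0003,
                  k=0.04, r0=2.0, dx=0.0, dy=0.0):
    return pd.DataFrame([{
        "filter_id": 0, "ftype": ftype, "x0": x0, "y0": y0,
        "sigma_c": sigma_c, "a_c": a_c, "k": k, "r0": r0,
        "sub_dx": dx, "sub_dy": dy,
        "axis_deg": (np.degrees(np.arctan2(dy, dx)) % 180.0
                     if ftype == "ON_OFF" else np.nan),
    }])


class TestTemporalKernel:
    def test_zero_at_origin(self):
        assert temporal_kernel(0.04, 0.0) == 0.0

    def test_root_at_sqrt_six_over_k(self):
        k = 0.043
        assert temporal_kernel(k, np.sqrt(6.0) / k) == pytest.approx(0.0,
                                                                    abs=1e-12)

    def test_integral_is_zero(self):
        # the positive early lobe exactly cancels the late negative lobe
        k = 0.04
        val, _ = integrate.quad(lambda t: temporal_kernel(k, t), 0, 3000,
                                limit=300)
        peak = temporal_kernel(k, 1.0 / k)
        assert abs(val) < 1e-9 * peak * 1000

    def test_discrete_kernel_exact_zero_sum(self):
        for k in (0.036, 0.0412, 0.047):
            w = discrete_temporal_kernel(k)
            assert abs(w.sum()) < 1e-12


class TestSpatialKernel:
    def test_center_value_five_sixths(self):
        a_c = 0.7
        assert spatial_kernel(0, 0, 0, 0, 2.5, a_c) == \
            pytest.approx(a_c * 5.0 / 6.0)

    def test_far_field_decay(self):
        assert abs(spatial_kernel(100, 0, 0, 0, 2.5, 1.0)) < 1e-12

    def test_plane_integral_closed_form(self):
        # (2 pi / 3) A_c sigma_c^2: centre minus 2/3-weighted surround
        sc, a_c = 2.5, 0.9
        g = np.linspace(-60, 60, 1201)
        vals = spatial_kernel(g[None, :], g[:, None], 0, 0, sc, a_c)
        integral = vals.sum() * (g[1] - g[0]) ** 2
        assert integral == pytest.approx(2 * np.pi / 3 * a_c * sc ** 2,
                                         rel=1e-3)


class TestFilterResponse:
    def test_static_gray_returns_baseline_exactly(self):
        bank = place_filters(n_per_type=3, field=(30, 30), seed=0)
        rates = bank_rates(bank, make_gray(1500))
        assert np.array_equal(rates,
                              np.tile(bank["r0"].to_numpy()[:, None], 1500))

    def test_first_500ms_overridden_with_baseline(self):
        f = single_filter()
        r = filter_response(f.iloc[0], make_grating(0, 0.05, 4.0,
                                                    duration_ms=1000))
        assert np.all(r[:500] == f["r0"].iloc[0])

    def test_on_off_mirror_linear_cancellation(self):
        # an ON and an OFF filter at the same spot see S and 255 - S; with
        # a high baseline neither rectifies and the linear parts cancel
        movie = make_grating(0, 0.05, 4.0, duration_ms=1000)
        on = single_filter("ON", r0=50.0)
        off = single_filter("OFF", r0=50.0)
        r_on = filter_response(on.iloc[0], movie)
        r_off = filter_response(off.iloc[0], movie)
        assert np.allclose(r_on + r_off, 100.0, atol=1e-9)
        assert r_on[500:].std() > 0.1       # but each one does modulate

    def test_movie_shorter_than_prefix_rejected(self):
        import v1l4sim.stimuli as st
        movie = st.StimulusMovie(np.full((300, 96, 192), 127.0,
                                         dtype=np.float32), "short")
        with pytest.raises(ValueError):
            bank_rates(single_filter(), movie)

    def test_rectification_floor(self):
        # tiny baseline, strong stimulus: rate never goes negative
        f = single_filter(r0=0.1, a_c=0.01)
        r = filter_response(f.iloc[0], make_grating(0, 0.05, 4.0,
                                                    duration_ms=1500))
        assert r.min() >= 0.0


class TestSpikes:
    def test_zero_rate_empty_train(self):
        assert len(generate_spikes(np.zeros(1000), seed=0)) == 0

    def test_poisson_count_statistics(self):
        rate = np.full(100_000, 10.0)          # 10 Hz for 100 s
        counts = [len(generate_spikes(rate, seed=s)) for s in range(30)]
        assert np.mean(counts) == pytest.approx(1000, rel=0.05)
        assert np.var(counts) == pytest.approx(1000, rel=0.5)

    def test_seeds_independent_same_rate(self):
        rate = np.full(5000, 20.0)
        a = generate_spikes(rate, seed=1)
        b = generate_spikes(rate, seed=2)
        assert not np.array_equal(a, b)
        assert len(a) == pytest.approx(len(b), rel=0.5)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            generate_spikes(np.array([-1.0]), seed=0)


class TestBank:
    def test_default_bank_composition(self):
        bank = place_filters(n_per_type=50, seed=0)
        assert len(bank) == 150
        assert (bank["ftype"].value_counts() == 50).all()

    def test_centers_within_field(self):
        bank = place_filters(n_per_type=200, field=(130, 90), seed=1)
        assert bank["x0"].abs().max() <= 65
        assert bank["y0"].abs().max() <= 45

    def test_on_off_subfields_distinct_and_displaced(self):
        bank = place_filters(n_per_type=20, seed=2)
        subs = subfield_table(bank)
        two = bank[bank["ftype"] == "ON_OFF"]
        assert len(subs) == 2 * 20 + 2 * 20   # ON + OFF singles, pairs
        d = np.hypot(two["sub_dx"], two["sub_dy"])
        assert np.allclose(d, 2.0 * two["sigma_c"])

    def test_parameter_ranges_respected(self):
        r = DEFAULT_PARAM_RANGES
        bank = place_filters(n_per_type=300, seed=3)
        assert bank["k"].between(*r.k).all()
        assert bank["sigma_c"].between(*r.sigma_c).all()
        assert bank["r0"].between(*r.r0).all()
        assert bank["a_c"].between(r.a_c * 0.9, r.a_c * 1.1).all()


class TestCalibrationTargets:
    def test_calibrated_ranges_peak_on_target_grid_cells(self):
        # independent check of the frozen defaults: every sampled filter's
        # F0 tuning, computed through the full movie pipeline, must peak at
        # 0.05 cpd and 4 Hz on the standard grids
        bank = place_filters(n_per_type=6, field=(30, 30), seed=5)
        f0_sf, f0_tf = lgn.sf_tf_tuning(bank)
        from v1l4sim.stimuli import GRATING_SFS, GRATING_TFS
        assert np.all(np.array(GRATING_SFS)[f0_sf.argmax(1)] == 0.05)
        assert np.all(np.array(GRATING_TFS)[f0_tf.argmax(1)] == 4.0)

    def test_kernel_peak_frequency_solvers_match_closed_form(self):
        # closed forms: temporal peak at 0.6102 k (rad/ms); spatial peak at
        # sqrt(ln(8/3)/3) / (pi sqrt(2) sigma_c) cycles per degree
        k = 0.0412
        got_tf = lgn._temporal_peak_tf(k)
        assert got_tf == pytest.approx(0.6102 * k / (2 * np.pi) * 1000,
                                       rel=0.02)
        sc = 2.574
        got_sf = lgn._spatial_peak_sf(sc)
        assert got_sf == pytest.approx(np.sqrt(np.log(8 / 3) / 3)
                                       / (np.pi * np.sqrt(2) * sc), rel=0.05)


class TestRetinotopy:
    @pytest.mark.parametrize("x_um,y_um,az,el", [
        (0, 0, 0, 0),
        (500, 0, 60, 0),
        (0, -200, 0, -10),
        (-845, 423, -101.4, 21.15),
    ])
    def test_linear_map(self, x_um, y_um, az, el):
        got = retinotopy_map(x_um, y_um)
        assert got[0] == pytest.approx(az)
        assert got[1] == pytest.approx(el)


class TestWiring:
    def test_caps_and_synapse_count(self):
        bank = place_filters(n_per_type=400, field=(40, 30), seed=6)
        cells = make_cells([("Scnn1a", 0, 0, 0), ("Scnn1a", 50, 20, 90),
                            ("PV1", -30, 10, 45)])
        conns = wire_lgn_to_l4(bank, cells, seed=7)
        assert np.all(conns.n_syn == 30)
        per_cell = pd.Series(conns.target).value_counts()
        assert per_cell.get(0, 0) <= 24 and per_cell.get(1, 0) <= 24
        assert per_cell.get(2, 0) <= 45

    def test_far_away_filter_never_selected(self):
        # a bank 50 degrees off the cell's mapped position is outside
        # every lasso
        bank = place_filters(n_per_type=100, field=(10, 10), seed=8)
        bank["x0"] += 50.0
        cells = make_cells([("Scnn1a", 0, 0, 0), ("PV1", 0, 0, 0)])
        conns = wire_lgn_to_l4(bank, cells, seed=9)
        assert len(conns) == 0

    def test_on_off_axis_condition(self):
        # ON/OFF filters aligned with the cell's preferred orientation are
        # eligible; orthogonal ones are not
        base = place_filters(n_per_type=1, field=(1, 1), seed=0)
        aligned = base[base["ftype"] == "ON_OFF"].copy()
        aligned[["x0", "y0"]] = 0.0
        aligned["axis_deg"] = 5.0
        orth = aligned.copy()
        orth["filter_id"] = 99
        orth["axis_deg"] = 95.0
        bank = pd.concat([aligned, orth], ignore_index=True)
        bank["ftype"] = bank["ftype"].astype("category")
        cells = make_cells([("Scnn1a", 0, 0, 0)])   # prefers 0 degrees
        conns = wire_lgn_to_l4(bank, cells, seed=1)
        assert set(conns.source) == {aligned["filter_id"].iloc[0]}
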