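import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from drowsefuse.indicators import (
    INDICATOR_CHANNEL,
    INDICATOR_NAMES,
    IndicatorParams,
    compute_indicator_series,
    lanex,
    load_params_preset,
    mse_indicator,
    perclos,
    rswm,
    std_indicator,
    tlc_5s,
    tlc_avg,
    tlc_series,
)

from conftest import make_session


# ---------------------------------------------------------------------------
# independent brute-force oracles (plain Python loops, no shared code path)
# ---------------------------------------------------------------------------


def oracle_std(xs):
    mean = sum(xs) / len(xs)
    return math.sqrt(sum((x - mean) ** 2 for x in xs) / (len(xs) - 1))


def oracle_mse(xs, p):
    return math.sqrt(sum((x - p) ** 2 for x in xs) / (len(xs) - 1))


def oracle_lanex(xs, x_l, x_r):
    return sum(1 for x in xs if x > x_l or x < x_r) / len(xs)


def oracle_tlc(xs, vs, x_l, x_r, tlc_max):
    out = []
    for x, v in zip(xs, vs):
        d_r, d_l = x_r - x, x_l - x
        if v < 0:
            t = d_r / v
        elif v > 0:
            t = d_l / v
        else:
            t = tlc_max
        t = min(t, tlc_max)
        if d_l < 0 or d_r > 0:
            t = 0.0
        out.append(t)
    return out


def oracle_tlc_5s(ts, a):
    return sum(1 for t in ts[:-1] if t < a)


def oracle_rswm(ss, d):
    return sum(1 for s in ss[1:] if abs(s) > d) / (len(ss) - 1)


def oracle_perclos(xs, thr, blink_max, rate):
    retained, run = 0, 0
    for x in list(xs) + [0.0]:  # sentinel flushes the final run
        if x > thr:
            run += 1
        else:
            if run / rate > blink_max:
                retained += run
            run = 0
    return retained / len(xs)


class TestAgainstOracles:
    """Every indicator matches its independently coded oracle on random windows."""

    def test_std_mse(self, rng):
        for _ in range(20):
            w = rng.normal(1.875, 0.4, 900)
            assert std_indicator(w) == pytest.approx(oracle_std(w.tolist()), rel=1e-12)
            p = rng.uniform(1.0, 2.7)
            assert mse_indicator(w, p) == pytest.approx(oracle_mse(w.tolist(), p), rel=1e-12)

    def test_lanex_counting(self, rng):
        for _ in range(20):
            w = rng.uniform(0.5, 3.2, 900)
            assert lanex(w, 2.625, 1.125) == pytest.approx(oracle_lanex(w.tolist(), 2.625, 1.125), rel=1e-12)

    def test_tlc_chain(self, rng):
        for _ in range(20):
            x = rng.uniform(0.8, 2.9, 900)
            v = rng.normal(0.0, 0.4, 900)
            v[rng.integers(0, 900, 30)] = 0.0  # exercise the zero-speed branch
            got = tlc_series(x, v, 2.625, 1.125, 30.0)
            exp = np.array(oracle_tlc(x.tolist(), v.tolist(), 2.625, 1.125, 30.0))
            assert np.allclose(got, exp, rtol=1e-12, atol=0)
            assert tlc_5s(got, 5.0) == oracle_tlc_5s(exp.tolist(), 5.0)
            assert tlc_avg(got) == pytest.approx(-np.mean(exp), rel=1e-12)

    def test_rswm_counting(self, rng):
        for _ in range(20):
            s = rng.normal(0.0, 60.0, 900)
            for d in (125.0, 13.0):
                assert rswm(s, d) == pytest.approx(oracle_rswm(s.tolist(), d), rel=1e-12)

    def test_perclos_episodes(self, rng):
        for _ in range(20):
            w = rng.uniform(0.0, 1.0, 900)
            got = perclos(w, 0.8, 0.5, 30.0)
            assert got == pytest.approx(oracle_perclos(w.tolist(), 0.8, 0.5, 30.0), abs=1e-15)


class TestWorkedExamples:
    def test_std_of_two_values(self):
        assert std_indicator(np.array([1.0, 3.0])) == pytest.approx(math.sqrt(2.0), rel=1e-12)

    def test_std_constant_window(self):
        assert std_indicator(np.full(900, 1.875)) == 0.0

    def test_mse_reduces_to_std_at_window_mean(self, rng):
        w = rng.normal(0.0, 1.0, 900)
        assert mse_indicator(w, w.mean()) == pytest.approx(std_indicator(w), rel=1e-12)

    def test_mse_zero_at_reference(self):
        assert mse_indicator(np.full(900, 1.875), 1.875) == 0.0

    def test_lanex_extremes_and_half(self):
        inside = np.full(900, 1.875)
        assert lanex(inside, 2.625, 1.125) == 0.0
        outside = np.full(900, 3.0)
        assert lanex(outside, 2.625, 1.125) == 1.0
        half = np.concatenate([np.full(450, 3.0), np.full(450, 1.875)])
        assert lanex(half, 2.625, 1.125) == 0.5

    def test_lanex_boundary_counts_as_inside(self):
        # strict inequalities: samples exactly on a line are inside
        on_lines = np.concatenate([np.full(450, 2.625), np.full(450, 1.125)])
        assert lanex(on_lines, 2.625, 1.125) == 0.0

    def test_tlc_worked_case(self):
        """Center of the lane moving right at 0.375 m/s: d_R = -0.75 m -> 2 s."""
        t = tlc_series(np.array([1.875]), np.array([-0.375]))
        assert t[0] == pytest.approx(2.0, rel=1e-12)

    def test_tlc_zero_speed_saturates(self):
        t = tlc_series(np.array([1.875]), np.array([0.0]), tlc_max=30.0)
        assert t[0] == 30.0

    def test_tlc_outside_virtual_lane_is_zero(self):
        t = tlc_series(np.array([2.70]), np.array([0.1]))
        assert t[0] == 0.0

    def test_tlc_5s_ignores_last_sample(self):
        below = np.full(900, 1.0)
        assert tlc_5s(below, 5.0) == 899
        assert tlc_5s(np.full(900, 30.0), 5.0) == 0

    def test_tlc_avg_sign(self):
        assert tlc_avg(np.full(10, 2.0)) == -2.0
        assert tlc_avg(np.zeros(10)) == 0.0

    def test_rswm_extremes_and_count(self, rng):
        assert rswm(np.zeros(900), 125.0) == 0.0
        assert rswm(np.full(900, 200.0), 125.0) == 1.0
        s = np.zeros(900)
        s[1:451] = 200.0  # 450 exceedances among samples 2..900
        assert rswm(s, 125.0) == pytest.approx(450 / 899, rel=1e-12)

    def test_perclos_examples(self):
        open_eyes = np.full(900, 0.1)
        assert perclos(open_eyes) == 0.0
        closed = np.full(900, 1.0)
        assert perclos(closed) == 1.0
        # one 9-s closed episode in a 30-s window -> 270/900
        w = np.full(900, 0.1)
        w[100 : 100 + 270] = 1.0
        assert perclos(w) == pytest.approx(0.3, rel=1e-12)

    def test_perclos_excludes_blinks(self):
        w = np.full(900, 0.1)
        for k in range(10):  # ten isolated 0.2-s closures
            start = k * 90
            w[start : start + 6] = 1.0
        assert perclos(w, blink_max=0.5) == 0.0

    def test_perclos_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            perclos(np.full(900, 1.5))


class TestInvariants:
    @given(
        w=arrays(float, 50, elements=st.floats(-100, 100)),
        shift=st.floats(-50, 50),
        scale=st.floats(0.1, 10),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_std_translation_and_scale(self, w, shift, scale):
        base = std_indicator(w)
        assert std_indicator(w + shift) == pytest.approx(base, rel=1e-9, abs=1e-9)
        assert std_indicator(w * scale) == pytest.approx(scale * base, rel=1e-9, abs=1e-9)

    @given(
        w=arrays(float, 50, elements=st.floats(-10, 10)),
        p=st.floats(-10, 10),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mse_dominates_std(self, w, p):
        assert mse_indicator(w, p) >= std_indicator(w) - 1e-12

    def test_lanex_monotone_in_lane_width(self, rng):
        w = rng.uniform(0.5, 3.2, 900)
        narrow = lanex(w, 2.3, 1.4)
        wide = lanex(w, 2.6, 1.2)
        assert wide <= narrow

    def test_rswm_monotone_in_threshold(self, rng):
        s = rng.normal(0.0, 60.0, 900)
        assert rswm(s, 50.0) >= rswm(s, 125.0)

    def test_tlc_5s_monotone_in_alarm(self, rng):
        x = rng.uniform(1.2, 2.6, 900)
        t = tlc_series(x, rng.normal(0, 0.3, 900))
        assert tlc_5s(t, 6.4) >= tlc_5s(t, 5.0)

    def test_bounded_outputs(self, rng):
        x = rng.uniform(0.0, 3.75, 900)
        v = rng.normal(0, 0.5, 900)
        t = tlc_series(x, v, tlc_max=30.0)
        assert np.all((t >= 0) & (t <= 30.0))
        assert 0 <= lanex(x, 2.625, 1.125) <= 1
        assert 0 <= rswm(v * 100, 125.0) <= 1
        assert -30.0 <= tlc_avg(t) <= 0

    def test_identical_windows_identical_values(self, rng):
        """Indicators are functions of the window alone."""
        w = rng.uniform(0.5, 3.2, 900)
        session = make_session(
            n_seconds=90,
            lateral_position=np.tile(w, 3),
            eye_closure=np.tile(rng.uniform(0, 1, 900), 3),
        )
        for name in ("STD_lp", "MSE_lp", "Lanex", "PERCLOS"):
            series = compute_indicator_series(session, IndicatorParams.defaults(name))
            assert np.allclose(series.values, series.values[0])


class TestSeriesDispatch:
    def test_ten_windows_per_interval(self):
        session = make_session(n_seconds=300)
        series = compute_indicator_series(session, IndicatorParams.defaults("STD_lp"))
        assert len(series) == 10
        assert np.allclose(series.t_end, np.arange(1, 11) * 30.0)

    def test_constant_lateral_position_gives_zero_std(self):
        session = make_session(n_seconds=300, lateral_position=np.full(9000, 1.875))
        series = compute_indicator_series(session, IndicatorParams.defaults("STD_lp"))
        assert np.allclose(series.values, 0.0)

    @pytest.mark.parametrize("name", INDICATOR_NAMES)
    def test_dispatch_matches_per_window_oracle(self, name, rng):
        """Series values equal the scalar kernels applied window by window."""
        session = make_session(n_seconds=120, seed=3)
        params = IndicatorParams.defaults(name)
        series = compute_indicator_series(session, params)
        channel = session.channel(INDICATOR_CHANNEL[name])
        from drowsefuse.signal_core import derivative

        speed = derivative(channel, session.sample_rate)
        for i in range(len(series)):
            w = channel[i * 900 : (i + 1) * 900]
            sw = speed[i * 900 : (i + 1) * 900]
            if name in ("STD_lp", "STD_sw", "STD_he"):
                expected = std_indicator(w)
            elif name in ("MSE_lp", "MSE_he"):
                expected = mse_indicator(w, params.p)
            elif name == "Lanex":
                expected = lanex(w, params.x_L, params.x_R)
            elif name == "TLC_5s":
                expected = float(tlc_5s(tlc_series(w, sw, params.x_L, params.x_R, params.tlc_max), params.a))
            elif name == "TLC_avg":
                expected = tlc_avg(tlc_series(w, sw, params.x_L, params.x_R, params.tlc_max))
            elif name == "RSWM":
                expected = rswm(sw, params.d)
            else:
                expected = perclos(w, params.closure_threshold, params.blink_max, session.sample_rate)
            assert series.values[i] == pytest.approx(expected, rel=1e-12, abs=1e-15)

    def test_unknown_indicator_rejected(self):
        with pytest.raises(ValueError):
            IndicatorParams(name="BOGUS")


class TestPresets:
    def test_shipped_presets_load(self):
        defaults = load_params_preset("defaults")
        optimized = load_params_preset("table2_optimized")
        assert defaults["MSE_lp"].p == 1.875
        assert defaults["RSWM"].d == 125.0
        assert optimized["MSE_lp"].p == 1.865
        assert optimized["MSE_he"].p == -1.2
        assert optimized["Lanex"].x_L == 2.27
        assert optimized["Lanex"].x_R == 1.42
        assert optimized["TLC_5s"].a == 6.4
        assert optimized["RSWM"].d == 13.0

    def test_yaml_preset_files_match_constructors(self):
        from importlib import resources

        for preset_name, ctor in (
            ("defaults", IndicatorParams.defaults),
            ("table2_optimized", IndicatorParams.table2_optimized),
        ):
            path = resources.files("drowsefuse") / "presets" / f"{preset_name}.yaml"
            loaded = load_params_preset(str(path))
            for name in INDICATOR_NAMES:
                built = ctor(name)
                for attr in ("p", "x_L", "x_R", "a", "d", "closure_threshold"):
                    assert getattr(loaded[name], attr) == getattr(built, attr)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            IndicatorParams(name="Lanex", x_L=1.0, x_R=2.0)
        with pytest.raises(ValueError):
            IndicatorParams(name="TLC_5s", a=40.0, tlc_max=30.0)
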