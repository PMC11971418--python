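"""Unit and property tests for the EF-LUE stress factors and daily GPP."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cropwue as cw
from cropwue.params import WATTS_TO_MJ_DAY


# --- independent scalar oracles, written directly from the model equations ---

def ft_oracle(t, tmin, tmax, topt):
    if t < tmin or t > tmax:
        return 0.0
    num = (t - tmin) * (t - tmax)
    den = num - (t - topt) ** 2
    return num / den if den != 0 else 1.0


def vpd_oracle(t, td, c=17.27):
    return 0.6108 * (math.exp(c * t / (t + 237.3)) - math.exp(c * td / (td + 237.3)))


def fw_oracle(et, rn, g, lam=2.45):
    avail = (rn - g) * WATTS_TO_MJ_DAY
    if avail <= 0:
        return 0.0
    return min(1.0, max(0.0, lam * et / avail))


class TestTemperatureFactor:
    @pytest.mark.parametrize("ta, expected", [
        (30.0, 1.0),     # at the optimum the quadratic term vanishes
        (-5.0, 0.0),     # below the lower cutoff -> zero LUE
        (45.0, 0.0),     # above the upper cutoff -> zero LUE
        (0.0, 0.0),      # boundary: quotient itself is zero
        (40.0, 0.0),
        (20.0, 0.8),     # hand evaluation: -400 / (-400 - 100)
    ])
    def test_examples(self, params, ta, expected):
        assert cw.temperature_factor(ta, params) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(-60, 80))
    @settings(deadline=None, max_examples=200)
    def test_in_unit_interval(self, ta):
        p = cw.LUEParameters(3.0, 30.0, 2.0)
        f = cw.temperature_factor(ta, p)
        assert 0.0 <= f <= 1.0


class TestVPD:
    def test_saturated_air_has_zero_deficit(self, params):
        assert cw.vpd_from_temperatures(15.0, 15.0) == pytest.approx(0.0)

    def test_tetens_hand_value(self):
        # 0.6108*(e^{17.27*25/262.3} - e^{17.27*15/252.3})
        assert cw.vpd_from_temperatures(25.0, 15.0) == pytest.approx(1.4624, abs=1e-3)

    def test_printed_variant_coefficient(self):
        got = cw.vpd_from_temperatures(25.0, 15.0, magnus_coef=12.27)
        assert got == pytest.approx(vpd_oracle(25.0, 15.0, 12.27), rel=1e-12)

    def test_rejects_dew_point_above_air(self):
        with pytest.raises(ValueError):
            cw.vpd_from_temperatures(10.0, 12.0)

    def test_monotone_in_dew_point(self):
        td = np.linspace(-5.0, 25.0, 50)
        vpd = cw.vpd_from_temperatures(np.full_like(td, 25.0), td)
        assert np.all(np.diff(vpd) < 0)
        assert np.all(vpd >= 0)


class TestVPDFactor:
    @pytest.mark.parametrize("vpd, expected", [
        (0.0, 1.0),
        (2.0, 0.5),   # half-saturation at vpd == vpd0
        (6.0, 0.25),  # 2 / (2 + 6)
    ])
    def test_examples(self, params, vpd, expected):
        assert cw.vpd_factor(vpd, params) == pytest.approx(expected)

    def test_rejects_negative(self, params):
        with pytest.raises(ValueError):
            cw.vpd_factor(-0.1, params)

    def test_strictly_decreasing(self, params):
        v = np.linspace(0, 5, 100)
        f = cw.vpd_factor(v, params)
        assert np.all(np.diff(f) < 0)
        assert np.all((f > 0) & (f <= 1))


class TestWaterFactor:
    def test_exact_energy_balance_gives_one(self):
        rn, g = 110.0, 10.0
        et = (rn - g) * WATTS_TO_MJ_DAY / 2.45
        assert cw.water_factor(et, rn, g) == pytest.approx(1.0)

    def test_zero_et_gives_zero(self):
        assert cw.water_factor(0.0, 100.0, 10.0) == 0.0

    def test_clamping(self):
        rn, g = 100.0, 0.0
        et_high = 1.3 * rn * WATTS_TO_MJ_DAY / 2.45  # EF = 1.3
        assert cw.water_factor(et_high, rn, g) == 1.0

    def test_degenerate_energy_fallback(self):
        assert cw.water_factor(1.0, -5.0, 0.0) == 0.0
        assert cw.water_factor(1.0, 10.0, 10.0) == 0.0


class TestDailyGPP:
    def _unstressed(self, n=4):
        # ta at t_opt, td == ta (VPD 0), EF >= 1: all factors exactly 1
        rn = np.full(n, 200.0)
        g = np.zeros(n)
        et = 1.1 * rn * WATTS_TO_MJ_DAY / 2.45
        return cw.DailyForcing(ta=np.full(n, 30.0), td=np.full(n, 30.0),
                               sw=np.full(n, 125.0 / 6.0), et=et, rn=rn, g=g,
                               fapar=np.full(n, 0.5), lai=np.zeros(n))

    def test_pure_product(self, params):
        f = self._unstressed()
        # fapar * (0.48 * sw) * eps_max = 0.5 * 10 * 3
        assert cw.daily_gpp(f, params) == pytest.approx(15.0)

    def test_zero_above_tmax(self, params):
        f = self._unstressed()
        f.ta[:] = 45.0
        f.td[:] = 20.0
        assert np.all(cw.daily_gpp(f, params) == 0.0)

    def test_linear_in_fapar(self, params):
        f1 = self._unstressed()
        f2 = self._unstressed()
        f2.fapar[:] = 2 * f1.fapar
        assert cw.daily_gpp(f2, params) == pytest.approx(2 * cw.daily_gpp(f1, params))

    def test_monotone_in_drivers(self, params, rng):
        f = self._unstressed(50)
        f.ta[:] = rng.uniform(5, 25, 50)
        f.td[:] = f.ta - rng.uniform(0, 5, 50)
        base = cw.daily_gpp(f, params)
        for attr in ("fapar", "sw"):
            bumped = self._unstressed(50)
            bumped.ta[:], bumped.td[:] = f.ta, f.td
            getattr(bumped, attr)[:] = getattr(f, attr) * 1.1
            assert np.all(cw.daily_gpp(bumped, params) >= base - 1e-12)


class TestOracleEquivalence:
    def test_factors_match_direct_evaluation(self, rng):
        """Vectorized factors agree with scalar transcriptions of the model
        equations on 1,000 random admissible inputs to 1e-12."""
        p = cw.LUEParameters(3.364, 29.995, 2.380)
        n = 1000
        ta = rng.uniform(-10, 45, n)
        td = ta - rng.uniform(0, 10, n)
        et = rng.uniform(0, 8, n)
        rn = rng.uniform(-20, 250, n)
        g = rng.uniform(-5, 30, n)
        ft = cw.temperature_factor(ta, p)
        vpd = np.where(ta > p.t_min, cw.vpd_from_temperatures(ta, td), 0.0)
        fw = cw.water_factor(et, rn, g)
        for i in range(n):
            assert ft[i] == pytest.approx(
                ft_oracle(ta[i], p.t_min, p.t_max, p.t_opt), rel=1e-12, abs=1e-12)
            assert fw[i] == pytest.approx(
                fw_oracle(et[i], rn[i], g[i]), rel=1e-12, abs=1e-12)
            if ta[i] > p.t_min:
                assert vpd[i] == pytest.approx(
                    vpd_oracle(ta[i], td[i]), rel=1e-12, abs=1e-12)
                assert cw.vpd_factor(vpd[i], p) == pytest.approx(
                    p.vpd0 / (p.vpd0 + vpd_oracle(ta[i], td[i])), rel=1e-12)


class TestInterpolation:
    def test_midpoint_of_linear_segment(self):
        nodes = pd.Series([0.2, 1.0],
                          index=pd.to_datetime(["2001-01-01", "2001-01-09"]))
        daily = cw.interpolate_8day_to_daily(nodes)
        assert daily["2001-01-05"] == pytest.approx(0.6)

    def test_nodes_preserved_and_terminal_hold(self):
        idx = pd.to_datetime(["2001-01-01", "2001-01-09", "2001-01-17"])
        nodes = pd.Series([0.3, 0.7, 0.4], index=idx)
        target = pd.date_range("2000-12-28", "2001-01-20", freq="D")
        daily = cw.interpolate_8day_to_daily(nodes, target)
        for d, v in nodes.items():
            assert daily[d] == pytest.approx(v)
        assert daily["2000-12-30"] == pytest.approx(0.3)  # hold before first
        assert daily["2001-01-20"] == pytest.approx(0.4)  # hold after last

    def test_constant_nodes_give_constant_series(self):
        idx = pd.date_range("2001-01-01", periods=5, freq="8D")
        daily = cw.interpolate_8day_to_daily(pd.Series(0.42, index=idx))
        assert np.allclose(daily.to_numpy(), 0.42)

    def test_single_node_warns_and_is_constant(self):
        nodes = pd.Series([0.5], index=pd.to_datetime(["2001-01-01"]))
        target = pd.date_range("2001-01-01", periods=10, freq="D")
        with pytest.warns(UserWarning):
            daily = cw.interpolate_8day_to_daily(nodes, target)
        assert np.allclose(daily.to_numpy(), 0.5)

    def test_rejects_unsorted_nodes(self):
        idx = pd.to_datetime(["2001-01-09", "2001-01-01"])
        with pytest.raises(ValueError):
            cw.interpolate_8day_to_daily(pd.Series([1.0, 2.0], index=idx))


@given(ta=st.floats(-30, 60), dew_dep=st.floats(0, 20),
       et=st.floats(0, 10), rn=st.floats(-50, 300), g=st.floats(-10, 50),
       fapar=st.floats(0, 1), sw=st.floats(0, 35))
@settings(deadline=None, max_examples=300)
def test_gpp_nonnegative_and_factors_bounded(ta, dew_dep, et, rn, g, fapar, sw):
    """For any admissible drivers, all stress factors lie in [0,1] and GPP >= 0."""
    p = cw.LUEParameters(3.0, 28.0, 1.2)
    ft = cw.temperature_factor(ta, p)
    fw = cw.water_factor(et, rn, g)
    assert 0.0 <= ft <= 1.0
    assert 0.0 <= fw <= 1.0
    f = cw.DailyForcing(*[np.array([x], float) for x in
                          (ta, ta - dew_dep, sw, et, rn, g, fapar, 0.0)])
    assert cw.daily_gpp(f, p)[0] >= 0.0
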