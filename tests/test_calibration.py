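"""Per-zone bounded least-squares calibration and the parameter lookup."""

import numpy as np
import pandas as pd
import pytest

import cropwue as cw
from cropwue.calibration import TooFewDataError


def make_records(truth, noise=0.0, n_sites=3, seed=1, zone="Dfa"):
    cfg = cw.SyntheticConfig(n_sites=n_sites, n_years=1, seed=seed,
                             noise_sd_frac=noise)
    forcing = cw.generate_daily_forcing(cfg)
    return [cw.generate_site_observations(frame, truth, noise,
                                          seed=seed * 100 + i,
                                          site_id=sid, zone=zone)
            for i, (sid, frame) in enumerate(forcing.items())]


class TestFitZone:
    def test_noiseless_recovery_is_exact(self):
        """Noiseless synthetic records invert to the generating triple."""
        truth = cw.LUEParameters(3.364, 29.995, 2.380)
        res = cw.fit_zone(make_records(truth, noise=0.0))
        for got, want in zip(res.triple, truth.triple):
            assert got == pytest.approx(want, abs=1e-3)
        assert res.rmse < 1e-6
        assert res.converged

    def test_noiseless_recovery_interior_optimum(self):
        """A triple with t_opt well inside the observed temperature range
        is also recovered to optimizer tolerance."""
        truth = cw.LUEParameters(2.5, 20.0, 1.5)
        res = cw.fit_zone(make_records(truth, noise=0.0, seed=5))
        for got, want in zip(res.triple, truth.triple):
            assert got == pytest.approx(want, abs=1e-3)

    def test_objective_never_worse_than_start(self):
        truth = cw.LUEParameters(3.0, 25.0, 2.0)
        res = cw.fit_zone(make_records(truth, noise=0.10, seed=3))
        assert res.cost <= res.cost_at_init
        assert res.nfev >= 1
        assert res.nobs >= 30

    def test_bounds_respected(self):
        spec = cw.OptimizationSpec()
        truth = cw.LUEParameters(3.8, 29.0, 2.9)
        res = cw.fit_zone(make_records(truth, noise=0.20, seed=9), spec=spec)
        for v, lo, hi in zip(res.triple, spec.lower, spec.upper):
            assert lo <= v <= hi

    def test_zero_variance_flags_non_identifiable(self, site_forcing):
        data = site_forcing.copy()
        data["gpp_obs"] = 0.0
        rec = cw.SiteRecordSet("s0", "Dfa", data)
        res = cw.fit_zone([rec])
        assert not res.identifiable
        assert "not identifiable" in res.summary()

    def test_too_few_days_rejected(self, site_forcing):
        data = site_forcing.copy()
        data["gpp_obs"] = 1.0
        data.iloc[10:, data.columns.get_loc("gpp_obs")] = np.nan
        rec = cw.SiteRecordSet("s0", "Dfa", data)
        with pytest.raises(TooFewDataError):
            cw.fit_zone([rec])

    def test_per_site_diagnostic_mode(self):
        truth = cw.LUEParameters(3.0, 22.0, 2.0)
        records = make_records(truth, noise=0.0, n_sites=2)
        fits = cw.fit_per_site(records)
        assert set(fits) == {r.site_id for r in records}
        for res in fits.values():
            assert res.params.eps_max == pytest.approx(3.0, abs=1e-3)


class TestRecoveryUnderNoise:
    def test_median_eps_max_error_under_5pct_noise(self):
        """Across 20 seeds at 5% observation noise, the median absolute
        eps_max error stays below 5% of truth."""
        truth = cw.LUEParameters(3.364, 29.995, 2.380)
        errs = []
        for seed in range(20):
            res = cw.fit_zone(make_records(truth, noise=0.05, seed=seed))
            errs.append(abs(res.params.eps_max - truth.eps_max) / truth.eps_max)
        assert np.median(errs) <= 0.05


class TestZoneParameterTable:
    def test_packaged_table_rows(self, zone_table):
        frame = zone_table.to_frame()
        assert len(frame) == 9
        assert set(frame["zone"]) == {"Bwk", "BSk", "Csa", "Cfa", "Cfb",
                                      "Dfa", "Dfb", "Dfc", "Default"}
        assert zone_table.default_entry.triple == (3.364, 29.995, 2.380)
        assert zone_table.lookup("BSk").triple == (3.997, 19.683, 2.996)

    def test_unlisted_zone_falls_back_to_default(self, zone_table):
        assert zone_table.lookup("Af") is zone_table.default_entry
        assert "Af" not in zone_table

    def test_csv_round_trip(self, zone_table, tmp_path):
        path = tmp_path / "table.csv"
        zone_table.to_csv(path)
        back = cw.ZoneParameterTable.from_csv(path)
        for z in ("Bwk", "Dfc"):
            assert back.lookup(z).triple == zone_table.lookup(z).triple
        assert back.default_entry.triple == zone_table.default_entry.triple

    def test_build_is_order_independent(self):
        t1 = cw.LUEParameters(3.0, 22.0, 2.0)
        t2 = cw.LUEParameters(2.2, 18.0, 1.0)
        r1 = make_records(t1, n_sites=2, seed=1, zone="Dfa")
        r2 = make_records(t2, n_sites=2, seed=2, zone="Cfb")
        table_a = cw.build_parameter_table({"Dfa": r1, "Cfb": r2}, r1 + r2)
        table_b = cw.build_parameter_table({"Cfb": r2, "Dfa": r1}, r2 + r1)
        for z in ("Dfa", "Cfb"):
            assert table_a.lookup(z).triple == pytest.approx(
                table_b.lookup(z).triple, rel=1e-6)
        assert "Dfa" in table_a and "Cfb" in table_a
        assert table_a.default_entry is not None


class TestParametersToRaster:
    def test_uniform_map_gives_constant_bands(self, zone_table):
        zm = np.full((4, 5), "Cfa", dtype="<U8")
        bands = cw.parameters_to_raster(zone_table, zm)
        assert bands.shape == (3, 4, 5)
        p = zone_table.lookup("Cfa")
        assert np.all(bands[0] == p.eps_max)
        assert np.all(bands[1] == p.t_opt)
        assert np.all(bands[2] == p.vpd0)

    def test_unlisted_code_gets_default(self, zone_table):
        zm = np.full((2, 2), "Af", dtype="<U8")
        bands = cw.parameters_to_raster(zone_table, zm)
        assert np.all(bands[0] == zone_table.default_entry.eps_max)

    def test_checkerboard_exact_assignment(self, zone_table):
        zm = np.empty((4, 4), dtype="<U8")
        zm[::2, ::2] = zm[1::2, 1::2] = "Dfa"
        zm[::2, 1::2] = zm[1::2, ::2] = "BSk"
        bands = cw.parameters_to_raster(zone_table, zm)
        for r in range(4):
            for c in range(4):
                want = zone_table.lookup(str(zm[r, c]))
                assert bands[0, r, c] == want.eps_max
                assert bands[2, r, c] == want.vpd0

    def test_nodata_label_propagates(self, zone_table):
        zm = np.array([["Dfa", ""], ["", "Dfa"]], dtype="<U8")
        bands = cw.parameters_to_raster(zone_table, zm, nodata_label="")
        assert np.isnan(bands[0, 0, 1]) and np.isnan(bands[1, 1, 0])
        assert bands[0, 0, 0] == zone_table.lookup("Dfa").eps_max
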