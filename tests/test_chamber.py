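"""Closed-chamber flux computation: fitting, gas-law conversion, QC,
outlier screening and annual aggregation."""

import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_run, ols_oracle
from peatflux import chamber as ch
from peatflux.chamber import (
    AnnualFlux,
    FitError,
    FluxRecord,
    aggregate_daily_plot,
    annualize,
    ch4_to_co2e,
    fit_linear_deadband,
    landscape_mean,
    qc_filter,
    screen_outliers,
    site_total_co2e,
    slope_to_flux,
)
from peatflux.constants import R_GAS, mg_ha_yr_to_umol, umol_to_mg_ha_yr


class TestFitLinearDeadband:
    def test_noiseless_line_recovered_exactly(self):
        t = np.arange(0.0, 121.0)
        fit = fit_linear_deadband(t, 400.0 + 0.5 * t)
        assert fit.slope == pytest.approx(0.5, rel=1e-12)
        assert fit.intercept == pytest.approx(400.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.n_points == 110  # (10, 120] at 1 Hz

    def test_constant_series_slope_zero_r2_zero(self):
        t = np.arange(0.0, 121.0)
        fit = fit_linear_deadband(t, np.full_like(t, 420.0))
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0  # zero-variance convention

    def test_window_excludes_dead_band_and_respects_stop(self):
        # Concentrations before the dead band are wild; the fit must ignore them
        t = np.arange(0.0, 121.0)
        y = 400.0 + 0.5 * t
        y[t <= 10] = 9999.0
        y[t > 115] = -9999.0
        fit = fit_linear_deadband(t, y, deadband_s=10, stop_s=115)
        assert fit.slope == pytest.approx(0.5, rel=1e-12)

    def test_too_few_points_raises(self):
        with pytest.raises(FitError):
            fit_linear_deadband([0, 5, 50, 130], [1, 2, 3, 4], deadband_s=10, stop_s=120)

    def test_matches_normal_equations_oracle_on_noisy_ramp(self, rng):
        t = np.linspace(0, 120, 121)
        y = 420.0 + 0.13 * t + rng.normal(0, 0.3, t.size)
        fit = fit_linear_deadband(t, y)
        mask = (t > 10) & (t <= 120)
        slope, intercept, r2 = ols_oracle(t[mask], y[mask])
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10)
        assert fit.r_squared == pytest.approx(r2, rel=1e-10)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        slope=st.floats(-0.5, 0.5),
        noise=st.floats(0.0, 2.0),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_fit_equivalence_property(self, slope, noise, seed):
        """Fitted slope/R² agree with the brute-force oracle on any window data."""
        r = np.random.default_rng(seed)
        t = np.arange(0.0, 121.0)
        y = 420.0 + slope * t + r.normal(0, noise, t.size)
        fit = fit_linear_deadband(t, y)
        mask = (t > 10) & (t <= 120)
        o_slope, _, o_r2 = ols_oracle(t[mask], y[mask])
        assert fit.slope == pytest.approx(o_slope, rel=1e-10, abs=1e-14)
        assert fit.r_squared == pytest.approx(o_r2, rel=1e-10, abs=1e-12)


class TestSlopeToFlux:
    def test_hand_computed_value(self):
        # flux = slope · P·V/(R·T·A), evaluated once by hand for these inputs
        expected = 0.5 * (101325.0 * 0.004) / (R_GAS * 298.15 * 0.0314)
        got = slope_to_flux(0.5, 298.15, 101.325, 0.004, 0.0314)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(2.6036, rel=1e-4)

    def test_zero_slope_zero_flux(self):
        assert slope_to_flux(0.0, 300.0, 101.0, 0.005, 0.03) == 0.0

    def test_linearity_in_volume_and_area(self):
        base = slope_to_flux(0.2, 300.0, 101.0, 0.005, 0.03)
        assert slope_to_flux(0.2, 300.0, 101.0, 0.010, 0.03) == pytest.approx(2 * base)
        assert slope_to_flux(0.2, 300.0, 101.0, 0.005, 0.06) == pytest.approx(base / 2)

    @pytest.mark.parametrize("bad", ["temp", "pressure", "volume", "area"])
    def test_nonpositive_parameters_rejected(self, bad):
        kwargs = dict(air_temp_k=300.0, pressure_kpa=101.0, volume_m3=0.005, area_m2=0.03)
        key = {"temp": "air_temp_k", "pressure": "pressure_kpa",
               "volume": "volume_m3", "area": "area_m2"}[bad]
        kwargs[key] = 0.0
        with pytest.raises(ValueError):
            slope_to_flux(0.1, **kwargs)


def _record(gas, r2, flux=1.0, site="PPSF", plot=1, rep=1, date=dt.date(2022, 10, 10)):
    fit = ch.FitResult(0.1, 420.0, r2, 110, (10.0, 120.0))
    return FluxRecord(f"{site}-{plot}-{rep}", site, plot, date, rep, gas, flux, fit, qc_pass=True)


class TestQC:
    @pytest.mark.parametrize(
        "gas,r2,expected",
        [
            ("CO2", 0.85, False),  # below the CO2 threshold
            ("CH4", 0.85, True),   # above the CH4 threshold
            ("CO2", 1.0, True),
            ("CH4", 1.0, True),
            ("CO2", 0.9, False),   # boundary: strict inequality
            ("CH4", 0.7, False),
            ("CO2", 0.90001, True),
        ],
    )
    def test_threshold_rules(self, gas, r2, expected):
        assert qc_filter(_record(gas, r2)) is expected

    def test_unknown_gas_rejected(self):
        with pytest.raises(ValueError):
            qc_filter(_record("N2O", 0.99))

    def test_lowering_threshold_never_loses_records(self, rng):
        records = [_record("CO2", r2) for r2 in rng.uniform(0, 1, 200)]
        counts = [
            sum(qc_filter(r, {"CO2": thr, "CH4": 0.7}) for r in records)
            for thr in (0.95, 0.9, 0.7, 0.5, 0.0)
        ]
        assert counts == sorted(counts)


class TestOutlierScreen:
    def test_identical_fluxes_none_flagged(self):
        recs = [_record("CO2", 0.99, flux=1.0, rep=i) for i in range(10)]
        assert not any(r.outlier for r in screen_outliers(recs))

    def test_single_extreme_value_flagged(self, rng):
        fluxes = list(1.0 + 0.05 * rng.standard_normal(29)) + [100.0]
        recs = [_record("CO2", 0.99, flux=f, rep=i) for i, f in enumerate(fluxes)]
        out = screen_outliers(recs, k=3.0)
        flagged = [r for r in out if r.outlier]
        assert len(flagged) == 1
        assert flagged[0].flux_umol_m2_s == 100.0

    def test_infinite_k_flags_nothing(self, rng):
        recs = [_record("CO2", 0.99, flux=f, rep=i)
                for i, f in enumerate(rng.uniform(-10, 10, 30))]
        assert not any(r.outlier for r in screen_outliers(recs, k=math.inf))

    def test_inputs_not_mutated(self):
        recs = [_record("CO2", 0.99, flux=f, rep=i) for i, f in enumerate([1, 1, 1, 50.0])]
        screen_outliers(recs)
        assert not any(r.outlier for r in recs)


class TestDailyAggregation:
    def test_replicate_means(self):
        recs = [_record("CO2", 0.99, flux=f, rep=i) for i, f in enumerate((0.8, 1.0, 1.2))]
        daily = aggregate_daily_plot(recs)
        assert len(daily) == 1
        assert daily["flux_umol_m2_s"].iloc[0] == pytest.approx(1.0)
        assert daily["n_replicates"].iloc[0] == 3

    def test_failing_replicates_excluded(self):
        recs = [_record("CO2", 0.99, flux=1.0, rep=1),
                _record("CO2", 0.99, flux=3.0, rep=2),
                _record("CO2", 0.5, flux=99.0, rep=3)]
        recs[2].qc_pass = False
        daily = aggregate_daily_plot(recs)
        assert daily["flux_umol_m2_s"].iloc[0] == pytest.approx(2.0)
        assert daily["n_replicates"].iloc[0] == 2

    def test_all_failing_yields_no_row(self):
        recs = [_record("CO2", 0.2, flux=1.0, rep=i) for i in range(3)]
        for r in recs:
            r.qc_pass = False
        assert aggregate_daily_plot(recs).empty


class TestAnnualize:
    def test_constant_one_umol_co2(self):
        # 1 µmol CO2 m-2 s-1 · 44.01 g mol-1 · 31,536,000 s · 1e-8 = 13.8790
        res = annualize(np.ones(360), "CO2", "PPSF")
        assert res.mean == pytest.approx(44.01 * 31_536_000 * 1e-8, rel=1e-12)
        assert res.mean == pytest.approx(13.8790, abs=5e-5)
        assert res.se == 0.0
        assert res.n == 360

    def test_all_zero(self):
        res = annualize(np.zeros(10), "CO2")
        assert res.mean == 0.0 and res.se == 0.0

    def test_se_is_sd_over_sqrt_n(self, rng):
        x = rng.normal(1.0, 0.3, 360)
        res = annualize(x, "CH4")
        factor = umol_to_mg_ha_yr("CH4")
        assert res.se == pytest.approx(np.std(x, ddof=1) / np.sqrt(360) * factor, rel=1e-12)

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(ValueError):
            annualize([1.0], "CO2")

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.floats(1e-6, 1e3))
    def test_unit_round_trip_identity(self, x):
        for gas in ("CO2", "CH4"):
            back = x * umol_to_mg_ha_yr(gas) * mg_ha_yr_to_umol(gas)
            assert back == pytest.approx(x, rel=1e-12)


class TestCO2e:
    def test_gwp_factor_exact(self):
        f = AnnualFlux("PPSF", "CH4", 1.0, 0.1, 360, "MgCH4 ha-1 yr-1")
        out = ch4_to_co2e(f)
        assert out.mean / f.mean == 27.0
        assert out.se == pytest.approx(2.7)

    def test_zero_maps_to_zero(self):
        f = AnnualFlux("PPSF", "CH4", 0.0, 0.0, 360, "MgCH4 ha-1 yr-1")
        assert ch4_to_co2e(f).mean == 0.0

    def test_back_implied_ch4_mass(self):
        # A 0.70 MgCO2e flux corresponds to 0.70/27 ≈ 0.0259 MgCH4
        f = AnnualFlux("PPSF", "CH4", 0.70 / 27.0, 0.0, 360, "MgCH4 ha-1 yr-1")
        assert ch4_to_co2e(f).mean == pytest.approx(0.70, rel=1e-12)
        assert f.mean == pytest.approx(0.0259, abs=5e-5)


class TestSiteAndLandscape:
    def _f(self, site, mean, se, units="MgCO2 ha-1 yr-1", gas="CO2"):
        return AnnualFlux(site, gas, mean, se, 360, units)

    def test_landscape_co2_mean_and_quadrature_se(self):
        out = landscape_mean([self._f("PPSF", 12.61, 0.41), self._f("SPSF", 9.43, 0.27)])
        assert out.mean == pytest.approx(11.02, abs=1e-9)
        assert out.se == pytest.approx(math.sqrt(0.41**2 + 0.27**2), rel=1e-12)
        assert round(out.se, 2) == 0.49

    def test_landscape_ch4(self):
        out = landscape_mean([
            self._f("PPSF", 0.70, 0.04, "MgCO2e ha-1 yr-1", "CH4"),
            self._f("SPSF", 0.46, 0.02, "MgCO2e ha-1 yr-1", "CH4"),
        ])
        assert out.mean == pytest.approx(0.58)
        assert round(out.se, 2) == 0.04

    def test_identical_sites_mean_preserved(self):
        out = landscape_mean([self._f("A", 5.0, 1.0), self._f("B", 5.0, 1.0)])
        assert out.mean == 5.0

    def test_mean_rule_scales_se_by_n(self):
        sites = [self._f("A", 5.0, 0.3), self._f("B", 7.0, 0.4)]
        quad = landscape_mean(sites, "quadrature").se
        assert landscape_mean(sites, "mean").se == pytest.approx(quad / 2)

    def test_site_totals(self):
        co2 = self._f("PPSF", 12.61, 0.41)
        ch4 = self._f("PPSF", 0.70, 0.04, "MgCO2e ha-1 yr-1", "CH4")
        total = site_total_co2e(co2, ch4)
        assert total.mean == pytest.approx(13.31)
        co2b = self._f("SPSF", 9.43, 0.27)
        ch4b = self._f("SPSF", 0.46, 0.02, "MgCO2e ha-1 yr-1", "CH4")
        assert site_total_co2e(co2b, ch4b).mean == pytest.approx(9.89)

    def test_site_mismatch_rejected(self):
        with pytest.raises(ValueError):
            site_total_co2e(self._f("PPSF", 1, 0.1),
                            self._f("SPSF", 1, 0.1, "MgCO2e ha-1 yr-1", "CH4"))


class TestProcessRuns:
    def test_clean_linear_run_produces_passing_records(self):
        run = make_run()
        records = ch.process_runs([run])
        assert {r.gas for r in records} == {"CO2", "CH4"}
        assert all(r.qc_pass for r in records)
        co2 = next(r for r in records if r.gas == "CO2")
        expected = slope_to_flux(0.1, run.air_temp_k, run.pressure_kpa,
                                 run.chamber_volume_m3, run.collar_area_m2)
        assert co2.flux_umol_m2_s == pytest.approx(expected, rel=1e-9)
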