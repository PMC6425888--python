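"""Radiation, PET, water balance, SPEI, aridity and bioclim variables."""

import numpy as np
import pandas as pd
import pytest

from dendroprov import climate as cm
from dendroprov.io import MonthlyClimate


class TestRadiation:
    def test_fao_worked_example(self):
        """Published reference case: 20°S in early September ≈ 32.2."""
        assert cm.ra_daily(-20.0, 246) == pytest.approx(32.2, rel=0.02)

    def test_equator_equinox_near_annual_maximum(self):
        ra = [cm.extraterrestrial_radiation(0.0, m) for m in range(1, 13)]
        assert ra[2] >= max(ra) - 0.8  # March within the month grid of the max

    def test_hemispheric_symmetry(self):
        """Ra is hemispherically symmetric six months apart once the
        Earth-Sun distance factor is divided out (orbital eccentricity is a
        genuine ±3.3% asymmetry; the remaining mismatch is only the
        representative-day offset)."""
        def dr(m):
            j = cm.MID_MONTH_DAY[m - 1]
            return 1.0 + 0.033 * np.cos(2 * np.pi * j / 365.0)
        for lat in (10, 30, 50):
            for m in range(1, 13):
                m2 = (m + 5) % 12 + 1
                a = cm.extraterrestrial_radiation(lat, m) / dr(m)
                b = cm.extraterrestrial_radiation(-lat, m2) / dr(m2)
                assert a == pytest.approx(b, rel=0.03)

    def test_polar_latitude_rejected(self):
        with pytest.raises(ValueError):
            cm.extraterrestrial_radiation(70.0, 6)


class TestHargreaves:
    def test_zero_temperature_range(self):
        assert cm.hargreaves_pet(10.0, 10.0, 10.0, 30.0) == 0.0

    def test_zero_factor_temperature(self):
        assert cm.hargreaves_pet(-17.8, -15.0, -20.6, 30.0) == 0.0

    def test_hand_evaluation(self):
        expected = 0.408 * 0.0023 * 37.8 * np.sqrt(10) * 30
        assert cm.hargreaves_pet(20.0, 25.0, 15.0, 30.0) == \
            pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(3.365, abs=5e-4)

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            cm.hargreaves_pet(10.0, 5.0, 15.0, 30.0)

    def test_cold_month_floored_at_zero(self):
        assert cm.hargreaves_pet(-30.0, -25.0, -35.0, 5.0) == 0.0


def _flat_climate(years, tmean=10.0, prec=50.0):
    rows = [(y, m, tmean, tmean + 5, tmean - 5, prec)
            for y in years for m in range(1, 13)]
    return MonthlyClimate("S", 52.0, pd.DataFrame(
        rows, columns=["year", "month", "tmean", "tmax", "tmin", "prec"]))


class TestWaterBalance:
    def test_cwb_plus_pet_equals_precipitation(self, dry_climate):
        cwb = cm.climatic_water_balance(dry_climate)
        pet = cm.monthly_pet(dry_climate)
        p = dry_climate.complete_table()["prec"].to_numpy()
        assert np.allclose(cwb.values() + pet.values(), p)

    def test_zero_precipitation_gives_negative_pet(self):
        clim = _flat_climate(range(2000, 2002), prec=0.0)
        cwb = cm.climatic_water_balance(clim)
        pet = cm.monthly_pet(clim)
        assert np.allclose(cwb.values(), -pet.values())

    def test_dry_site_has_lower_growing_season_cwb(self, dry_climate,
                                                   moist_climate):
        def gs_mean(clim):
            t = cm.climatic_water_balance(clim).table
            return t.loc[t["month"].isin((5, 6, 7, 8)), "value"].mean()
        assert gs_mean(dry_climate) < gs_mean(moist_climate)


class TestSpei:
    @pytest.mark.parametrize("k", [3, 6])
    def test_calibration_standardization(self, dry_climate, k):
        s = cm.spei(dry_climate, k)
        M = s.monthly_matrix()
        assert float(M.mean().abs().max()) < 0.05
        assert 0.9 <= float(M.std(ddof=1).min())
        assert float(M.std(ddof=1).max()) <= 1.1

    def test_first_k_minus_one_months_undefined(self, dry_climate):
        s = cm.spei(dry_climate, 3)
        v = s.table.sort_values(["year", "month"])["value"].to_numpy()
        assert np.all(np.isnan(v[:2])) and np.all(np.isfinite(v[2:]))

    def test_monotone_in_water_balance(self, dry_climate):
        """Within a calendar month, larger D sums map to larger SPEI."""
        s = cm.spei(dry_climate, 3)
        cwb = cm.climatic_water_balance(dry_climate)
        t = cwb.table.sort_values(["year", "month"]).reset_index(drop=True)
        d = t["value"].to_numpy()
        dk = np.full(len(d), np.nan)
        dk[2:] = np.convolve(d, np.ones(3), "valid")
        z = s.table.sort_values(["year", "month"])["value"].to_numpy()
        for m in range(1, 13):
            sel = (t["month"].to_numpy() == m) & np.isfinite(dk)
            order = np.argsort(dk[sel])
            assert np.all(np.diff(z[sel][order]) > 0)

    def test_location_invariance(self, dry_climate):
        """Adding a constant to every D value leaves SPEI unchanged."""
        from dendroprov.climate import (_loglogistic_cdf, _loglogistic_pwm)
        rng = np.random.default_rng(3)
        x = rng.gamma(4, 20, 60)
        a1, b1, g1 = _loglogistic_pwm(x)
        a2, b2, g2 = _loglogistic_pwm(x + 500.0)
        p1 = _loglogistic_cdf(x, a1, b1, g1)
        p2 = _loglogistic_cdf(x + 500.0, a2, b2, g2)
        assert np.allclose(p1, p2, atol=1e-9)

    def test_median_maps_to_zero(self):
        from dendroprov.climate import (_loglogistic_cdf, _loglogistic_pwm)
        rng = np.random.default_rng(4)
        x = rng.gamma(4, 20, 500)
        a, b, g = _loglogistic_pwm(x)
        median = g + a  # (alpha/(x-gamma))^beta = 1 at x = gamma + alpha
        assert float(_loglogistic_cdf(median, a, b, g)) == pytest.approx(0.5)

    def test_fit_recovers_fisk_parameters(self):
        """Independent cross-check against scipy's log-logistic."""
        from scipy import stats
        from dendroprov.climate import _loglogistic_pwm
        x = stats.fisk.rvs(c=4.0, loc=10.0, scale=50.0, size=4000,
                           random_state=np.random.default_rng(0))
        a, b, g = _loglogistic_pwm(x)
        assert b == pytest.approx(4.0, rel=0.1)
        assert a == pytest.approx(50.0, rel=0.1)
        assert g == pytest.approx(10.0, abs=5.0)

    def test_short_record_rejected(self):
        clim = _flat_climate(range(2000, 2010))
        with pytest.raises(ValueError, match="20"):
            cm.spei(clim, 3)

    def test_zero_variance_month_rejected(self):
        clim = _flat_climate(range(2000, 2025))
        with pytest.raises(ValueError):
            cm.spei(clim, 3)


class TestAridity:
    def test_de_martonne_default(self):
        clim = _flat_climate(range(2000, 2002), tmean=10.0, prec=50.0)
        res = cm.aridity_index(clim)
        assert res["value"] == pytest.approx(600.0 / 20.0)
        assert res["formula"] == "de-martonne"

    def test_more_precipitation_is_more_humid(self, dry_climate):
        base = cm.aridity_index(dry_climate)["value"]
        doubled = MonthlyClimate(
            "S", dry_climate.latitude,
            dry_climate.table.assign(prec=dry_climate.table["prec"] * 2))
        assert cm.aridity_index(doubled)["value"] > base

    def test_drier_site_classified_more_arid(self, dry_climate):
        drier = MonthlyClimate(
            "S2", dry_climate.latitude,
            dry_climate.table.assign(prec=dry_climate.table["prec"] * 0.8))
        assert cm.aridity_index(drier)["value"] < \
            cm.aridity_index(dry_climate)["value"]


def _random_normals(rng):
    tmean = rng.uniform(-5, 20, 12)
    half = rng.uniform(2, 8, 12)
    return tmean, tmean + half, tmean - half, rng.uniform(0, 120, 12)


def _brute_quarter(x, agg):
    windows = [[(i + j) % 12 for j in range(3)] for i in range(12)]
    return [agg([x[k] for k in w]) for w in windows]


class TestBioclim:
    def test_constant_climate(self):
        v = cm.bioclim_variables([10.0] * 12, [10.0] * 12, [10.0] * 12,
                                 [50.0] * 12)
        assert v[1] == 10.0
        assert v[4] == 0.0
        assert v[7] == 0.0
        assert np.isnan(v[3])          # isothermality undefined
        assert v[12] == 600.0
        assert v[15] == 0.0
        assert v[16] == 150.0 and v[17] == 150.0

    def test_identities_on_random_fixtures(self, rng):
        for _ in range(100):
            tm, tx, tn, pr = _random_normals(rng)
            v = cm.bioclim_variables(tm, tx, tn, pr)
            assert v[7] == pytest.approx(v[5] - v[6])
            assert v[12] == pytest.approx(pr.sum())
            assert v[5] >= v[6]
            assert v[13] >= v[14]
            assert v[16] >= v[17]
            assert v[2] == pytest.approx(np.mean(tx - tn))
            assert v[3] == pytest.approx(v[2] / v[7] * 100)

    def test_extreme_quarters_match_brute_force(self, rng):
        for _ in range(100):
            tm, tx, tn, pr = _random_normals(rng)
            v = cm.bioclim_variables(tm, tx, tn, pr)
            pq = _brute_quarter(pr, sum)
            tq = [t / 3 for t in _brute_quarter(tm, sum)]
            assert v[16] == pytest.approx(max(pq))
            assert v[17] == pytest.approx(min(pq))
            assert v[10] == pytest.approx(max(tq))
            assert v[11] == pytest.approx(min(tq))
            assert v[8] == pytest.approx(tq[int(np.argmax(pq))])
            assert v[9] == pytest.approx(tq[int(np.argmin(pq))])
            assert v[18] == pytest.approx(pq[int(np.argmax(tq))])
            assert v[19] == pytest.approx(pq[int(np.argmin(tq))])

    def test_single_wet_month(self):
        pr = np.zeros(12)
        pr[6] = 90.0
        tm = np.linspace(0, 11, 12)
        v = cm.bioclim_variables(tm, tm + 5, tm - 5, pr)
        assert v[13] == 90.0
        assert v[16] == 90.0  # the wet month's window

    def test_missing_month_rejected(self):
        with pytest.raises(ValueError):
            cm.bioclim_variables([10.0] * 11, [15.0] * 12, [5.0] * 12,
                                 [50.0] * 12)
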