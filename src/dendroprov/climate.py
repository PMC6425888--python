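"""Derived climate indices from monthly station data.

Potential evapotranspiration follows Hargreaves (temperature + extraterrestrial
radiation only — the choice of record-poor sites), the climatic water balance
is P − PET, and SPEI-k standardizes k-month rolling water-balance sums through
a three-parameter log-logistic distribution fitted per calendar month by
unbiased probability-weighted moments.  The 19 bioclimatic summary variables
are computed from monthly normals with wrap-around three-month quarters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gamma as _gamma
from scipy.stats import norm

from .io import MonthlyClimate

__all__ = [
    "DerivedClimateSeries",
    "BioclimVector",
    "extraterrestrial_radiation",
    "ra_daily",
    "hargreaves_pet",
    "monthly_pet",
    "climatic_water_balance",
    "spei",
    "aridity_index",
    "bioclim_variables",
    "MID_MONTH_DAY",
    "DAYS_IN_MONTH",
]

# non-leap calendar; monthly climatology does not track leap days
DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
# representative (mid-month) Julian day, J = int(30.4 m - 15)
MID_MONTH_DAY = np.array([int(30.4 * m - 15.0) for m in range(1, 13)])

_GSC = 0.0820  # solar constant, MJ m-2 min-1


@dataclass(frozen=True)
class DerivedClimateSeries:
    """Monthly derived series (PET, CWB, SPEI-k, external PDSI) for one site."""

    site: str
    variable: str      # e.g. "PET", "CWB", "SPEI3"
    units: str         # "mm/month" or "z"
    table: pd.DataFrame  # columns: year, month, value

    def values(self) -> np.ndarray:
        return self.table["value"].to_numpy()

    def monthly_matrix(self) -> pd.DataFrame:
        return self.table.pivot(index="year", columns="month", values="value")


# ---------------------------------------------------------------------------
# radiation and PET
# ---------------------------------------------------------------------------

def ra_daily(latitude: float, day_of_year: int) -> float:
    """Extraterrestrial radiation Ra (MJ m⁻² day⁻¹) for one day.

    Standard daily solar geometry: inverse relative Earth–Sun distance,
    solar declination, and sunset hour angle.
    """
    if abs(latitude) > 66.5:
        raise ValueError(
            f"latitude {latitude}°: polar day/night not supported (|lat| ≤ 66.5)"
        )
    phi = np.deg2rad(latitude)
    j = float(day_of_year)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * j / 365.0)
    delta = 0.409 * np.sin(2.0 * np.pi * j / 365.0 - 1.39)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0))
    ra = (24.0 * 60.0 / np.pi) * _GSC * dr * (
        ws * np.sin(phi) * np.sin(delta)
        + np.cos(phi) * np.cos(delta) * np.sin(ws)
    )
    return float(max(ra, 0.0))


def extraterrestrial_radiation(latitude: float, month: int) -> float:
    """Monthly-representative Ra (MJ m⁻² day⁻¹), evaluated mid-month."""
    if not 1 <= int(month) <= 12:
        raise ValueError(f"month {month} out of 1..12")
    return ra_daily(latitude, int(MID_MONTH_DAY[int(month) - 1]))


def hargreaves_pet(tmean: float, tmax: float, tmin: float, ra: float) -> float:
    """Hargreaves reference evapotranspiration, mm day⁻¹.

    PET = 0.408 × 0.0023 (Tmean + 17.8) √(Tmax − Tmin) Ra, with 0.408
    converting MJ m⁻² day⁻¹ to mm day⁻¹.  Negative results (very cold months)
    are floored at zero.
    """
    if tmax < tmin:
        raise ValueError(f"tmax {tmax} < tmin {tmin}")
    pet = 0.408 * 0.0023 * (tmean + 17.8) * np.sqrt(tmax - tmin) * ra
    return float(max(pet, 0.0))


def monthly_pet(climate: MonthlyClimate) -> DerivedClimateSeries:
    """Monthly PET sums (mm month⁻¹) over the complete years of a record."""
    ct = climate.complete_table()
    vals = []
    for _, r in ct.iterrows():
        m = int(r["month"])
        daily = hargreaves_pet(r["tmean"], r["tmax"], r["tmin"],
                               extraterrestrial_radiation(climate.latitude, m))
        vals.append(daily * DAYS_IN_MONTH[m - 1])
    out = ct[["year", "month"]].copy()
    out["value"] = vals
    return DerivedClimateSeries(climate.site, "PET", "mm/month", out)


def climatic_water_balance(climate: MonthlyClimate) -> DerivedClimateSeries:
    """Monthly climatic water balance CWB = P − PET (mm month⁻¹)."""
    pet = monthly_pet(climate)
    ct = climate.complete_table()
    out = ct[["year", "month"]].copy()
    out["value"] = ct["prec"].to_numpy() - pet.values()
    return DerivedClimateSeries(climate.site, "CWB", "mm/month", out)


# ---------------------------------------------------------------------------
# SPEI
# ---------------------------------------------------------------------------

def _pwm_unbiased(x: np.ndarray) -> tuple[float, float, float]:
    """Unbiased probability-weighted moments w_s = E[X (1−F)^s], s = 0, 1, 2."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    i = np.arange(1, n + 1, dtype=float)
    w0 = x.mean()
    w1 = np.sum((n - i) / (n - 1) * x) / n
    w2 = np.sum((n - i) * (n - i - 1) / ((n - 1) * (n - 2)) * x) / n
    return float(w0), float(w1), float(w2)


def _loglogistic_pwm(x: np.ndarray) -> tuple[float, float, float]:
    """Fit the 3-parameter log-logistic (alpha scale, beta shape, gamma loc).

    CDF: F(x) = [1 + (alpha / (x − gamma))^beta]⁻¹ for x > gamma.
    """
    b0, b1, b2 = _pwm_unbiased(x)
    denom = 6.0 * b1 - b0 - 6.0 * b2
    if denom == 0:
        raise ZeroDivisionError("degenerate PWM system")
    beta = (2.0 * b1 - b0) / denom
    if beta <= 2.0:
        # shape must exceed 2 for the PWM relations (finite first two moments)
        raise ValueError(f"log-logistic shape {beta:.3f} ≤ 2: fit unstable")
    g1 = _gamma(1.0 + 1.0 / beta) * _gamma(1.0 - 1.0 / beta)
    alpha = (b0 - 2.0 * b1) * beta / (_gamma(1.0 + 1.0 / beta)
                                      * _gamma(1.0 - 1.0 / beta))
    gamma_loc = b0 - alpha * g1
    return float(alpha), float(beta), float(gamma_loc)


def _loglogistic_cdf(x, alpha: float, beta: float, gamma_loc: float):
    x = np.asarray(x, dtype=float)
    z = x - gamma_loc
    out = np.empty_like(z)
    pos = z > 0
    out[pos] = 1.0 / (1.0 + (alpha / z[pos]) ** beta)
    out[~pos] = 0.0
    return out


def spei(climate: MonthlyClimate, k: int = 3,
         min_years: int = 20) -> DerivedClimateSeries:
    """Standardized precipitation–evapotranspiration index at scale k months.

    D = P − PET is summed over backward k-month windows; per calendar month a
    three-parameter log-logistic distribution is fitted by unbiased PWM over
    the full record (the calibration period), and non-exceedance probabilities
    are mapped to standard normal deviates.  The first k−1 months are
    undefined (NaN).
    """
    if k < 1:
        raise ValueError("aggregation scale k must be ≥ 1")
    cwb = climatic_water_balance(climate)
    t = cwb.table.sort_values(["year", "month"]).reset_index(drop=True)
    nyears = t["year"].nunique()
    if nyears < min_years:
        raise ValueError(
            f"SPEI calibration needs ≥ {min_years} complete years, got {nyears}"
        )
    d = t["value"].to_numpy()
    dk = np.full(len(d), np.nan)
    if len(d) >= k:
        c = np.convolve(d, np.ones(k), mode="valid")
        dk[k - 1:] = c
    z = np.full(len(d), np.nan)
    months = t["month"].to_numpy()
    for m in range(1, 13):
        sel = (months == m) & np.isfinite(dk)
        xs = dk[sel]
        if xs.size == 0:
            continue
        if np.ptp(xs) == 0:
            raise ValueError(
                f"SPEI: zero variance in calendar month {m}, cannot fit"
            )
        # the log-logistic handles right-skewed samples; left-skewed months
        # (e.g. drought-thinned summer tails) are fitted on the reflected
        # sample and the probit negated, preserving monotonicity in D
        from scipy.stats import skew as _skew
        order = (1.0, -1.0) if _skew(xs) >= 0 else (-1.0, 1.0)
        p = None
        for sign in order:
            try:
                alpha, beta, gloc = _loglogistic_pwm(sign * xs)
            except ValueError:
                continue
            p = _loglogistic_cdf(sign * xs, alpha, beta, gloc)
            if sign < 0:
                p = 1.0 - p
            break
        if p is None:
            raise ValueError(
                f"SPEI: log-logistic fit failed for calendar month {m}"
            )
        # clip away exact 0/1 so the probit stays finite
        eps = 1.0 / (4.0 * xs.size)
        z[sel] = norm.ppf(np.clip(p, eps, 1.0 - eps))
    out = t[["year", "month"]].copy()
    out["value"] = z
    return DerivedClimateSeries(climate.site, f"SPEI{k}", "z", out)


# ---------------------------------------------------------------------------
# aridity
# ---------------------------------------------------------------------------

def aridity_index(climate: MonthlyClimate, formula: str = "de-martonne"
                  ) -> dict:
    """Annual aridity summary from mean annual temperature and precipitation.

    Default is the de Martonne index P / (T + 10) (mm °C⁻¹): higher = more
    humid.  The formula used is recorded in the returned metadata so exported
    tables are self-describing.
    """
    ct = climate.complete_table()
    if ct.empty:
        raise ValueError("no complete year in the climate record")
    per_year = ct.groupby("year").agg(t=("tmean", "mean"), p=("prec", "sum"))
    t = float(per_year["t"].mean())
    p = float(per_year["p"].mean())
    if formula == "de-martonne":
        value = p / (t + 10.0)
    else:
        raise ValueError(f"unknown aridity formula {formula!r}")
    return {"site": climate.site, "formula": formula, "value": float(value),
            "mean_annual_t": t, "mean_annual_p": p}


# ---------------------------------------------------------------------------
# bioclim
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BioclimVector:
    """The 19 standard bioclim summaries of a 12-month climate normal.

    Temperatures in °C (bio4 = s.d. × 100), precipitation in mm, bio3 and
    bio15 in % — bio3 (isothermality) is NaN when the annual range is zero and
    bio15 is NaN when mean monthly precipitation is zero (flagged-undefined
    rather than stabilized).
    """

    values: tuple[float, ...]  # bio1..bio19

    def __getitem__(self, i: int) -> float:
        """1-based access: v[7] is bio7."""
        if not 1 <= i <= 19:
            raise IndexError("bioclim variables are bio1..bio19")
        return self.values[i - 1]

    def as_dict(self) -> dict[str, float]:
        return {f"bio{i}": self.values[i - 1] for i in range(1, 20)}


def _quarters(x: np.ndarray) -> np.ndarray:
    """Sums of the 12 wrap-around 3-consecutive-month windows (Dec–Jan wraps)."""
    xx = np.concatenate([x, x[:2]])
    return np.array([xx[i:i + 3].sum() for i in range(12)])


def bioclim_variables(tmean, tmax, tmin, prec) -> BioclimVector:
    """Compute bio1..bio19 from 12-month normals.

    Quarters are all 12 wrap-around three-month windows; the extreme quarter
    is the first window attaining the extreme (stable tie-break).  bio4 uses
    the sample standard deviation × 100; bio15 is the plain CV in percent.
    """
    arrs = [np.asarray(a, dtype=float) for a in (tmean, tmax, tmin, prec)]
    for a in arrs:
        if a.shape != (12,):
            raise ValueError("each normal vector must have exactly 12 months")
        if np.any(~np.isfinite(a)):
            raise ValueError("missing month in normals")
    tmean, tmax, tmin, prec = arrs
    if np.any(prec < 0):
        raise ValueError("negative precipitation normal")
    if np.any(tmax < tmin):
        raise ValueError("tmax < tmin in normals")

    tq = _quarters(tmean) / 3.0          # quarterly mean temperature
    pq = _quarters(prec)                 # quarterly precipitation sum

    bio1 = tmean.mean()
    bio2 = float(np.mean(tmax - tmin))
    bio4 = float(np.std(tmean, ddof=1) * 100.0)
    bio5 = float(tmax.max())
    bio6 = float(tmin.min())
    bio7 = bio5 - bio6
    bio3 = float(bio2 / bio7 * 100.0) if bio7 != 0 else float("nan")
    iw, idry = int(np.argmax(pq)), int(np.argmin(pq))
    iwarm, icold = int(np.argmax(tq)), int(np.argmin(tq))
    bio8 = float(tq[iw])
    bio9 = float(tq[idry])
    bio10 = float(tq[iwarm])
    bio11 = float(tq[icold])
    bio12 = float(prec.sum())
    bio13 = float(prec.max())
    bio14 = float(prec.min())
    pm = prec.mean()
    bio15 = float(np.std(prec, ddof=1) / pm * 100.0) if pm > 0 else float("nan")
    bio16 = float(pq[iw])
    bio17 = float(pq[idry])
    bio18 = float(pq[iwarm])
    bio19 = float(pq[icold])
    return BioclimVector(values=(
        float(bio1), bio2, bio3, bio4, bio5, bio6, float(bio7), bio8, bio9,
        bio10, bio11, bio12, bio13, bio14, bio15, bio16, bio17, bio18, bio19,
    ))


def bioclim_from_climate(climate: MonthlyClimate) -> BioclimVector:
    """Bioclim vector of a record's monthly normals (means over complete years)."""
    ct = climate.complete_table()
    g = ct.groupby("month")
    return bioclim_variables(
        g["tmean"].mean().to_numpy(),
        g["tmax"].mean().to_numpy(),
        g["tmin"].mean().to_numpy(),
        g["prec"].mean().to_numpy(),
    )
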