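"""Synthetic two-site provenance-trial generator with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
shared monthly climate signal per site, provenance-specific growth response
vectors, a negative-exponential age trend, and a site "marginality" knob
that operationalizes Liebig's law of the minimum — the degree to which a
single water-balance factor caps growth for every tree regardless of
provenance.  At marginality 0 each provenance follows its own climate
response; at 1 all trees share the water-limited signal exactly, which is
the mechanism behind diminishing between-provenance differentiation at
climatically marginal sites.

Annual ring width for tree t of provenance p in year y:

    log w = log A(age) + min( (1−m)·s_p(y) + m·u(y),  u(y) + 3(1−m) )
            + tree effect + noise

where s_p is the provenance's standardized response to monthly climate
anomalies, u is the standardized growing-season water balance of the site,
and m is the marginality.  The min() is a hard Liebig ceiling: at m = 1 it
coincides with the blend (all trees collapse onto u), at m = 0 it sits 3
log-units above the signal and never binds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import MonthlyClimate, RingWidthSeries

__all__ = [
    "SiteClimateParams",
    "ProvenanceParams",
    "TrialConfig",
    "GroundTruthRecord",
    "simulate_site_climate",
    "simulate_provenance_trial",
    "make_fixture_suite",
    "default_sites",
    "default_provenances",
    "PROVENANCE_CODES",
]

# the ten provenance codes used throughout the trial
PROVENANCE_CODES = ("BA", "PR", "BO", "NR", "WS", "IS", "RY", "OR", "WT", "ZL")

_MONTH_DIURNAL_HALF_RANGE = 5.0  # °C between tmean and tmax/tmin
_SUMMER = (5, 6, 7, 8)           # May–August: drought-sensitive window
_SIGNAL_SD = 0.25                # s.d. of the annual log-growth climate signal


@dataclass(frozen=True)
class SiteClimateParams:
    """Climatology of one trial site.

    Temperate-lowland defaults: a mild/moist site would carry higher
    precipitation normals and low drought frequency, a drought-prone site
    lower summer precipitation and frequent drought years.
    """

    site: str
    latitude: float
    t_normals: tuple[float, ...]       # 12 monthly mean temperatures, °C
    p_normals: tuple[float, ...]       # 12 monthly precipitation sums, mm
    t_interannual_sd: float = 1.0      # °C, year-level anomaly
    p_dispersion: float = 0.3          # gamma CV of monthly precipitation
    drought_freq: float = 0.1          # probability a year is a drought year
    drought_severity: float = 0.5      # fractional summer precip reduction

    def __post_init__(self):
        if len(self.t_normals) != 12 or len(self.p_normals) != 12:
            raise ValueError("normals must have 12 monthly entries")
        if any(p < 0 for p in self.p_normals):
            raise ValueError("precipitation normals must be ≥ 0")
        if not 0.0 <= self.drought_freq <= 1.0:
            raise ValueError("drought frequency must be in [0, 1]")
        if not 0.0 <= self.drought_severity <= 1.0:
            raise ValueError("drought severity must be in [0, 1]")


@dataclass(frozen=True)
class ProvenanceParams:
    """Ground-truth growth parameters of one provenance.

    ``response`` weights the 24 standardized monthly covariates (12 monthly
    temperature anomalies then 12 precipitation anomalies) of the current
    year; it is normalized internally so only its direction matters.
    """

    provenance: str
    response: tuple[float, ...]        # 24 weights, dimensionless
    baseline_mm: float = 3.0           # young-tree ring width level
    age_decay: float = 0.03            # 1/year negative-exponential trend
    tree_sd: float = 0.10              # lognormal between-tree s.d. (fraction)

    def __post_init__(self):
        if self.baseline_mm <= 0:
            raise ValueError("baseline growth must be positive")
        r = np.asarray(self.response, dtype=float)
        if r.shape != (24,) or not np.all(np.isfinite(r)):
            raise ValueError("response must be 24 finite weights")
        object.__setattr__(self, "response", tuple(float(v) for v in r))


@dataclass(frozen=True)
class TrialConfig:
    trees_per_provenance: int = 15
    years: int = 40
    marginality: float = 0.0           # 0 = provenance-driven, 1 = water-capped
    noise_sd: float = 0.15             # lognormal year×tree noise (fraction)
    seed: int = 0

    def __post_init__(self):
        if self.trees_per_provenance < 2:
            raise ValueError("need at least 2 trees per provenance")
        if self.years < 15:
            raise ValueError("need at least 15 simulated years")
        if not 0.0 <= self.marginality <= 1.0:
            raise ValueError("marginality must be in [0, 1]")


@dataclass
class GroundTruthRecord:
    """Everything needed to reconstruct a simulated trial bit-for-bit."""

    site_params: SiteClimateParams
    provenances: tuple[ProvenanceParams, ...]
    config: TrialConfig
    climate_seed: int
    tree_seeds: dict[str, int]         # series id -> substream seed
    first_year: int

    def as_dict(self) -> dict:
        return {
            "site_params": (asdict(self.site_params)
                            if self.site_params is not None else None),
            "provenances": [asdict(p) for p in self.provenances],
            "config": asdict(self.config),
            "climate_seed": self.climate_seed,
            "tree_seeds": dict(self.tree_seeds),
            "first_year": self.first_year,
        }


# ---------------------------------------------------------------------------
# climate simulation
# ---------------------------------------------------------------------------

def simulate_site_climate(params: SiteClimateParams, years: int, seed: int,
                          first_year: int = 1975) -> MonthlyClimate:
    """Simulate a monthly climate record around a site's normals.

    Temperature: normals + a year-level Gaussian anomaly (shared by all
    months of the year).  Precipitation: gamma-distributed around the monthly
    normal with the site's dispersion (so P ≥ 0; zero dispersion reproduces
    the normals exactly).  Drought years occur with the site's frequency and
    impose a multiplicative May–August precipitation reduction plus a +1.5 °C
    summer temperature bump.  Identical seed and parameters reproduce an
    identical table.
    """
    if years < 1:
        raise ValueError("years must be ≥ 1")
    rng = np.random.default_rng(seed)
    tn = np.asarray(params.t_normals)
    pn = np.asarray(params.p_normals)
    rows = []
    drought_years = []
    for iy in range(years):
        year = first_year + iy
        t_anom = rng.normal(0.0, params.t_interannual_sd) \
            if params.t_interannual_sd > 0 else 0.0
        drought = bool(rng.random() < params.drought_freq)
        if drought:
            drought_years.append(year)
        for m in range(1, 13):
            t = tn[m - 1] + t_anom
            if params.p_dispersion > 0:
                cv2 = params.p_dispersion ** 2
                p = rng.gamma(shape=1.0 / cv2, scale=pn[m - 1] * cv2) \
                    if pn[m - 1] > 0 else 0.0
            else:
                p = float(pn[m - 1])
            if drought and m in _SUMMER:
                p *= 1.0 - params.drought_severity
                t += 1.5
            rows.append((year, m, t, t + _MONTH_DIURNAL_HALF_RANGE,
                         t - _MONTH_DIURNAL_HALF_RANGE, p))
    table = pd.DataFrame(rows, columns=["year", "month", "tmean", "tmax",
                                        "tmin", "prec"])
    return MonthlyClimate(site=params.site, latitude=params.latitude,
                          table=table, drought_years=tuple(drought_years))


def _standardized_monthly_anomalies(climate: MonthlyClimate) -> np.ndarray:
    """Years × 24 matrix of z-scored monthly tmean and precipitation."""
    tm = climate.monthly_matrix("tmean").to_numpy()
    pm = climate.monthly_matrix("prec").to_numpy()
    Z = np.column_stack([tm, pm])
    mu = Z.mean(axis=0)
    sd = Z.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (Z - mu) / sd


def _water_balance_signal(climate: MonthlyClimate) -> np.ndarray:
    """Standardized growing-season water-balance proxy per year.

    Summer precipitation minus a temperature-driven demand term, z-scored
    over the record — the single limiting factor of a marginal site.
    """
    ct = climate.complete_table()
    summer = ct[ct["month"].isin(_SUMMER)]
    g = summer.groupby("year")
    w = g["prec"].sum() - 10.0 * g["tmean"].mean()
    w = w.to_numpy(dtype=float)
    sd = w.std(ddof=0)
    return (w - w.mean()) / (sd if sd > 0 else 1.0)


def simulate_provenance_trial(climate: MonthlyClimate,
                              provenances,
                              config: TrialConfig
                              ) -> tuple[list[RingWidthSeries],
                                         GroundTruthRecord]:
    """Simulate ring-width series for every tree of every provenance.

    See the module docstring for the growth model.  Per-tree noise streams
    are spawned from the master seed, so each tree's draw is reproducible
    independently of tree ordering.
    """
    provenances = list(provenances)
    if len(provenances) < 2:
        raise ValueError("need at least 2 provenances")
    years_avail = climate.complete_years()
    if len(years_avail) < config.years:
        raise ValueError(
            f"climate covers {len(years_avail)} complete years "
            f"< {config.years} simulated years"
        )
    years = years_avail[-config.years:]
    sel = np.isin(climate.complete_years(), years)
    Z = _standardized_monthly_anomalies(climate)[sel]
    u = _water_balance_signal(climate)[sel]
    m = config.marginality
    cap = u + 3.0 * (1.0 - m)

    ss = np.random.SeedSequence(config.seed)
    out: list[RingWidthSeries] = []
    tree_seeds: dict[str, int] = {}
    age = np.arange(1, config.years + 1, dtype=float)
    for p in provenances:
        r = np.asarray(p.response, dtype=float)
        norm = np.linalg.norm(r)
        rhat = r / norm if norm > 0 else r
        s_p = (Z @ rhat)
        sd = s_p.std(ddof=0)
        s_p = s_p / (sd if sd > 0 else 1.0)
        signal = np.minimum((1.0 - m) * s_p + m * u, cap) * _SIGNAL_SD
        trend = p.baseline_mm * np.exp(-p.age_decay * age) + 0.3
        for t in range(config.trees_per_provenance):
            child = ss.spawn(1)[0]
            sub_seed = int(child.generate_state(1, np.uint32)[0]) % (2 ** 31)
            rng = np.random.default_rng(sub_seed)
            # site prefix keeps ids unique across a two-site bundle while
            # respecting the 8-character Tucson id field
            sid = f"{climate.site[:3]}{p.provenance}{t + 1:02d}"
            tree_seeds[sid] = sub_seed
            tree_eff = rng.normal(0.0, p.tree_sd) if p.tree_sd > 0 else 0.0
            noise = rng.normal(0.0, config.noise_sd, config.years) \
                if config.noise_sd > 0 else np.zeros(config.years)
            w = trend * np.exp(signal + tree_eff + noise)
            w = np.round(np.maximum(w, 0.01), 2)  # 0.01 mm measurement grid
            out.append(RingWidthSeries(
                series_id=sid, first_year=int(years[0]),
                widths=tuple(w), tree_id=sid,
                provenance=p.provenance, site=climate.site,
            ))
    truth = GroundTruthRecord(
        site_params=None, provenances=tuple(provenances), config=config,
        climate_seed=-1, tree_seeds=tree_seeds, first_year=int(years[0]),
    )
    return out, truth


# ---------------------------------------------------------------------------
# canned scenarios
# ---------------------------------------------------------------------------

def default_sites() -> dict[str, SiteClimateParams]:
    """Two contrasting temperate-lowland sites: mild/moist vs drought-prone."""
    t_norm = (-2.0, -1.0, 3.0, 8.5, 14.0, 17.0, 19.0, 18.5, 13.5, 8.5, 3.0, -0.5)
    p_mild = (35, 30, 35, 40, 60, 75, 80, 70, 55, 45, 40, 40)
    p_dry = (30, 25, 30, 32, 45, 55, 60, 52, 42, 35, 33, 34)
    return {
        "MOIST": SiteClimateParams(
            site="MOIST", latitude=53.2, t_normals=t_norm, p_normals=p_mild,
            t_interannual_sd=0.8, p_dispersion=0.30,
            drought_freq=0.08, drought_severity=0.40),
        "DRY": SiteClimateParams(
            site="DRY", latitude=52.2,
            t_normals=tuple(t + 0.8 for t in t_norm), p_normals=p_dry,
            t_interannual_sd=0.8, p_dispersion=0.35,
            drought_freq=0.25, drought_severity=0.50),
    }


def default_provenances(seed: int = 12345,
                        n: int = 10) -> list[ProvenanceParams]:
    """Ten provenances with distinct random climate-response directions.

    Responses are random unit-ish vectors over the 24 monthly covariates with
    a shared summer-moisture component, so provenances are correlated but
    distinguishable — the realistic common-garden situation.
    """
    rng = np.random.default_rng(seed)
    base = np.zeros(24)
    base[12 + 4: 12 + 8] = 1.0   # shared May–Aug precipitation response
    base[4:8] = -0.6             # shared May–Aug temperature response
    out = []
    for i in range(n):
        code = PROVENANCE_CODES[i] if i < len(PROVENANCE_CODES) else f"P{i:02d}"
        own = rng.normal(0.0, 1.0, 24)
        resp = 0.8 * base / np.linalg.norm(base) + 0.6 * own / np.linalg.norm(own)
        out.append(ProvenanceParams(
            provenance=code, response=tuple(resp),
            baseline_mm=float(rng.uniform(2.5, 3.6)),
            age_decay=0.03, tree_sd=0.10))
    return out


def make_fixture_suite(seed: int, trees: int = 15, years: int = 40,
                       n_provenances: int = 10) -> dict[str, dict]:
    """Three canned scenarios keyed by name, each with climate, series, truth.

    * ``"null"`` — all provenances share one parameter record (exchangeable
      trees; any detected differentiation is type-I error).
    * ``"divergent-mild"`` — distinct responses, marginality 0.1 (a mild
      site where provenance-specific patterns can express themselves).
    * ``"uniform-marginal"`` — the *same* provenance list, marginality 0.9
      (a water-limited site collapsing every tree onto the common signal).
    """
    ss = np.random.SeedSequence(seed)
    s_climate, s_trial = [int(c.generate_state(1, np.uint32)[0])
                          for c in ss.spawn(2)]
    sites = default_sites()
    provs = default_provenances(seed=12345, n=n_provenances)
    null_provs = [ProvenanceParams(
        provenance=p.provenance, response=provs[0].response,
        baseline_mm=provs[0].baseline_mm, age_decay=provs[0].age_decay,
        tree_sd=provs[0].tree_sd) for p in provs]
    suite = {}
    for name, plist, marg, site_key in (
            ("null", null_provs, 0.5, "MOIST"),
            ("divergent-mild", provs, 0.1, "MOIST"),
            ("uniform-marginal", provs, 0.9, "DRY")):
        clim = simulate_site_climate(sites[site_key], years + 5,
                                     seed=s_climate)
        cfg = TrialConfig(trees_per_provenance=trees, years=years,
                          marginality=marg, seed=s_trial)
        series, truth = simulate_provenance_trial(clim, plist, cfg)
        truth.site_params = sites[site_key]
        truth.climate_seed = s_climate
        suite[name] = {"climate": clim, "series": series, "truth": truth}
    return suite
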