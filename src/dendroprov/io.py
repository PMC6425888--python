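"""Reading and writing ring-width and climate data.

Ring widths travel in the Tucson/RWL decadal format used by the ITRDB and
virtually every measurement program.  Two dialects are in circulation and both
are supported, always explicitly:

* ``"0.01mm"`` — integer hundredths of a millimetre, end-of-series sentinel 999
* ``"0.001mm"`` — integer thousandths, sentinel -9999

Site and provenance labels do not fit the format's 8-character series id, so
they ride in a sidecar metadata CSV keyed by series id.  Monthly climate is a
plain CSV with columns ``year, month, tmean, tmax, tmin, prec`` and the station
latitude in a ``# latitude:`` header comment (or passed explicitly).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RingWidthSeries",
    "MonthlyClimate",
    "RWLDialect",
    "DIALECTS",
    "RWLParseError",
    "RWLFormatError",
    "ClimateValidationError",
    "read_rwl",
    "write_rwl",
    "read_climate_csv",
    "write_climate_csv",
    "read_metadata_csv",
    "write_metadata_csv",
    "attach_metadata",
    "read_pdsi_csv",
    "export_long_table",
]


class RWLParseError(ValueError):
    """Malformed Tucson/RWL content; carries the offending line number."""


class RWLFormatError(ValueError):
    """A value cannot be represented in the requested RWL dialect."""


class ClimateValidationError(ValueError):
    """Climate table violates a structural invariant (lists offending rows)."""


@dataclass(frozen=True)
class RWLDialect:
    name: str
    precision_mm: float   # mm per integer unit
    sentinel: int         # end-of-series marker value

    def to_int(self, width_mm: float) -> int:
        return int(round(width_mm / self.precision_mm))

    def to_mm(self, units: int) -> float:
        return units * self.precision_mm


DIALECTS = {
    "0.01mm": RWLDialect("0.01mm", 0.01, 999),
    "0.001mm": RWLDialect("0.001mm", 0.001, -9999),
}
DEFAULT_DIALECT = "0.01mm"


@dataclass(frozen=True)
class RingWidthSeries:
    """One tree's dated annual ring widths in mm.

    ``widths[i]`` is the ring formed in calendar year ``first_year + i``.
    A width of exactly 0 encodes a locally absent (missing) ring.
    """

    series_id: str
    first_year: int
    widths: tuple[float, ...]
    tree_id: str = ""
    provenance: str = ""
    site: str = ""

    def __post_init__(self):
        if len(self.widths) < 1:
            raise ValueError(f"series {self.series_id!r}: no widths")
        if any(w < 0 for w in self.widths):
            raise ValueError(f"series {self.series_id!r}: negative width")
        object.__setattr__(self, "widths", tuple(float(w) for w in self.widths))

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + len(self.widths))

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.widths) - 1

    def values(self) -> np.ndarray:
        return np.asarray(self.widths, dtype=float)


@dataclass
class MonthlyClimate:
    """Per-site monthly climate: a tidy table plus the station latitude.

    ``table`` columns: year, month, tmean, tmax, tmin, prec (°C / mm).
    ``incomplete_years`` lists calendar years lacking all 12 months; they are
    retained in the table but excluded from derived-index calculations.
    """

    site: str
    latitude: float
    table: pd.DataFrame
    incomplete_years: tuple[int, ...] = ()
    drought_years: tuple[int, ...] = ()  # populated by the simulator

    def __post_init__(self):
        req = ["year", "month", "tmean", "tmax", "tmin", "prec"]
        missing = [c for c in req if c not in self.table.columns]
        if missing:
            raise ClimateValidationError(f"missing columns: {missing}")
        t = self.table
        bad = t.index[(t["month"] < 1) | (t["month"] > 12)].tolist()
        if bad:
            raise ClimateValidationError(f"month out of 1..12 at rows {bad}")
        bad = t.index[t["tmax"] < t["tmin"]].tolist()
        if bad:
            raise ClimateValidationError(f"tmax < tmin at rows {bad}")
        bad = t.index[t["prec"] < 0].tolist()
        if bad:
            raise ClimateValidationError(f"negative precipitation at rows {bad}")
        counts = t.groupby("year")["month"].nunique()
        incomplete = tuple(int(y) for y in counts.index[counts < 12])
        object.__setattr__(self, "incomplete_years", incomplete)
        self.table = t.sort_values(["year", "month"]).reset_index(drop=True)

    def complete_years(self) -> np.ndarray:
        years = self.table["year"].unique()
        return np.sort(np.setdiff1d(years, np.asarray(self.incomplete_years)))

    def complete_table(self) -> pd.DataFrame:
        return self.table[self.table["year"].isin(self.complete_years())].reset_index(
            drop=True
        )

    def monthly_matrix(self, var: str) -> pd.DataFrame:
        """Complete years × months 1..12 matrix for one variable."""
        ct = self.complete_table()
        return ct.pivot(index="year", columns="month", values=var)


# ---------------------------------------------------------------------------
# Tucson / RWL decadal format
# ---------------------------------------------------------------------------

def _parse_rwl_value(tok: str, lineno: int) -> int:
    try:
        return int(tok)
    except ValueError:
        raise RWLParseError(f"line {lineno}: non-integer value {tok!r}") from None


def read_rwl(path, dialect: str = DEFAULT_DIALECT) -> list[RingWidthSeries]:
    """Parse a decadal Tucson file into a list of :class:`RingWidthSeries`.

    The end-of-series sentinel (999 or -9999 by dialect) is consumed, series
    ids are preserved verbatim (stripped of trailing blanks), and the result
    round-trips through :func:`write_rwl`.
    """
    d = DIALECTS[dialect]
    text = Path(path).read_text(encoding="utf-8")
    # per-series accumulation: id -> {year: units}
    acc: dict[str, dict[int, int]] = {}
    order: list[str] = []
    closed: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip():
            continue
        sid = raw[:8].strip()
        rest = raw[8:]
        if not sid:
            raise RWLParseError(f"line {lineno}: empty series id")
        try:
            year = int(rest[:4])
        except ValueError:
            raise RWLParseError(
                f"line {lineno}: bad decade year {rest[:4]!r}"
            ) from None
        toks = rest[4:].split()
        if not toks:
            raise RWLParseError(f"line {lineno}: decade line with no values")
        if sid in closed:
            raise RWLParseError(
                f"line {lineno}: data for series {sid!r} after its sentinel"
            )
        if sid not in acc:
            acc[sid] = {}
            order.append(sid)
        vals = [_parse_rwl_value(t, lineno) for t in toks]
        for k, v in enumerate(vals):
            if v == d.sentinel:
                if k != len(vals) - 1:
                    raise RWLParseError(
                        f"line {lineno}: values after sentinel in series {sid!r}"
                    )
                closed.add(sid)
                break
            y = year + k
            if y in acc[sid]:
                raise RWLParseError(
                    f"line {lineno}: overlapping year {y} in series {sid!r}"
                )
            acc[sid][y] = v
    unterminated = [s for s in order if s not in closed]
    if unterminated:
        raise RWLParseError(
            f"series without end-of-series sentinel: {unterminated}"
        )
    out = []
    for sid in order:
        years = sorted(acc[sid])
        if not years:
            raise RWLParseError(f"series {sid!r} holds no values")
        if years != list(range(years[0], years[-1] + 1)):
            raise RWLParseError(f"series {sid!r}: years not consecutive")
        out.append(
            RingWidthSeries(
                series_id=sid,
                first_year=years[0],
                widths=tuple(d.to_mm(acc[sid][y]) for y in years),
            )
        )
    return out


def write_rwl(collection: Sequence[RingWidthSeries], path,
              dialect: str = DEFAULT_DIALECT) -> None:
    """Write series in standard decadal layout.  Inverse of :func:`read_rwl`."""
    d = DIALECTS[dialect]
    lines: list[str] = []
    for s in collection:
        if len(s.series_id) > 8:
            raise RWLFormatError(f"series id {s.series_id!r} exceeds 8 characters")
        units = []
        for w in s.widths:
            u = d.to_int(w)
            if abs(u * d.precision_mm - w) > 1e-6:
                raise RWLFormatError(
                    f"series {s.series_id!r}: width {w} not representable at "
                    f"{d.name} precision"
                )
            if u == d.sentinel:
                raise RWLFormatError(
                    f"series {s.series_id!r}: width {w} collides with the "
                    f"{d.name} sentinel {d.sentinel}"
                )
            if not -9999 <= u <= 99999:
                raise RWLFormatError(
                    f"series {s.series_id!r}: width {w} exceeds field width"
                )
            units.append(u)
        units.append(d.sentinel)
        year = s.first_year
        i = 0
        while i < len(units):
            # first line runs to the end of the start year's decade
            decade_end = (year // 10) * 10 + 9
            ncols = min(decade_end - year + 1, len(units) - i)
            row = units[i:i + ncols]
            lines.append(
                f"{s.series_id:<8}{year:>4}" + "".join(f"{u:>6}" for u in row)
            )
            i += ncols
            year += ncols
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""),
                          encoding="utf-8")


# ---------------------------------------------------------------------------
# climate / metadata CSV
# ---------------------------------------------------------------------------

def read_climate_csv(path, site: str | None = None,
                     latitude: float | None = None) -> MonthlyClimate:
    """Load a monthly climate CSV into a validated :class:`MonthlyClimate`.

    Latitude and site may appear as ``# latitude: X`` / ``# site: S`` header
    comments; explicit arguments win.  Years without all 12 months are flagged
    incomplete and excluded from index calculations downstream.
    """
    head_site, head_lat = None, None
    text = Path(path).read_text(encoding="utf-8")
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            k, _, v = line.lstrip("# ").partition(":")
            k = k.strip().lower()
            if k == "latitude":
                head_lat = float(v)
            elif k == "site":
                head_site = v.strip()
        else:
            body_lines.append(line)
    df = pd.read_csv(_io.StringIO("\n".join(body_lines)))
    df.columns = [c.strip().lower() for c in df.columns]
    req = {"year", "month", "tmean", "tmax", "tmin", "prec"}
    if not req.issubset(df.columns):
        raise ClimateValidationError(f"missing columns: {sorted(req - set(df.columns))}")
    lat = latitude if latitude is not None else head_lat
    if lat is None:
        raise ClimateValidationError("latitude missing from header and arguments")
    return MonthlyClimate(site=site or head_site or "", latitude=lat,
                          table=df[sorted(req, key=list(df.columns).index)]
                          [["year", "month", "tmean", "tmax", "tmin", "prec"]])


def write_climate_csv(climate: MonthlyClimate, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# site: {climate.site}\n# latitude: {climate.latitude}\n")
        climate.table.to_csv(fh, index=False, lineterminator="\n")


def read_metadata_csv(path) -> pd.DataFrame:
    """Sidecar metadata: columns series_id, tree_id, provenance, site."""
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    req = {"series_id", "tree_id", "provenance", "site"}
    if not req.issubset(df.columns):
        raise ClimateValidationError(
            f"metadata missing columns: {sorted(req - set(df.columns))}"
        )
    return df


def write_metadata_csv(collection: Sequence[RingWidthSeries], path) -> None:
    pd.DataFrame(
        {
            "series_id": [s.series_id for s in collection],
            "tree_id": [s.tree_id for s in collection],
            "provenance": [s.provenance for s in collection],
            "site": [s.site for s in collection],
        }
    ).to_csv(path, index=False, lineterminator="\n")


def attach_metadata(collection: Iterable[RingWidthSeries],
                    meta: pd.DataFrame) -> list[RingWidthSeries]:
    """Return copies of the series with tree/provenance/site labels filled in."""
    dup = meta["series_id"][meta["series_id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate series ids in metadata: {dup}")
    idx = meta.set_index("series_id")
    out = []
    for s in collection:
        if s.series_id not in idx.index:
            raise KeyError(f"no metadata row for series {s.series_id!r}")
        row = idx.loc[s.series_id]
        out.append(replace(s, tree_id=row["tree_id"],
                           provenance=row["provenance"], site=row["site"]))
    return out


def read_pdsi_csv(path, site: str = "") -> pd.DataFrame:
    """Validate an externally supplied PDSI series (year, month, pdsi).

    PDSI is consumed, never computed: the expected source is a reanalysis
    download.  Returns a tidy frame with a ``site`` column attached.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    req = {"year", "month", "pdsi"}
    if not req.issubset(df.columns):
        raise ClimateValidationError(
            f"PDSI file missing columns: {sorted(req - set(df.columns))}"
        )
    bad = df.index[(df["month"] < 1) | (df["month"] > 12)].tolist()
    if bad:
        raise ClimateValidationError(f"PDSI month out of range at rows {bad}")
    df = df[["year", "month", "pdsi"]].copy()
    df["site"] = site
    return df


def export_long_table(rwi_collection, path=None) -> pd.DataFrame:
    """Long-format single-tree RWI table for external mixed-model/GEE fitting.

    One row per tree × year; columns ``site, prov, tree, year, rwi`` in that
    (stable, documented) order.  Row count equals the sum of series lengths.
    """
    rows = []
    for r in rwi_collection:
        for y, v in zip(r.years, r.values()):
            rows.append((r.site, r.provenance, r.tree_id or r.series_id,
                         int(y), float(v)))
    df = pd.DataFrame(rows, columns=["site", "prov", "tree", "year", "rwi"])
    if path is not None:
        df.to_csv(path, index=False, lineterminator="\n")
    return df
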