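"""Event- and pointer-year detection from single-tree ring-width indices.

Each tree's index is standardized within a short moving window (Cropper
values); thresholds 1 / 1.28 / 1.645 grade weak, strong and extreme event
years.  A provenance registers a pointer year when at least a threshold
fraction (default 65%) of its assessable trees show a same-sign event, and
a common pointer year (CPY) needs agreement from a minimum number of
provenances (default 6 of 10).  Because the window statistics travel with
the series, a sustained multi-year depression suppresses single-year
flags — the metric sees the depressed years as the new local norm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WEAK", "STRONG", "EXTREME",
    "PointerTable",
    "cropper_values",
    "classify_intensity",
    "provenance_pointer_years",
    "common_pointer_years",
]

WEAK, STRONG, EXTREME = 1.0, 1.28, 1.645
_CLASS_NAMES = {0: "none", 1: "weak", 2: "strong", 3: "extreme"}


@dataclass(frozen=True)
class PointerTable:
    """Per-year event statistics and pointer flags for one provenance×site."""

    provenance: str
    site: str
    table: pd.DataFrame
    # columns: year, n_trees, mean_cropper,
    #          frac_weak_pos .. frac_extreme_neg, pointer (−1/0/+1), intensity

    def pointer_years(self, sign: int | None = None) -> list[int]:
        t = self.table
        sel = t["pointer"] != 0 if sign is None else t["pointer"] == sign
        return [int(y) for y in t.loc[sel, "year"]]


def cropper_values(values, window: int = 5) -> np.ndarray:
    """Moving-window standardization C_t = (x_t − mean_w) / sd_w.

    The window is centred on t; sd is the sample (n−1) standard deviation.
    Edge years without a full window — and windows with zero spread — are NaN.
    """
    x = np.asarray(values, dtype=float)
    if window % 2 != 1 or window < 3:
        raise ValueError("window must be an odd integer ≥ 3")
    n = len(x)
    if n < window:
        raise ValueError(f"series length {n} < window {window}")
    half = window // 2
    out = np.full(n, np.nan)
    for t in range(half, n - half):
        w = x[t - half: t + half + 1]
        sd = w.std(ddof=1)
        if sd > 0:
            out[t] = (x[t] - w.mean()) / sd
    return out


def classify_intensity(c: float) -> tuple[str, int]:
    """Neuwirth intensity class of a Cropper value: (class name, sign).

    |C| > 1.645 extreme, > 1.28 strong, > 1 weak, else none; sign follows C.
    """
    if not np.isfinite(c):
        raise ValueError("Cropper value undefined")
    a = abs(c)
    if a > EXTREME:
        level = 3
    elif a > STRONG:
        level = 2
    elif a > WEAK:
        level = 1
    else:
        level = 0
    sign = 0 if level == 0 else (1 if c > 0 else -1)
    return _CLASS_NAMES[level], sign


def _levels(c: np.ndarray) -> np.ndarray:
    """Vectorized intensity level (0..3, signed) of Cropper values."""
    a = np.abs(c)
    lvl = np.where(a > EXTREME, 3, np.where(a > STRONG, 2,
                   np.where(a > WEAK, 1, 0)))
    return np.where(np.isfinite(c), lvl * np.sign(c), np.nan)


def provenance_pointer_years(rwi_set, window: int = 5,
                             series_threshold: float = 0.65,
                             min_trees: int = 5,
                             provenance: str = "", site: str = ""
                             ) -> PointerTable:
    """Aggregate single-tree event classes into a provenance pointer table.

    A year is a pointer year of a given sign when ≥ ``series_threshold`` of
    the assessable trees show at least a weak event of that sign; the pointer
    intensity is the highest class still met by that share of trees.  Years
    with fewer than ``min_trees`` assessable trees are not assessed.
    """
    if not 0 < series_threshold <= 1:
        raise ValueError("series threshold must be in (0, 1]")
    rwi_set = list(rwi_set)
    if not rwi_set:
        raise ValueError("empty series set")
    provenance = provenance or rwi_set[0].provenance
    site = site or rwi_set[0].site
    y0 = min(r.first_year for r in rwi_set)
    y1 = max(r.first_year + len(r.index) - 1 for r in rwi_set)
    years = np.arange(y0, y1 + 1)
    L = np.full((len(rwi_set), len(years)), np.nan)
    C = np.full_like(L, np.nan)
    for i, r in enumerate(rwi_set):
        c = cropper_values(r.values(), window)
        j0 = r.first_year - y0
        C[i, j0: j0 + len(c)] = c
        L[i, j0: j0 + len(c)] = _levels(c)
    rows = []
    for j, y in enumerate(years):
        lv = L[:, j]
        ok = np.isfinite(lv)
        n = int(ok.sum())
        rec = {"year": int(y), "n_trees": n,
               "mean_cropper": float(np.nanmean(C[:, j])) if n else np.nan}
        for name, lo in (("weak", 1), ("strong", 2), ("extreme", 3)):
            rec[f"frac_{name}_pos"] = float(np.mean(lv[ok] >= lo)) if n else np.nan
            rec[f"frac_{name}_neg"] = float(np.mean(lv[ok] <= -lo)) if n else np.nan
        pointer, intensity = 0, "none"
        if n >= min_trees:
            for sgn, tag in ((1, "pos"), (-1, "neg")):
                if rec[f"frac_weak_{tag}"] >= series_threshold:
                    pointer = sgn
                    for name, lo in (("extreme", 3), ("strong", 2), ("weak", 1)):
                        if rec[f"frac_{name}_{tag}"] >= series_threshold:
                            intensity = name
                            break
                    break
        rec["pointer"] = pointer
        rec["intensity"] = intensity
        rows.append(rec)
    return PointerTable(provenance=provenance, site=site,
                        table=pd.DataFrame(rows))


def common_pointer_years(tables, min_provenances: int = 6) -> pd.DataFrame:
    """Years where ≥ ``min_provenances`` provenances share a same-sign pointer.

    All tables must come from one site.  Returns a frame with columns
    ``year, sign, n_provenances``; a year can appear for at most one sign
    (the sign meeting the quorum — if both did, both rows are kept).
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no pointer tables supplied")
    sites = {t.site for t in tables}
    if len(sites) > 1:
        raise ValueError(f"pointer tables mix sites: {sorted(sites)}")
    counts: dict[tuple[int, int], int] = {}
    for t in tables:
        for _, row in t.table.iterrows():
            s = int(row["pointer"])
            if s != 0:
                key = (int(row["year"]), s)
                counts[key] = counts.get(key, 0) + 1
    rows = [
        {"year": y, "sign": s, "n_provenances": c}
        for (y, s), c in sorted(counts.items())
        if c >= min_provenances
    ]
    return pd.DataFrame(rows, columns=["year", "sign", "n_provenances"])
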