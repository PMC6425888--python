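"""Climate–growth correlations, chronology clustering and bioclim ordination.

Chronologies are correlated month-by-month with climate covariates over a
20-month window from March of the previous year through October of the
current year — the span in which temperate-conifer ring formation integrates
weather.  Provenance chronologies are grouped by Euclidean-distance
hierarchical clustering (linkage chosen by the agglomerative coefficient,
cluster count by the Mojena stopping rule), and site/provenance climates are
ordinated by a PCA of the 19 bioclim variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

from .climate import BioclimVector

__all__ = [
    "CLIMATE_WINDOW_MONTHS",
    "CorrelationTable",
    "ClusterResult",
    "climate_growth_correlations",
    "agglomerative_coefficient",
    "cluster_chronologies",
    "mojena_k",
    "bioclim_pca",
    "cluster_to_newick",
]

# (year offset, month): previous-year March .. current-year October
CLIMATE_WINDOW_MONTHS: tuple[tuple[int, int], ...] = tuple(
    [(-1, m) for m in range(3, 13)] + [(0, m) for m in range(1, 11)]
)


def _month_label(offset: int, month: int) -> str:
    name = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
            "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"][month - 1]
    return f"prev{name}" if offset else f"cur{name}"


@dataclass(frozen=True)
class CorrelationTable:
    """Pearson r / p of one chronology against monthly climate covariates."""

    provenance: str
    site: str
    table: pd.DataFrame  # columns: variable, month_label, r, p, tier, n

    def grid(self, value: str = "r") -> pd.DataFrame:
        return self.table.pivot(index="variable", columns="month_label",
                                values=value)


@dataclass(frozen=True)
class ClusterResult:
    """One linkage tree with its agglomerative coefficient and Mojena k."""

    labels: tuple[str, ...]
    method: str
    merge: np.ndarray            # scipy linkage matrix
    agglomerative_coef: float
    mojena_clusters: int


def climate_growth_correlations(chronology, climate_series: dict,
                                years: range | None = None,
                                tiers=(0.05, 0.01, 0.001)) -> CorrelationTable:
    """Correlate a chronology with each climate variable over the 20-month window.

    ``climate_series`` maps variable name -> tidy frame with columns
    year, month, value (a :class:`~dendroprov.climate.DerivedClimateSeries`
    table, or raw temperature/precipitation reshaped the same way).  Months
    with undefined values (e.g. SPEI spin-up) are excluded pairwise.
    """
    chron_years = chronology.years
    cvals = chronology.values()
    if years is not None:
        sel = np.isin(chron_years, np.asarray(list(years)))
        chron_years, cvals = chron_years[sel], cvals[sel]
    rows = []
    for var, tab in climate_series.items():
        tab = tab.table if hasattr(tab, "table") else tab
        lut = {(int(y), int(m)): v for y, m, v in
               zip(tab["year"], tab["month"], tab["value"])}
        for off, month in CLIMATE_WINDOW_MONTHS:
            xs, ys = [], []
            for y, c in zip(chron_years, cvals):
                v = lut.get((int(y) + off, month))
                if v is not None and np.isfinite(v):
                    xs.append(v)
                    ys.append(c)
            if len(xs) < 20:
                raise ValueError(
                    f"{var} {_month_label(off, month)}: overlap {len(xs)} < 20 years"
                )
            r, p = pearsonr(xs, ys)
            tier = ""
            for t in sorted(tiers):
                if p < t:
                    tier = f"p<{t:g}"
                    break
            rows.append({"variable": var,
                         "month_label": _month_label(off, month),
                         "r": float(r), "p": float(p), "tier": tier,
                         "n": len(xs)})
    return CorrelationTable(provenance=getattr(chronology, "provenance", ""),
                            site=getattr(chronology, "site", ""),
                            table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

_METHODS = {"single": "single", "complete": "complete",
            "UPGMA": "average", "Ward": "ward"}


def agglomerative_coefficient(merge: np.ndarray) -> float:
    """Agnes-style agglomerative coefficient of a linkage tree.

    1 − mean over objects of (height of the object's first merge / height of
    the final merge); values near 1 indicate strong clustering structure.
    """
    Z = np.asarray(merge, dtype=float)
    n = Z.shape[0] + 1
    final = Z[-1, 2]
    if final <= 0:
        return 0.0
    first = np.full(n, np.nan)
    members: list[list[int]] = [[i] for i in range(n)]
    for k in range(Z.shape[0]):
        i, j, h = int(Z[k, 0]), int(Z[k, 1]), Z[k, 2]
        merged = []
        for c in (i, j):
            objs = members[c] if c < n else members[c]
            merged.extend(objs)
            for o in objs:
                if np.isnan(first[o]):
                    first[o] = h
        members.append(merged)
    return float(np.mean(1.0 - first / final))


def mojena_k(merge_heights, constant: float = 1.25) -> int:
    """Mojena stopping rule: cut before the first unusually high fusion.

    With fusion heights h_1..h_{n−1} in agglomeration order, the chosen
    partition precedes the first fusion exceeding mean(h) + constant × sd(h);
    if no fusion exceeds the threshold there is no structure and k = 1.
    """
    h = np.asarray(merge_heights, dtype=float)
    if h.size < 2:
        raise ValueError("need at least 2 merges")
    thr = h.mean() + constant * h.std(ddof=1)
    exceed = np.nonzero(h > thr)[0]
    if exceed.size == 0:
        return 1
    j = int(exceed[0])          # 0-based index of first exceeding fusion
    n = h.size + 1
    return n - j


def cluster_chronologies(chronologies, methods=("single", "complete",
                                                "UPGMA", "Ward"),
                         mojena_constant: float = 1.25
                         ) -> tuple[dict[str, ClusterResult], str]:
    """Cluster chronologies by Euclidean distance under several linkages.

    Series are truncated to their common period (with a warning when spans
    differ).  Every requested linkage is fitted; the method with the highest
    agglomerative coefficient is flagged as selected, and the Mojena rule on
    the selected tree picks the cluster count.
    Returns ``(results by method, selected method name)``.
    """
    chronologies = list(chronologies)
    if len(chronologies) < 3:
        raise ValueError("need at least 3 chronologies")
    y0 = max(c.first_year for c in chronologies)
    y1 = min(c.first_year + len(c.values_) - 1 for c in chronologies)
    if y1 < y0:
        raise ValueError("chronologies share no common period")
    spans = {(c.first_year, c.first_year + len(c.values_) - 1)
             for c in chronologies}
    if len(spans) > 1:
        warnings.warn(f"unequal spans; truncated to common period {y0}-{y1}")
    X = np.vstack([c.values()[y0 - c.first_year: y1 - c.first_year + 1]
                   for c in chronologies])
    labels = tuple(f"{c.site}_{c.provenance}" for c in chronologies)
    d = pdist(X, metric="euclidean")
    results = {}
    for m in methods:
        Z = linkage(d, method=_METHODS[m])
        results[m] = ClusterResult(
            labels=labels, method=m, merge=Z,
            agglomerative_coef=agglomerative_coefficient(Z),
            mojena_clusters=mojena_k(Z[:, 2], mojena_constant),
        )
    selected = max(results, key=lambda m: results[m].agglomerative_coef)
    return results, selected


def cluster_to_newick(result: ClusterResult) -> str:
    """Newick export with branch lengths derived from merge heights."""
    Z = result.merge
    n = Z.shape[0] + 1
    height = {i: 0.0 for i in range(n)}
    node = {i: result.labels[i] for i in range(n)}
    for k in range(Z.shape[0]):
        i, j, h = int(Z[k, 0]), int(Z[k, 1]), float(Z[k, 2])
        bi, bj = h - height[i], h - height[j]
        node[n + k] = f"({node[i]}:{bi:.6g},{node[j]}:{bj:.6g})"
        height[n + k] = h
    return node[n + Z.shape[0] - 1] + ";"


# ---------------------------------------------------------------------------
# bioclim ordination
# ---------------------------------------------------------------------------

def bioclim_pca(vectors: dict, n_components: int = 3) -> dict:
    """PCA of standardized bioclim variables across locations.

    ``vectors`` maps location label -> :class:`BioclimVector` (or a 19-vector).
    Variables are standardized to zero mean / unit variance, so eigenvalues
    sum to the number of retained variables; zero-variance (or undefined)
    variables are dropped with a warning.  Each component is oriented so its
    largest-magnitude variable correlation is positive.

    Returns a dict with ``eigenvalues``, ``variance_pct``,
    ``correlations`` (variable × PC frame), ``scores`` (location × PC frame)
    and ``dropped``.
    """
    labels = list(vectors)
    if len(labels) < 3:
        raise ValueError("need at least 3 locations")
    rows = []
    for lab in labels:
        v = vectors[lab]
        rows.append(list(v.values) if isinstance(v, BioclimVector) else list(v))
    X = np.asarray(rows, dtype=float)
    varnames = [f"bio{i}" for i in range(1, X.shape[1] + 1)]
    keep, dropped = [], []
    for j, name in enumerate(varnames):
        col = X[:, j]
        if np.all(np.isfinite(col)) and np.std(col, ddof=1) > 0:
            keep.append(j)
        else:
            dropped.append(name)
    if dropped:
        warnings.warn(f"dropped zero-variance/undefined variables: {dropped}")
    X = X[:, keep]
    names = [varnames[j] for j in keep]
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    R = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0, None), evecs[:, order]
    ncomp = min(n_components, len(names))
    corr = evecs[:, :ncomp] * np.sqrt(evals[:ncomp])
    scores = Z @ evecs[:, :ncomp]
    for k in range(ncomp):
        jmax = int(np.argmax(np.abs(corr[:, k])))
        if corr[jmax, k] < 0:
            corr[:, k] = -corr[:, k]
            scores[:, k] = -scores[:, k]
    pcs = [f"PC{k+1}" for k in range(ncomp)]
    return {
        "eigenvalues": evals,
        "variance_pct": evals / len(names) * 100.0,
        "correlations": pd.DataFrame(corr, index=names, columns=pcs),
        "scores": pd.DataFrame(scores, index=labels, columns=pcs),
        "dropped": tuple(dropped),
    }
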