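"""Principal component gradient analysis (PCGA) and its pairwise refinement.

PCGA orders individual trees by the polar angle of their loadings on the
first two principal components of the tree × year index matrix: trees whose
year-to-year growth variation is alike sit at similar angles, and a
systematic angular shift between two provenances indicates provenance-
specific growth patterns.  The pairwise refinement runs a separate PCGA for
every provenance pair and tests the resulting gradient ranks with a
Wilcoxon rank-sum test, yielding a provenance × provenance p-value matrix.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = [
    "GradientResult",
    "PairwisePCGAResult",
    "pcga_gradient",
    "rank_sum_test",
    "pairwise_pcga",
    "differentiation_score",
    "common_period_matrix",
]


@dataclass(frozen=True)
class GradientResult:
    """Loadings, polar angles and gradient ranks of one PCGA run."""

    series_ids: tuple[str, ...]
    loadings: np.ndarray        # (n_trees, 2), PC1/PC2 loadings
    angles: np.ndarray          # radians, atan2(PC2, PC1)
    ranks: np.ndarray           # permutation of 1..n (midranks on ties)
    variance_explained: tuple[float, float]  # percent, PC1 ≥ PC2


@dataclass(frozen=True)
class PairwisePCGAResult:
    """Symmetric provenance × provenance p-value matrix for one site."""

    site: str
    provenances: tuple[str, ...]
    p_matrix: pd.DataFrame              # index/columns = provenances, NaN diag
    gradients: dict                     # (provA, provB) -> GradientResult
    excluded: tuple[str, ...] = ()      # provenances with too few trees

    def pairs(self):
        for a, b in itertools.combinations(self.provenances, 2):
            yield a, b, float(self.p_matrix.loc[a, b])

    def long_table(self, tiers=(0.05, 0.01)) -> pd.DataFrame:
        rows = []
        for a, b, p in self.pairs():
            tier = ""
            if np.isfinite(p):
                if p < min(tiers):
                    tier = "p<%.2g" % min(tiers)
                elif p < max(tiers):
                    tier = "p<%.2g" % max(tiers)
            rows.append((a, b, p, tier))
        return pd.DataFrame(rows, columns=["provA", "provB", "p", "tier"])


def common_period_matrix(rwi_set) -> tuple[np.ndarray, list[str]]:
    """Years × trees matrix over the common overlap of a set of index series."""
    rwi_set = list(rwi_set)
    y0 = max(r.first_year for r in rwi_set)
    y1 = min(r.first_year + len(r.index) - 1 for r in rwi_set)
    if y1 < y0:
        raise ValueError("series share no common period")
    cols = [r.values()[y0 - r.first_year: y1 - r.first_year + 1]
            for r in rwi_set]
    return np.column_stack(cols), [r.series_id for r in rwi_set]


def pcga_gradient(matrix: np.ndarray, series_ids=None) -> GradientResult:
    """PCA of tree series over their common period; trees ranked by angle.

    Columns (trees) are centred on their own means; loadings are each tree's
    projection pattern on the first two components.  PC1 is oriented so the
    mean tree loading is positive (and PC2 likewise), which fixes the
    reflection ambiguity of polar coordinates; ranks order trees by angle,
    ties broken by stable series order.
    """
    X = np.asarray(matrix, dtype=float)
    nyears, ntrees = X.shape
    if ntrees < 4:
        raise ValueError(f"PCGA needs ≥ 4 trees, got {ntrees}")
    if nyears < 10:
        raise ValueError(f"PCGA needs ≥ 10 common years, got {nyears}")
    if not np.all(np.isfinite(X)):
        raise ValueError("missing cells in the common period")
    if series_ids is None:
        series_ids = [f"t{i}" for i in range(ntrees)]
    Xc = X - X.mean(axis=0, keepdims=True)
    # SVD of the year × tree matrix: V columns are tree loading patterns
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    if var.max() <= 0:
        raise ValueError("degenerate matrix: no positive-variance component")
    share = var / var.sum() * 100.0
    load = (Vt[:2].T * s[:2])  # scale by singular values: correlation-like
    for k in range(2):
        if load[:, k].mean() < 0:
            load[:, k] = -load[:, k]
    angles = np.arctan2(load[:, 1], load[:, 0])
    # stable rank: sort by (angle, original order)
    order = np.lexsort((np.arange(ntrees), angles))
    ranks = np.empty(ntrees, dtype=float)
    ranks[order] = np.arange(1, ntrees + 1)
    return GradientResult(
        series_ids=tuple(series_ids),
        loadings=load,
        angles=angles,
        ranks=ranks,
        variance_explained=(float(share[0]), float(share[1])),
    )


def rank_sum_test(a, b) -> tuple[float, float]:
    """Wilcoxon rank-sum: statistic (Mann-Whitney U of group A) and two-sided p.

    Exact enumeration when the combined sample is small (n ≤ 12) and untied;
    otherwise the normal approximation with tie and continuity corrections.
    Identical constant samples give p = 1 with a ties warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("all observations identical; rank-sum p set to 1")
        return float(a.size * b.size / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    n = a.size + b.size
    method = "exact" if (n <= 12 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method,
                       use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def pairwise_pcga(rwi_by_provenance: dict, site: str = "",
                  min_trees: int = 4) -> PairwisePCGAResult:
    """Pairwise PCGA over all provenance pairs at one site.

    For each unordered pair, only those two provenances' trees enter the PCA;
    gradient ranks are then compared between the provenances with the
    rank-sum test.  Provenances with fewer than ``min_trees`` trees are
    excluded (their matrix rows stay NaN).
    """
    provs = list(rwi_by_provenance)
    if len(provs) < 2:
        raise ValueError("need at least 2 provenances")
    excluded = tuple(p for p in provs if len(rwi_by_provenance[p]) < min_trees)
    for p in excluded:
        warnings.warn(f"provenance {p}: fewer than {min_trees} trees, excluded")
    kept = [p for p in provs if p not in excluded]
    pm = pd.DataFrame(np.nan, index=provs, columns=provs)
    gradients = {}
    for pa, pb in itertools.combinations(kept, 2):
        sa, sb = list(rwi_by_provenance[pa]), list(rwi_by_provenance[pb])
        X, ids = common_period_matrix(sa + sb)
        g = pcga_gradient(X, ids)
        na = len(sa)
        _, p = rank_sum_test(g.ranks[:na], g.ranks[na:])
        pm.loc[pa, pb] = pm.loc[pb, pa] = p
        gradients[(pa, pb)] = g
    return PairwisePCGAResult(site=site, provenances=tuple(provs),
                              p_matrix=pm, gradients=gradients,
                              excluded=excluded)


def differentiation_score(result: PairwisePCGAResult,
                          alpha: float = 0.05) -> float:
    """Fraction of provenance pairs significantly separated at level alpha.

    The scalar used to compare sites: low values mean provenances grow alike
    (the homogenised, marginal-site pattern), high values mean strong
    between-provenance differentiation.
    """
    ps = [p for _, _, p in result.pairs() if np.isfinite(p)]
    if not ps:
        raise ValueError("no valid provenance pair")
    return float(np.mean([p < alpha for p in ps]))
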