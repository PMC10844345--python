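"""Group-level statistics on vertex stability maps.

Vertex-wise GLM contrast (two-sample t with optional nuisance covariates),
connected-component cluster formation on the mesh with an area threshold,
cluster-level inference by group-label permutation of maximal cluster extent,
Benjamini-Hochberg FDR across clusters, clinical correlations, and the
usual cohort demographics tests.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from .surface import ParcellationAtlas, SurfaceMesh, adjacency, vertex_areas

__all__ = [
    "GroupDesign",
    "ClusterResult",
    "StatTestResult",
    "fit_group_glm",
    "form_clusters",
    "cluster_pvalues_permutation",
    "bh_fdr",
    "hemisphere_bonferroni",
    "cluster_mean_stability",
    "spearman",
    "demographics_tests",
    "label_clusters",
]


@dataclass
class GroupDesign:
    """Group indicator plus optional nuisance covariates.

    ``group`` is coded patient=1 / control=0 (any two labels accepted; the
    lexicographically later one is coded 1 when strings are supplied).
    """

    group: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.group)
        if g.dtype.kind in "UOS":
            levels = sorted(set(g.tolist()))
            if len(levels) != 2:
                raise ValueError(f"need exactly 2 group levels, got {levels}")
            g = (g == levels[-1]).astype(float)
        self.group = np.asarray(g, dtype=float)
        counts = [(self.group == v).sum() for v in (0.0, 1.0)]
        if min(counts) < 2:
            raise ValueError("both groups need at least 2 subjects")

    def matrix(self) -> np.ndarray:
        cols = [np.ones_like(self.group), self.group]
        if self.covariates is not None and len(self.covariates.columns):
            c = np.asarray(self.covariates, dtype=float)
            cols += [c[:, i] for i in range(c.shape[1])]
        x = np.column_stack(cols)
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError("design matrix is rank deficient")
        return x


@dataclass
class ClusterResult:
    """A connected suprathreshold vertex set on one hemisphere."""

    vertices: np.ndarray
    sign: int                       # +1 increase, -1 decrease
    hemisphere: str
    area_mm2: float
    n_vertices: int
    peak_vertex: int
    peak_coord: np.ndarray
    peak_t: float
    p: float | None = None
    q: float | None = None
    region_labels: list = field(default_factory=list)
    network_labels: list = field(default_factory=list)


@dataclass
class StatTestResult:
    test: str
    statistic: float
    p: float
    n: tuple


# ---------------------------------------------------------------------------
# vertex-wise GLM

def fit_group_glm(maps: np.ndarray, design: GroupDesign,
                  mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Per-vertex OLS of stability on [intercept, group, covariates].

    Returns the group-coefficient t-statistic per vertex (NaN outside the
    mask) and the residual degrees of freedom n - rank(design).  With no
    covariates this equals the classical pooled-variance two-sample t.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 2:
        raise ValueError("maps must be (subjects, vertices)")
    x = design.matrix()
    n, p = x.shape
    if x.shape[0] != maps.shape[0]:
        raise ValueError("design rows must match number of subject maps")
    df = n - p
    if df < 3:
        raise ValueError(f"only {df} residual degrees of freedom; need >= 3")
    mask = np.asarray(mask, dtype=bool)
    y = maps[:, mask]
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[1] / se
    out = np.full(maps.shape[1], np.nan)
    out[mask] = t
    return out, df


# ---------------------------------------------------------------------------
# clusters

def _components(vertex_set: np.ndarray, adj: sp.csr_matrix) -> list[np.ndarray]:
    if vertex_set.size == 0:
        return []
    sub = adj[vertex_set][:, vertex_set]
    n_comp, labels = connected_components(sub, directed=False)
    return [vertex_set[labels == c] for c in range(n_comp)]


def form_clusters(tmap: np.ndarray, df: int, mesh: SurfaceMesh,
                  mask: np.ndarray, vertex_p: float = 0.001,
                  min_area_mm2: float = 20.0) -> list[ClusterResult]:
    """Threshold |t| at the two-sided ``vertex_p`` critical value and form
    connected components per sign; components with area <= ``min_area_mm2``
    are discarded (strict '>' survival rule)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    t_crit = st.t.isf(vertex_p / 2.0, df)
    areas = vertex_areas(mesh)
    adj = adjacency(mesh)
    out: list[ClusterResult] = []
    finite = np.isfinite(tmap) & mask
    for sign in (+1, -1):
        supra = np.flatnonzero(finite & (sign * tmap >= t_crit))
        for comp in _components(supra, adj):
            area = float(areas[comp].sum())
            if not area > min_area_mm2:
                continue
            peak_local = comp[np.argmax(np.abs(tmap[comp]))]
            out.append(ClusterResult(
                vertices=np.sort(comp), sign=sign, hemisphere=mesh.hemisphere,
                area_mm2=area, n_vertices=len(comp),
                peak_vertex=int(peak_local),
                peak_coord=mesh.coords[peak_local].copy(),
                peak_t=float(tmap[peak_local])))
    out.sort(key=lambda c: -c.area_mm2)
    return out


def cluster_pvalues_permutation(maps: np.ndarray, design: GroupDesign,
                                clusters: list[ClusterResult],
                                mesh: SurfaceMesh, mask: np.ndarray,
                                n_perm: int = 499, seed: int = 0,
                                vertex_p: float = 0.001) -> np.ndarray:
    """Cluster p-values by group-label permutation of maximal cluster extent.

    For each permutation the group labels are shuffled, the GLM re-fit
    (covariates stay attached to their subjects) and the maximal
    suprathreshold cluster area over the whole thresholded |t| map (both
    signs) recorded; an observed cluster's p-value is
    (1 + #{perm max area >= observed}) / (1 + n_perm).  Using the global
    maximum rather than a per-sign maximum keeps the run-level error rate of
    the two-sided test at its nominal level instead of doubling it.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives a minimum attainable p of "
                      f"{1.0 / (1 + n_perm):.3g}; consider more permutations",
                      RuntimeWarning)
    if not clusters:
        return np.array([])
    rng = np.random.default_rng(seed)
    mask = np.asarray(mask, dtype=bool)
    areas = vertex_areas(mesh)
    adj = adjacency(mesh)

    def max_area(tmap: np.ndarray, df: int) -> float:
        t_crit = st.t.isf(vertex_p / 2.0, df)
        finite = np.isfinite(tmap) & mask
        best = 0.0
        for sign in (+1, -1):
            supra = np.flatnonzero(finite & (sign * tmap >= t_crit))
            for comp in _components(supra, adj):
                best = max(best, float(areas[comp].sum()))
        return best

    null_max = np.empty(n_perm)
    base_group = design.group.copy()
    for b in range(n_perm):
        perm = rng.permutation(len(base_group))
        d = GroupDesign(base_group[perm], design.covariates)
        tmap, df = fit_group_glm(maps, d, mask)
        null_max[b] = max_area(tmap, df)
    pvals = np.array([
        (1.0 + np.sum(null_max >= c.area_mm2)) / (1.0 + n_perm)
        for c in clusters])
    return pvals


def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejected flags, adjusted values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, adjusted


def hemisphere_bonferroni(alpha: float = 0.05, n_hemis: int = 2) -> float:
    """Per-hemisphere cluster-wise threshold alpha / n_hemis (0.05/2 = 0.025)."""
    if n_hemis < 1:
        raise ValueError("n_hemis must be >= 1")
    return alpha / n_hemis


# ---------------------------------------------------------------------------
# clinical correlation helpers

def cluster_mean_stability(smap, cluster: ClusterResult,
                           weights: np.ndarray | None = None) -> float:
    """Mean stability over a cluster's vertices (optionally area-weighted)."""
    values = smap.values if hasattr(smap, "values") else np.asarray(smap, float)
    if cluster.n_vertices == 0:
        raise ValueError("empty cluster")
    v = values[cluster.vertices]
    if weights is None:
        return float(v.mean())
    w = np.asarray(weights, float)[cluster.vertices]
    return float(np.average(v, weights=w))


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with pairwise-complete missing handling.

    p-value from the t approximation with n-2 df; for n <= 9 an exact
    permutation p is used instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    rx = st.rankdata(x)
    ry = st.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("zero rank variance")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        perms = np.array(list(itertools.permutations(ry)))
        rxc = rx - rx.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        null = (pc @ rxc) / (np.linalg.norm(pc, axis=1) * np.linalg.norm(rxc))
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    else:
        tstat = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho ** 2))
        p = float(2.0 * st.t.sf(abs(tstat), n - 2))
    return rho, min(p, 1.0)


def demographics_tests(design: pd.DataFrame, group_col: str = "group",
                       age_col: str = "age", sex_col: str = "sex",
                       md_left_col: str | None = None,
                       md_right_col: str | None = None,
                       continuity: bool = False) -> dict[str, StatTestResult]:
    """Standard cohort-description tests.

    Mann-Whitney U for age, Pearson chi-square (no continuity correction by
    default) for sex, and — when paired visual-field columns are supplied —
    a Wilcoxon signed-rank test of the inter-eye mean-deviation difference
    within the patient group.
    """
    out: dict[str, StatTestResult] = {}
    levels = sorted(design[group_col].unique().tolist())
    if len(levels) != 2:
        raise ValueError("need exactly two groups")
    a = design.loc[design[group_col] == levels[0]]
    b = design.loc[design[group_col] == levels[1]]

    u, p = st.mannwhitneyu(a[age_col], b[age_col], alternative="two-sided")
    out["age"] = StatTestResult("mann-whitney-u", float(u), float(p),
                                (len(a), len(b)))

    table = pd.crosstab(design[group_col], design[sex_col]).to_numpy()
    if (table == 0).any():
        warnings.warn("empty cell in the sex contingency table; applying "
                      "continuity correction", RuntimeWarning)
        continuity = True
    chi2, p, _, _ = st.chi2_contingency(table, correction=continuity)
    out["sex"] = StatTestResult("chi-square", float(chi2), float(p),
                                (len(a), len(b)))

    if md_left_col and md_right_col:
        patients = design.loc[design[group_col].str.lower().str.startswith("p")]
        d = (patients[md_left_col] - patients[md_right_col]).dropna()
        if np.allclose(d, 0):
            warnings.warn("no non-zero inter-eye differences; signed-rank "
                          "test undefined", RuntimeWarning)
            out["md_inter_eye"] = StatTestResult(
                "wilcoxon-signed-rank", np.nan, np.nan, (len(d),))
        else:
            w, p = st.wilcoxon(d, alternative="two-sided")
            out["md_inter_eye"] = StatTestResult(
                "wilcoxon-signed-rank", float(w), float(p), (len(d),))
    return out


def label_clusters(clusters: list[ClusterResult], atlas: ParcellationAtlas,
                   min_coverage: float = 0.10) -> list[ClusterResult]:
    """Attach region/network names: parcels covering >= 10% of the cluster's
    vertices, ordered by coverage.  Pure lookup; ids when names are absent."""
    for c in clusters:
        labs = atlas.labels[c.vertices]
        labs = labs[labs > 0]
        if labs.size == 0:
            c.region_labels, c.network_labels = [], []
            continue
        uniq, counts = np.unique(labs, return_counts=True)
        frac = counts / c.n_vertices
        order = np.argsort(-frac)
        keep = [int(uniq[i]) for i in order if frac[i] >= min_coverage - 1e-12]
        names = atlas.label_names or {}
        nets = atlas.network_map or {}
        c.region_labels = [names.get(lab, lab) for lab in keep]
        seen: list = []
        for lab in keep:
            net = nets.get(lab)
            if net is not None and net not in seen:
                seen.append(net)
        c.network_labels = seen
    return clusters
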