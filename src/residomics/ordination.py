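"""Ordination and summary statistics for compound presence/absence data.

Jaccard distances with non-metric multidimensional scaling (NMDS) and
Ward ("ward.D" dialect) clustering operate on merged compound lists;
Pareto-scaled PCA operates on the aligned abundance matrix with missing
cells treated as zeros (presence/absence semantics).  The Jaccard
construction, the Pareto transform, the Kruskal stress computation, and
the ward.D recurrence are implemented here; eigendecomposition and NMDS
optimization are delegated to scikit-learn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

from .align import AlignedMatrix, CompoundList

log = logging.getLogger(__name__)

__all__ = [
    "Ordination",
    "jaccard_distances",
    "kruskal_stress",
    "nmds",
    "ward_cluster",
    "pareto_pca",
    "feature_count_summary",
    "plot_ordination",
]


@dataclass
class Ordination:
    """Sample coordinates plus method-specific quality measures."""

    coords: pd.DataFrame                      # samples x dimensions
    stress: float | None = None               # NMDS Kruskal stress-1
    explained: np.ndarray | None = None       # PCA variance fractions
    loadings: pd.DataFrame | None = None      # PCA feature loadings
    clusters: pd.Series | None = None         # Ward assignment


def jaccard_distances(
    lists: Mapping[str, CompoundList | frozenset | set]
) -> pd.DataFrame:
    """Pairwise Jaccard distances d = 1 - |a&b|/|a|b| on compound sets.

    Two empty sets are at distance 0 by convention (logged)."""
    names = sorted(lists)
    sets = {n: (v.ids if isinstance(v, CompoundList) else frozenset(v))
            for n, v in lists.items()}
    if len(names) < 2:
        raise ValueError("need at least two samples")
    d = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            union = sets[a] | sets[b]
            if not union:
                log.warning("jaccard_distances: %s and %s both empty; d=0", a, b)
                dist = 0.0
            else:
                dist = 1.0 - len(sets[a] & sets[b]) / len(union)
            d.loc[a, b] = d.loc[b, a] = dist
    return d


def kruskal_stress(coords: np.ndarray, dissim: np.ndarray) -> float:
    """Kruskal stress-1 of an embedding against input dissimilarities.

    Disparities are the isotonic (monotone non-decreasing) regression of
    embedded distances on dissimilarity rank; stress-1 =
    sqrt(sum (d - dhat)^2 / sum d^2) over the upper triangle.
    """
    coords = np.asarray(coords, dtype=float)
    dissim = np.asarray(dissim, dtype=float)
    iu = np.triu_indices(dissim.shape[0], k=1)
    delta = dissim[iu]
    d = np.sqrt(((coords[iu[0]] - coords[iu[1]]) ** 2).sum(axis=1))
    order = np.argsort(delta, kind="stable")
    dhat = np.empty_like(d)
    dhat[order] = IsotonicRegression().fit_transform(
        np.arange(order.size), d[order])
    denom = (d ** 2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def nmds(
    dist: pd.DataFrame,
    k: int = 2,
    n_starts: int = 20,
    seed: int = 0,
) -> Ordination:
    """Non-metric MDS embedding of a distance matrix.

    Best of ``n_starts`` SMACOF starts (scikit-learn), deterministic under
    ``seed``; the reported stress is Kruskal stress-1 recomputed from the
    returned coordinates via :func:`kruskal_stress`.
    """
    n = dist.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of samples ({n})")
    kwargs = dict(n_components=k, n_init=n_starts, random_state=seed,
                  normalized_stress=True, max_iter=300, eps=1e-9)
    try:  # scikit-learn >= 1.9 API
        mds = MDS(metric_mds=False, metric="precomputed", init="random", **kwargs)
        coords = mds.fit_transform(dist.to_numpy())
    except (TypeError, ValueError):  # older spelling of the same options
        mds = MDS(metric=False, dissimilarity="precomputed", **kwargs)
        coords = mds.fit_transform(dist.to_numpy())
    stress = kruskal_stress(coords, dist.to_numpy())
    cdf = pd.DataFrame(coords, index=dist.index,
                       columns=[f"NMDS{i + 1}" for i in range(k)])
    return Ordination(coords=cdf, stress=stress)


def ward_cluster(dist: pd.DataFrame, n_clusters: int = 2) -> pd.Series:
    """Agglomerative clustering with the ward.D update (Lance-Williams on
    the dissimilarities as given, no squaring — the R ``hclust`` ward.D
    dialect).  Returns cluster labels at ``n_clusters`` groups."""
    names = list(dist.index)
    n = len(names)
    if not (1 <= n_clusters <= n):
        raise ValueError("n_clusters out of range")
    d = dist.to_numpy().astype(float).copy()
    np.fill_diagonal(d, np.inf)
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    next_id = n
    while len(active) > n_clusters:
        # find closest active pair
        sub = d[np.ix_(active, active)]
        flat = np.argmin(sub)
        ai, aj = np.unravel_index(flat, sub.shape)
        i, j = active[ai], active[aj]
        if i > j:
            i, j = j, i
        ni, nj = sizes[i], sizes[j]
        dij = d[i, j]
        # ward.D Lance-Williams update against every other active cluster
        for kdx in active:
            if kdx in (i, j):
                continue
            nk = sizes[kdx]
            dn = ((ni + nk) * d[i, kdx] + (nj + nk) * d[j, kdx] - nk * dij) / (
                ni + nj + nk)
            d[i, kdx] = d[kdx, i] = dn
        sizes[i] = ni + nj
        members[i] = members[i] + members[j]
        active.remove(j)
    labels = np.empty(n, dtype=int)
    for lab, cl in enumerate(sorted(active, key=lambda c: min(members[c]))):
        labels[members[cl]] = lab
    return pd.Series(labels, index=names, name="cluster")


def ward_merge_heights(dist: pd.DataFrame) -> list[float]:
    """Merge heights of the full ward.D agglomeration (for cross-checks)."""
    n = dist.shape[0]
    d = dist.to_numpy().astype(float).copy()
    np.fill_diagonal(d, np.inf)
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    heights = []
    while len(active) > 1:
        sub = d[np.ix_(active, active)]
        ai, aj = np.unravel_index(np.argmin(sub), sub.shape)
        i, j = sorted((active[ai], active[aj]))
        ni, nj = sizes[i], sizes[j]
        dij = d[i, j]
        heights.append(float(dij))
        for kdx in active:
            if kdx in (i, j):
                continue
            nk = sizes[kdx]
            dn = ((ni + nk) * d[i, kdx] + (nj + nk) * d[j, kdx] - nk * dij) / (
                ni + nj + nk)
            d[i, kdx] = d[kdx, i] = dn
        sizes[i] = ni + nj
        active.remove(j)
    return heights


def pareto_pca(matrix: AlignedMatrix, k: int = 2) -> Ordination:
    """Pareto-scaled PCA of the aligned abundance matrix (runs as samples).

    Missing cells become zeros; each feature is mean-centered and divided
    by the square root of its standard deviation (ddof=1), damping the
    dominance of high-abundance features; zero-variance features are
    dropped with a warning.  No feature filtering beyond that is applied.
    """
    X = matrix.abundance.T.fillna(0.0)
    sd = X.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        log.warning("pareto_pca: dropping %d zero-variance features", int(zero.sum()))
        X = X.loc[:, ~zero]
        sd = sd[~zero]
    scaled = (X - X.mean(axis=0)) / np.sqrt(sd)
    k = min(k, min(scaled.shape) - 1) if min(scaled.shape) > 1 else 1
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(scaled.to_numpy())
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return Ordination(
        coords=pd.DataFrame(scores, index=X.index, columns=cols),
        explained=pca.explained_variance_ratio_,
        loadings=pd.DataFrame(pca.components_.T, index=X.columns, columns=cols),
    )


def pareto_scale(X: pd.DataFrame) -> pd.DataFrame:
    """The bare Pareto transform: (x - mean) / sqrt(sd), ddof=1."""
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-variance feature; drop before scaling")
    return (X - X.mean(axis=0)) / np.sqrt(sd)


def feature_count_summary(matrix: AlignedMatrix, group_by: str = "solvent") -> pd.DataFrame:
    """Per-run feature counts aggregated by a column-metadata key.

    Returns the box-plot statistics (n runs, mean, median, min, max of the
    number of rows with abundance) per group of ``group_by`` (one of the
    column-metadata fields, e.g. solvent or species)."""
    if group_by not in matrix.col_meta.columns:
        raise KeyError(f"unknown grouping key {group_by!r}; "
                       f"have {list(matrix.col_meta.columns)}")
    counts = matrix.abundance.notna().sum(axis=0).rename("n_features")
    df = pd.concat([counts, matrix.col_meta[group_by]], axis=1)
    out = df.groupby(group_by)["n_features"].agg(
        n_runs="count", mean="mean", median="median", min="min", max="max")
    return out.reset_index()


def plot_ordination(ordination: Ordination, path, label_by: Mapping[str, str] | None = None):
    """Scatter plot of the first two ordination axes (PNG/SVG by suffix)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = ordination.coords
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(coords.iloc[:, 0], coords.iloc[:, 1], s=20)
    for name, (x, y) in coords.iloc[:, :2].iterrows():
        ax.annotate(label_by.get(name, name) if label_by else name, (x, y),
                    fontsize=7, xytext=(2, 2), textcoords="offset points")
    ax.set_xlabel(coords.columns[0])
    ax.set_ylabel(coords.columns[1])
    if ordination.stress is not None:
        ax.set_title(f"stress = {ordination.stress:.4f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
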