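"""i-niche extraction, clustering, profiling and the niche-dependence F-test.

An *i-niche* is the unordered ring of first-tier Delaunay neighbours of an
*index cell*, summarised as a vector of neighbour-type fractions (the index
cell itself is excluded from its own ring).  Clustering all index cells'
composition vectors with K-means (K = 100 on full-scale data) yields a
catalogue of recurring micro-neighbourhoods; profiling marker expression of
the index cells per niche then asks whether a cell's surface phenotype
depends on who its neighbours are.  That question is answered formally by a
nested linear model: marker ~ cell type (reduced) versus marker ~ cell type
+ niche (full), both as categorical one-hot factors, compared with a
partial F-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .interactions import NeighborhoodGraph
from .stacks_io import marker_columns

__all__ = [
    "NicheModel",
    "NicheProfile",
    "AnovaResult",
    "niche_composition",
    "cluster_niches",
    "niche_marker_profile",
    "niche_compartment_distribution",
    "marker_niche_anova",
    "assign_cell_types",
]

DEFAULT_K = 100          # K of the full-scale analysis; phantoms use fewer
DEFAULT_MIN_NEIGHBORS = 3


@dataclass
class NicheModel:
    """K-means model over cell-type composition space.

    Niche ids are ordered by decreasing abundance (niche 0 is the most
    populated).  ``assignment`` maps index-cell id -> niche id.
    """

    k: int
    centroids: pd.DataFrame       # (k, types) rows sum to ~1
    assignment: pd.Series         # index = cell ids
    seed: int
    inertia: float

    def abundance(self) -> pd.Series:
        return self.assignment.value_counts().reindex(range(self.k)).fillna(0).astype(int)


@dataclass
class NicheProfile:
    """Mean marker expression of index cells of one type, per niche.

    Niches holding no index cell of the chosen type are masked (NaN rows,
    True in ``empty``) and never imputed.
    """

    values: pd.DataFrame          # (k, markers)
    empty: pd.Series              # (k,) bool
    index_type: str


class AnovaResult(NamedTuple):
    F: float
    p: float
    delta_r2: float
    df_num: int
    df_den: int


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def niche_composition(graph: NeighborhoodGraph, types,
                      min_degree: int = 1) -> tuple[pd.DataFrame, np.ndarray]:
    """Neighbour-type fraction vector per index cell.

    Returns ``(compositions, excluded_ids)``: a DataFrame indexed by cell id
    with one column per type, rows summing to 1, and the ids of cells with
    fewer than ``min_degree`` neighbours (excluded — a tiny ring makes the
    fraction vector degenerate).
    """
    if isinstance(types, dict):
        arr = np.array([types[i] for i in graph.ids], dtype=object)
    else:
        arr = np.asarray(types, dtype=object)
        if len(arr) != graph.n_nodes:
            raise ValueError("one type label per node required")
    names = sorted(set(arr.tolist()))
    tindex = {t: i for i, t in enumerate(names)}
    codes = np.array([tindex[t] for t in arr])
    T = len(names)
    tallies = np.zeros((graph.n_nodes, T))
    if graph.n_edges:
        e = graph.edges
        np.add.at(tallies, (e[:, 0], codes[e[:, 1]]), 1)
        np.add.at(tallies, (e[:, 1], codes[e[:, 0]]), 1)
    deg = tallies.sum(axis=1)
    keep = deg >= max(1, min_degree)
    comp = tallies[keep] / deg[keep, None]
    excluded = np.asarray(graph.ids)[~keep]
    return (pd.DataFrame(comp, index=np.asarray(graph.ids)[keep], columns=names),
            excluded)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def cluster_niches(compositions: pd.DataFrame, k: int = DEFAULT_K,
                   seed: int = 0, n_init: int = 10) -> NicheModel:
    """K-means over composition vectors; deterministic for a fixed seed.

    Distances are squared-Euclidean on the raw fraction vectors.  The best
    of ``n_init`` restarts (lowest inertia) is kept, and niche ids are
    relabelled in order of decreasing abundance.
    """
    if k > len(compositions):
        raise ValueError(f"k={k} exceeds the {len(compositions)} index cells")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw_labels = km.fit_predict(compositions.to_numpy())
    order = np.argsort(-np.bincount(raw_labels, minlength=k), kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = remap[raw_labels]
    centroids = km.cluster_centers_[order]
    return NicheModel(
        k=k,
        centroids=pd.DataFrame(centroids, columns=compositions.columns),
        assignment=pd.Series(labels, index=compositions.index, name="niche"),
        seed=seed, inertia=float(km.inertia_))


# ---------------------------------------------------------------------------
# Profiles and compartment mapping
# ---------------------------------------------------------------------------

def niche_marker_profile(table: pd.DataFrame, model: NicheModel,
                         index_type: str,
                         markers: list[str] | None = None) -> NicheProfile:
    """Mean marker expression of index cells of ``index_type`` per niche."""
    if "type" not in table.columns:
        raise ValueError("table must carry a 'type' column")
    if index_type not in set(table["type"]):
        raise ValueError(f"index type {index_type!r} absent from the table")
    if markers is None:
        markers = marker_columns(table)
    sub = table.set_index("cell_id").loc[
        table.set_index("cell_id").index.intersection(model.assignment.index)]
    sub = sub.assign(niche=model.assignment.loc[sub.index])
    sub = sub[sub["type"] == index_type]
    means = sub.groupby("niche")[markers].mean().reindex(range(model.k))
    empty = means[markers[0]].isna() if markers else pd.Series(True, index=means.index)
    return NicheProfile(values=means, empty=empty, index_type=index_type)


def niche_compartment_distribution(model: NicheModel, compartment_of_cell,
                                   sample_of_cell=None, threshold: float = 0.9
                                   ) -> tuple[pd.DataFrame, list[int], pd.DataFrame | None]:
    """Compartment occupancy of each niche, and the compartment-specific set.

    Returns ``(fractions, specific, per_sample)``: per niche the fraction of
    index cells in each compartment (rows sum to 1); the niches whose top
    compartment exceeds ``threshold`` (the > 90% rule used to treat niches
    as anatomical landmarks); and, when sample labels are given, a niche x
    sample abundance table.
    """
    comp = pd.Series(compartment_of_cell)
    comp = comp.reindex(model.assignment.index)
    df = pd.DataFrame({"niche": model.assignment, "compartment": comp})
    tab = pd.crosstab(df["niche"], df["compartment"]).reindex(range(model.k)).fillna(0)
    fractions = tab.div(tab.sum(axis=1), axis=0)
    specific = [int(n) for n in fractions.index
                if fractions.loc[n].max() > threshold]
    per_sample = None
    if sample_of_cell is not None:
        samp = pd.Series(sample_of_cell).reindex(model.assignment.index)
        per_sample = pd.crosstab(model.assignment, samp).reindex(range(model.k)).fillna(0)
    return fractions, specific, per_sample


# ---------------------------------------------------------------------------
# Nested F-test: does the niche add predictive power beyond the cell type?
# ---------------------------------------------------------------------------

def _one_hot(labels: np.ndarray) -> tuple[np.ndarray, list]:
    levels = sorted(set(labels.tolist()))
    cols = [np.asarray(labels == lv, dtype=float) for lv in levels[1:]]
    return (np.stack(cols, axis=1) if cols else np.empty((len(labels), 0))), levels


def marker_niche_anova(table: pd.DataFrame, model: NicheModel, marker: str,
                       type_col: str = "type") -> AnovaResult:
    """Partial F-test of niche dependence of a marker's expression.

    Fits marker ~ type (reduced) and marker ~ type + niche (full), both with
    intercept and one-hot-coded categorical factors (empty levels dropped),
    and compares them with

        F = ((RSS_r - RSS_f) / (df_r - df_f)) / (RSS_f / df_f)

    against an F(df_r - df_f, df_f) reference.  ``delta_r2`` is the share of
    total variance the niche factor explains beyond the cell type.
    """
    sub = table.set_index("cell_id")
    common = sub.index.intersection(model.assignment.index)
    sub = sub.loc[common]
    y = sub[marker].to_numpy(dtype=float)
    types = sub[type_col].to_numpy()
    niches = model.assignment.loc[common].to_numpy()
    n = len(y)
    t_levels = len(set(types.tolist()))
    n_levels = len(set(niches.tolist()))
    if t_levels < 1 or n_levels < 2:
        raise ValueError("need >= 2 occupied niches (and >= 1 cell type)")

    x_type, _ = _one_hot(types)
    x_niche, _ = _one_hot(niches)
    intercept = np.ones((n, 1))
    X_r = np.hstack([intercept, x_type])
    X_f = np.hstack([intercept, x_type, x_niche])
    rank_r = np.linalg.matrix_rank(X_r)
    rank_f = np.linalg.matrix_rank(X_f)
    if rank_f < X_f.shape[1]:
        raise ValueError(
            "full design is rank deficient: some niche levels are collinear "
            "with the cell-type levels (e.g. a niche occupied by a single type)")
    if n <= rank_f:
        raise ValueError("more parameters than cells")

    rss_r = _rss(X_r, y)
    rss_f = _rss(X_f, y)
    df_num = rank_f - rank_r
    df_den = n - rank_f
    if df_num == 0:
        raise ValueError("niche factor adds no degrees of freedom")
    F = ((rss_r - rss_f) / df_num) / (rss_f / df_den)
    p = float(stats.f.sf(F, df_num, df_den))
    tss = float(np.sum((y - y.mean()) ** 2))
    delta_r2 = float((rss_r - rss_f) / tss) if tss > 0 else 0.0
    return AnovaResult(F=float(F), p=p, delta_r2=delta_r2,
                       df_num=df_num, df_den=df_den)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


# ---------------------------------------------------------------------------
# Cell-type labels (pluggable)
# ---------------------------------------------------------------------------

def assign_cell_types(table: pd.DataFrame, method: str = "external_labels",
                      labels=None, k: int | None = None, seed: int = 0,
                      markers: list[str] | None = None) -> pd.Series:
    """Cell-type labels, either passed through or from a baseline K-means.

    Phenotype clustering proper (e.g. density-based methods) is a pluggable
    upstream step; ``external_labels`` validates and passes labels through.
    ``baseline_kmeans`` clusters the standardized marker space and names
    clusters after their highest-mean marker — plumbing good enough for
    phantoms, not a phenotyping method.
    """
    if method == "external_labels":
        if labels is None:
            raise ValueError("external_labels requires labels")
        ser = pd.Series(labels)
        if len(ser) != len(table):
            raise ValueError("label count does not match table")
        if ser.isna().any():
            raise ValueError("labels contain missing values")
        return pd.Series(ser.to_numpy(), index=table.index, name="type")
    if method != "baseline_kmeans":
        raise ValueError(f"unknown method {method!r}")
    if k is None or k < 1:
        raise ValueError("baseline_kmeans requires k >= 1")
    if markers is None:
        markers = marker_columns(table)
    X = table[markers].to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    cl = km.fit_predict((X - mu) / sd)
    names = []
    seen: dict[str, int] = {}
    for center in km.cluster_centers_:
        m = markers[int(np.argmax(center))]
        seen[m] = seen.get(m, 0) + 1
        names.append(f"{m}+" if seen[m] == 1 else f"{m}+{seen[m]}")
    return pd.Series([names[c] for c in cl], index=table.index, name="type")
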