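"""Delaunay neighborhood graphs and pairwise cell-type interaction statistics.

Cell-to-cell contacts are read off a 2-D Delaunay triangulation of the cell
centers, pruned of implausibly long edges.  For every unordered pair of cell
types (A, B) the specificity of contact is the log odds ratio

    log_odds(A, B) = ln( observed(A, B) / expected(A, B) )

where the observed co-occurrence frequency is the mean of a Beta
distribution with alpha = N_AB (edges joining A and B) and beta = E - N_AB
(all other edges), i.e. simply N_AB / E, and the expected frequency is the
product of the types' incident-edge frequencies (under the default
half-edge convention: 2 * f_A * f_B heterotypic, f_A^2 homotypic, which is
null-centred).  Positive values mean attraction, negative avoidance.
Significance
uses the lower tail of Binomial(E, expected): after Benjamini-Hochberg
correction, q < 0.05 flags avoidance and q > 0.95 flags attraction.

Cross-condition comparisons use two-sample t-tests on per-sample normalized
interaction counts, and a chi deviation statistic (root sum of squared
z-scores against a reference condition's mean/SD) summarises whole-matrix
deviation when sample-specific variation precludes a common mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import Delaunay, QhullError

__all__ = [
    "NeighborhoodGraph",
    "InteractionResult",
    "delaunay_graph",
    "interaction_counts",
    "odds_ratio_matrix",
    "binomial_pvalues",
    "bh_fdr",
    "interaction_analysis",
    "compare_conditions",
    "chi_deviation",
    "interaction_change_summary",
    "ChiDeviation",
]

#: count threshold up to which binomial p-values use the exact distribution
EXACT_BINOMIAL_MAX_TRIALS = 10_000

SIGNIFICANCE_Q = 0.05  # q < 0.05 avoidance, q > 1 - 0.05 attraction


@dataclass
class NeighborhoodGraph:
    """Undirected graph over cells from a pruned Delaunay triangulation.

    ``edges`` holds 0-based positional indices into ``ids``/``xy``.
    """

    ids: np.ndarray            # (n,) cell ids
    xy: np.ndarray             # (n, 2) centroids
    edges: np.ndarray          # (m, 2) positional indices, u < v
    max_edge_length: float

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if len(self.edges):
            if (self.edges[:, 0] == self.edges[:, 1]).any():
                raise ValueError("self-edges are not allowed")
            e = np.sort(self.edges, axis=1)
            if len(np.unique(e[:, 0] * len(self.ids) + e[:, 1])) != len(e):
                raise ValueError("duplicate edges are not allowed")
            self.edges = e

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        if len(self.edges):
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def adjacency_lists(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for u, v in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        return adj


def delaunay_graph(points: np.ndarray, ids: np.ndarray | None = None,
                   max_edge_length: float | str = "auto") -> NeighborhoodGraph:
    """2-D Delaunay triangulation pruned of edges longer than a cutoff.

    ``max_edge_length='auto'`` uses three times the median Delaunay edge
    length, which removes the spurious long edges spanning the convex hull
    of a tissue section while keeping genuine first-tier contacts.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if len(points) < 3:
        raise ValueError("Delaunay triangulation needs at least 3 points")
    if ids is None:
        ids = np.arange(len(points))
    try:
        tri = Delaunay(points)
    except QhullError as exc:
        raise ValueError(f"degenerate point set (collinear?): {exc}") from exc
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            u, v = simplex[a], simplex[(a + 1) % 3]
            edges.add((min(u, v), max(u, v)))
    edges = np.array(sorted(edges), dtype=int)
    lengths = np.linalg.norm(points[edges[:, 0]] - points[edges[:, 1]], axis=1)
    if max_edge_length == "auto":
        max_edge_length = 3.0 * float(np.median(lengths))
    keep = lengths <= max_edge_length
    return NeighborhoodGraph(ids=np.asarray(ids), xy=points,
                             edges=edges[keep], max_edge_length=float(max_edge_length))


# ---------------------------------------------------------------------------
# Counts and odds ratios
# ---------------------------------------------------------------------------

def _as_type_array(graph: NeighborhoodGraph, types) -> tuple[np.ndarray, list[str]]:
    if isinstance(types, dict):
        arr = np.array([types.get(i) for i in graph.ids], dtype=object)
    else:
        arr = np.asarray(types, dtype=object)
        if len(arr) != graph.n_nodes:
            raise ValueError("one type label per node is required")
    if any(t is None or (isinstance(t, float) and np.isnan(t)) for t in arr):
        raise ValueError("every node must carry a type label")
    names = sorted(set(arr.tolist()))
    return arr, names


def interaction_counts(graph: NeighborhoodGraph, types) -> pd.DataFrame:
    """Symmetric type-by-type edge count matrix.

    Heterotypic edges appear at both (A, B) and (B, A); homotypic edges are
    counted once, on the diagonal, so the sum over unordered pairs (upper
    triangle including the diagonal) equals the total edge count.
    """
    arr, names = _as_type_array(graph, types)
    tindex = {t: i for i, t in enumerate(names)}
    codes = np.array([tindex[t] for t in arr])
    T = len(names)
    counts = np.zeros((T, T))
    if graph.n_edges:
        a = codes[graph.edges[:, 0]]
        b = codes[graph.edges[:, 1]]
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        flat = np.bincount(lo * T + hi, minlength=T * T).reshape(T, T)
        counts = flat + np.triu(flat, 1).T
    return pd.DataFrame(counts, index=names, columns=names, dtype=float)


DEFAULT_INCIDENT_MODE = "halfedge"


def incident_edge_frequencies(counts: pd.DataFrame,
                              mode: str = DEFAULT_INCIDENT_MODE) -> pd.Series:
    """Frequency of edges incident to each type.

    ``mode='halfedge'`` (default): f_A = (half-edges at type-A nodes) /
    (2E), the degree-mass frequency.  Combined with the factor-2 heterotypic
    expectation in :func:`odds_ratio_matrix` this is the random-endpoint
    null model, under which the log odds ratio is centred at 0 for randomly
    permuted labels.  ``mode='edge'``: f_A = (# edges with >= 1 endpoint of
    type A) / E, the most literal reading of "edges incident to a type";
    note the resulting expectations exceed 1 in total, biasing every pair
    toward apparent avoidance.
    """
    E = total_edges(counts)
    if E == 0:
        raise ValueError("zero total edges")
    if mode == "edge":
        inc = counts.sum(axis=1)  # off-diagonals (doubled storage) + diagonal once
        return inc / E
    if mode == "halfedge":
        inc = counts.sum(axis=1) + np.diag(counts.to_numpy())
        return inc / (2 * E)
    raise ValueError(f"unknown incident mode {mode!r}")


def total_edges(counts: pd.DataFrame) -> float:
    m = counts.to_numpy()
    return float(np.triu(m).sum())


def odds_ratio_matrix(counts: pd.DataFrame, pseudocount: float = 0.0,
                      incident_mode: str = DEFAULT_INCIDENT_MODE,
                      type_counts: pd.Series | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Log odds ratios with their observed and expected frequencies.

    observed(A, B) is the beta-distribution mean N_AB / E.  Under the
    default half-edge convention the expected frequency is the
    random-endpoint probability 2 * f_A * f_B for A != B and f_A^2 on the
    diagonal, which sums to 1 over unordered pairs and centres the log odds
    at 0 for randomly arranged labels.  When ``type_counts`` (cells per
    type) is given, the expectation additionally carries the finite-size
    correction for sampling endpoints without replacement —
    n/(n-1) heterotypic and (n_A-1)/n_A * n/(n-1) homotypic — which removes
    the residual O(1/n_A) homotypic bias on small populations.  Under
    ``incident_mode='edge'`` the expectation is the literal f_A * f_B of
    the incident-edge frequencies.  With no pseudocount (the default),
    pairs with N_AB = 0 receive a -inf sentinel rather than an imputed
    value.
    """
    E = total_edges(counts)
    if E == 0:
        raise ValueError("zero total edges")
    f = incident_edge_frequencies(counts, mode=incident_mode)
    observed = (counts + pseudocount) / (E + pseudocount)
    exp = np.outer(f, f)
    if incident_mode == "halfedge":
        exp = exp * (2.0 - np.eye(len(f)))
        if type_counts is not None:
            n_t = type_counts.reindex(counts.index).to_numpy(dtype=float)
            n = n_t.sum()
            with np.errstate(divide="ignore", invalid="ignore"):
                diag_corr = np.where(n_t > 0, (n_t - 1) / n_t, 0.0)
            exp = exp * (n / (n - 1))
            exp[np.diag_indices_from(exp)] *= diag_corr
    expected = pd.DataFrame(exp, index=counts.index, columns=counts.columns)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = observed.to_numpy() / expected.to_numpy()
        log_odds = np.full_like(ratio, -np.inf)
        pos = ratio > 0
        log_odds[pos] = np.log(ratio[pos])
    log_odds = pd.DataFrame(log_odds, index=counts.index, columns=counts.columns)
    return log_odds, observed, expected


def binomial_pvalues(counts: pd.DataFrame, expected: pd.DataFrame | None = None,
                     incident_mode: str = DEFAULT_INCIDENT_MODE) -> pd.DataFrame:
    """One-sided lower-tail binomial p-values per type pair.

    p = P(X <= N_AB) with X ~ Binomial(E, expected_AB): small p means fewer
    contacts than chance (avoidance), p near 1 means more (attraction).
    Exact up to ``EXACT_BINOMIAL_MAX_TRIALS`` trials; above that, a normal
    approximation with continuity correction.
    """
    if expected is None:
        _, _, expected = odds_ratio_matrix(counts, incident_mode=incident_mode)
    E = int(round(total_edges(counts)))
    n_ab = counts.to_numpy()
    p_ab = np.clip(expected.to_numpy(), 0.0, 1.0)
    if E <= EXACT_BINOMIAL_MAX_TRIALS:
        p = stats.binom.cdf(n_ab, E, p_ab)
    else:
        mu = E * p_ab
        sd = np.sqrt(E * p_ab * (1 - p_ab))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (n_ab + 0.5 - mu) / sd
        p = np.where(sd > 0, stats.norm.cdf(z), (n_ab >= mu).astype(float))
    return pd.DataFrame(p, index=counts.index, columns=counts.columns)


def bh_fdr(pvalues, m: int | None = None):
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1; a monotone transform
    of the p-values.  Accepts an array-like of any shape.
    """
    p = np.asarray(pvalues, dtype=float)
    flat = p.ravel()
    if m is None:
        m = flat.size
    order = np.argsort(flat, kind="stable")
    ranked = flat[order]
    q = ranked * m / np.arange(1, flat.size + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty_like(flat)
    out[order] = q
    out = out.reshape(p.shape)
    if isinstance(pvalues, pd.DataFrame):
        return pd.DataFrame(out, index=pvalues.index, columns=pvalues.columns)
    return out


@dataclass
class InteractionResult:
    """Pairwise interaction statistics of one sample or condition."""

    counts: pd.DataFrame
    observed: pd.DataFrame
    expected: pd.DataFrame
    log_odds: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    f_incident: pd.Series
    n_edges: float
    type_counts: pd.Series

    @property
    def types(self) -> list[str]:
        return list(self.counts.index)

    def attraction(self, q_threshold: float = SIGNIFICANCE_Q) -> pd.DataFrame:
        return self.q > 1 - q_threshold

    def avoidance(self, q_threshold: float = SIGNIFICANCE_Q) -> pd.DataFrame:
        return self.q < q_threshold

    def to_long(self) -> pd.DataFrame:
        rows = []
        names = self.types
        for i, a in enumerate(names):
            for b in names[i:]:
                rows.append((a, b, self.counts.loc[a, b], self.log_odds.loc[a, b],
                             self.p.loc[a, b], self.q.loc[a, b]))
        return pd.DataFrame(rows, columns=["type_a", "type_b", "count",
                                           "log_odds", "p", "q"])


def interaction_analysis(graph: NeighborhoodGraph, types,
                         pseudocount: float = 0.0,
                         incident_mode: str = DEFAULT_INCIDENT_MODE) -> InteractionResult:
    """Counts, odds ratios, binomial p and BH q in one pass.

    BH correction runs over the unordered type pairs (upper triangle
    including the diagonal); q-values are mirrored to keep the matrix
    symmetric.
    """
    arr, names = _as_type_array(graph, types)
    counts = interaction_counts(graph, types)
    tc = pd.Series(arr).value_counts().reindex(names).fillna(0)
    log_odds, observed, expected = odds_ratio_matrix(
        counts, pseudocount=pseudocount, incident_mode=incident_mode,
        type_counts=tc)
    p = binomial_pvalues(counts, expected)
    iu = np.triu_indices(len(names))
    q_flat = bh_fdr(p.to_numpy()[iu])
    q = np.zeros_like(p.to_numpy())
    q[iu] = q_flat
    q = q + np.triu(q, 1).T
    q = pd.DataFrame(q, index=p.index, columns=p.columns)
    f = incident_edge_frequencies(counts, mode=incident_mode)
    return InteractionResult(counts=counts, observed=observed, expected=expected,
                             log_odds=log_odds, p=p, q=q, f_incident=f,
                             n_edges=total_edges(counts), type_counts=tc)


# ---------------------------------------------------------------------------
# Cross-condition statistics
# ---------------------------------------------------------------------------

def compare_conditions(matrices_a: list[pd.DataFrame],
                       matrices_b: list[pd.DataFrame],
                       fdr_max: float = 0.05,
                       min_abs_delta_count: float = 150.0) -> pd.DataFrame:
    """Two-sample t-tests on normalized interaction counts per type pair.

    Each sample's count matrix is normalized by its total edge count; the
    test compares conditions A and B per unordered type pair, with BH-FDR
    across pairs.  ``delta_count`` is the difference of condition means of
    raw counts (B - A) and ``delta_log_odds`` the difference of mean
    per-sample log odds (pairs with no finite value in a condition report
    NaN).  Rows with q <= fdr_max and |delta_count| >= min_abs_delta_count
    are flagged ``top_scoring``.
    """
    if len(matrices_a) < 2 or len(matrices_b) < 2:
        raise ValueError("at least 2 samples per condition are required")
    names = list(matrices_a[0].index)
    for m in matrices_a + matrices_b:
        if list(m.index) != names:
            raise ValueError("all matrices must share the same type set")

    def norm_stack(ms):
        return np.stack([m.to_numpy() / total_edges(m) for m in ms])

    def lo_stack(ms):
        return np.stack([odds_ratio_matrix(m)[0].to_numpy() for m in ms])

    na, nb = norm_stack(matrices_a), norm_stack(matrices_b)
    ra, rb = np.stack([m.to_numpy() for m in matrices_a]), \
        np.stack([m.to_numpy() for m in matrices_b])
    la, lb = lo_stack(matrices_a), lo_stack(matrices_b)

    rows = []
    iu = list(zip(*np.triu_indices(len(names))))
    for i, j in iu:
        xa, xb = na[:, i, j], nb[:, i, j]
        if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0:
            if xa.mean() == xb.mean():
                t, p, flag = 0.0, 1.0, True
            else:
                t, p, flag = np.inf * np.sign(xb.mean() - xa.mean()), 0.0, True
        else:
            t, p = stats.ttest_ind(xb, xa, equal_var=True)
            flag = False
        fa, fb = la[:, i, j], lb[:, i, j]
        dlo = (np.mean(fb[np.isfinite(fb)]) if np.isfinite(fb).any() else np.nan) \
            - (np.mean(fa[np.isfinite(fa)]) if np.isfinite(fa).any() else np.nan)
        rows.append({
            "type_a": names[i], "type_b": names[j], "t": float(t), "p": float(p),
            "delta_count": float(rb[:, i, j].mean() - ra[:, i, j].mean()),
            "delta_log_odds": float(dlo),
            "degenerate": flag,
        })
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["top_scoring"] = (out["q"] <= fdr_max) & \
        (out["delta_count"].abs() >= min_abs_delta_count)
    return out


class ChiDeviation(NamedTuple):
    chi: float
    n_used: int
    n_excluded: int


def chi_deviation(matrix, reference_mean, reference_sd) -> ChiDeviation:
    """Root sum of squared z-scores of a matrix against a reference condition.

    chi = sqrt(sum(((x - mu) / sigma)^2)) over elements with sigma > 0;
    zero-SD or non-finite elements are excluded and counted.  Applicable
    identically to count matrices and log-odds matrices.
    """
    x = np.asarray(matrix, dtype=float)
    mu = np.asarray(reference_mean, dtype=float)
    sd = np.asarray(reference_sd, dtype=float)
    ok = (sd > 0) & np.isfinite(x) & np.isfinite(mu) & np.isfinite(sd)
    if not ok.any():
        raise ValueError("all matrix elements excluded (zero or invalid reference SD)")
    z = (x[ok] - mu[ok]) / sd[ok]
    return ChiDeviation(chi=float(np.sqrt(np.sum(z**2))),
                        n_used=int(ok.sum()), n_excluded=int((~ok).sum()))


def interaction_change_summary(result_a: InteractionResult,
                               result_b: InteractionResult) -> tuple[pd.DataFrame, dict]:
    """Per-pair deltas between two conditions plus the two co-distribution R^2.

    Reports, for every unordered type pair, the change in interaction counts
    and in log odds between conditions, and the change in the summed node
    frequencies of the two types.  The returned dict holds the OLS R^2 of
    delta-log-odds vs delta-count and of delta-frequency-sum vs delta-count;
    pairs with a -inf log odds in either condition are excluded from the
    first regression and counted.
    """
    names = result_a.types
    if names != result_b.types:
        raise ValueError("conditions must share the same type set")
    freq_a = result_a.type_counts / result_a.type_counts.sum()
    freq_b = result_b.type_counts / result_b.type_counts.sum()
    rows = []
    for i, a in enumerate(names):
        for b in names[i:]:
            rows.append({
                "type_a": a, "type_b": b,
                "delta_count": result_b.counts.loc[a, b] - result_a.counts.loc[a, b],
                "delta_log_odds": result_b.log_odds.loc[a, b] - result_a.log_odds.loc[a, b],
                "delta_freq_sum": (freq_b[a] + freq_b[b]) - (freq_a[a] + freq_a[b]),
            })
    table = pd.DataFrame(rows)

    def r2(x, y):
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if len(x) < 3 or x.std() == 0 or y.std() == 0:
            return float("nan"), int((~ok).sum())
        res = stats.linregress(x, y)
        return float(res.rvalue**2), int((~ok).sum())

    r2_odds, excl_odds = r2(table["delta_log_odds"].to_numpy(),
                            table["delta_count"].to_numpy())
    r2_freq, excl_freq = r2(table["delta_freq_sum"].to_numpy(),
                            table["delta_count"].to_numpy())
    summary = {"r2_odds_vs_count": r2_odds, "r2_freq_vs_count": r2_freq,
               "excluded_pairs_odds": excl_odds, "excluded_pairs_freq": excl_freq}
    return table, summary
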