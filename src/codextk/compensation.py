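"""Positional spillover compensation and cleanup gating.

In densely packed tissue, the membrane signals of adjacent cells overlap, so
a fraction of each cell's quantified intensity "spills" into its neighbours
(positional spillover — distinct from fluorophore spectral spillover).  The
spill is modelled as proportional to the fraction of shared boundary between
each pair of cell objects, yielding a sparse banded cell-by-cell spill
matrix S such that

    observed = S @ true        (per marker)

with the column-conserving convention

    S[i, j] = c * b_ij / B_j            for i != j
    S[j, j] = 1 - c * sum_i b_ij / B_j

where ``b_ij`` is the count of shared voxel faces between cells i and j,
``B_j`` the total boundary face count of cell j (including faces to
background), and ``c`` a global spill coefficient in (0, 0.5).  Columns sum
to 1, so total signal per marker is conserved, and S is strictly diagonally
dominant (hence invertible) whenever c < 0.5.  Compensation multiplies the
raw intensity vectors by the inverse spill matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu

from .stacks_io import marker_columns

__all__ = [
    "BoundaryGraph",
    "SpillMatrix",
    "GateConfig",
    "boundary_graph_from_mask",
    "contact_fractions",
    "build_spill_matrix",
    "compensate",
    "cleanup_gate",
]

DEFAULT_SPILL_C = 0.3


@dataclass
class BoundaryGraph:
    """Shared-boundary face counts between labelled cells.

    ``pairs`` holds unordered label pairs (i < j, 1-based labels) with their
    shared face counts; ``total_boundary[j-1]`` is B_j, the full boundary
    face count of cell j including faces to background.
    """

    n_cells: int
    pairs: np.ndarray          # (m, 2) int labels, i < j
    counts: np.ndarray         # (m,) shared face counts b_ij
    total_boundary: np.ndarray  # (n_cells,) B_j

    def neighbor_fraction(self, i: int, j: int) -> float:
        """b_ij / B_j — the fraction of cell j's boundary facing cell i."""
        a, b = min(i, j), max(i, j)
        hit = (self.pairs[:, 0] == a) & (self.pairs[:, 1] == b)
        if not hit.any():
            return 0.0
        return float(self.counts[hit][0] / self.total_boundary[j - 1])


@dataclass
class SpillMatrix:
    """Sparse cell-by-cell spill matrix with its boundary provenance."""

    matrix: sparse.csc_matrix
    c: float
    boundary: BoundaryGraph

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def to_triplets(self) -> pd.DataFrame:
        coo = self.matrix.tocoo()
        return pd.DataFrame({"i": coo.row + 1, "j": coo.col + 1, "value": coo.data})


def boundary_graph_from_mask(labels: np.ndarray) -> BoundaryGraph:
    """Count voxel face adjacencies (6-connectivity) between labelled cells.

    Faces at the volume border count toward a cell's background boundary.
    """
    labels = np.asarray(labels)
    n_cells = int(labels.max())
    padded = np.pad(labels, 1, mode="constant", constant_values=0)
    total = np.zeros(n_cells + 1, dtype=np.int64)
    pair_keys: list[np.ndarray] = []
    pair_cnts: list[np.ndarray] = []
    for ax in range(padded.ndim):
        a = np.moveaxis(padded, ax, 0)[:-1].ravel()
        b = np.moveaxis(padded, ax, 0)[1:].ravel()
        diff = a != b
        a, b = a[diff], b[diff]
        # every differing face contributes to the boundary of both sides
        total += np.bincount(a, minlength=n_cells + 1)
        total += np.bincount(b, minlength=n_cells + 1)
        both = (a > 0) & (b > 0)
        if both.any():
            lo = np.minimum(a[both], b[both]).astype(np.int64)
            hi = np.maximum(a[both], b[both]).astype(np.int64)
            keys, cnts = np.unique(lo * (n_cells + 1) + hi, return_counts=True)
            pair_keys.append(keys)
            pair_cnts.append(cnts)
    if pair_keys:
        keys = np.concatenate(pair_keys)
        cnts = np.concatenate(pair_cnts)
        keys, inv = np.unique(keys, return_inverse=True)
        counts = np.zeros(len(keys), dtype=np.int64)
        np.add.at(counts, inv, cnts)
        pairs = np.stack([keys // (n_cells + 1), keys % (n_cells + 1)], axis=1)
    else:
        pairs = np.empty((0, 2), dtype=np.int64)
        counts = np.empty(0, dtype=np.int64)
    return BoundaryGraph(n_cells=n_cells, pairs=pairs, counts=counts,
                         total_boundary=total[1:])


def build_spill_matrix(boundary: BoundaryGraph, c: float = DEFAULT_SPILL_C) -> SpillMatrix:
    """Assemble the column-stochastic spill matrix from boundary fractions."""
    if not 0 <= c < 0.5:
        raise ValueError(f"spill coefficient c must be in [0, 0.5); got {c}")
    n = boundary.n_cells
    B = boundary.total_boundary.astype(float)
    rows, cols, vals = [], [], []
    off_diag_colsum = np.zeros(n)
    if len(boundary.pairs):
        i = boundary.pairs[:, 0] - 1
        j = boundary.pairs[:, 1] - 1
        b = boundary.counts.astype(float)
        # spill from column j into row i and vice versa
        rows.extend([i, j])
        cols.extend([j, i])
        vals.extend([c * b / B[j], c * b / B[i]])
        np.add.at(off_diag_colsum, j, c * b / B[j])
        np.add.at(off_diag_colsum, i, c * b / B[i])
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(1.0 - off_diag_colsum)
    S = sparse.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows).astype(int),
                                np.concatenate(cols).astype(int))),
        shape=(n, n))
    return SpillMatrix(matrix=S, c=c, boundary=boundary)


def contact_fractions(mask, c: float = DEFAULT_SPILL_C) -> SpillMatrix:
    """Spill matrix of a segmentation mask from shared-boundary fractions."""
    labels = getattr(mask, "labels", mask)
    return build_spill_matrix(boundary_graph_from_mask(labels), c=c)


# ---------------------------------------------------------------------------
# Compensation
# ---------------------------------------------------------------------------

def compensate(table: pd.DataFrame, spill: SpillMatrix,
               markers: list[str] | None = None,
               clamp_negative: bool = True) -> pd.DataFrame:
    """Invert the spill model: compensated = S^-1 @ raw, per marker.

    Rows must be ordered by ``cell_id`` matching the mask labels 1..N used to
    build the spill matrix.  Negative compensated intensities (possible under
    noise) are clamped to 0 and flagged in ``compensation_clamped``;
    per-marker totals are preserved before clamping.
    """
    n = spill.n
    if len(table) != n:
        raise ValueError(f"table has {len(table)} rows but spill matrix is {n}x{n}")
    if "cell_id" in table.columns and not np.array_equal(
            table["cell_id"].to_numpy(), np.arange(1, n + 1)):
        raise ValueError("table rows must be sorted by cell_id 1..N to match the mask labels")
    if markers is None:
        markers = marker_columns(table, include_blank=True)
    raw = table[markers].to_numpy(dtype=float)
    try:
        lu = splu(spill.matrix.tocsc())
    except RuntimeError as exc:  # pragma: no cover - c < 0.5 guarantees invertibility
        raise ValueError(f"spill matrix is singular: {exc}") from exc
    comp = lu.solve(raw)
    out = table.copy()
    clamped = (comp < 0).any(axis=1)
    if clamp_negative:
        comp = np.maximum(comp, 0.0)
    out[markers] = comp
    out["compensation_clamped"] = clamped
    return out


# ---------------------------------------------------------------------------
# Cleanup gating
# ---------------------------------------------------------------------------

@dataclass
class GateConfig:
    """Thresholds for the three-step cleanup gating.

    Gate 1: nuclear stain density (nuclear signal / cell size) within
    ``density_range`` AND profile homogeneity, the relative variance of the
    per-cycle signal totals var/mean^2, at most ``homogeneity_max``.
    Gate 2: every blank-cycle channel at most ``blank_max``.
    Gate 3: cell size within ``size_range``.
    """

    density_range: tuple[float, float] = (0.0, np.inf)
    homogeneity_max: float = np.inf
    blank_max: float = np.inf
    size_range: tuple[float, float] = (0.0, np.inf)

    def __post_init__(self) -> None:
        if self.density_range[0] > self.density_range[1]:
            raise ValueError("density_range min exceeds max")
        if self.size_range[0] > self.size_range[1]:
            raise ValueError("size_range min exceeds max")

    @classmethod
    def from_reference_table(cls, table: pd.DataFrame,
                             percentiles: tuple[float, float] = (1.0, 99.0),
                             homogeneity_max: float = np.inf,
                             blank_max: float = np.inf) -> "GateConfig":
        """Derive density and size windows from a trusted reference table.

        The windows span the given percentiles of the reference population
        (e.g. ground-truth cells of a phantom, or a hand-curated sample).
        """
        density = table["nuclear"] / table["size"]
        lo, hi = percentiles
        return cls(
            density_range=(float(np.percentile(density, lo)),
                           float(np.percentile(density, hi))),
            homogeneity_max=homogeneity_max,
            blank_max=blank_max,
            size_range=(float(np.percentile(table["size"], lo)),
                        float(np.percentile(table["size"], hi))),
        )


def cleanup_gate(table: pd.DataFrame, gates: GateConfig
                 ) -> tuple[pd.DataFrame, dict]:
    """Apply the three sequential cleanup gates; returns (kept, report).

    The report counts the objects removed at each gate in order, so the
    per-gate counts sum to the total removed.
    """
    blank_cols = [c for c in table.columns if c.startswith("blank_")]
    if np.isfinite(gates.blank_max) and not blank_cols:
        raise ValueError("blank gate requested but table has no blank_ channels")
    cycle_cols = sorted(c for c in table.columns if c.startswith("cycle_total_"))

    n0 = len(table)
    density = table["nuclear"] / table["size"]
    keep1 = (density >= gates.density_range[0]) & (density <= gates.density_range[1])
    if cycle_cols and np.isfinite(gates.homogeneity_max):
        tot = table[cycle_cols].to_numpy(dtype=float)
        mean = tot.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel_var = np.where(mean > 0, tot.var(axis=1) / mean**2, np.inf)
        keep1 &= rel_var <= gates.homogeneity_max
    t1 = table[keep1]

    if blank_cols:
        keep2 = (t1[blank_cols] <= gates.blank_max).all(axis=1)
    else:
        keep2 = pd.Series(True, index=t1.index)
    t2 = t1[keep2]

    keep3 = (t2["size"] >= gates.size_range[0]) & (t2["size"] <= gates.size_range[1])
    t3 = t2[keep3]

    report = {
        "input": n0,
        "removed_gate1_density_homogeneity": int(n0 - len(t1)),
        "removed_gate2_blank": int(len(t1) - len(t2)),
        "removed_gate3_size": int(len(t2) - len(t3)),
        "kept": int(len(t3)),
    }
    return t3.reset_index(drop=True), report
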