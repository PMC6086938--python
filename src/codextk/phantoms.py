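"""Synthetic tissue phantoms with full ground truth.

Every downstream stage (segmentation, spillover compensation, interaction
statistics, i-niche clustering) is exercised against phantoms generated
here, so no external image data is needed.  A phantom emulates a thin
tissue section: densely packed spherical cells truncated to a z-slab, each
with a concentric nucleus, a membrane shell of fixed thickness, and a
cell-type-specific marker expression profile.  The generator also renders
the multicycle image stack (nuclear + membrane reference channels in every
cycle, marker channels spread over cycles, blank cycles with noise only),
and provides placement routines that plant pairwise type attractions or
niche archetypes for testing the spatial statistics.

Geometry: voxel arrays are (z, y, x); cell boundaries between overlapping
spheres follow the scaled-distance (multiplicative Voronoi) rule, i.e. a
voxel belongs to the cell minimising dist/radius, so touching cells share a
well-defined boundary ridge.  Nuclei of distinct cells never overlap;
membranes may touch.

The forward spillover model reuses the exact matrix construction of
:mod:`codextk.compensation`, so the forward and inverse models are
consistent by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .compensation import BoundaryGraph, boundary_graph_from_mask, build_spill_matrix
from .stacks_io import ChannelMeta, ImageStack

__all__ = [
    "CellType",
    "Compartment",
    "NoiseModel",
    "PhantomSpec",
    "GroundTruth",
    "make_cell_map",
    "render_image_stack",
    "apply_spill",
    "plant_interactions",
    "plant_niches",
    "standard_dense_spec",
    "easy_spec",
    "adjacency_spec",
    "DEFAULT_SEEDS",
]

#: fixed seeds of the standard phantom fixtures
DEFAULT_SEEDS = {"dense": 11, "easy": 23, "adjacency": 37}

#: rendered intensities of the structural channels (arbitrary units)
NUCLEAR_INTENSITY = 1000.0
MEMBRANE_INTENSITY = 500.0


@dataclass(frozen=True)
class CellType:
    """A named cell type with its marker expression profile (a.u. per marker)."""

    name: str
    profile: dict[str, float]


@dataclass(frozen=True)
class Compartment:
    """A named x-stripe of the section with its own cell-type frequencies.

    ``x_range`` is given as fractions of the x extent, so compartments form a
    partition of the plane when their ranges tile [0, 1].
    """

    name: str
    x_range: tuple[float, float]
    type_freqs: dict[str, float]


@dataclass(frozen=True)
class NoiseModel:
    gaussian_sd: float = 0.0
    poisson: bool = False


@dataclass
class PhantomSpec:
    """Full description of a synthetic tissue phantom.

    ``shape`` is the voxel volume as (z, y, x).  ``cell_radius_range`` and
    ``membrane_thickness`` are in voxels; ``nucleus_radius_fraction`` in
    (0, 1).  ``blank_cycles`` lists cycle indices whose marker channels are
    rendered with noise only.  ``spill_c`` is the global spill coefficient
    used by the forward spillover model.  ``min_center_spacing`` optionally
    enforces extra separation between cell centers (used by the easy,
    well-separated fixture); the baseline constraint is only that nuclei
    never overlap.
    """

    shape: tuple[int, int, int] = (9, 200, 200)
    n_cells: int = 200
    cell_radius_range: tuple[float, float] = (4.5, 6.5)
    nucleus_radius_fraction: float = 0.55
    membrane_thickness: float = 1.5
    cell_types: list[CellType] = field(default_factory=list)
    type_freqs: dict[str, float] | None = None
    compartments: list[Compartment] | None = None
    noise: NoiseModel = field(default_factory=lambda: NoiseModel(5.0, True))
    blur_sigma: float = 0.7
    blank_cycles: list[int] = field(default_factory=list)
    markers_per_cycle: int = 2
    spill_c: float = 0.3
    expression_cv: float = 0.1
    min_center_spacing: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cell_types:
            self.cell_types = _default_cell_types()
        if not 0 < self.nucleus_radius_fraction < 1:
            raise ValueError("nucleus_radius_fraction must be in (0, 1)")
        if not 0 <= self.spill_c < 0.5:
            raise ValueError("spill_c must be in [0, 0.5)")
        names = {t.name for t in self.cell_types}
        for freqs in self._all_freq_maps():
            if set(freqs) - names:
                raise ValueError(f"unknown cell types in frequencies: {set(freqs) - names}")
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ValueError("type frequencies must sum to 1")

    def _all_freq_maps(self) -> list[dict[str, float]]:
        if self.compartments:
            return [c.type_freqs for c in self.compartments]
        if self.type_freqs is not None:
            return [self.type_freqs]
        return [{t.name: 1.0 / len(self.cell_types) for t in self.cell_types}]

    @property
    def markers(self) -> list[str]:
        seen: list[str] = []
        for t in self.cell_types:
            for m in t.profile:
                if m not in seen:
                    seen.append(m)
        return seen

    def to_dict(self) -> dict:
        """Plain-data form of the spec (JSON-serialisable)."""
        return {
            "shape": list(self.shape), "n_cells": self.n_cells,
            "cell_radius_range": list(self.cell_radius_range),
            "nucleus_radius_fraction": self.nucleus_radius_fraction,
            "membrane_thickness": self.membrane_thickness,
            "cell_types": [{"name": t.name, "profile": dict(t.profile)}
                           for t in self.cell_types],
            "type_freqs": self.type_freqs,
            "compartments": None if self.compartments is None else [
                {"name": c.name, "x_range": list(c.x_range),
                 "type_freqs": dict(c.type_freqs)} for c in self.compartments],
            "noise": {"gaussian_sd": self.noise.gaussian_sd,
                      "poisson": self.noise.poisson},
            "blur_sigma": self.blur_sigma, "blank_cycles": list(self.blank_cycles),
            "markers_per_cycle": self.markers_per_cycle, "spill_c": self.spill_c,
            "expression_cv": self.expression_cv,
            "min_center_spacing": self.min_center_spacing, "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "cell_types" in d and d["cell_types"]:
            d["cell_types"] = [CellType(t["name"], t["profile"])
                               for t in d["cell_types"]]
        if d.get("compartments"):
            d["compartments"] = [Compartment(c["name"], tuple(c["x_range"]),
                                             c["type_freqs"])
                                 for c in d["compartments"]]
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseModel(**d["noise"])
        for key in ("shape", "cell_radius_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def compartment_at(self, x: float) -> Compartment | None:
        if not self.compartments:
            return None
        frac = x / self.shape[2]
        for comp in self.compartments:
            if comp.x_range[0] <= frac < comp.x_range[1]:
                return comp
        return self.compartments[-1]


def _default_cell_types() -> list[CellType]:
    return [
        CellType("A", {"M1": 200.0, "M2": 5.0, "M3": 5.0}),
        CellType("B", {"M1": 5.0, "M2": 200.0, "M3": 5.0}),
        CellType("C", {"M1": 5.0, "M2": 5.0, "M3": 200.0}),
    ]


@dataclass
class GroundTruth:
    """Everything the generator knows about a phantom."""

    mask: np.ndarray                  # labelled (z, y, x), 0 = background
    centers: np.ndarray               # (n, 3) float voxel coords (z, y, x)
    radii: np.ndarray                 # (n,) cell radii
    types: np.ndarray                 # (n,) type names (str)
    expression: pd.DataFrame          # (n, markers) true per-cell intensities
    graph: BoundaryGraph              # shared-boundary adjacency of the mask
    compartment_of_cell: np.ndarray   # (n,) compartment names ('' if none)
    spec: PhantomSpec

    @property
    def n_cells(self) -> int:
        return len(self.centers)

    def table(self) -> pd.DataFrame:
        """Ground-truth cell table (id, centroid, size, type, expression)."""
        sizes = np.bincount(self.mask.ravel(), minlength=self.n_cells + 1)[1:]
        df = pd.DataFrame({
            "cell_id": np.arange(1, self.n_cells + 1),
            "x": self.centers[:, 2], "y": self.centers[:, 1], "z": self.centers[:, 0],
            "size": sizes,
            "type": self.types,
        })
        return pd.concat([df, self.expression.reset_index(drop=True)], axis=1)


# ---------------------------------------------------------------------------
# Cell placement and mask rendering
# ---------------------------------------------------------------------------

def make_cell_map(spec: PhantomSpec, max_attempts_per_cell: int = 400) -> GroundTruth:
    """Place cells by rejection sampling and render the ground-truth mask.

    Centers are drawn uniformly over the section; each cell's type is drawn
    from the frequencies of the compartment its center falls in (or the
    global frequencies).  A candidate is rejected if its nucleus would
    overlap an existing nucleus, or (when ``min_center_spacing`` is set) if
    it sits closer than that spacing to an existing center.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    r_lo, r_hi = spec.cell_radius_range
    centers: list[np.ndarray] = []
    radii: list[float] = []
    if spec.n_cells > 0:
        acc_centers = np.empty((spec.n_cells, 3))
        acc_nucr = np.empty(spec.n_cells)
        placed = 0
        attempts_left = max_attempts_per_cell * spec.n_cells
        while placed < spec.n_cells:
            if attempts_left <= 0:
                density = placed / (ny * nx)
                raise RuntimeError(
                    f"could not place {spec.n_cells} cells without nuclear overlap: "
                    f"placed {placed} (areal density {density:.4f} cells/voxel^2); "
                    "reduce n_cells or cell_radius_range")
            attempts_left -= 1
            r = rng.uniform(r_lo, r_hi)
            margin = max(1.0, 0.5 * r)
            c = np.array([
                nz / 2 + rng.uniform(-1.0, 1.0),
                rng.uniform(margin, ny - margin),
                rng.uniform(margin, nx - margin)])
            nr = spec.nucleus_radius_fraction * r
            if placed:
                d = np.linalg.norm(acc_centers[:placed] - c, axis=1)
                if np.any(d < acc_nucr[:placed] + nr):
                    continue
                if spec.min_center_spacing and np.any(d < spec.min_center_spacing):
                    continue
            acc_centers[placed] = c
            acc_nucr[placed] = nr
            radii.append(r)
            placed += 1
        centers = acc_centers
        radii = np.array(radii)
    else:
        centers = np.empty((0, 3))
        radii = np.empty(0)

    mask = _render_mask(spec.shape, centers, radii)

    type_names = np.empty(len(centers), dtype=object)
    comp_names = np.empty(len(centers), dtype=object)
    all_types = [t.name for t in spec.cell_types]
    global_freqs = spec._all_freq_maps()[0] if not spec.compartments else None
    for i, c in enumerate(centers):
        comp = spec.compartment_at(c[2])
        freqs = comp.type_freqs if comp else global_freqs
        probs = np.array([freqs.get(t, 0.0) for t in all_types])
        type_names[i] = all_types[rng.choice(len(all_types), p=probs / probs.sum())]
        comp_names[i] = comp.name if comp else ""

    markers = spec.markers
    profiles = {t.name: t.profile for t in spec.cell_types}
    expr = np.zeros((len(centers), len(markers)))
    for i, tname in enumerate(type_names):
        base = np.array([profiles[tname].get(m, 0.0) for m in markers])
        if spec.expression_cv > 0:
            sigma = math.sqrt(math.log(1 + spec.expression_cv**2))
            base = base * rng.lognormal(-sigma**2 / 2, sigma, size=len(markers))
        expr[i] = base
    expression = pd.DataFrame(expr, columns=markers)

    graph = boundary_graph_from_mask(mask)
    return GroundTruth(mask=mask, centers=np.asarray(centers), radii=np.asarray(radii),
                       types=type_names.astype(str) if len(centers) else np.empty(0, dtype=str),
                       expression=expression, graph=graph,
                       compartment_of_cell=comp_names.astype(str) if len(centers) else np.empty(0, dtype=str),
                       spec=spec)


def _render_mask(shape: tuple[int, int, int], centers: np.ndarray,
                 radii: np.ndarray) -> np.ndarray:
    """Scaled-distance Voronoi rendering of truncated spheres."""
    mask = np.zeros(shape, dtype=np.int32)
    best = np.full(shape, np.inf, dtype=np.float32)
    nz, ny, nx = shape
    for idx, (c, r) in enumerate(zip(centers, radii), start=1):
        zlo, zhi = max(0, int(c[0] - r)), min(nz, int(math.ceil(c[0] + r)) + 1)
        ylo, yhi = max(0, int(c[1] - r)), min(ny, int(math.ceil(c[1] + r)) + 1)
        xlo, xhi = max(0, int(c[2] - r)), min(nx, int(math.ceil(c[2] + r)) + 1)
        zz, yy, xx = np.meshgrid(np.arange(zlo, zhi), np.arange(ylo, yhi),
                                 np.arange(xlo, xhi), indexing="ij")
        score = np.sqrt((zz - c[0])**2 + (yy - c[1])**2 + (xx - c[2])**2) / r
        sub = (slice(zlo, zhi), slice(ylo, yhi), slice(xlo, xhi))
        claim = (score <= 1.0) & (score < best[sub])
        mask[sub][claim] = idx
        best[sub][claim] = score[claim]
    return mask


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------

def _membrane_shell(mask: np.ndarray, thickness: float) -> np.ndarray:
    """Boolean shell: cell voxels within ``thickness`` of a label boundary."""
    if mask.max() == 0:
        return np.zeros_like(mask, dtype=bool)
    boundary = np.zeros(mask.shape, dtype=bool)
    for ax in range(mask.ndim):
        m = np.moveaxis(mask, ax, 0)
        b = np.moveaxis(boundary, ax, 0)
        diff = m[:-1] != m[1:]
        b[:-1] |= diff
        b[1:] |= diff
    # outer slab faces are also cell boundary
    boundary[[0, -1], :, :] |= mask[[0, -1], :, :] > 0
    boundary &= mask > 0
    dist = ndi.distance_transform_edt(~boundary)
    return (mask > 0) & (dist < thickness)


def render_image_stack(truth: GroundTruth, spec: PhantomSpec | None = None) -> ImageStack:
    """Render the multicycle image stack of a phantom.

    Channel layout per cycle: channel 0 nuclear stain, channel 1 membrane
    reference, then ``markers_per_cycle`` marker channels.  Marker channels
    carry the membrane shell of each cell at that cell's true expression
    value; blank cycles carry noise only in their marker slots.  An optional
    Gaussian blur emulates optical spread; noise (Poisson then additive
    Gaussian) is applied last, independently per cycle.
    """
    if spec is None:
        spec = truth.spec
    if truth.mask.shape != tuple(spec.shape):
        raise ValueError(f"truth mask shape {truth.mask.shape} does not match "
                         f"spec shape {tuple(spec.shape)}")
    rng = np.random.default_rng(spec.seed + 1_000_003)
    markers = spec.markers
    mpc = spec.markers_per_cycle
    n_marker_cycles = max(1, math.ceil(len(markers) / mpc))
    blank = sorted(set(spec.blank_cycles))
    n_cycles = n_marker_cycles + len(blank)

    nucleus_mask = _nucleus_mask(truth, spec)
    shell = _membrane_shell(truth.mask, spec.membrane_thickness)
    nuclear_img = np.where(nucleus_mask, NUCLEAR_INTENSITY, 0.0)
    membrane_img = np.where(shell, MEMBRANE_INTENSITY, 0.0)

    # per-cell expression painted onto the shell
    expr_lookup = np.zeros((truth.n_cells + 1, len(markers)))
    if truth.n_cells:
        expr_lookup[1:] = truth.expression[markers].to_numpy()
    shell_labels = np.where(shell, truth.mask, 0)

    n_channels = 2 + mpc
    voxels = np.zeros((n_cycles, n_channels) + tuple(spec.shape), dtype=np.float32)
    channel_meta: list[list[ChannelMeta]] = []
    marker_queue = list(markers)
    for ci in range(n_cycles):
        metas = [ChannelMeta("DRAQ5", nuclear=True), ChannelMeta("CD45", membrane=True)]
        planes = [nuclear_img, membrane_img]
        is_blank_cycle = ci in blank
        for slot in range(mpc):
            if not is_blank_cycle and marker_queue:
                m = marker_queue.pop(0)
                metas.append(ChannelMeta(m))
                planes.append(expr_lookup[shell_labels, markers.index(m)])
            else:
                metas.append(ChannelMeta(f"blank_{ci}_{slot}", blank=True))
                planes.append(np.zeros(spec.shape))
        for hi, img in enumerate(planes):
            img = np.asarray(img, dtype=float)
            if spec.blur_sigma > 0:
                img = ndi.gaussian_filter(img, spec.blur_sigma)
            if spec.noise.poisson:
                img = rng.poisson(np.maximum(img, 0.0)).astype(float)
            if spec.noise.gaussian_sd > 0:
                img = img + rng.normal(0.0, spec.noise.gaussian_sd, size=img.shape)
            voxels[ci, hi] = np.maximum(img, 0.0)
        channel_meta.append(metas)
    return ImageStack(voxels=voxels, channel_meta=channel_meta)


def _nucleus_mask(truth: GroundTruth, spec: PhantomSpec) -> np.ndarray:
    out = np.zeros(truth.mask.shape, dtype=bool)
    nz, ny, nx = truth.mask.shape
    for c, r in zip(truth.centers, truth.radii):
        nr = spec.nucleus_radius_fraction * r
        zlo, zhi = max(0, int(c[0] - nr)), min(nz, int(math.ceil(c[0] + nr)) + 1)
        ylo, yhi = max(0, int(c[1] - nr)), min(ny, int(math.ceil(c[1] + nr)) + 1)
        xlo, xhi = max(0, int(c[2] - nr)), min(nx, int(math.ceil(c[2] + nr)) + 1)
        zz, yy, xx = np.meshgrid(np.arange(zlo, zhi), np.arange(ylo, yhi),
                                 np.arange(xlo, xhi), indexing="ij")
        d = np.sqrt((zz - c[0])**2 + (yy - c[1])**2 + (xx - c[2])**2)
        out[zlo:zhi, ylo:yhi, xlo:xhi] |= d <= nr
    return out


# ---------------------------------------------------------------------------
# Forward spillover model
# ---------------------------------------------------------------------------

def apply_spill(true_table: pd.DataFrame, true_graph: BoundaryGraph,
                c: float, markers: list[str] | None = None) -> pd.DataFrame:
    """Mix true per-cell intensities through the spill matrix: observed = S @ true.

    Uses the identical matrix construction as the compensation module, so
    per-marker totals are conserved exactly (column sums of S are 1).
    """
    if not 0 <= c < 0.5:
        raise ValueError(f"spill coefficient c must be in [0, 0.5); got {c}")
    spill = build_spill_matrix(true_graph, c=c)
    if len(true_table) != spill.n:
        raise ValueError("table does not match boundary graph size")
    if markers is None:
        from .stacks_io import marker_columns
        markers = marker_columns(true_table)
    out = true_table.copy()
    out[markers] = spill.matrix @ true_table[markers].to_numpy(dtype=float)
    return out


# ---------------------------------------------------------------------------
# Planted spatial structure
# ---------------------------------------------------------------------------

def _jittered_grid(n: int, rng: np.random.Generator, spacing: float = 1.0,
                   jitter: float = 0.25) -> np.ndarray:
    side = math.ceil(math.sqrt(n))
    ys, xs = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    pts = np.stack([xs.ravel(), ys.ravel()], axis=1)[:n] * spacing
    return pts + rng.uniform(-jitter, jitter, size=pts.shape) * spacing


def plant_interactions(n_cells: int, type_freqs: dict[str, float],
                       attraction: dict[tuple[str, str], float] | None = None,
                       seed: int = 0, max_iter: int | None = None,
                       tol: float = 0.05):
    """Position cells on a jittered grid and swap type labels until the
    measured interaction log-odds match the requested targets.

    ``attraction`` maps unordered type pairs to target log-odds (natural
    log) of their Delaunay edge co-occurrence.  Labels of random cell pairs
    are swapped greedily (Gibbs-like), accepting swaps that reduce the sum
    of squared deviations from the targets; with no targets the labels stay
    a random assignment.  Returns ``(table, graph)`` where the table has
    columns cell_id, x, y, type.

    If a target is unreachable within ``max_iter`` swaps a warning reports
    the achieved values.
    """
    from .interactions import delaunay_graph

    if attraction:
        for pair, target in attraction.items():
            if not np.isfinite(target):
                raise ValueError(f"target log-odds for {pair} must be finite")
    rng = np.random.default_rng(seed)
    pts = _jittered_grid(n_cells, rng)
    graph = delaunay_graph(pts, max_edge_length="auto")

    names = sorted(type_freqs)
    probs = np.array([type_freqs[t] for t in names], dtype=float)
    if abs(probs.sum() - 1) > 1e-9 or (probs < 0).any():
        raise ValueError("type_freqs must be nonnegative and sum to 1")
    T = len(names)
    tindex = {t: i for i, t in enumerate(names)}
    labels = rng.choice(T, size=n_cells, p=probs)

    edges = graph.edges
    adj: list[list[int]] = [[] for _ in range(n_cells)]
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)

    counts = np.zeros((T, T))
    for u, v in edges:
        a, b = labels[u], labels[v]
        counts[a, b] += 1
        if a != b:
            counts[b, a] += 1
    E = len(edges)

    targets = []
    if attraction:
        for (a, b), val in attraction.items():
            targets.append((tindex[a], tindex[b], float(val)))

    def pair_log_odds(cnt: np.ndarray, a: int, b: int) -> float:
        # same finite-size-corrected random-endpoint convention as
        # interactions.odds_ratio_matrix with type_counts
        half = cnt.sum(axis=1) + np.diag(cnt)  # degree mass per type
        f_a, f_b = half[a] / (2 * E), half[b] / (2 * E)
        n_t = np.bincount(labels, minlength=T).astype(float)
        if a != b:
            exp = 2.0 * f_a * f_b * n_cells / (n_cells - 1)
        else:
            exp = f_a * f_b * (max(n_t[a] - 1, 0) / max(n_t[a], 1)) \
                * n_cells / (n_cells - 1)
        n_ab = cnt[a, b]
        if n_ab == 0 or exp == 0:
            return -np.inf
        return math.log((n_ab / E) / exp)

    def objective(cnt: np.ndarray) -> float:
        if not targets:
            return 0.0
        obj = 0.0
        for a, b, tgt in targets:
            lo = pair_log_odds(cnt, a, b)
            if not np.isfinite(lo):
                lo = -10.0
            obj += (lo - tgt) ** 2
        return obj

    def apply_label(cnt: np.ndarray, node: int, old: int, new: int, sign_done=None):
        for w in adj[node]:
            b = labels[w]
            cnt[old, b] -= 1
            if old != b:
                cnt[b, old] -= 1
            cnt[new, b] += 1
            if new != b:
                cnt[b, new] += 1

    if targets and E > 0:
        if max_iter is None:
            max_iter = 40 * n_cells
        obj = objective(counts)
        for _ in range(max_iter):
            if obj <= tol**2 * len(targets):
                break
            u, v = rng.integers(0, n_cells, size=2)
            if labels[u] == labels[v]:
                continue
            lu, lv = labels[u], labels[v]
            trial = counts.copy()
            apply_label(trial, u, lu, lv)
            labels[u] = lv
            apply_label(trial, v, lv, lu)
            labels[u] = lu
            new_obj = objective(trial)
            if new_obj < obj:
                labels[u], labels[v] = lv, lu
                counts = trial
                obj = new_obj
        else:
            achieved = {(names[a], names[b]): pair_log_odds(counts, a, b)
                        for a, b, _ in targets}
            warnings.warn(f"plant_interactions did not reach targets; achieved {achieved}")

    table = pd.DataFrame({
        "cell_id": np.arange(1, n_cells + 1),
        "x": pts[:, 0], "y": pts[:, 1],
        "type": [names[i] for i in labels],
    })
    return table, graph


def plant_niches(K: int, archetypes: np.ndarray, n_index_cells: int,
                 seed: int = 0, ring_size: int = 8,
                 type_names: list[str] | None = None):
    """Build a star-graph phantom whose first-tier rings follow K archetypes.

    Each index cell is assigned one of the K archetype composition vectors
    (uniformly at random) and its ring of ``ring_size`` neighbours is drawn
    multinomially from that archetype.  Returns ``(table, graph,
    true_labels, index_ids)``; ``true_labels`` gives the planted archetype
    per index cell.
    """
    from .interactions import NeighborhoodGraph

    archetypes = np.asarray(archetypes, dtype=float)
    if archetypes.shape[0] != K:
        raise ValueError(f"expected {K} archetype vectors, got {archetypes.shape[0]}")
    if (archetypes < 0).any() or np.any(np.abs(archetypes.sum(axis=1) - 1) > 1e-9):
        raise ValueError("archetype vectors must be nonnegative and sum to 1")
    if K > n_index_cells:
        raise ValueError(f"K={K} exceeds n_index_cells={n_index_cells}")
    T = archetypes.shape[1]
    if type_names is None:
        type_names = [f"T{i}" for i in range(T)]

    rng = np.random.default_rng(seed)
    centers = _jittered_grid(n_index_cells, rng, spacing=10.0, jitter=0.1)
    true_labels = rng.integers(0, K, size=n_index_cells)

    ids, xs, ys, types = [], [], [], []
    edges = []
    next_id = 0
    index_ids = []
    for i in range(n_index_cells):
        idx_id = next_id
        next_id += 1
        index_ids.append(idx_id)
        ids.append(idx_id)
        xs.append(centers[i, 0])
        ys.append(centers[i, 1])
        types.append(type_names[rng.integers(0, T)])
        ring_types = rng.choice(T, size=ring_size, p=archetypes[true_labels[i]])
        for k, rt in enumerate(ring_types):
            ang = 2 * math.pi * k / ring_size
            ids.append(next_id)
            xs.append(centers[i, 0] + 2.5 * math.cos(ang))
            ys.append(centers[i, 1] + 2.5 * math.sin(ang))
            types.append(type_names[rt])
            edges.append((idx_id, next_id))
            next_id += 1

    table = pd.DataFrame({"cell_id": np.array(ids) + 1,
                          "x": xs, "y": ys, "type": types})
    xy = np.stack([table["x"].to_numpy(), table["y"].to_numpy()], axis=1)
    graph = NeighborhoodGraph(ids=table["cell_id"].to_numpy(),
                              xy=xy, edges=np.array(edges, dtype=int),
                              max_edge_length=3.0)
    return table, graph, true_labels, np.array(index_ids) + 1


# ---------------------------------------------------------------------------
# Standard fixtures
# ---------------------------------------------------------------------------

def standard_dense_spec(seed: int | None = None) -> PhantomSpec:
    """Densely packed 200-cell phantom used for segmentation benchmarks."""
    return PhantomSpec(
        shape=(9, 200, 200), n_cells=200,
        cell_radius_range=(4.5, 6.5), nucleus_radius_fraction=0.55,
        membrane_thickness=1.5,
        noise=NoiseModel(gaussian_sd=5.0, poisson=True), blur_sigma=0.7,
        blank_cycles=[2], spill_c=0.3,
        seed=DEFAULT_SEEDS["dense"] if seed is None else seed)


def easy_spec(seed: int | None = None) -> PhantomSpec:
    """Well-separated 40-cell phantom (centers at least 3 radii apart)."""
    return PhantomSpec(
        shape=(9, 200, 200), n_cells=40,
        cell_radius_range=(4.5, 6.5), nucleus_radius_fraction=0.55,
        membrane_thickness=1.5,
        noise=NoiseModel(gaussian_sd=2.0, poisson=True), blur_sigma=0.7,
        blank_cycles=[2], spill_c=0.3,
        min_center_spacing=3 * 6.5,
        seed=DEFAULT_SEEDS["easy"] if seed is None else seed)


def adjacency_spec(seed: int | None = None) -> PhantomSpec:
    """Dense two-type phantom with mutually exclusive markers, for testing
    spillover compensation on biaxial double positives."""
    types = [CellType("X", {"MX": 200.0, "MY": 0.0}),
             CellType("Y", {"MX": 0.0, "MY": 200.0})]
    return PhantomSpec(
        shape=(9, 220, 220), n_cells=400,
        cell_radius_range=(4.0, 6.0), nucleus_radius_fraction=0.55,
        membrane_thickness=1.5, cell_types=types,
        noise=NoiseModel(gaussian_sd=0.0, poisson=True), blur_sigma=0.0,
        spill_c=0.3, expression_cv=0.1,
        seed=DEFAULT_SEEDS["adjacency"] if seed is None else seed)
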