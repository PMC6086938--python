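"""Reading, writing and aligning multicycle image stacks, and cell-table export.

A CODEX-style acquisition produces one multichannel z-stack per rendering
cycle.  Every cycle re-images a nuclear stain and a ubiquitous membrane
reference marker (e.g. CD45) alongside the cycle's antibody channels, which
makes the membrane channel usable as a registration reference across cycles.

Conventions
-----------
* Voxel arrays are indexed ``(cycle, channel, z, y, x)``; 0-based indices.
* Centroids and exported coordinates are 0-based voxel units, x fastest.
* The reference cycle for drift correction is cycle 0.
"""

from __future__ import annotations

import json

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage.registration import phase_cross_correlation

__all__ = [
    "ChannelMeta",
    "ImageStack",
    "DriftSolution",
    "write_stack",
    "read_stack",
    "estimate_drift",
    "apply_shifts",
    "export_cells",
    "read_fcs",
]

#: default physical voxel size (z, y, x) in micrometres; 188 nm lateral
DEFAULT_VOXEL_SIZE = (1.5, 0.188, 0.188)

#: columns of a cell table that are never treated as marker intensities
RESERVED_COLUMNS = frozenset(
    {"cell_id", "x", "y", "z", "size", "nuclear", "membrane", "type",
     "sample", "condition", "niche", "compartment", "compensation_clamped"}
)


def marker_columns(table: pd.DataFrame, include_blank: bool = False) -> list[str]:
    """Marker intensity columns of a cell table (excluding bookkeeping columns)."""
    cols = []
    for c in table.columns:
        if c in RESERVED_COLUMNS or c.startswith("cycle_total_"):
            continue
        if c.startswith("blank_") and not include_blank:
            continue
        if pd.api.types.is_numeric_dtype(table[c]):
            cols.append(c)
    return cols


@dataclass(frozen=True)
class ChannelMeta:
    """Identity of one (cycle, channel) plane group."""

    marker: str
    blank: bool = False
    nuclear: bool = False
    membrane: bool = False

    def to_dict(self) -> dict:
        return {"marker": self.marker, "blank": self.blank,
                "nuclear": self.nuclear, "membrane": self.membrane}

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelMeta":
        return cls(**d)


@dataclass
class ImageStack:
    """Multicycle, multichannel voxel data with per-channel metadata.

    Parameters
    ----------
    voxels : ndarray, shape (n_cycles, n_channels, z, y, x)
    channel_meta : list of list of ChannelMeta
        ``channel_meta[cycle][channel]``; the nuclear and membrane reference
        channels must sit at the same channel index in every cycle.
    voxel_size : (z, y, x) physical units per voxel.
    valid : optional boolean per-cycle mask (n_cycles, z, y, x); False marks
        voxels shifted in from outside the field after drift correction.
    """

    voxels: np.ndarray
    channel_meta: list[list[ChannelMeta]]
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 5:
            raise ValueError(f"voxels must be 5-D (cycle, channel, z, y, x); got {v.ndim}-D")
        self.voxels = v
        if len(self.channel_meta) != v.shape[0]:
            raise ValueError("channel_meta must have one entry per cycle")
        for ci, metas in enumerate(self.channel_meta):
            if len(metas) != v.shape[1]:
                raise ValueError(f"cycle {ci}: expected {v.shape[1]} channel metas, got {len(metas)}")
        nuc = {tuple(m.nuclear for m in metas).index(True)
               for metas in self.channel_meta if any(m.nuclear for m in metas)}
        mem = {tuple(m.membrane for m in metas).index(True)
               for metas in self.channel_meta if any(m.membrane for m in metas)}
        if len(nuc) != 1 or len(mem) != 1:
            raise ValueError("exactly one nuclear and one membrane channel, at a "
                             "consistent index across cycles, are required")
        self._nuclear_index = nuc.pop()
        self._membrane_index = mem.pop()

    # -- shape helpers -------------------------------------------------
    @property
    def n_cycles(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[1]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[2:]

    @property
    def nuclear_index(self) -> int:
        return self._nuclear_index

    @property
    def membrane_index(self) -> int:
        return self._membrane_index

    def nuclear(self, cycle: int = 0) -> np.ndarray:
        return self.voxels[cycle, self._nuclear_index]

    def membrane(self, cycle: int = 0) -> np.ndarray:
        return self.voxels[cycle, self._membrane_index]

    def iter_channels(self):
        """Yield (cycle, channel, meta, volume) over all planes."""
        for ci, metas in enumerate(self.channel_meta):
            for hi, meta in enumerate(metas):
                yield ci, hi, meta, self.voxels[ci, hi]


@dataclass
class DriftSolution:
    """Per-cycle displacement (dz, dy, dx) of each cycle relative to cycle 0.

    A cycle whose content moved by (0, 3, -2) voxels reports (0, 3, -2);
    :func:`apply_shifts` translates by the negative to realign.
    """

    shifts: np.ndarray  # (n_cycles, 3)

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 3:
            raise ValueError("shifts must be (n_cycles, 3)")
        if np.any(self.shifts[0] != 0):
            raise ValueError("shift of the reference cycle must be (0, 0, 0)")


# ---------------------------------------------------------------------------
# TIFF round trip
# ---------------------------------------------------------------------------

def _meta_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as a multipage TIFF plus a JSON layout sidecar.

    Pages are ordered cycle-major, then channel, then z.  The sidecar records
    the layout and channel identities so :func:`read_stack` can reassemble
    the stack without guessing.
    """
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.voxels, dtype=np.float32))
    meta = {
        "n_cycles": stack.n_cycles,
        "n_channels": stack.n_channels,
        "spatial_shape": list(stack.spatial_shape),
        "voxel_size": list(stack.voxel_size),
        "channel_meta": [[m.to_dict() for m in metas] for metas in stack.channel_meta],
    }
    _meta_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_stack(path: str | Path, layout: dict | None = None) -> ImageStack:
    """Read a multipage TIFF written by :func:`write_stack` (or compatible).

    Parameters
    ----------
    layout : optional dict with keys ``n_cycles``, ``n_channels``,
        ``channel_meta`` (nested dicts) and optionally ``voxel_size``.
        When omitted, the JSON sidecar written by :func:`write_stack` is used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout is None:
        mp = _meta_path(path)
        if not mp.exists():
            raise FileNotFoundError(f"no layout given and sidecar {mp} not found")
        layout = json.loads(mp.read_text())
    data = tifffile.imread(path)
    n_cycles, n_channels = int(layout["n_cycles"]), int(layout["n_channels"])
    metas = [[ChannelMeta.from_dict(d) for d in row] for row in layout["channel_meta"]]
    if len(metas) != n_cycles:
        raise ValueError(
            f"layout references {len(metas)} cycles but declares n_cycles={n_cycles}")
    data = np.asarray(data)
    if data.ndim == 5:
        if data.shape[:2] != (n_cycles, n_channels):
            raise ValueError(
                f"TIFF holds {data.shape[:2]} (cycle, channel) planes; layout "
                f"expects {(n_cycles, n_channels)}")
        voxels = data
    else:
        # flat page sequence: cycle-major, channel, z
        pages = data.reshape(-1, *data.shape[-2:])
        n_pages = pages.shape[0]
        if n_pages % (n_cycles * n_channels):
            raise ValueError(
                f"{path.name}: {n_pages} pages do not divide into "
                f"{n_cycles} cycles x {n_channels} channels")
        nz = n_pages // (n_cycles * n_channels)
        voxels = pages.reshape(n_cycles, n_channels, nz, *data.shape[-2:])
    return ImageStack(voxels=voxels, channel_meta=metas,
                      voxel_size=tuple(layout.get("voxel_size", DEFAULT_VOXEL_SIZE)))


# ---------------------------------------------------------------------------
# Drift alignment
# ---------------------------------------------------------------------------

def estimate_drift(stack: ImageStack, reference_channel: int | None = None,
                   max_shift: int = 20, subvoxel: bool = False) -> DriftSolution:
    """Estimate per-cycle 3-D drift against cycle 0 by phase correlation.

    The reference channel (the membrane channel by default) of each cycle is
    cross-correlated with the same channel of cycle 0.  Integer-voxel
    resolution by default; ``subvoxel=True`` refines by Fourier upsampling.

    Raises
    ------
    ValueError
        If the reference image of any cycle is flat (zero variance) or the
        estimated shift exceeds ``max_shift`` on any axis.
    """
    if reference_channel is None:
        reference_channel = stack.membrane_index
    ref = np.asarray(stack.voxels[0, reference_channel], dtype=float)
    if ref.std() == 0:
        raise ValueError("reference channel of cycle 0 has zero variance")
    shifts = np.zeros((stack.n_cycles, 3))
    for ci in range(1, stack.n_cycles):
        moving = np.asarray(stack.voxels[ci, reference_channel], dtype=float)
        if moving.std() == 0:
            raise ValueError(f"reference channel of cycle {ci} has zero variance")
        shift, _, _ = phase_cross_correlation(
            ref, moving, upsample_factor=10 if subvoxel else 1,
            normalization=None)
        shift = -shift  # report the cycle's displacement, not the correction
        if np.any(np.abs(shift) > max_shift):
            raise ValueError(
                f"cycle {ci}: estimated shift {tuple(shift)} exceeds max_shift={max_shift}")
        shifts[ci] = shift
    return DriftSolution(shifts=shifts)


def apply_shifts(stack: ImageStack, drift: DriftSolution,
                 fill_value: float = 0.0) -> ImageStack:
    """Translate every channel of every cycle by its drift shift.

    Voxels shifted in from outside the field are set to ``fill_value`` and
    marked False in the returned stack's ``valid`` mask so quantification can
    exclude them.
    """
    if drift.shifts.shape[0] != stack.n_cycles:
        raise ValueError("drift solution does not match number of cycles")
    out = np.empty_like(stack.voxels)
    valid = np.ones((stack.n_cycles,) + stack.spatial_shape, dtype=bool)
    for ci in range(stack.n_cycles):
        shift = -drift.shifts[ci]  # undo the cycle's displacement
        if np.all(shift == 0):
            out[ci] = stack.voxels[ci]
            continue
        if np.all(shift == np.round(shift)):
            ishift = tuple(int(s) for s in shift)
            for hi in range(stack.n_channels):
                out[ci, hi] = _integer_shift(stack.voxels[ci, hi], ishift, fill_value)
            valid[ci] = _integer_shift(np.ones(stack.spatial_shape), ishift, 0.0) > 0
        else:
            for hi in range(stack.n_channels):
                out[ci, hi] = ndi.shift(stack.voxels[ci, hi], shift, order=1,
                                        mode="constant", cval=fill_value)
            valid[ci] = ndi.shift(np.ones(stack.spatial_shape), shift, order=0,
                                  mode="constant", cval=0.0) > 0
    return ImageStack(voxels=out, channel_meta=stack.channel_meta,
                      voxel_size=stack.voxel_size, valid=valid)


def _integer_shift(vol: np.ndarray, shift: tuple[int, int, int],
                   fill_value: float) -> np.ndarray:
    out = np.full_like(vol, fill_value)
    src, dst = [], []
    for n, s in zip(vol.shape, shift):
        if abs(s) >= n:
            return out
        if s >= 0:
            dst.append(slice(s, n))
            src.append(slice(0, n - s))
        else:
            dst.append(slice(0, n + s))
            src.append(slice(-s, n))
    out[tuple(dst)] = vol[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# Cell-table export: CSV and FCS 3.0
# ---------------------------------------------------------------------------

#: spatial/QC parameters exported to FCS alongside the markers
FCS_SPATIAL_PARAMS = ("cell_id", "x", "y", "size")


def export_cells(table: pd.DataFrame, path: str | Path, format: str = "csv") -> Path:
    """Export a cell table as CSV or as an FCS 3.0 file (one event per cell).

    The FCS file carries one parameter per marker plus the four spatial/QC
    fields ``cell_id, x, y, size``, all stored as 32-bit little-endian
    floats, which any standard cytometry parser can read.
    """
    path = Path(path)
    if format == "csv":
        table.to_csv(path, index=False)
        return path
    if format != "fcs":
        raise ValueError(f"unknown format {format!r}; use 'csv' or 'fcs'")
    for c in table.columns:
        if c in RESERVED_COLUMNS or c.startswith("cycle_total_"):
            continue
        if not pd.api.types.is_numeric_dtype(table[c]):
            raise ValueError(f"marker column {c!r} is not numeric; cannot export to FCS")
    params = [c for c in FCS_SPATIAL_PARAMS if c in table.columns]
    params += marker_columns(table, include_blank=True)
    data = table[params].to_numpy(dtype="<f4") if len(table) else \
        np.empty((0, len(params)), dtype="<f4")
    _write_fcs(path, params, data)
    return path


def _write_fcs(path: Path, params: list[str], data: np.ndarray) -> None:
    n_events, n_par = data.shape
    delim = "/"
    kw = {
        "$MODE": "L", "$DATATYPE": "F", "$BYTEORD": "1,2,3,4",
        "$NEXTDATA": "0", "$TOT": str(n_events), "$PAR": str(n_par),
    }
    for i, name in enumerate(params, start=1):
        kw[f"$P{i}N"] = name.replace(delim, "_")
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        rng = float(data[:, i - 1].max()) if n_events else 1.0
        kw[f"$P{i}R"] = str(int(np.ceil(rng)) + 1)
    # fixed-width offsets so the TEXT segment length is stable
    kw["$BEGINDATA"] = "%012d" % 0
    kw["$ENDDATA"] = "%012d" % 0

    def render(d: dict) -> bytes:
        return (delim + delim.join(f"{k}{delim}{v}" for k, v in d.items()) + delim).encode()

    text_start = 58
    text = render(kw)
    data_start = text_start + len(text)
    data_end = data_start + data.nbytes - 1 if data.nbytes else 0
    kw["$BEGINDATA"] = "%012d" % data_start
    kw["$ENDDATA"] = "%012d" % max(data_end, 0)
    text = render(kw)
    header = (b"FCS3.0    "
              + b"%8d%8d" % (text_start, text_start + len(text) - 1)
              + b"%8d%8d" % (data_start if data.nbytes else 0, max(data_end, 0))
              + b"%8d%8d" % (0, 0))
    assert len(header) == 58
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())


def read_fcs(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read an FCS 3.0 file with float data; returns (events, keywords)."""
    raw = Path(path).read_bytes()
    if not raw.startswith(b"FCS3.0"):
        raise ValueError("not an FCS 3.0 file")
    text_start, text_end = int(raw[10:18]), int(raw[18:26])
    text = raw[text_start:text_end + 1].decode()
    delim = text[0]
    items = text.strip(delim).split(delim)
    kw = dict(zip(items[::2], items[1::2]))
    n_par, n_tot = int(kw["$PAR"]), int(kw["$TOT"])
    names = [kw[f"$P{i}N"] for i in range(1, n_par + 1)]
    if n_tot:
        ds, de = int(kw["$BEGINDATA"]), int(kw["$ENDDATA"])
        vals = np.frombuffer(raw[ds:de + 1], dtype="<f4").reshape(n_tot, n_par)
    else:
        vals = np.empty((0, n_par), dtype="<f4")
    return pd.DataFrame(vals, columns=names), kw
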