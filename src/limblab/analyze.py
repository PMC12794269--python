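"""Numerical operators behind the visualization suite.

Everything here is a pure function of its input grids: orthogonal and
oblique slices, thick-slab projections (mean/max), line probes across
channels, capped multi-isosurface families, and histogram summaries.
Rendering (colormaps, opacity, interactivity) is presentation and lives
outside this package; these operators produce the numbers those displays
would show.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    DegenerateInputError,
    ParameterError,
    SurfaceMesh,
    VoxelGrid,
)
from .surface import extract_isosurface

__all__ = [
    "SlabResult",
    "ProbeResult",
    "ortho_slice",
    "oblique_slice",
    "slab_project",
    "probe_line",
    "multi_isosurfaces",
    "histogram_summary",
    "MAX_ISOSURFACES",
]

MAX_ISOSURFACES = 10


@dataclass
class SlabResult:
    """2D projection of a thick slab with its provenance metadata."""

    image: np.ndarray
    axis: int
    index_range: tuple[int, int]  # half-open [lo, hi) in voxel indices
    operation: str

    def metadata(self) -> dict:
        return {
            "axis": self.axis,
            "range": list(self.index_range),
            "operation": self.operation,
        }


@dataclass
class ProbeResult:
    """Intensity profiles of one or more channels along a line."""

    sample_points: np.ndarray
    values: dict[str, np.ndarray]
    arclength: np.ndarray


def ortho_slice(grid: VoxelGrid, axis: int, index: int) -> np.ndarray:
    """Exact copy of one plane of the grid (no interpolation)."""
    if axis not in (0, 1, 2):
        raise ParameterError(f"axis must be 0, 1 or 2, got {axis}")
    n = grid.data.shape[axis]
    if not 0 <= index < n:
        raise ParameterError(f"index {index} out of range for axis {axis} (0..{n - 1})")
    return np.take(grid.data, index, axis=axis).copy()


def _shared_geometry(grids: list[VoxelGrid]) -> None:
    g0 = grids[0]
    for g in grids[1:]:
        if (
            g.data.shape != g0.data.shape
            or g.spacing != g0.spacing
            or g.origin != g0.origin
        ):
            raise ParameterError("channels do not share a common grid geometry")


def oblique_slice(
    grids: VoxelGrid | list[VoxelGrid],
    plane_origin,
    plane_normal,
    resolution: int = 128,
    half_extent: float | None = None,
) -> list[np.ndarray]:
    """Sample one plane through multiple channels on a shared lattice.

    An orthonormal in-plane basis is built deterministically from the
    normal; all channels are trilinearly sampled at bitwise-identical
    coordinates.  Out-of-volume samples are 0.
    """
    if isinstance(grids, VoxelGrid):
        grids = [grids]
    _shared_geometry(grids)
    g0 = grids[0]
    n = np.asarray(plane_normal, dtype=float)
    nn = np.linalg.norm(n)
    if nn == 0:
        raise ParameterError("plane normal must be nonzero")
    n = n / nn
    # in-plane basis: cross with the world axis least aligned with n
    seed = np.zeros(3)
    seed[int(np.abs(n).argmin())] = 1.0
    u = np.cross(n, seed)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    if half_extent is None:
        extent = np.asarray(g0.data.shape) * np.asarray(g0.spacing)
        half_extent = float(np.linalg.norm(extent)) / 2.0
    s = np.linspace(-half_extent, half_extent, resolution)
    uu, vv = np.meshgrid(s, s, indexing="ij")
    pts = (
        np.asarray(plane_origin, dtype=float)
        + uu[..., None] * u
        + vv[..., None] * v
    )
    idx = (pts - np.asarray(g0.origin)) / np.asarray(g0.spacing)
    coords = np.moveaxis(idx, -1, 0)
    return [
        ndimage.map_coordinates(
            g.data.astype(float), coords, order=1, mode="constant", cval=0.0
        )
        for g in grids
    ]


def slab_project(
    grid: VoxelGrid, axis: int, index_range: tuple[int, int], operation: str = "mean"
) -> SlabResult:
    """Reduce a half-open slab [lo, hi) along one axis by mean or max."""
    if axis not in (0, 1, 2):
        raise ParameterError(f"axis must be 0, 1 or 2, got {axis}")
    lo, hi = int(index_range[0]), int(index_range[1])
    n = grid.data.shape[axis]
    if not (0 <= lo < hi <= n):
        raise ParameterError(
            f"index range [{lo}, {hi}) invalid for axis {axis} of length {n}"
        )
    if operation not in ("mean", "max"):
        raise ParameterError(f"operation must be 'mean' or 'max', got {operation!r}")
    slab = np.take(grid.data, np.arange(lo, hi), axis=axis).astype(float)
    image = slab.mean(axis=axis) if operation == "mean" else slab.max(axis=axis)
    return SlabResult(image=image, axis=axis, index_range=(lo, hi), operation=operation)


def probe_line(
    grids: VoxelGrid | list[VoxelGrid] | dict[str, VoxelGrid],
    start,
    end,
    n_samples: int = 100,
) -> ProbeResult:
    """Trilinear intensity profile along a segment, per channel.

    The same ``n_samples`` evenly spaced physical points are used for every
    channel, so profiles are directly comparable across genes.
    """
    if isinstance(grids, VoxelGrid):
        named = {grids.channel_name or "channel0": grids}
    elif isinstance(grids, dict):
        named = dict(grids)
    else:
        named = {g.channel_name or f"channel{i}": g for i, g in enumerate(grids)}
    glist = list(named.values())
    _shared_geometry(glist)
    if n_samples < 2:
        raise ParameterError("n_samples must be >= 2")
    p0 = np.asarray(start, dtype=float)
    p1 = np.asarray(end, dtype=float)
    length = float(np.linalg.norm(p1 - p0))
    if length == 0:
        raise ParameterError("zero-length probe segment")
    t = np.linspace(0.0, 1.0, n_samples)
    pts = p0 + t[:, None] * (p1 - p0)
    g0 = glist[0]
    idx = (pts - np.asarray(g0.origin)) / np.asarray(g0.spacing)
    values = {
        name: ndimage.map_coordinates(
            g.data.astype(float), idx.T, order=1, mode="constant", cval=0.0
        )
        for name, g in named.items()
    }
    return ProbeResult(sample_points=pts, values=values, arclength=t * length)


def multi_isosurfaces(
    grid: VoxelGrid, v_low: float, v_high: float, n: int
) -> list[SurfaceMesh]:
    """Up to 10 isosurfaces at levels linearly spaced over [v_low, v_high].

    The cap of 10 keeps downstream displays legible; empty levels (outside
    the data range, e.g. interior levels of a clamped volume) are skipped
    with a warning rather than raising.
    """
    if not v_low < v_high:
        raise ParameterError(f"need v_low < v_high, got ({v_low}, {v_high})")
    if n < 1:
        raise ParameterError("n must be >= 1")
    n_eff = min(int(n), MAX_ISOSURFACES)
    levels = np.linspace(v_low, v_high, n_eff) if n_eff > 1 else np.array([v_low])
    out = []
    for lev in levels:
        try:
            out.append(extract_isosurface(grid, float(lev)))
        except DegenerateInputError:
            warnings.warn(f"isosurface level {lev} is empty; skipped", stacklevel=2)
    return out


def histogram_summary(
    grid: VoxelGrid, n_bins: int = 64, exclude_zeros: bool = False
) -> dict:
    """Histogram plus the summary statistics shown beside it.

    With ``exclude_zeros`` the mean matches the automatic-isovalue
    statistic used for surface extraction.
    """
    if n_bins < 1:
        raise ParameterError("n_bins must be >= 1")
    data = grid.data.ravel()
    if exclude_zeros:
        data = data[data > 0]
    if data.size == 0:
        raise DegenerateInputError("no voxels to histogram")
    counts, edges = np.histogram(data, bins=n_bins)
    return {
        "bin_edges": edges,
        "counts": counts,
        "mean": float(data.mean()),
        "min": float(data.min()),
        "max": float(data.max()),
        "n_voxels": int(data.size),
    }
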