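"""Spatial alignment of a limb surface to a reference.

Two registration routes mirror the align workflow: a linear
(rigid/similarity) route — landmark-based least squares optionally refined
by iterative closest point matching against a staged reference mesh — and
a non-linear route that fits a thin-plate-spline warp to landmark pairs,
optionally augmented with automatically generated closest-point pairs.
Either transform can then be applied to whole gene-expression volumes by
inverse-mapped trilinear resampling, keeping all channels spatially
consistent, and judged by surface-to-surface distance maps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from scipy import ndimage

from .core import (
    AffineTransform4,
    DegenerateInputError,
    LandmarkSet,
    ParameterError,
    SurfaceMesh,
    TPSWarp,
    VoxelGrid,
    tps_kernel,
)

__all__ = [
    "ReferenceRegistry",
    "DistanceMap",
    "registry_build",
    "similarity_from_landmarks",
    "closest_points_on_mesh",
    "augment_pairs_closest",
    "icp_refine",
    "tps_fit",
    "warp_grid",
    "distance_map",
]


# ---------------------------------------------------------------------------
# reference registry

MESH_SUFFIXES = (".vtk", ".ply")


@dataclass
class ReferenceRegistry:
    """Map from integer morphological stage to a reference mesh file."""

    entries: dict[int, Path]

    def stages(self) -> list[int]:
        return sorted(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def nearest_stage(self, stage: float) -> int:
        """Round-half-up to the nearest integer stage, clamped to the range."""
        s = int(np.floor(stage + 0.5))
        lo, hi = min(self.entries), max(self.entries)
        return min(max(s, lo), hi)

    def path_for(self, stage: float) -> Path:
        return self.entries[self.nearest_stage(stage)]


def registry_build(
    stage_range: tuple[int, int], mesh_dir: str | Path
) -> ReferenceRegistry:
    """Build a registry with one mesh per integer stage, inclusive endpoints.

    Files are matched as ``stage_<n>.<ext>`` (also tolerating a bare
    ``<n>.<ext>``) for ext in .vtk/.ply.  A stage without a mesh is an
    error naming that stage.
    """
    lo, hi = int(stage_range[0]), int(stage_range[1])
    if hi < lo:
        raise ParameterError(f"empty stage range {stage_range}")
    mesh_dir = Path(mesh_dir)
    available: dict[int, Path] = {}
    for p in sorted(mesh_dir.glob("*")):
        if p.suffix.lower() not in MESH_SUFFIXES:
            continue
        m = re.fullmatch(r"(?:stage[_-])?(\d+)", p.stem)
        if m:
            available.setdefault(int(m.group(1)), p)
    entries = {}
    for s in range(lo, hi + 1):
        if s not in available:
            raise ParameterError(f"no reference mesh for stage {s} in {mesh_dir}")
        entries[s] = available[s]
    return ReferenceRegistry(entries)


# ---------------------------------------------------------------------------
# similarity estimation (Umeyama least squares)


def similarity_from_landmarks(
    source: LandmarkSet, target: LandmarkSet, with_scale: bool = True
) -> AffineTransform4:
    """Least-squares similarity minimizing Σ‖s·R·pᵢ + t − qᵢ‖².

    Closed-form solution via SVD of the cross-covariance with determinant
    correction, so R is always a proper rotation (det +1) even for
    reflection-like correspondences.  ``with_scale=False`` fixes s = 1
    (rigid 6-DOF).
    """
    p = source.points
    q = target.points
    if len(p) != len(q):
        raise ParameterError("source and target landmark counts differ")
    if len(p) < 3:
        raise ParameterError(f"need >= 3 landmark pairs, got {len(p)}")
    mu_p = p.mean(axis=0)
    mu_q = q.mean(axis=0)
    x = p - mu_p
    y = q - mu_q
    var_p = float((x**2).sum() / len(p))
    if var_p < 1e-24:
        raise DegenerateInputError("source landmarks are coincident")
    cov = y.T @ x / len(p)
    u, d, vt = np.linalg.svd(cov)
    if d[1] < 1e-12 * max(d[0], 1e-300):
        raise DegenerateInputError("landmarks are collinear: rotation undetermined")
    sgn = np.ones(3)
    if np.linalg.det(u) * np.linalg.det(vt) < 0:
        sgn[2] = -1.0
    rot = u @ np.diag(sgn) @ vt
    scale = float((d * sgn).sum() / var_p) if with_scale else 1.0
    if scale <= 0:
        raise DegenerateInputError("degenerate configuration: non-positive scale")
    t = mu_q - scale * rot @ mu_p
    return AffineTransform4.from_rotation_translation(rot, t, scale)


# ---------------------------------------------------------------------------
# exact closest points on a triangulated surface


def _closest_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle for each query (paired, vectorized)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def assign(mask, value):
        m = mask & ~done
        if m.any():
            out[m] = value[m] if value.ndim == 2 else value
            done[m] = True

    assign((d1 <= 0) & (d2 <= 0), a)
    assign((d3 >= 0) & (d4 <= d3), b)
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = d1 / (d1 - d3)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)
    assign((d6 >= 0) & (d5 <= d6), c)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = d2 / (d2 - d6)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    assign(
        (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0),
        b + w_bc[:, None] * (c - b),
    )
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = vb / denom
        w = vc / denom
    assign(np.ones(len(p), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)
    return out


class _MeshProximity:
    """Closest-point queries against a fixed triangle mesh.

    Candidate triangles come from the faces incident to the k nearest
    vertices (k = 8); the exact minimum over candidates is returned.
    """

    def __init__(self, mesh: SurfaceMesh, k: int = 8):
        if mesh.n_faces == 0:
            raise DegenerateInputError("target mesh has no faces")
        self.mesh = mesh
        self.k = min(k, mesh.n_vertices)
        self.tree = cKDTree(mesh.vertices)
        nv = mesh.n_vertices
        counts = np.zeros(nv + 1, dtype=np.int64)
        for c in range(3):
            np.add.at(counts, mesh.faces[:, c] + 1, 1)
        self.offsets = np.cumsum(counts)
        order = np.argsort(mesh.faces.ravel(order="F"), kind="stable")
        self.incident = np.tile(np.arange(mesh.n_faces), 3)[order]

    def _faces_of(self, v: int) -> np.ndarray:
        return self.incident[self.offsets[v] : self.offsets[v + 1]]

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (closest points (n,3), distances (n,)). Fully vectorized:
        every (query, candidate-triangle) pair is evaluated in one batch."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(points)
        _, nn = self.tree.query(points, k=self.k)
        nn = np.atleast_2d(nn).reshape(n, -1)
        flat_v = nn.ravel()  # (n*k,)
        cnt = self.offsets[flat_v + 1] - self.offsets[flat_v]
        start = self.offsets[flat_v]
        total = int(cnt.sum())
        # concatenate incident-face index ranges without a python loop
        shift = np.repeat(np.cumsum(cnt) - cnt, cnt)
        flat_idx = np.arange(total) - shift + np.repeat(start, cnt)
        cand_faces = self.incident[flat_idx]
        point_idx = np.repeat(np.repeat(np.arange(n), nn.shape[1]), cnt)
        tri = self.mesh.vertices[self.mesh.faces[cand_faces]]
        cp = _closest_on_triangles(points[point_idx], tri)
        d2 = ((cp - points[point_idx]) ** 2).sum(axis=1)
        best = np.full(n, np.inf)
        np.fmin.at(best, point_idx, d2)
        is_best = d2 <= best[point_idx]
        first = np.full(n, -1, dtype=np.int64)
        # first winning candidate per point (deterministic tie-break)
        hit_pts, hit_pos = np.unique(point_idx[is_best], return_index=True)
        first[hit_pts] = np.flatnonzero(is_best)[hit_pos]
        closest = cp[first]
        return closest, np.sqrt(best)


def closest_points_on_mesh(
    points: np.ndarray, mesh: SurfaceMesh
) -> tuple[np.ndarray, np.ndarray]:
    """Exact closest points on ``mesh`` (any triangle, not just vertices)."""
    return _MeshProximity(mesh).query(points)


# ---------------------------------------------------------------------------
# distance maps


@dataclass
class DistanceMap:
    """Per-vertex distances from a source mesh to a target surface (µm)."""

    distances: np.ndarray
    summary: dict

    @property
    def mean(self) -> float:
        return self.summary["mean"]


def distance_map(source_mesh: SurfaceMesh, target_mesh: SurfaceMesh) -> DistanceMap:
    """Euclidean distance from each source vertex to the target surface."""
    if source_mesh.n_vertices == 0:
        raise DegenerateInputError("source mesh has no vertices")
    _, d = _MeshProximity(target_mesh).query(source_mesh.vertices)
    summary = {
        "mean": float(d.mean()),
        "max": float(d.max()),
        "rms": float(np.sqrt((d**2).mean())),
    }
    return DistanceMap(distances=d, summary=summary)


# ---------------------------------------------------------------------------
# closest-point pair augmentation


def augment_pairs_closest(
    source_mesh: SurfaceMesh,
    target_mesh: SurfaceMesh,
    seed_pairs: tuple[LandmarkSet, LandmarkSet],
    n_extra: int,
) -> tuple[LandmarkSet, LandmarkSet]:
    """Add automatically generated pairs after the user's seed pairs.

    Extra source points are farthest-point samples of the source vertices
    (seeded by the user's picks, so new points spread away from them); each
    is paired with its closest point on the target surface.  Assumes the
    meshes are already roughly aligned.
    """
    seeds_src, seeds_tgt = seed_pairs
    if len(seeds_src) != len(seeds_tgt):
        raise ParameterError("seed pair lists differ in length")
    if n_extra < 0 or n_extra > source_mesh.n_vertices:
        raise ParameterError(
            f"n_extra must be in [0, {source_mesh.n_vertices}], got {n_extra}"
        )
    if n_extra == 0:
        return seeds_src, seeds_tgt
    verts = source_mesh.vertices
    mind = np.full(len(verts), np.inf)
    for s in seeds_src.points:
        mind = np.minimum(mind, np.linalg.norm(verts - s, axis=1))
    chosen = []
    for _ in range(n_extra):
        i = int(mind.argmax())
        chosen.append(i)
        mind = np.minimum(mind, np.linalg.norm(verts - verts[i], axis=1))
    extra_src = verts[chosen]
    extra_tgt, _ = _MeshProximity(target_mesh).query(extra_src)
    return (
        LandmarkSet(np.vstack([seeds_src.points, extra_src])),
        LandmarkSet(np.vstack([seeds_tgt.points, extra_tgt])),
    )


# ---------------------------------------------------------------------------
# iterative closest point


def icp_refine(
    source_mesh: SurfaceMesh,
    target_mesh: SurfaceMesh,
    init: AffineTransform4 | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    with_scale: bool = False,
    return_history: bool = False,
):
    """ICP refinement of an initial alignment.

    Alternates exact closest-point correspondence (source vertices against
    the target surface) and least-squares transform estimation; pairs
    farther than 3× the median distance are rejected for robustness.  The
    mean closest-point distance is non-increasing over accepted iterations;
    iteration stops when it improves by less than ``tol`` (µm) or at
    ``max_iter``.  Returns the composed transform (including ``init``), and
    the mean-distance trace when ``return_history``.
    """
    if source_mesh.n_vertices == 0 or target_mesh.n_faces == 0:
        raise DegenerateInputError("ICP needs non-empty meshes")
    current = init or AffineTransform4.identity()
    prox = _MeshProximity(target_mesh)
    pts0 = source_mesh.vertices
    history: list[float] = []
    best_mean = np.inf
    for _ in range(max_iter):
        moved = current.apply(pts0)
        closest, d = prox.query(moved)
        mean_d = float(d.mean())
        if mean_d > best_mean:  # reject non-improving update
            break
        history.append(mean_d)
        improved = best_mean - mean_d
        best_mean = mean_d
        if mean_d < tol or improved < tol and len(history) > 1:
            break
        med = np.median(d)
        keep = d <= 3.0 * med + 1e-30
        if keep.sum() < 3:
            break
        step = similarity_from_landmarks(
            LandmarkSet(moved[keep]), LandmarkSet(closest[keep]), with_scale=with_scale
        )
        current = step.compose(current)
    if return_history:
        return current, history
    return current


# ---------------------------------------------------------------------------
# thin-plate-spline fitting


def tps_fit(
    source: LandmarkSet, target: LandmarkSet, regularization: float = 0.0
) -> TPSWarp:
    """Fit the 3D thin-plate-spline warp carrying source onto target.

    Kernel U(r) = r (3D biharmonic); the kernel weights satisfy the side
    conditions (orthogonality to the affine monomials), so the warp is the
    minimum-bending-energy interpolant.  λ = 0 interpolates the landmarks
    exactly; λ > 0 trades exactness for smoothness (ridge on the kernel
    block).  The bending energy is the quadratic form −Σ_d w_dᵀ K w_d,
    which vanishes when the landmark relation is exactly affine.
    """
    p = source.points
    q = target.points
    n = len(p)
    if n != len(q):
        raise ParameterError("source and target landmark counts differ")
    if n < 4:
        raise ParameterError(f"TPS needs >= 4 landmark pairs, got {n}")
    lam = float(regularization)
    if lam < 0:
        raise ParameterError("regularization must be >= 0")
    centered = p - p.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if lam == 0 and sv[2] < 1e-9 * max(sv[0], 1e-300):
        raise DegenerateInputError(
            "coplanar/degenerate landmarks make the λ=0 TPS system singular; "
            "use regularization > 0"
        )
    K = tps_kernel(np.linalg.norm(p[:, None, :] - p[None, :, :], axis=2))
    P = np.concatenate([np.ones((n, 1)), p], axis=1)
    sys = np.zeros((n + 4, n + 4))
    sys[:n, :n] = K + lam * np.eye(n)
    sys[:n, n:] = P
    sys[n:, :n] = P.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = q
    try:
        sol = np.linalg.solve(sys, rhs)
    except np.linalg.LinAlgError as exc:
        raise DegenerateInputError(
            f"singular TPS system ({exc}); try regularization > 0"
        ) from exc
    w = sol[:n]
    affine = np.zeros((3, 4))
    affine[:, 3] = sol[n]
    affine[:, :3] = sol[n + 1 :].T
    energy = float(-np.einsum("id,ij,jd->", w, K, w))
    return TPSWarp(
        source_landmarks=p,
        target_landmarks=q,
        affine_part=affine,
        kernel_weights=w,
        bending_energy=energy,
        regularization=lam,
    )


# ---------------------------------------------------------------------------
# applying transforms to whole volumes


def warp_grid(
    grid: VoxelGrid,
    transform: AffineTransform4 | TPSWarp,
    reference: VoxelGrid | tuple | None = None,
    tps_inverse: str = "reverse-fit",
) -> VoxelGrid:
    """Resample a volume through a spatial transform (inverse mapping).

    Each output voxel centre (on the reference geometry, default: the input
    grid's own) is mapped through the inverse transform and trilinearly
    sampled from the input; out-of-domain samples are 0.  The affine
    inverse is exact.  For TPS warps the inverse is approximated either by
    fitting the reverse-direction spline (``"reverse-fit"``, adequate for
    smooth morphs) or by per-voxel fixed-point iteration
    (``"fixed-point"``).
    """
    if reference is None:
        shape, spacing, origin = grid.data.shape, grid.spacing, grid.origin
    elif isinstance(reference, VoxelGrid):
        shape, spacing, origin = reference.data.shape, reference.spacing, reference.origin
    else:
        shape, spacing, origin = reference
    shape = tuple(int(n) for n in shape)
    idx = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    phys = np.stack(
        [o + i * s for i, s, o in zip(idx, spacing, origin)], axis=-1
    ).reshape(-1, 3)

    if isinstance(transform, AffineTransform4):
        src_phys = transform.inverse().apply(phys)
    else:
        if tps_inverse == "reverse-fit":
            inv = tps_fit(
                LandmarkSet(transform.target_landmarks),
                LandmarkSet(transform.source_landmarks),
                regularization=transform.regularization,
            )
            src_phys = inv.apply(phys)
        elif tps_inverse == "fixed-point":
            src_phys = phys.copy()
            for _ in range(20):
                err = transform.apply(src_phys) - phys
                src_phys -= 0.9 * err
                if np.abs(err).max() < 1e-6:
                    break
        else:
            raise ParameterError(f"unknown tps_inverse mode {tps_inverse!r}")

    src_idx = (src_phys - np.asarray(grid.origin)) / np.asarray(grid.spacing)
    data = ndimage.map_coordinates(
        grid.data.astype(float),
        src_idx.T.reshape(3, *shape),
        order=1,
        mode="constant",
        cval=0.0,
    )
    return VoxelGrid(
        data=data, spacing=tuple(spacing), origin=tuple(origin),
        channel_name=grid.channel_name,
    )
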