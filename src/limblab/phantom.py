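"""Synthetic limb-bud phantoms with known ground truth.

The phantom emulates the data the pipeline consumes, downstream of the
microscope: a "nuclei" channel shaped like a paddle (half-ellipsoid
protruding from the flank along the proximodistal axis) carrying
multiplicative speckle noise, plus gene-expression channels on the same
grid — a proximodistal gradient, a bilobed double-Gaussian, and a torus
(a ring of expression around the proximodistal axis, the donut-shaped
domain a stripe appears as in 2D).  Every output has analytic surface,
volume and landmark ground truth, and all randomness flows through one
seed so equal specs are bitwise-identical.

Axis convention: array axis 1 is proximodistal (the paddle protrudes
toward increasing axis-1 coordinates); axes 0 and 2 are the width and
thickness of the paddle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial.transform import Rotation

from .core import (
    AffineTransform4,
    LandmarkSet,
    ParameterError,
    SurfaceMesh,
    TPSWarp,
    VoxelGrid,
)
from .register import ReferenceRegistry, registry_build, tps_fit

__all__ = [
    "PhantomSpec",
    "make_limb_phantom",
    "make_gene_domain",
    "make_reference_set",
    "perturb_with_known_transform",
]

INSIDE_INTENSITY = 100.0
DEFAULT_NOISE = 0.05


@dataclass
class PhantomSpec:
    """Geometry and noise of one synthetic limb bud.

    shape/spacing define the voxel grid (spacing in µm); ``semi_axes``
    (a, b, c) are the half-ellipsoid semi-axes in µm along array axes
    (0, 1, 2), with b the proximodistal protrusion length.  ``noise_level``
    is the multiplicative speckle std (default 0.05, typical of cleared
    light-sheet texture).
    """

    shape: tuple[int, int, int] = (64, 96, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    semi_axes: tuple[float, float, float] = (24.0, 70.0, 16.0)
    noise_level: float = DEFAULT_NOISE
    domain_kind: str = "gradient"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_level < 0:
            raise ParameterError("noise_level must be >= 0")
        if any(s <= 0 for s in self.semi_axes):
            raise ParameterError("semi-axes must be positive")
        a, b, c = self.semi_axes
        ext = [n * s for n, s in zip(self.shape, self.spacing)]
        cen = self.center
        margin = [sp for sp in self.spacing]
        fits = (
            cen[0] - a >= margin[0]
            and cen[0] + a <= ext[0] - margin[0]
            and cen[1] >= margin[1]
            and cen[1] + b <= ext[1] - margin[1]
            and cen[2] - c >= margin[2]
            and cen[2] + c <= ext[2] - margin[2]
        )
        if not fits:
            raise ParameterError(
                f"semi-axes {self.semi_axes} do not fit inside the grid extent {ext} "
                "with a one-voxel margin"
            )

    @property
    def center(self) -> tuple[float, float, float]:
        """Centre of the ellipsoid = base of the paddle (µm)."""
        ext = [n * s for n, s in zip(self.shape, self.spacing)]
        return (ext[0] / 2.0, 2.0 * self.spacing[1], ext[2] / 2.0)

    @property
    def analytic_volume(self) -> float:
        """Half-ellipsoid volume (2/3)·π·a·b·c, µm³."""
        a, b, c = self.semi_axes
        return 2.0 / 3.0 * np.pi * a * b * c


def _physical_axes(spec: PhantomSpec, oversample: int = 1):
    """Voxel-centre coordinates per axis, optionally supersampled."""
    # voxel-centre convention: the coordinate of index i is i * spacing
    # (origin 0); supersampled coordinates average back to the centres
    axes = []
    for n, s in zip(spec.shape, spec.spacing):
        step = s / oversample
        axes.append(-0.5 * s + (np.arange(n * oversample) + 0.5) * step)
    return axes


def _paddle_fraction(spec: PhantomSpec, oversample: int = 2) -> np.ndarray:
    """Volume fraction of each voxel inside the half-ellipsoid (0..1).

    Computed by 2× supersampling of the analytic indicator, which places
    marching-cubes boundary crossings with sub-voxel accuracy.
    """
    ax = _physical_axes(spec, oversample)
    c = spec.center
    a, b, cc = spec.semi_axes
    q = (
        ((ax[0] - c[0]) / a)[:, None, None] ** 2
        + ((ax[1] - c[1]) / b)[None, :, None] ** 2
        + ((ax[2] - c[2]) / cc)[None, None, :] ** 2
    )
    inside = (q <= 1.0) & ((ax[1] - c[1]) >= 0.0)[None, :, None]
    frac = inside.astype(float)
    o = oversample
    n0, n1, n2 = spec.shape
    return frac.reshape(n0, o, n1, o, n2, o).mean(axis=(1, 3, 5))


def make_limb_phantom(spec: PhantomSpec) -> dict:
    """Nuclei channel + analytic truth + AER landmarks.

    The nuclei channel is the paddle indicator at intensity 100 inside / 0
    outside (boundary voxels hold the interior volume fraction), multiplied
    by speckle ``1 + noise_level·N(0,1)`` from the spec seed.  Landmarks
    trace the AER arc along the distal rim in the mid-thickness plane and
    lie exactly on the truth surface.
    """
    frac = _paddle_fraction(spec)
    rng = np.random.default_rng(spec.seed)
    speckle = 1.0 + spec.noise_level * rng.standard_normal(spec.shape)
    data = INSIDE_INTENSITY * frac * speckle
    grid = VoxelGrid(
        data=data, spacing=spec.spacing, origin=(0.0, 0.0, 0.0), channel_name="nuclei"
    )
    c = spec.center
    a, b, cc = spec.semi_axes
    theta = np.deg2rad(np.linspace(-75.0, 75.0, 9))
    landmarks = LandmarkSet(
        np.stack(
            [
                c[0] + a * np.sin(theta),
                c[1] + b * np.cos(theta),
                np.full_like(theta, c[2]),
            ],
            axis=1,
        )
    )
    truth = {
        "center": list(c),
        "semi_axes": list(spec.semi_axes),
        "volume": spec.analytic_volume,
        "inside_intensity": INSIDE_INTENSITY,
    }
    return {"nuclei": grid, "truth": truth, "landmarks": landmarks}


def make_gene_domain(spec: PhantomSpec, kind: str | None = None) -> VoxelGrid:
    """Expression channel on the nuclei grid geometry.

    ``gradient``: linear proximodistal ramp masked by the paddle.
    ``bilobed``: two Gaussian foci straddling the midline in the distal
    half (two maxima, reduced signal in the centre).
    ``torus``: Gaussian tube around a ring centred on the proximodistal
    axis — the donut-shaped domain.
    """
    kind = kind or spec.domain_kind
    c = spec.center
    a, b, cc = spec.semi_axes
    ax = _physical_axes(spec, 1)
    x0 = ax[0][:, None, None]
    x1 = ax[1][None, :, None]
    x2 = ax[2][None, None, :]
    if kind == "gradient":
        frac = _paddle_fraction(spec)
        ramp = np.clip((ax[1] - c[1]) / b, 0.0, 1.0)[None, :, None]
        data = INSIDE_INTENSITY * ramp * frac
    elif kind == "bilobed":
        sigma = a / 4.0
        foci = [
            (c[0] - a / 2.0, c[1] + 0.5 * b, c[2]),
            (c[0] + a / 2.0, c[1] + 0.5 * b, c[2]),
        ]
        data = np.zeros(spec.shape)
        for f in foci:
            d2 = (x0 - f[0]) ** 2 + (x1 - f[1]) ** 2 + (x2 - f[2]) ** 2
            data += INSIDE_INTENSITY * np.exp(-d2 / (2 * sigma**2))
    elif kind == "torus":
        ring_r = 0.5 * a
        tube_w = 0.125 * a  # Gaussian width; 50% level tube radius ≈ 1.18 w
        t1 = c[1] + 0.55 * b
        rho = np.sqrt((x0 - c[0]) ** 2 + (x2 - c[2]) ** 2)
        d2 = (rho - ring_r) ** 2 + (x1 - t1) ** 2
        data = INSIDE_INTENSITY * np.exp(-d2 / (2 * tube_w**2))
    else:
        raise ParameterError(
            f"unknown gene-domain kind {kind!r}; choose gradient|bilobed|torus"
        )
    return VoxelGrid(
        data=data, spacing=spec.spacing, origin=(0.0, 0.0, 0.0), channel_name=kind
    )


def torus_truth(spec: PhantomSpec) -> dict:
    """Ring centre/radii of the torus domain for probe construction."""
    c = spec.center
    a, b, _ = spec.semi_axes
    return {
        "center": (c[0], c[1] + 0.55 * b, c[2]),
        "ring_radius": 0.5 * a,
        "tube_width": 0.125 * a,
    }


def make_reference_set(
    stage_range: tuple[int, int],
    base_spec: PhantomSpec | None = None,
    out_dir: str | Path = ".",
) -> ReferenceRegistry:
    """Placeholder reference meshes, one per integer stage.

    Each mesh is an ellipsoid whose semi-axes scale linearly with stage
    (a stand-in for a real staged atlas, not biology): enclosed volume is
    strictly monotone in stage.  Files are written as ``stage_<n>.ply``
    and the directory round-trips through :func:`registry_build`.
    """
    base_spec = base_spec or PhantomSpec()
    lo, hi = int(stage_range[0]), int(stage_range[1])
    if hi < lo:
        raise ParameterError(f"empty stage range {stage_range}")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create reference directory {out_dir}: {exc}") from exc
    from .io import write_mesh

    ico = trimesh.creation.icosphere(subdivisions=2)
    semi = np.asarray(base_spec.semi_axes)
    centre = np.asarray(base_spec.center)
    for s in range(lo, hi + 1):
        scale = s / float(max(hi, 1))
        verts = ico.vertices * (semi * scale) + centre
        mesh = SurfaceMesh(verts, np.asarray(ico.faces))
        write_mesh(mesh, out_dir / f"stage_{s}.ply")
    return registry_build((lo, hi), out_dir)


def perturb_with_known_transform(
    obj: SurfaceMesh | VoxelGrid,
    kind: str = "rigid",
    magnitude: float | tuple = (5.0, 2.0),
    seed: int = 0,
) -> dict:
    """Perturb a mesh or grid by a known transform, for recovery tests.

    ``rigid``: magnitude = (rotation °, translation µm); ``similarity``
    adds a scale factor (rotation °, translation µm, scale); ``tps``:
    magnitude = displacement amplitude in µm of a smooth random warp built
    from a coarse control lattice.  Returns the perturbed object and the
    exact ground-truth transform.
    """
    rng = np.random.default_rng(seed)
    if kind in ("rigid", "similarity"):
        if np.isscalar(magnitude):
            magnitude = (float(magnitude), float(magnitude))
        angle = float(magnitude[0])
        shift = float(magnitude[1])
        scale = float(magnitude[2]) if kind == "similarity" and len(magnitude) > 2 else 1.0
        if angle == 0 and shift == 0 and scale == 1.0:
            transform = AffineTransform4.identity()
        else:
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            rot = Rotation.from_rotvec(np.deg2rad(angle) * axis).as_matrix()
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            transform = AffineTransform4.from_rotation_translation(
                rot, shift * direction, scale
            )
    elif kind == "tps":
        amp = float(magnitude if np.isscalar(magnitude) else magnitude[0])
        if isinstance(obj, SurfaceMesh):
            lo = obj.vertices.min(axis=0)
            hi = obj.vertices.max(axis=0)
        else:
            lo = np.asarray(obj.origin)
            hi = lo + (np.asarray(obj.data.shape) - 1) * np.asarray(obj.spacing)
        pad = 0.1 * (hi - lo)
        gridpts = np.meshgrid(
            *[np.linspace(l - p, h + p, 3) for l, h, p in zip(lo, hi, pad)],
            indexing="ij",
        )
        src = np.stack(gridpts, axis=-1).reshape(-1, 3)
        tgt = src + amp * rng.uniform(-1.0, 1.0, src.shape)
        transform = tps_fit(LandmarkSet(src), LandmarkSet(tgt))
    else:
        raise ParameterError(f"unknown perturbation kind {kind!r}")

    if isinstance(obj, SurfaceMesh):
        perturbed: SurfaceMesh | VoxelGrid = SurfaceMesh(
            transform.apply(obj.vertices), obj.faces.copy(),
            None if obj.scalars is None else obj.scalars.copy(),
        )
    else:
        from .register import warp_grid

        perturbed = warp_grid(obj, transform)
    return {"perturbed": perturbed, "transform": transform}
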