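"""Domain types shared by every pipeline stage.

Physical coordinates are in micrometres (µm) throughout.  A voxel grid
stores a 3D scalar field together with its per-axis spacing and origin,
using the voxel-centre convention: the physical coordinate of array index
``(i, j, k)`` is ``origin + (i, j, k) * spacing``.  Spacing components are
given in array-axis order (``spacing[0]`` is the step along ``data`` axis 0).

The experiment ledger (``pipeline.log``) is the append-only record of every
user-chosen and auto-assigned parameter; replaying the recorded values
reproduces a deterministic pipeline run.
"""

from __future__ import annotations

import datetime as _dt
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LimbLabError",
    "ParameterError",
    "FormatError",
    "DegenerateInputError",
    "StagingServiceError",
    "VoxelGrid",
    "SurfaceMesh",
    "LandmarkSet",
    "LimbMetadata",
    "StageResult",
    "AffineTransform4",
    "TPSWarp",
    "ExperimentLedger",
    "tps_kernel",
]


class LimbLabError(Exception):
    """Base class for pipeline errors."""


class ParameterError(LimbLabError, ValueError):
    """A user-supplied parameter violates a precondition."""


class FormatError(LimbLabError, ValueError):
    """A file does not conform to its expected format."""


class DegenerateInputError(LimbLabError, ValueError):
    """Input data is degenerate for the requested operation."""


class StagingServiceError(LimbLabError, RuntimeError):
    """The staging service failed or returned an unusable response."""

    def __init__(self, message: str, status: int | None = None, body: str = ""):
        super().__init__(message)
        self.status = status
        self.body = body[:500]


# ---------------------------------------------------------------------------
# voxel grids


@dataclass
class VoxelGrid:
    """3D scalar intensity field with physical calibration.

    Parameters
    ----------
    data : ndarray, shape (n0, n1, n2)
        Scalar intensities in arbitrary units.
    spacing : 3 floats
        Physical size of one voxel along each array axis, µm; all > 0.
    origin : 3 floats
        Physical coordinate of voxel index (0, 0, 0), µm.
    channel_name : str
        Label of the imaged channel (e.g. ``"DAPI"``, ``"Hoxa11"``).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ParameterError(
                f"grid data must be 3D with every axis >= 1, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        self.origin = tuple(float(o) for o in self.origin)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ParameterError(f"spacing must be 3 positive reals, got {self.spacing}")
        if len(self.origin) != 3:
            raise ParameterError("origin must have 3 components")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) array indices to physical µm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def physical_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def copy_with(self, data: np.ndarray | None = None, **kw) -> "VoxelGrid":
        return VoxelGrid(
            data=self.data.copy() if data is None else data,
            spacing=kw.get("spacing", self.spacing),
            origin=kw.get("origin", self.origin),
            channel_name=kw.get("channel_name", self.channel_name),
        )


# ---------------------------------------------------------------------------
# surface meshes


@dataclass
class SurfaceMesh:
    """Triangulated surface in physical µm coordinates.

    ``vertices`` is float (n, 3); ``faces`` int (m, 3) indexing vertices;
    ``scalars`` optional per-vertex values (e.g. surface-to-surface distance).
    """

    vertices: np.ndarray
    faces: np.ndarray
    scalars: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ParameterError("face indices out of range")
        if len(self.faces):
            f = self.faces
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
                raise ParameterError("faces with repeated vertices are not allowed")
        if self.scalars is not None:
            self.scalars = np.asarray(self.scalars, dtype=float).ravel()
            if len(self.scalars) != len(self.vertices):
                raise ParameterError("scalars must be per-vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges_unique(self) -> np.ndarray:
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.scalars is None else self.scalars.copy(),
        )


# ---------------------------------------------------------------------------
# landmarks and metadata


@dataclass
class LandmarkSet:
    """Ordered list of 3D physical points (µm) with optional labels."""

    points: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 1:
            raise ParameterError("landmarks must be an (n >= 1, 3) array")
        if not np.all(np.isfinite(self.points)):
            raise ParameterError("landmark coordinates must be finite")
        if self.labels is not None and len(self.labels) != len(self.points):
            raise ParameterError("labels must match point count")

    def __len__(self) -> int:
        return len(self.points)


SIDES = ("left", "right")
LIMB_TYPES = ("forelimb", "hindlimb")


@dataclass(frozen=True)
class LimbMetadata:
    """Acquisition metadata: limb laterality/type and microscope voxel size."""

    side: str
    limb_type: str
    voxel_spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ParameterError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.limb_type not in LIMB_TYPES:
            raise ParameterError(
                f"limb_type must be one of {LIMB_TYPES}, got {self.limb_type!r}"
            )
        sp = tuple(float(s) for s in self.voxel_spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ParameterError("voxel_spacing must be 3 positive reals")
        object.__setattr__(self, "voxel_spacing", sp)


@dataclass(frozen=True)
class StageResult:
    """Morphological stage assigned by the staging service.

    ``stage`` is in staging-system units (≈ developmental hours post
    conception for the mouse system), ``uncertainty`` in hours.
    """

    stage: float
    uncertainty: float
    summary: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.stage):
            raise ParameterError("stage must be finite")
        if self.uncertainty < 0:
            raise ParameterError("uncertainty must be >= 0")


# ---------------------------------------------------------------------------
# affine transforms


class AffineTransform4:
    """4×4 homogeneous transform ``[[R, t], [0, 1]]`` acting on µm points.

    ``R`` is the 3×3 linear part (rotation·scale for similarity transforms)
    and ``t`` the translation.  Application to a point p is ``R @ p + t``.
    """

    def __init__(self, matrix: np.ndarray):
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise ParameterError(f"expected 4x4 matrix, got shape {m.shape}")
        if not np.array_equal(m[3], [0.0, 0.0, 0.0, 1.0]):
            raise ParameterError("last row must be exactly (0, 0, 0, 1)")
        if abs(np.linalg.det(m[:3, :3])) < 1e-300:
            raise ParameterError("linear part is singular")
        self.matrix = m

    # constructors -----------------------------------------------------------
    @classmethod
    def identity(cls) -> "AffineTransform4":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(
        cls, rotation: np.ndarray, translation: Sequence[float], scale: float = 1.0
    ) -> "AffineTransform4":
        m = np.eye(4)
        m[:3, :3] = float(scale) * np.asarray(rotation, dtype=float)
        m[:3, 3] = np.asarray(translation, dtype=float)
        return cls(m)

    @classmethod
    def translation(cls, t: Sequence[float]) -> "AffineTransform4":
        return cls.from_rotation_translation(np.eye(3), t)

    # algebra ----------------------------------------------------------------
    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def offset(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def compose(self, other: "AffineTransform4") -> "AffineTransform4":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return AffineTransform4(self.matrix @ other.matrix)

    def inverse(self) -> "AffineTransform4":
        rinv = np.linalg.inv(self.linear)
        m = np.eye(4)
        m[:3, :3] = rinv
        m[:3, 3] = -rinv @ self.offset
        return AffineTransform4(m)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.linear.T + self.offset
        return out if np.asarray(points).ndim == 2 else out[0]

    def is_similarity(self, tol: float = 1e-9) -> bool:
        g = self.linear.T @ self.linear
        s2 = np.trace(g) / 3.0
        return bool(np.allclose(g, s2 * np.eye(3), atol=tol * max(1.0, s2)))

    # serialization ----------------------------------------------------------
    def to_json(self) -> dict:
        return {"type": "affine", "matrix": self.matrix.tolist()}

    @classmethod
    def from_json(cls, obj: dict) -> "AffineTransform4":
        return cls(np.asarray(obj["matrix"], dtype=float))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "AffineTransform4":
        return cls.from_json(json.loads(Path(path).read_text()))

    def __repr__(self) -> str:
        return f"AffineTransform4(\n{np.array_str(self.matrix, precision=6)})"


def transform_compose(a: AffineTransform4, b: AffineTransform4) -> AffineTransform4:
    """Compose two affine transforms: result applies ``b`` first, then ``a``."""
    return a.compose(b)


# ---------------------------------------------------------------------------
# thin-plate-spline warps


def tps_kernel(r: np.ndarray) -> np.ndarray:
    """3D thin-plate (biharmonic) radial kernel U(r) = r."""
    return np.asarray(r, dtype=float)


class TPSWarp:
    """Thin-plate-spline deformation of 3D space.

    p' = A [p; 1] + Σᵢ wᵢ U(‖p − sᵢ‖) with U(r) = r, the 3D biharmonic
    fundamental solution.  With regularization λ = 0 the warp interpolates
    the landmarks exactly; the kernel weights are orthogonal to the affine
    monomials, which makes the bending energy a well-defined quadratic form
    that vanishes exactly when the landmark relation is affine.
    """

    def __init__(
        self,
        source_landmarks: np.ndarray,
        target_landmarks: np.ndarray,
        affine_part: np.ndarray,
        kernel_weights: np.ndarray,
        bending_energy: float,
        regularization: float = 0.0,
    ):
        self.source_landmarks = np.asarray(source_landmarks, dtype=float).reshape(-1, 3)
        self.target_landmarks = np.asarray(target_landmarks, dtype=float).reshape(-1, 3)
        self.affine_part = np.asarray(affine_part, dtype=float).reshape(3, 4)
        self.kernel_weights = np.asarray(kernel_weights, dtype=float).reshape(-1, 3)
        if len(self.source_landmarks) != len(self.target_landmarks):
            raise ParameterError("source and target landmark counts differ")
        if len(self.kernel_weights) != len(self.source_landmarks):
            raise ParameterError("one kernel weight vector per landmark required")
        self.bending_energy = max(0.0, float(bending_energy))
        self.regularization = float(regularization)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = np.linalg.norm(pts[:, None, :] - self.source_landmarks[None, :, :], axis=2)
        out = (
            pts @ self.affine_part[:, :3].T
            + self.affine_part[:, 3]
            + tps_kernel(d) @ self.kernel_weights
        )
        return out if np.asarray(points).ndim == 2 else out[0]

    def to_json(self) -> dict:
        return {
            "type": "tps",
            "source_landmarks": self.source_landmarks.tolist(),
            "target_landmarks": self.target_landmarks.tolist(),
            "affine_part": self.affine_part.tolist(),
            "kernel_weights": self.kernel_weights.tolist(),
            "bending_energy": self.bending_energy,
            "regularization": self.regularization,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "TPSWarp":
        return cls(
            np.asarray(obj["source_landmarks"]),
            np.asarray(obj["target_landmarks"]),
            np.asarray(obj["affine_part"]),
            np.asarray(obj["kernel_weights"]),
            obj["bending_energy"],
            obj.get("regularization", 0.0),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TPSWarp":
        return cls.from_json(json.loads(Path(path).read_text()))


def load_transform(path: str | Path) -> AffineTransform4 | TPSWarp:
    """Load a ``*.transform.json`` file written by either transform class."""
    obj = json.loads(Path(path).read_text())
    if obj.get("type") == "tps":
        return TPSWarp.from_json(obj)
    return AffineTransform4.from_json(obj)


def transform_apply_points(
    t: AffineTransform4 | TPSWarp, pts: LandmarkSet
) -> LandmarkSet:
    """Apply an affine transform or TPS warp to a landmark set."""
    return LandmarkSet(t.apply(pts.points), labels=pts.labels)


# ---------------------------------------------------------------------------
# experiment ledger


class ExperimentLedger:
    """Append-only ``pipeline.log``: one ``timestamp<TAB>key<TAB>JSON`` line
    per recorded value.  Reading a key returns its last-written value, so a
    pipeline stage can be re-run and the ledger keeps the full audit trail.
    """

    FILENAME = "pipeline.log"

    def __init__(self, path: str | Path):
        self.path = Path(path)
        if self.path.is_dir():
            self.path = self.path / self.FILENAME

    def record(self, key: str, value) -> "ExperimentLedger":
        if not key or "\t" in key or "\n" in key:
            raise ParameterError(f"invalid ledger key {key!r}")
        if isinstance(value, np.ndarray):
            value = value.tolist()
        elif isinstance(value, (np.floating, np.integer)):
            value = value.item()
        elif isinstance(value, tuple):
            value = list(value)
        elif isinstance(value, Path):
            value = str(value)
        line = "\t".join(
            [
                _dt.datetime.now(_dt.timezone.utc).isoformat(),
                key,
                json.dumps(value),
            ]
        )
        try:
            with open(self.path, "a", encoding="utf-8") as fh:
                fh.write(line + "\n")
                fh.flush()
                os.fsync(fh.fileno())
        except OSError as exc:
            raise LimbLabError(f"cannot append to ledger at {self.path}: {exc}") from exc
        return self

    def record_many(self, items: dict) -> "ExperimentLedger":
        for k, v in items.items():
            self.record(k, v)
        return self

    def entries(self) -> list[tuple[str, str, object]]:
        if not self.path.exists():
            return []
        out = []
        for raw in self.path.read_text(encoding="utf-8").splitlines():
            if not raw.strip():
                continue
            ts, key, val = raw.split("\t", 2)
            out.append((ts, key, json.loads(val)))
        return out

    _MISSING = object()

    def read(self, key: str, default=_MISSING):
        value = self._MISSING
        for _, k, v in self.entries():
            if k == key:
                value = v
        if value is self._MISSING:
            if default is self._MISSING:
                raise KeyError(key)
            return default
        return value

    def has(self, key: str) -> bool:
        return any(k == key for _, k, _ in self.entries())

    def keys(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, k, _ in self.entries():
            seen[k] = None
        return list(seen)


def ledger_record(ledger: ExperimentLedger, key: str, value) -> ExperimentLedger:
    """Functional alias for :meth:`ExperimentLedger.record`."""
    return ledger.record(key, value)
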