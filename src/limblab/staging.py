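"""Developmental staging of the limb bud.

The stage of a fixed limb is estimated from the geometry of its apical
ectodermal ridge (AER): user-picked landmarks along the ridge are
interpolated by a spline, a least-squares plane is fitted, the limb is
reoriented so the plane normal points along the canonical (0, 0, −1)
(dorsal view), and the projected 2D outline points are submitted to the
morphological staging service.  The service itself (the eMOSS reference
trajectory) is external; this module ships an HTTP client for it and a
deterministic mock used for offline work and testing.
"""

from __future__ import annotations

import hashlib
import json
import urllib.error
import urllib.request
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .core import (
    AffineTransform4,
    DegenerateInputError,
    ExperimentLedger,
    LandmarkSet,
    ParameterError,
    StageResult,
    StagingServiceError,
)

__all__ = [
    "StagingRequest",
    "fit_spline_aer",
    "fit_plane",
    "reorient_to_axis",
    "project_to_2d",
    "MockStagingClient",
    "HTTPStagingClient",
    "request_stage",
]

CANONICAL_NORMAL = np.array([0.0, 0.0, -1.0])
DEFAULT_ENDPOINT = "https://limbstaging.embl.es/api"


@dataclass
class StagingRequest:
    """Payload for the staging service: reoriented 2D outline points."""

    points_2d: np.ndarray
    side: str
    limb_type: str

    def __post_init__(self) -> None:
        self.points_2d = np.atleast_2d(np.asarray(self.points_2d, dtype=float))
        if self.points_2d.shape[1] != 2 or len(self.points_2d) < 3:
            raise ParameterError("staging request needs >= 3 finite 2D points")
        if not np.all(np.isfinite(self.points_2d)):
            raise ParameterError("staging request points must be finite")

    def to_json(self, points_field: str = "points") -> str:
        return json.dumps(
            {
                points_field: self.points_2d.tolist(),
                "side": self.side,
                "limb_type": self.limb_type,
            }
        )


def fit_spline_aer(points: LandmarkSet, n_samples: int = 100) -> LandmarkSet:
    """Interpolating cubic spline through ordered AER landmarks.

    Chord-length parameterization; resampled at ``n_samples``
    parameter-uniform locations (endpoints included).  The curve passes
    through every input point.
    """
    pts = points.points
    if len(pts) < 3:
        raise ParameterError(f"need >= 3 AER points, got {len(pts)}")
    if n_samples < 2:
        raise ParameterError("n_samples must be >= 2")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0):
        raise ParameterError("consecutive duplicate AER points")
    t = np.concatenate([[0.0], np.cumsum(seg)])
    spline = CubicSpline(t, pts, axis=0)
    ts = np.linspace(0.0, t[-1], n_samples)
    return LandmarkSet(spline(ts))


def fit_plane(points: LandmarkSet) -> dict:
    """Least-squares plane through 3D points.

    The normal is the smallest-eigenvalue direction of the centered
    covariance (total least squares), unit length, with a deterministic
    sign: non-negative z-component, ties broken by non-negative y then x.
    """
    pts = points.points
    if len(pts) < 3:
        raise DegenerateInputError(f"need >= 3 points to fit a plane, got {len(pts)}")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise DegenerateInputError("points are collinear: plane is undefined")
    normal = vt[-1]
    for c in (2, 1, 0):
        if abs(normal[c]) > 1e-12:
            if normal[c] < 0:
                normal = -normal
            break
    return {"normal": normal, "centroid": centroid}


def reorient_to_axis(
    normal: np.ndarray, target: np.ndarray = CANONICAL_NORMAL
) -> AffineTransform4:
    """Minimal rotation carrying ``normal`` onto ``target`` (default (0,0,−1)).

    Pure rotation (det +1, no scale or translation) about
    ``normal × target``; the antiparallel case rotates 180° about the
    x-axis by convention.
    """
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    t = np.asarray(target, dtype=float)
    t = t / np.linalg.norm(t)
    c = float(n @ t)
    axis = np.cross(n, t)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:  # already aligned
            return AffineTransform4.identity()
        rot = np.diag([1.0, -1.0, -1.0])  # 180° about x
        return AffineTransform4.from_rotation_translation(rot, (0, 0, 0))
    axis = axis / s
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    rot = np.eye(3) + s * K + (1 - c) * (K @ K)
    return AffineTransform4.from_rotation_translation(rot, (0, 0, 0))


def project_to_2d(points: LandmarkSet) -> np.ndarray:
    """Fit the AER plane, reorient its normal to (0,0,−1), drop z."""
    plane = fit_plane(points)
    rot = reorient_to_axis(plane["normal"])
    return rot.apply(points.points - plane["centroid"])[:, :2]


# ---------------------------------------------------------------------------
# staging clients


class MockStagingClient:
    """Deterministic offline staging service.

    Returns fixture stages keyed by a hash of the submitted point list, or
    a smooth fallback stage derived from the outline size (so phantom limbs
    of growing size stage monotonically).  Two identical requests always
    produce identical results.
    """

    def __init__(self, fixtures: dict[str, StageResult] | None = None):
        self.fixtures = dict(fixtures or {})

    @staticmethod
    def request_key(points_2d: np.ndarray) -> str:
        canon = np.round(np.asarray(points_2d, dtype=float), 6)
        return hashlib.sha256(canon.tobytes()).hexdigest()[:16]

    def submit(self, request: StagingRequest) -> StageResult:
        key = self.request_key(request.points_2d)
        if key in self.fixtures:
            return self.fixtures[key]
        # fallback: stage scales with outline extent inside the published
        # 249-290 window; uncertainty fixed at the system's ±2 h precision
        extent = float(np.ptp(request.points_2d, axis=0).max())
        stage = 249.0 + (extent % 41.0)
        return StageResult(stage=round(stage, 1), uncertainty=2.0, summary=f"mock:{key}")


class HTTPStagingClient:
    """Client for the live staging endpoint.

    Field names of the JSON schema are configurable because the service
    contract is external; defaults: ``points`` in, ``stage``/
    ``uncertainty``/``summary`` out.
    """

    def __init__(
        self,
        endpoint: str = DEFAULT_ENDPOINT,
        timeout: float = 30.0,
        points_field: str = "points",
        stage_field: str = "stage",
        uncertainty_field: str = "uncertainty",
        summary_field: str = "summary",
    ):
        self.endpoint = endpoint
        self.timeout = timeout
        self.points_field = points_field
        self.stage_field = stage_field
        self.uncertainty_field = uncertainty_field
        self.summary_field = summary_field

    def submit(self, request: StagingRequest) -> StageResult:
        body = request.to_json(self.points_field).encode()
        req = urllib.request.Request(
            self.endpoint, data=body, headers={"Content-Type": "application/json"}
        )
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                status = resp.status
                text = resp.read().decode("utf-8", "replace")
        except urllib.error.HTTPError as exc:
            raise StagingServiceError(
                f"staging service returned HTTP {exc.code}",
                status=exc.code,
                body=exc.read().decode("utf-8", "replace") if exc.fp else "",
            ) from exc
        except urllib.error.URLError as exc:
            raise StagingServiceError(f"staging service unreachable: {exc.reason}") from exc
        if not 200 <= status < 300:
            raise StagingServiceError(
                f"staging service returned HTTP {status}", status=status, body=text
            )
        try:
            payload = json.loads(text)
            return StageResult(
                stage=float(payload[self.stage_field]),
                uncertainty=float(payload.get(self.uncertainty_field, 0.0)),
                summary=str(payload.get(self.summary_field, "")),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise StagingServiceError(
                f"unparseable staging response: {exc}", status=status, body=text
            ) from exc


def request_stage(
    request: StagingRequest,
    client,
    ledger: ExperimentLedger | None = None,
) -> StageResult:
    """Submit a staging request and ledger-record the result.

    On service failure the error propagates and nothing is recorded — the
    pipeline never invents a default stage.
    """
    result = client.submit(request)
    if ledger is not None:
        ledger.record("stage", result.stage)
        ledger.record("stage_uncertainty", result.uncertainty)
    return result
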