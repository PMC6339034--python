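"""Geometry of the unit 2-sphere and pose sequences on its product.

A skeletal pose is encoded as the tuple of unit bone-direction vectors,
one point on S^2 per bone; a motion sample is a trajectory on the product
manifold S^2 x ... x S^2.  This module provides the log/exp maps, geodesic
distance, Karcher mean, geodesic interpolation and the conversion from
joint-position sequences to bone-direction pose sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConvergenceError,
    DegenerateBoneError,
    InvalidTangentError,
    UndefinedLogError,
)
from .skeleton_io import JointTrajectorySequence, SkeletonDefinition

_UNIT_TOL = 1e-9
_ANTIPODE_MARGIN = 1e-6


def _check_unit(x: np.ndarray, name: str = "point") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    norms = np.linalg.norm(x, axis=-1)
    if not np.all(np.abs(norms - 1.0) <= 1e-6):
        raise ValueError(f"{name} is not unit norm (|norm-1| up to "
                         f"{np.max(np.abs(norms - 1.0)):.3e})")
    return x


@dataclass(frozen=True)
class SpherePoint:
    """A point on the unit 2-sphere."""

    direction: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float).reshape(3)
        if abs(np.linalg.norm(d) - 1.0) > 1e-6:
            raise ValueError("SpherePoint direction must be unit norm")
        object.__setattr__(self, "direction", d)


@dataclass(frozen=True)
class TangentVector:
    """A vector in the tangent plane of ``base``, with arc length <= pi."""

    base: SpherePoint
    vector: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vector, dtype=float).reshape(3)
        if abs(float(self.base.direction @ v)) > 1e-6 * max(1.0, np.linalg.norm(v)):
            raise InvalidTangentError("tangent vector not orthogonal to base")
        if np.linalg.norm(v) > np.pi + 1e-9:
            raise ValueError("tangent vector longer than pi")
        object.__setattr__(self, "vector", v)


@dataclass
class PoseSequence:
    """A locomotion sample: F x B unit bone directions plus metadata."""

    directions: np.ndarray  # (F, B, 3), every row unit norm
    frame_rate: float
    subject_label: str
    sequence_id: str
    bone_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.directions = np.asarray(self.directions, dtype=float)
        if self.directions.ndim != 3 or self.directions.shape[-1] != 3:
            raise ValueError("directions must have shape (F, B, 3)")
        if self.directions.shape[0] < 2:
            raise ValueError("a pose sequence needs at least 2 frames")
        _check_unit(self.directions, "pose direction")

    @property
    def n_frames(self) -> int:
        return self.directions.shape[0]

    @property
    def n_bones(self) -> int:
        return self.directions.shape[1]

    def slice(self, start: int, stop: int) -> "PoseSequence":
        return PoseSequence(
            directions=self.directions[start:stop].copy(),
            frame_rate=self.frame_rate,
            subject_label=self.subject_label,
            sequence_id=f"{self.sequence_id}[{start}:{stop}]",
            bone_names=list(self.bone_names),
        )


# ---------------------------------------------------------------------------
# Core sphere maps (array-valued helpers first, typed wrappers below)
# ---------------------------------------------------------------------------

def log_map(base: np.ndarray, point: np.ndarray) -> np.ndarray:
    """Logarithm map on S^2, broadcasting over leading axes.

    Returns the tangent vector at ``base`` whose exp reaches ``point``;
    its norm is the geodesic angle.  Raises for (near-)antipodal pairs.
    """
    base = np.asarray(base, dtype=float)
    point = np.asarray(point, dtype=float)
    cos = np.clip(np.sum(base * point, axis=-1), -1.0, 1.0)
    theta = np.arccos(cos)
    if np.any(theta > np.pi - _ANTIPODE_MARGIN):
        raise UndefinedLogError("log map undefined at antipodal points")
    sin = np.sin(theta)
    # theta/sin(theta) -> 1 as theta -> 0
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(sin > 1e-12, theta / np.where(sin > 1e-12, sin, 1.0), 1.0)
    v = (point - cos[..., None] * base) * scale[..., None]
    # project out any numerical drift along base
    v -= np.sum(v * base, axis=-1, keepdims=True) * base
    return v


def exp_map(base: np.ndarray, tangent: np.ndarray) -> np.ndarray:
    """Exponential map on S^2, broadcasting over leading axes."""
    base = np.asarray(base, dtype=float)
    tangent = np.asarray(tangent, dtype=float)
    norm = np.linalg.norm(tangent, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(
            norm[..., None] > 1e-12, tangent / np.where(norm[..., None] > 1e-12,
                                                        norm[..., None], 1.0), 0.0)
    out = np.cos(norm)[..., None] * base + np.sin(norm)[..., None] * unit
    return out / np.linalg.norm(out, axis=-1, keepdims=True)


def sphere_log(base: SpherePoint, point: SpherePoint) -> TangentVector:
    """Log map with typed containers; see :func:`log_map`."""
    v = log_map(base.direction, point.direction)
    return TangentVector(base=base, vector=v)


def sphere_exp(base: SpherePoint, tangent: TangentVector | np.ndarray) -> SpherePoint:
    """Exp map with typed containers; validates tangency."""
    if isinstance(tangent, TangentVector):
        v = tangent.vector
    else:
        v = np.asarray(tangent, dtype=float).reshape(3)
        if abs(float(base.direction @ v)) > 1e-6 * max(1.0, np.linalg.norm(v)):
            raise InvalidTangentError("tangent vector not orthogonal to base")
    return SpherePoint(exp_map(base.direction, v))


def geodesic_distance(x: np.ndarray | SpherePoint, m: np.ndarray | SpherePoint) -> float:
    """Great-circle arc length (radians) between two unit vectors.

    Equals arccos of the clamped inner product; evaluated through atan2 of
    chord lengths, which stays accurate near 0 and pi where arccos loses
    half the significant digits.
    """
    if isinstance(x, SpherePoint):
        x = x.direction
    if isinstance(m, SpherePoint):
        m = m.direction
    x = _check_unit(x)
    m = _check_unit(m)
    return float(geodesic_distance_many(x, m))


def geodesic_distance_many(x: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Arc lengths, broadcasting over leading axes of unit-vector arrays."""
    x = np.asarray(x, float)
    m = np.asarray(m, float)
    diff = np.linalg.norm(x - m, axis=-1)
    summ = np.linalg.norm(x + m, axis=-1)
    return 2.0 * np.arctan2(diff / 2.0, summ / 2.0)


# ---------------------------------------------------------------------------
# Karcher mean
# ---------------------------------------------------------------------------

def karcher_mean(
    points,
    eps1: float = 1e-6,
    eps2: float = 1.0,
    max_iter: int = 100,
):
    """Riemannian (Karcher) mean of points on S^2.

    Iterates ``m <- exp_m(eps2 * mean_s log_m(x_s))`` until the mean tangent
    has norm <= ``eps1``.  Points are assumed to lie in an open hemisphere,
    which guarantees a unique minimizer of the summed squared distances.

    Accepts a list of :class:`SpherePoint` or an (S, 3) array; returns the
    matching type.
    """
    typed = len(points) > 0 and isinstance(points[0], SpherePoint)
    if typed:
        pts = np.stack([p.direction for p in points])
    else:
        pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("karcher_mean needs at least one point")
    pts = _check_unit(pts)

    m = pts[0].copy()
    for _ in range(max_iter + 1):
        v = log_map(m[None, :], pts)
        vbar = v.mean(axis=0)
        resid = float(np.linalg.norm(vbar))
        if resid <= eps1:
            return SpherePoint(m) if typed else m
        m = exp_map(m, eps2 * vbar)
    raise ConvergenceError(
        f"Karcher mean did not converge in {max_iter} iterations "
        f"(last |v| = {resid:.3e})", residual=resid)


def geodesic_interpolate(x_f, x_w, n_intermediate: int):
    """``n_intermediate`` equally spaced points strictly between two sphere points.

    Cuts the log of ``x_w`` at ``x_f`` into ``n_intermediate + 1`` equal
    parts and maps the cut points back with exp, so all consecutive gaps
    (endpoints included) equal ``d(x_f, x_w) / (n_intermediate + 1)``.
    """
    typed = isinstance(x_f, SpherePoint)
    a = x_f.direction if typed else np.asarray(x_f, dtype=float)
    b = x_w.direction if isinstance(x_w, SpherePoint) else np.asarray(x_w, dtype=float)
    if n_intermediate < 0:
        raise ValueError("n_intermediate must be >= 0")
    v = log_map(a, b)
    out = []
    for k in range(1, n_intermediate + 1):
        p = exp_map(a, (k / (n_intermediate + 1)) * v)
        out.append(SpherePoint(p) if typed else p)
    return out


def slerp(a: np.ndarray, b: np.ndarray, t: float | np.ndarray) -> np.ndarray:
    """Geodesic interpolation at parameter ``t`` in [0, 1], broadcastable."""
    v = log_map(a, b)
    t = np.asarray(t, dtype=float)
    return exp_map(a, t[..., None] * v if t.ndim else t * v)


# ---------------------------------------------------------------------------
# Position sequences -> pose sequences
# ---------------------------------------------------------------------------

def to_pose_sequence(
    seq: JointTrajectorySequence, skeleton: SkeletonDefinition
) -> PoseSequence:
    """Convert joint positions to unit parent->child bone directions.

    Bone lengths are discarded, so the representation is blind to static
    skeleton size.  A bone shorter than 1e-9 in any frame is rejected.
    """
    if seq.n_joints != skeleton.n_joints:
        raise ValueError(
            f"sequence has {seq.n_joints} joints, skeleton {skeleton.n_joints}")
    pos = seq.positions
    parents = np.array([p for p, _ in skeleton.bone_indices])
    children = np.array([c for _, c in skeleton.bone_indices])
    vec = pos[:, children, :] - pos[:, parents, :]
    lengths = np.linalg.norm(vec, axis=-1)
    if np.any(lengths < 1e-9):
        f, b = np.argwhere(lengths < 1e-9)[0]
        raise DegenerateBoneError(
            f"bone '{skeleton.bones[b][0]}->{skeleton.bones[b][1]}' degenerate "
            f"at frame {f} (length {lengths[f, b]:.3e})")
    return PoseSequence(
        directions=vec / lengths[..., None],
        frame_rate=seq.frame_rate,
        subject_label=seq.subject_label,
        sequence_id=seq.sequence_id,
        bone_names=[f"{p}->{c}" for p, c in skeleton.bones],
    )
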