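"""Spatial and temporal feature extraction on the manifold.

The aligned mean motion sequence holds one per-frame, per-bone Karcher mean
over all training cycles.  A cycle's spatial feature is the matrix of
geodesic distances to that mean; its temporal feature stacks the upper
triangles of covariance matrices computed over a two-level hierarchy of
(overlapping) frame windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConvergenceError, WindowTooSmallError
from .manifold import PoseSequence, geodesic_distance_many, karcher_mean


@dataclass
class MeanSequence:
    """Per-frame, per-bone Karcher-mean poses over a set of aligned cycles."""

    mean_poses: np.ndarray  # (F, B, 3) unit vectors
    convergence_report: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.mean_poses.shape[0]

    @property
    def n_bones(self) -> int:
        return self.mean_poses.shape[1]


@dataclass
class GeometricFeatureMatrix:
    """F x B geodesic distances to the mean sequence (radians)."""

    G: np.ndarray

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=float)
        if np.any(self.G < -1e-12) or np.any(self.G > np.pi + 1e-9):
            raise ValueError("geodesic features must lie in [0, pi]")

    @property
    def flattened(self) -> np.ndarray:
        """Row-major (frame-major) flattening, length F*B."""
        return self.G.reshape(-1)


@dataclass
class CovarianceDescriptor:
    """Hierarchical window covariances with their flattened upper triangles."""

    windows: list[tuple[int, int]]
    matrices: list[np.ndarray]

    def __post_init__(self):
        for c in self.matrices:
            if not np.allclose(c, c.T, atol=1e-10):
                raise ValueError("covariance matrix not symmetric")

    @property
    def flattened(self) -> np.ndarray:
        """Concatenated upper triangles (diagonal included), window order."""
        parts = []
        for c in self.matrices:
            iu = np.triu_indices(c.shape[0])
            parts.append(c[iu])
        return np.concatenate(parts)


def compute_mean_sequence(
    aligned_cycles: list[PoseSequence],
    eps1: float = 1e-6,
    eps2: float = 1.0,
    max_iter: int = 100,
) -> MeanSequence:
    """Karcher mean per (frame, bone) across aligned cycles."""
    if len(aligned_cycles) == 0:
        raise ValueError("need at least one cycle")
    shapes = {c.directions.shape for c in aligned_cycles}
    if len(shapes) != 1:
        raise ValueError(f"cycles have mismatched shapes: {shapes}")
    stack = np.stack([c.directions for c in aligned_cycles])  # (S, F, B, 3)
    s, f, b, _ = stack.shape
    means = np.empty((f, b, 3))
    worst_resid = 0.0
    for fi in range(f):
        for bi in range(b):
            try:
                means[fi, bi] = karcher_mean(
                    stack[:, fi, bi, :], eps1=eps1, eps2=eps2, max_iter=max_iter)
            except ConvergenceError as exc:
                raise ConvergenceError(
                    f"Karcher mean failed at frame {fi}, bone {bi}: {exc}",
                    residual=exc.residual) from exc
    report = {"eps1": eps1, "eps2": eps2, "max_iter": max_iter,
              "n_cycles": s, "worst_residual_bound": eps1 + worst_resid}
    return MeanSequence(mean_poses=means, convergence_report=report)


def geometric_features(
    cycle: PoseSequence, mean_seq: MeanSequence
) -> GeometricFeatureMatrix:
    """G[f, j] = geodesic distance between the cycle and the mean pose."""
    if cycle.directions.shape != mean_seq.mean_poses.shape:
        raise ValueError(
            f"cycle shape {cycle.directions.shape} does not match mean "
            f"{mean_seq.mean_poses.shape}")
    return GeometricFeatureMatrix(
        geodesic_distance_many(cycle.directions, mean_seq.mean_poses))


def covariance_window(G: GeometricFeatureMatrix, f1: int, f2: int) -> np.ndarray:
    """Unbiased sample covariance of the feature rows in window [f1, f2)."""
    n = f2 - f1
    if n < 2:
        raise WindowTooSmallError(f"window [{f1},{f2}) has {n} < 2 frames")
    rows = G.G[f1:f2]
    centered = rows - rows.mean(axis=0, keepdims=True)
    return centered.T @ centered / (n - 1)


def hierarchy_windows(
    n_frames: int,
    scheme: str = "figure",
    window_length: int | None = None,
    n_windows: int = 7,
) -> list[tuple[int, int]]:
    """Half-open frame windows of the two-level temporal hierarchy.

    ``figure``: one top-level window over all frames plus ``n_windows``
    overlapping second-level windows of length ``window_length`` (default
    floor(F/4)) with starts evenly spread over the sequence.  ``paper_dim``
    keeps only the second level (seven blocks -> 7*B*(B+1)/2 features).
    """
    if scheme not in {"figure", "paper_dim", "custom"}:
        raise ValueError(f"unknown hierarchy scheme '{scheme}'")
    w = window_length if window_length is not None else n_frames // 4
    if w < 2 or n_frames < 8 or w > n_frames:
        raise ValueError(
            f"F={n_frames} too small for hierarchy (window length {w})")
    if n_windows < 1:
        raise ValueError("need at least one second-level window")
    if n_windows == 1:
        starts = [0]
    else:
        starts = [(k * (n_frames - w)) // (n_windows - 1) for k in range(n_windows)]
    windows = [(s, s + w) for s in starts]
    if scheme != "paper_dim":
        windows = [(0, n_frames)] + windows
    return windows


def temporal_hierarchy(
    G: GeometricFeatureMatrix,
    scheme: str = "figure",
    window_length: int | None = None,
    n_windows: int = 7,
) -> CovarianceDescriptor:
    """Covariance descriptor over the hierarchy windows of the sequence."""
    f = G.G.shape[0]
    windows = hierarchy_windows(f, scheme, window_length, n_windows)
    mats = [covariance_window(G, a, b) for a, b in windows]
    return CovarianceDescriptor(windows=windows, matrices=mats)
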