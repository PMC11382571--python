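"""Alignment of a reconstructed cloud into the ground-truth frame.

Two steps mirror the field workflow for benchmarking reconstructions
against terrestrial-laser-scan ground truth:

1. *Correspondence-based initialization* — a least-squares similarity
   transform (scale, rotation, translation; the Umeyama solution) from a
   handful of manually picked point pairs, typically four.
2. *ICP refinement* — rigid point-to-point iterative closest point on
   voxel-downsampled clouds.  Two variants are provided:

   * ``three_stage``: the multiscale schedule of the Tanks-and-Temples
     style protocol — full voxel size, half voxel size, then full voxel
     size again with a tightened correspondence threshold;
   * ``single``: a single stage whose iteration budget is multiplied
     (10x by default), which on thin plant structures avoids the
     collapse the stage transitions can trigger.

Scale is estimated only during initialization and held fixed through ICP;
the ICP refinement itself is rigid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
from scipy.spatial import cKDTree

from plantrecon.cloud_io import PointCloud

__all__ = [
    "SimilarityTransform",
    "IcpConfig",
    "RegistrationResult",
    "DegenerateGeometryError",
    "RegistrationError",
    "estimate_initial_transform",
    "apply_transform",
    "icp_refine",
    "voxel_downsample",
    "load_correspondences",
]


class DegenerateGeometryError(ValueError):
    """Correspondence geometry too degenerate to determine a transform."""


class RegistrationError(RuntimeError):
    """ICP failed to find any correspondences; carries the initial transform."""

    def __init__(self, message: str, transform: "SimilarityTransform"):
        super().__init__(message)
        self.transform = transform


@dataclass(frozen=True)
class SimilarityTransform:
    """``p -> scale * rotation @ p + translation``.

    ``rotation`` is a proper orthonormal 3x3 matrix (det +1), ``scale`` a
    positive scalar, ``translation`` a 3-vector in meters.
    """

    scale: float
    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=np.float64))
        object.__setattr__(self, "translation",
                           np.asarray(self.translation, dtype=np.float64).reshape(3))
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        R = self.rotation
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal (R^T R = I within 1e-9)")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det +1)")

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(1.0, np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * points @ self.rotation.T + self.translation

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return SimilarityTransform(
            self.scale * other.scale,
            self.rotation @ other.rotation,
            self.scale * self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "SimilarityTransform":
        Rinv = self.rotation.T
        return SimilarityTransform(
            1.0 / self.scale, Rinv, -(Rinv @ self.translation) / self.scale)

    def as_matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        M = np.eye(4)
        M[:3, :3] = self.scale * self.rotation
        M[:3, 3] = self.translation
        return M

    def to_dict(self) -> dict:
        return {"scale": float(self.scale),
                "rotation": self.rotation.tolist(),
                "translation": self.translation.tolist()}

    @classmethod
    def from_dict(cls, obj: dict) -> "SimilarityTransform":
        return cls(float(obj["scale"]), np.asarray(obj["rotation"]),
                   np.asarray(obj["translation"]))


@dataclass(frozen=True)
class IcpConfig:
    """Parameters of the ICP refinement.

    voxel_size
        Edge (m) of the grid used to downsample both clouds before
        correspondence search.
    distance_threshold
        Maximum correspondence distance (m).
    base_iterations
        Iteration budget of one stage.
    iteration_multiplier
        Budget multiplier applied in ``single`` mode (10 by default).
    stages
        ``"single"`` or ``"three_stage"``.
    convergence_tolerance
        Stop early when the relative change of fitness and of inlier RMSE
        both fall below this value.
    """

    voxel_size: float = 0.01
    distance_threshold: float = 0.02
    base_iterations: int = 30
    iteration_multiplier: int = 10
    stages: str = "single"
    convergence_tolerance: float = 1e-7

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if self.base_iterations < 1 or self.iteration_multiplier < 1:
            raise ValueError("iteration counts must be >= 1")
        if self.stages not in ("single", "three_stage"):
            raise ValueError("stages must be 'single' or 'three_stage'")


@dataclass
class RegistrationResult:
    transform: SimilarityTransform
    inlier_rmse: float
    fitness: float
    iterations_run: int


def load_correspondences(path: Union[str, Path]) -> Tuple[np.ndarray, np.ndarray]:
    """Read a ``{"source": [[x,y,z],...], "target": [[x,y,z],...]}`` JSON file."""
    with open(path) as fh:
        obj = json.load(fh)
    src = np.asarray(obj["source"], dtype=float)
    tgt = np.asarray(obj["target"], dtype=float)
    return src, tgt


def estimate_initial_transform(
    source_points: np.ndarray, target_points: np.ndarray
) -> SimilarityTransform:
    """Least-squares similarity transform from paired correspondences.

    Closed-form Umeyama solution minimizing
    ``sum_i || s R src_i + t - tgt_i ||^2``.  Exact when the
    correspondences are noise-free.  Requires at least three
    non-collinear pairs.
    """
    src = np.asarray(source_points, dtype=np.float64)
    tgt = np.asarray(target_points, dtype=np.float64)
    if src.ndim != 2 or src.shape[1] != 3 or src.shape != tgt.shape:
        raise ValueError("source and target must be matching (N, 3) arrays")
    n = src.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need at least 3 correspondences, got {n}")
    mu_s, mu_t = src.mean(axis=0), tgt.mean(axis=0)
    src_c, tgt_c = src - mu_s, tgt - mu_t
    cov = tgt_c.T @ src_c / n
    var_s = (src_c**2).sum() / n
    U, D, Vt = np.linalg.svd(cov)
    # collinear (or coincident) sources leave the rotation underdetermined
    if np.linalg.matrix_rank(src_c, tol=1e-10 * max(1.0, np.abs(src_c).max())) < 2:
        raise DegenerateGeometryError("correspondence points are collinear or coincident")
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    # exactly rank-2 configurations (planar) are fine: the reflection fix above
    # already picks the proper rotation
    scale = float(np.trace(np.diag(D) @ S) / var_s)
    if scale <= 0:
        raise DegenerateGeometryError("estimated non-positive scale")
    t = mu_t - scale * R @ mu_s
    return SimilarityTransform(scale, R, t)


def apply_transform(cloud: PointCloud, transform: SimilarityTransform) -> PointCloud:
    """Map every point through the similarity transform; colors unchanged."""
    return PointCloud(transform.apply(cloud.points), cloud.colors)


def voxel_downsample(points: np.ndarray, voxel_size: float) -> np.ndarray:
    """One representative (centroid) per occupied voxel, deterministic order.

    Voxels are keyed on ``floor(p / voxel_size)``; output rows are ordered
    by first occurrence of each voxel in the input.
    """
    keys = np.floor(points / voxel_size).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    sums = np.zeros((len(first), 3))
    np.add.at(sums, inverse, points)
    counts = np.bincount(inverse, minlength=len(first)).astype(float)
    centroids = sums / counts[:, None]
    order = np.argsort(first, kind="stable")
    return centroids[order]


def _icp_stage(
    src: np.ndarray,
    tgt_tree: cKDTree,
    tgt: np.ndarray,
    R: np.ndarray,
    t: np.ndarray,
    threshold: float,
    max_iterations: int,
    tol: float,
) -> Tuple[np.ndarray, np.ndarray, float, float, int]:
    """Rigid point-to-point ICP from (R, t); returns updated pose + stats."""
    prev_fitness, prev_rmse = -1.0, np.inf
    fitness, rmse = 0.0, np.inf
    iters = 0
    for iters in range(1, max_iterations + 1):
        moved = src @ R.T + t
        dists, idx = tgt_tree.query(moved, distance_upper_bound=threshold)
        mask = np.isfinite(dists)
        n_in = int(mask.sum())
        if n_in == 0:
            return R, t, 0.0, np.inf, iters
        fitness = n_in / len(src)
        rmse = float(np.sqrt(np.mean(dists[mask] ** 2)))
        # Kabsch update on the current inlier correspondences
        a = src[mask]
        b = tgt[idx[mask]]
        mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
        H = (b - mu_b).T @ (a - mu_a)
        U, _, Vt = np.linalg.svd(H)
        S = np.eye(3)
        if np.linalg.det(U) * np.linalg.det(Vt) < 0:
            S[2, 2] = -1.0
        R = U @ S @ Vt
        t = mu_b - R @ mu_a
        if prev_fitness >= 0:
            df = abs(fitness - prev_fitness) / max(prev_fitness, 1e-300)
            dr = abs(rmse - prev_rmse) / max(prev_rmse, 1e-300)
            if df < tol and dr < tol:
                break
        prev_fitness, prev_rmse = fitness, rmse
    # report the statistics at the final pose, not the pre-update one
    moved = src @ R.T + t
    dists, _ = tgt_tree.query(moved, distance_upper_bound=threshold)
    mask = np.isfinite(dists)
    if mask.any():
        fitness = float(mask.mean())
        rmse = float(np.sqrt(np.mean(dists[mask] ** 2)))
    else:
        fitness, rmse = 0.0, np.inf
    return R, t, fitness, rmse, iters


def icp_refine(
    source: PointCloud,
    target: PointCloud,
    initial: SimilarityTransform,
    config: IcpConfig = IcpConfig(),
) -> RegistrationResult:
    """Refine an initial alignment with rigid point-to-point ICP.

    The source cloud is first mapped through ``initial`` (whose scale is
    frozen thereafter); both clouds are voxel-downsampled at
    ``config.voxel_size`` before correspondence search.  ``three_stage``
    reruns at half voxel size and then at the original voxel size with
    the correspondence threshold halved; ``single`` runs one stage for
    ``base_iterations * iteration_multiplier`` iterations.  Fully
    deterministic.
    """
    if source.count < 10 or target.count < 10:
        raise ValueError("ICP needs at least 10 points in each cloud")
    src0 = initial.apply(source.points)

    schedule = []
    if config.stages == "three_stage":
        schedule = [
            (config.voxel_size, config.distance_threshold, config.base_iterations),
            (config.voxel_size / 2, config.distance_threshold, config.base_iterations),
            (config.voxel_size, config.distance_threshold * 0.5, config.base_iterations),
        ]
    else:
        schedule = [(config.voxel_size, config.distance_threshold,
                     config.base_iterations * config.iteration_multiplier)]

    R = np.eye(3)
    t = np.zeros(3)
    total_iters = 0
    fitness, rmse = 0.0, np.inf
    first_stage = True
    for voxel, threshold, iters in schedule:
        src = voxel_downsample(src0, voxel)
        tgt = voxel_downsample(target.points, voxel)
        tree = cKDTree(tgt)
        if first_stage:
            d0, _ = tree.query(src @ R.T + t, distance_upper_bound=threshold)
            if not np.isfinite(d0).any():
                raise RegistrationError(
                    "no correspondences within threshold at the initial alignment",
                    initial)
            first_stage = False
        R, t, fitness, rmse, it = _icp_stage(
            src, tree, tgt, R, t, threshold, iters, config.convergence_tolerance)
        total_iters += it

    # final pose: rigid (R, t) composed with the scaled initial transform
    final = SimilarityTransform(1.0, R, t).compose(initial)
    return RegistrationResult(final, rmse, fitness, total_iters)
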