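"""Seeded synthetic fixtures emulating the benchmark's data sources.

Real inputs to the evaluation workflow are (a) a dense TLS scan of a plant
(~7 mm point spacing) as ground truth, (b) a radiance-field export of the
same scene — roughly a million points with jitter, dropout, stray
outliers, and an unknown similarity transform — and (c) an average-LPIPS
training curve that decays towards a plateau.  The generators here produce
deterministic stand-ins for all three, plus textured image pairs for the
2D metrics, so the entire pipeline is testable without GPUs or downloads.

Every generator is a pure function of its parameters and seed.  A single
pipeline seed fans out to per-stage child seeds via fixed offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from plantrecon.cloud_io import PointCloud
from plantrecon.image_metrics import Raster
from plantrecon.registration import SimilarityTransform
from plantrecon.training_monitor import MetricSeries

__all__ = [
    "PlantParams",
    "DegradeParams",
    "generate_plant_cloud",
    "degrade_cloud",
    "generate_training_curve",
    "generate_image_pair",
]


@dataclass(frozen=True)
class PlantParams:
    """Geometry and sampling of the synthetic plant.

    The plant is a vertical cylindrical stem with ``leaf_count`` parabolic
    ribbon leaves attached at evenly spaced nodes; surfaces are sampled
    uniformly by area at ``sampling_density`` points per square meter
    (2e4 / m^2 gives ~7 mm spacing, the TLS-like default).
    """

    stem_height: float = 1.2
    stem_radius: float = 0.01
    leaf_count: int = 8
    leaf_length: float = 0.25
    leaf_width: float = 0.05
    leaf_droop: float = 0.8
    sampling_density: float = 2.0e4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.stem_height, self.stem_radius, self.leaf_length,
               self.leaf_width, self.sampling_density) <= 0:
            raise ValueError("physical parameters must be positive")
        if self.leaf_count < 0:
            raise ValueError("leaf_count must be >= 0")


@dataclass(frozen=True)
class DegradeParams:
    """Degradations applied, in order: transform, jitter, dropout, outliers."""

    jitter_sigma: float = 0.0
    dropout_fraction: float = 0.0
    outlier_fraction: float = 0.0
    outlier_scale: float = 0.5
    transform: Optional[SimilarityTransform] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_fraction < 1.0):
            raise ValueError("dropout_fraction must lie in [0, 1)")
        if self.outlier_fraction < 0 or self.jitter_sigma < 0:
            raise ValueError("jitter_sigma and outlier_fraction must be >= 0")


def _stem_area(p: PlantParams) -> float:
    return 2.0 * np.pi * p.stem_radius * p.stem_height


def _leaf_area(p: PlantParams) -> float:
    # ribbon parameterized on [0, L] x [0, W]; droop curls it but the
    # parabolic arc stretches length only mildly — use arc-length factor
    s = p.leaf_droop
    # arc length of z = -s*u^2 for u in [0, L]: integrate sqrt(1 + (2 s u)^2)
    u = np.linspace(0.0, p.leaf_length, 257)
    arc = np.trapezoid(np.sqrt(1.0 + (2 * s * u) ** 2), u)
    return arc * p.leaf_width


def plant_surface_area(params: PlantParams) -> float:
    """Total sampled surface area (stem + leaves) in m^2."""
    return _stem_area(params) + params.leaf_count * _leaf_area(params)


def generate_plant_cloud(params: PlantParams = PlantParams()) -> PointCloud:
    """Sample a plant-like surface point cloud; deterministic per seed.

    Point counts per surface are Poisson with mean ``density * area``;
    points are uniform by area on each surface.
    """
    rng = np.random.default_rng(params.seed)
    pts = []

    n_stem = rng.poisson(params.sampling_density * _stem_area(params))
    if n_stem > 0:
        theta = rng.uniform(0, 2 * np.pi, n_stem)
        z = rng.uniform(0, params.stem_height, n_stem)
        pts.append(np.column_stack([
            params.stem_radius * np.cos(theta),
            params.stem_radius * np.sin(theta), z]))

    leaf_area = _leaf_area(params)
    for i in range(params.leaf_count):
        n_leaf = rng.poisson(params.sampling_density * leaf_area)
        if n_leaf == 0:
            continue
        # attachment node, evenly spaced along the stem, alternating azimuth
        frac = (i + 1) / (params.leaf_count + 1)
        z0 = frac * params.stem_height
        azim = i * (2 * np.pi / max(params.leaf_count, 1)) + 0.7
        # ribbon coordinates: u along the leaf, v across
        u = rng.uniform(0, params.leaf_length, n_leaf)
        v = rng.uniform(-params.leaf_width / 2, params.leaf_width / 2, n_leaf)
        droop = -params.leaf_droop * u**2
        local = np.column_stack([u, v, droop])
        c, s = np.cos(azim), np.sin(azim)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        world = local @ rot.T + np.array([params.stem_radius * c,
                                          params.stem_radius * s, z0])
        pts.append(world)

    if not pts:
        raise ValueError("sampling density too low: zero points generated")
    cloud = np.vstack(pts)
    if len(cloud) == 0:
        raise ValueError("sampling density too low: zero points generated")
    return PointCloud(cloud)


def degrade_cloud(cloud: PointCloud, params: DegradeParams) -> PointCloud:
    """Emulate a reconstruction export from a clean cloud.

    Applies in order: the optional similarity transform, Gaussian jitter,
    uniform dropout, and uniform outlier injection inside the cloud's
    bounding box inflated by ``outlier_scale`` on every side.
    Deterministic per seed.
    """
    rng = np.random.default_rng(params.seed)
    pts = cloud.points.copy()
    colors = cloud.colors
    if params.transform is not None:
        pts = params.transform.apply(pts)
    if params.jitter_sigma > 0:
        pts = pts + rng.normal(0.0, params.jitter_sigma, pts.shape)
    if params.dropout_fraction > 0:
        keep = rng.random(len(pts)) >= params.dropout_fraction
        if not keep.any():
            keep[rng.integers(len(pts))] = True
        pts = pts[keep]
        colors = colors[keep] if colors is not None else None
    if params.outlier_fraction > 0:
        n_out = int(round(params.outlier_fraction * len(pts)))
        if n_out > 0:
            lo = pts.min(axis=0) - params.outlier_scale
            hi = pts.max(axis=0) + params.outlier_scale
            outliers = rng.uniform(lo, hi, (n_out, 3))
            pts = np.vstack([pts, outliers])
            if colors is not None:
                colors = np.vstack([colors,
                                    np.zeros((n_out, 3), dtype=np.uint8)])
    return PointCloud(pts, colors)


def generate_training_curve(
    plateau_iteration: int,
    start_value: float = 0.6,
    floor_value: float = 0.1,
    noise_sigma: float = 0.0,
    checkpoints: Sequence[int] = (1000, 2000, 4000, 8000, 16000, 24000, 32000,
                                  40000, 48000, 56000, 60000),
    seed: int = 0,
) -> MetricSeries:
    """Exponential LPIPS-like decay with an engineered plateau.

    The decay rate is set so the curve closes 99% of the start-to-floor gap
    at ``plateau_iteration``; beyond that it is flat to within 1% of the
    amplitude.  Seeded Gaussian noise of ``noise_sigma`` is added when
    requested.
    """
    checkpoints = np.asarray(sorted(int(c) for c in checkpoints), dtype=np.int64)
    if start_value <= floor_value or floor_value < 0:
        raise ValueError("need start_value > floor_value >= 0")
    t0 = checkpoints[0]
    if not (t0 <= plateau_iteration <= checkpoints[-1]):
        raise ValueError("plateau_iteration must lie within the checkpoint span")
    span = max(plateau_iteration - t0, 1)
    k = np.log(100.0) / span  # 1% of the amplitude remains at the plateau
    values = floor_value + (start_value - floor_value) * np.exp(
        -k * (checkpoints - t0))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sigma, len(values))
    return MetricSeries(checkpoints, values)


def generate_image_pair(
    size: Tuple[int, int] = (64, 64),
    degradation: str = "none",
    amount: float = 0.0,
    seed: int = 0,
) -> Tuple[Raster, Raster]:
    """A textured base image and a degraded copy (both 8-bit grayscale).

    ``degradation`` is one of ``none``, ``gaussian_noise`` (sigma =
    ``amount`` intensity levels), ``blur`` (Gaussian radius ``amount``
    pixels), or ``intensity_shift`` (constant offset of ``amount``
    levels, clipped-free by construction: the base stays in
    ``[amount, 255]`` headroom).
    """
    m, n = size
    if m < 8 or n < 8:
        raise ValueError("image must be at least 8x8")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:m, 0:n].astype(float)
    base = (110.0
            + 60.0 * np.sin(2 * np.pi * xx / max(n / 4, 1))
            + 45.0 * np.cos(2 * np.pi * yy / max(m / 5, 1))
            + 10.0 * rng.standard_normal((m, n)))
    base = np.clip(base, 16.0, 239.0)  # leave headroom for shifts/noise

    if degradation == "none":
        test = base.copy()
    elif degradation == "gaussian_noise":
        test = np.clip(base + rng.normal(0.0, amount, (m, n)), 0.0, 255.0)
    elif degradation == "blur":
        test = ndimage.gaussian_filter(base, sigma=amount, mode="reflect")
    elif degradation == "intensity_shift":
        test = base + amount
        if test.max() > 255.0 or test.min() < 0.0:
            raise ValueError("intensity_shift pushes pixels out of range")
    else:
        raise ValueError(f"unknown degradation {degradation!r}")
    return Raster(base), Raster(test)
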