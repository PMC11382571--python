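"""Early stopping of radiance-field training from a perceptual-metric series.

Training checkpoints (often exponentially spaced) provide an average-LPIPS
value each; the series is linearly interpolated onto a uniform grid and
scanned for a *plateau*: the first index ``i`` at which ``C`` consecutive
absolute successive differences all stay below a threshold ``theta``.  The
recommended stopping iteration is the grid iteration at ``i + C`` — the
first moment an online monitor can confirm the plateau.

Defaults mirror the published configuration: ``theta = 0.005``, ``C = 6``,
interpolation granularity 1,000 points, spanning 60,000 iterations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from plantrecon.image_metrics import FeatureBackbone, Raster, lpips

__all__ = [
    "MetricSeries",
    "PlateauConfig",
    "PlateauResult",
    "build_series",
    "interpolate_series",
    "detect_plateau",
    "pearson_correlation",
    "correlation_report",
    "recommend_stop",
    "load_series",
    "save_series",
]


@dataclass(frozen=True)
class MetricSeries:
    """Parallel (iteration, value) arrays; iterations strictly increasing."""

    iterations: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        it = np.asarray(self.iterations, dtype=np.int64)
        vals = np.asarray(self.values, dtype=np.float64)
        if it.ndim != 1 or it.shape != vals.shape:
            raise ValueError("iterations and values must be parallel 1-D arrays")
        if len(it) and (np.any(np.diff(it) <= 0) or it[0] < 0):
            raise ValueError("iterations must be non-negative and strictly increasing")
        object.__setattr__(self, "iterations", it)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.iterations)


@dataclass(frozen=True)
class PlateauConfig:
    """theta: change threshold; consistency: required consecutive sub-theta
    steps; granularity: interpolation grid size; total_iterations: grid end."""

    theta: float = 0.005
    consistency: int = 6
    granularity: int = 1000
    total_iterations: int = 60000

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.consistency < 1:
            raise ValueError("consistency must be >= 1")
        if self.granularity < 2:
            raise ValueError("granularity must be >= 2")


@dataclass(frozen=True)
class PlateauResult:
    found: bool
    plateau_index: Optional[int]
    recommended_iteration: int


def load_series(path: Union[str, Path]) -> MetricSeries:
    """Read an ``iteration,value`` CSV into a series (sorted by iteration)."""
    df = pd.read_csv(path)
    missing = {"iteration", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: series CSV missing columns {sorted(missing)}")
    df = df.sort_values("iteration")
    return MetricSeries(df["iteration"].to_numpy(), df["value"].to_numpy())


def save_series(series: MetricSeries, path: Union[str, Path]) -> None:
    pd.DataFrame({"iteration": series.iterations, "value": series.values}).to_csv(
        path, index=False)


def build_series(
    checkpoints: Sequence[Tuple[int, Sequence[Raster]]],
    validation: Sequence[Raster],
    backbone: FeatureBackbone,
) -> MetricSeries:
    """Average LPIPS per checkpoint against the validation set, sorted.

    Each checkpoint supplies one rendered image per validation image, in
    matching order.
    """
    if len(checkpoints) < 2:
        raise ValueError("need at least 2 checkpoints")
    iters = [int(it) for it, _ in checkpoints]
    if len(set(iters)) != len(iters):
        raise ValueError("duplicate checkpoint iterations")
    entries = []
    for it, rendered in checkpoints:
        if len(rendered) != len(validation):
            raise ValueError(
                f"checkpoint {it}: {len(rendered)} renders vs {len(validation)} validation images")
        mean_lpips = float(np.mean([lpips(r, v, backbone)
                                    for r, v in zip(rendered, validation)]))
        entries.append((int(it), mean_lpips))
    entries.sort(key=lambda e: e[0])
    return MetricSeries([e[0] for e in entries], [e[1] for e in entries])


def interpolate_series(series: MetricSeries, config: PlateauConfig) -> MetricSeries:
    """Piecewise-linear resampling onto a uniform grid.

    The grid spans ``[first checkpoint iteration, total_iterations]`` with
    ``granularity`` points.  Beyond the last checkpoint the last value is
    held constant, so no slope is fabricated past the data.
    """
    if len(series) < 2:
        raise ValueError("interpolation needs at least 2 points")
    grid = np.linspace(series.iterations[0], config.total_iterations, config.granularity)
    vals = np.interp(grid, series.iterations, series.values)  # np.interp clamps ends
    return MetricSeries(np.round(grid).astype(np.int64), vals)


def detect_plateau(series: MetricSeries, config: PlateauConfig) -> PlateauResult:
    """First window of ``C`` consecutive absolute diffs below ``theta``.

    Returns the smallest index ``i`` with ``|v[j+1]-v[j]| < theta`` for all
    ``j in [i, i+C-1]``; the recommended iteration is the grid iteration at
    ``i + C``.  When no window qualifies, ``found`` is False and the final
    iteration is recommended.
    """
    c = config.consistency
    if len(series) <= c:
        raise ValueError(f"series too short for consistency length {c}")
    small = np.abs(np.diff(series.values)) < config.theta
    # rolling all-true test over windows of length c
    ok = np.convolve(small.astype(int), np.ones(c, dtype=int), mode="valid") == c
    idx = np.flatnonzero(ok)
    if len(idx) == 0:
        return PlateauResult(False, None, int(series.iterations[-1]))
    i = int(idx[0])
    return PlateauResult(True, i, int(series.iterations[i + c]))


def pearson_correlation(a: Sequence[float], b: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient (ddof=1 convention)."""
    x = np.asarray(a, dtype=np.float64)
    y = np.asarray(b, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    xc, yc = x - x.mean(), y - y.mean()
    sx, sy = np.sqrt((xc**2).sum()), np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        raise ValueError("undefined correlation: zero-variance input")
    return float((xc * yc).sum() / (sx * sy))


def correlation_report(metric_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson matrix over metric columns (unit diagonal, symmetric)."""
    if len(metric_table) < 3:
        raise ValueError("need at least 3 rows")
    cols = list(metric_table.columns)
    mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            r = pearson_correlation(metric_table[a].to_numpy(),
                                    metric_table[b].to_numpy())
            mat.loc[a, b] = mat.loc[b, a] = r
    return mat


def recommend_stop(
    series: MetricSeries, config: PlateauConfig = PlateauConfig()
) -> Tuple[int, PlateauResult]:
    """Interpolate, detect the plateau, and recommend a stop iteration.

    Returns ``(iteration, PlateauResult)``; when no plateau is found the
    recommendation falls back to ``total_iterations``.
    """
    interp = interpolate_series(series, config)
    result = detect_plateau(interp, config)
    if not result.found:
        return int(config.total_iterations), result
    return result.recommended_iteration, result
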