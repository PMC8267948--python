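"""Conduction velocity, phase distribution and conduction heterogeneity index.

Conduction velocity comes from local vectors within each triangle of electrodes:
every unit grid cell splits into two right triangles (along the lower-left to
upper-right diagonal, for determinism), a plane T(x, y) = a x + b y + c is fitted
through the three (position, LAT) points, and the local speed is 1 / |(a, b)| in
mm/ms (numerically identical to m/s) with propagation direction (a, b)/|(a, b)|.

The phase distribution collects, for every 2x2 quadruplet of adjacent electrodes
(16 on a 5x5 grid), the largest activation-time difference within the quadruplet,
pooled across beats.  The conduction heterogeneity index (CHI) is the 5th-to-95th
percentile span of that distribution divided by its median, with percentiles by
linear interpolation at positions p (n - 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .activation_mapping import ActivationMap
from .errors import InsufficientDataError, UndefinedStatisticError

log = logging.getLogger("atriamap")

PERCENTILE_CONVENTION = "linear interpolation at p*(n-1)"


@dataclass
class TriangleVelocity:
    """Local conduction vector for one electrode triangle."""

    centroid_mm: tuple[float, float]
    speed_mps: float
    direction: tuple[float, float]  # unit vector of propagation


@dataclass
class PhaseDistribution:
    """Pooled quadruplet activation-time differences (ms)."""

    values_ms: np.ndarray
    n_quadruplets_per_beat: int
    n_beats: int

    def __post_init__(self) -> None:
        self.values_ms = np.asarray(self.values_ms, dtype=float)


@dataclass
class ConductionResult:
    """Per-cycle-length conduction summary."""

    cycle_length_ms: float
    cv_mean_mps: float
    cv_vectors: list[TriangleVelocity]
    chi: float | None
    phase: PhaseDistribution
    tat_ms: float
    n_maps: int


def triangle_velocities(
    amap: ActivationMap, *, speed_cap_mps: float | None = None
) -> list[TriangleVelocity]:
    """Local velocity vectors from plane fits over every fully annotated triangle.

    Triangles with an unannotated vertex or a zero activation-time gradient are
    excluded (with a logged count), not errors.  ``speed_cap_mps`` optionally
    drops implausibly fast vectors; it is off by default.
    """
    g = amap.grid
    s = g.spacing_mm
    lat = amap.lat_ms
    out: list[TriangleVelocity] = []
    n_excluded = 0
    for r in range(g.rows - 1):
        for c in range(g.cols - 1):
            # cell corners: ll=(r,c) lr=(r,c+1) ul=(r+1,c) ur=(r+1,c+1); x along cols
            ll, lr, ul, ur = lat[r, c], lat[r, c + 1], lat[r + 1, c], lat[r + 1, c + 1]
            for tri in (
                ((0.0, 0.0, ll), (s, 0.0, lr), (s, s, ur)),
                ((0.0, 0.0, ll), (0.0, s, ul), (s, s, ur)),
            ):
                (x1, y1, t1), (x2, y2, t2), (x3, y3, t3) = tri
                if not (np.isfinite(t1) and np.isfinite(t2) and np.isfinite(t3)):
                    n_excluded += 1
                    continue
                # solve the 2x2 system for the in-plane gradient (a, b)
                m = np.array([[x2 - x1, y2 - y1], [x3 - x1, y3 - y1]])
                rhs = np.array([t2 - t1, t3 - t1])
                try:
                    a, b = np.linalg.solve(m, rhs)
                except np.linalg.LinAlgError:  # degenerate geometry
                    n_excluded += 1
                    log.warning("degenerate triangle geometry at cell (%d, %d)", r, c)
                    continue
                grad = float(np.hypot(a, b))
                if grad == 0.0:
                    n_excluded += 1
                    continue
                speed = 1.0 / grad
                if speed_cap_mps is not None and speed > speed_cap_mps:
                    n_excluded += 1
                    continue
                cx = g.origin_mm[0] + c * s + (x1 + x2 + x3) / 3.0
                cy = g.origin_mm[1] + r * s + (y1 + y2 + y3) / 3.0
                out.append(
                    TriangleVelocity(
                        centroid_mm=(cx, cy),
                        speed_mps=speed,
                        direction=(a / grad, b / grad),
                    )
                )
    if n_excluded:
        log.debug("beat %d: %d triangles excluded", amap.beat_index, n_excluded)
    return out


def mean_cv(vectors: list[TriangleVelocity]) -> float:
    """Arithmetic mean of the local triangle speeds (m/s)."""
    if not vectors:
        raise InsufficientDataError("no valid triangle vectors")
    return float(np.mean([v.speed_mps for v in vectors]))


def phase_distribution(maps: list[ActivationMap]) -> PhaseDistribution:
    """Largest activation difference within every 2x2 electrode quadruplet,
    pooled across the supplied maps; quadruplets with an unannotated channel are
    skipped."""
    if not maps:
        raise InsufficientDataError("no activation maps supplied")
    g = maps[0].grid
    values: list[float] = []
    for amap in maps:
        if amap.grid.rows != g.rows or amap.grid.cols != g.cols:
            raise InsufficientDataError("maps must share one grid")
        lat = amap.lat_ms
        for r in range(g.rows - 1):
            for c in range(g.cols - 1):
                quad = lat[r : r + 2, c : c + 2]
                if np.all(np.isfinite(quad)):
                    values.append(float(quad.max() - quad.min()))
    if not values:
        raise InsufficientDataError("no complete quadruplet in any map")
    return PhaseDistribution(
        values_ms=np.array(values),
        n_quadruplets_per_beat=(g.rows - 1) * (g.cols - 1),
        n_beats=len(maps),
    )


def chi(dist: PhaseDistribution | np.ndarray) -> float:
    """Conduction heterogeneity index: (P95 - P5) / P50 of the phase distribution."""
    values = dist.values_ms if isinstance(dist, PhaseDistribution) else np.asarray(dist, dtype=float)
    if values.size == 0:
        raise InsufficientDataError("empty phase distribution")
    if values.size < 20:
        warnings.warn(
            f"CHI computed from only {values.size} phase values (< 20 recommended)",
            stacklevel=2,
        )
    p5, p50, p95 = np.percentile(values, [5, 50, 95])  # linear interpolation at p*(n-1)
    if p50 == 0:
        raise UndefinedStatisticError("median phase difference is zero (uniform map)")
    return float((p95 - p5) / p50)


def conduction_result(
    maps: list[ActivationMap],
    *,
    cycle_length_ms: float,
    speed_cap_mps: float | None = None,
) -> ConductionResult:
    """Pool triangle vectors and quadruplet phases over the supplied beats and
    assemble the per-cycle-length conduction summary.  The reported TAT is the
    mean of the per-map total activation times."""
    from .activation_mapping import total_activation_time

    vectors: list[TriangleVelocity] = []
    for amap in maps:
        vectors.extend(triangle_velocities(amap, speed_cap_mps=speed_cap_mps))
    dist = phase_distribution(maps)
    try:
        chi_value: float | None = chi(dist)
    except UndefinedStatisticError:
        chi_value = None
    tat = float(np.mean([total_activation_time(m) for m in maps]))
    return ConductionResult(
        cycle_length_ms=cycle_length_ms,
        cv_mean_mps=mean_cv(vectors),
        cv_vectors=vectors,
        chi=chi_value,
        phase=dist,
        tat_ms=tat,
        n_maps=len(maps),
    )
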