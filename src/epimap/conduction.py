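"""Conduction-velocity vectors, wave propagation velocity, and the
conduction heterogeneity index.

A local velocity vector is fitted per electrode triangle by solving the
plane ``t = a*x + b*y + c`` through the three (position, activation time)
points: the gradient ``g = (a, b)`` (ms/mm) gives speed ``1/|g|`` (m/s)
and propagation direction along ``g`` (toward later activation). The wave
propagation velocity (WPV) summarizes valid triangle speeds. The phase
map assigns each channel its largest absolute activation-time difference
to any valid Moore neighbor; the conduction heterogeneity index (CHI) is
``(P95 - P5) / P50`` of those delays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    EmptyResultError,
    InvalidParameterError,
    NoEstimateError,
    UndefinedIndexError,
)
from .features import ActivationMap
from .synthetic.geometry import ArrayGeometry

#: minimum triangle area (mm^2) to attempt a plane fit
MIN_TRIANGLE_AREA_MM2 = 1e-6
#: minimum activation-time span across a triangle: one sample at 25 kHz (ms)
DEFAULT_MIN_DT_MS = 0.04
#: physiologically plausible speed bounds (m/s)
DEFAULT_SPEED_BOUNDS = (0.1, 5.0)
_GRADIENT_FLOOR_MS_PER_MM = 1e-12

REASON_OK = ""
REASON_INVALID_VERTEX = "invalid vertex"
REASON_DEGENERATE = "degenerate geometry"
REASON_UNRESOLVABLE = "unresolvable gradient"
REASON_TIME_SPAN = "time span below resolution"
REASON_SPEED_BOUNDS = "speed out of bounds"


@dataclass(frozen=True)
class TriangleFit:
    speed_mps: float
    direction_deg: float
    valid: bool
    reason: str = REASON_OK


def fit_triangle_velocity(positions_mm: np.ndarray, times_ms: np.ndarray,
                          speed_bounds: tuple[float, float] | None = None) -> TriangleFit:
    """Fit one conduction vector from three electrodes.

    Parameters
    ----------
    positions_mm : (3, 2) array of (x, y)
    times_ms : (3,) activation times
    speed_bounds : optional (lo, hi) validity bounds in m/s

    Invalid outcomes carry a reason: collinear electrodes ("degenerate
    geometry"), an unresolvably small time gradient such as equal times at
    all three electrodes ("unresolvable gradient"), or an out-of-bounds
    fitted speed.
    """
    pos = np.asarray(positions_mm, dtype=float)
    t = np.asarray(times_ms, dtype=float)
    if pos.shape != (3, 2) or t.shape != (3,):
        raise InvalidParameterError("need exactly three (x, y) positions and three times")

    v1 = pos[1] - pos[0]
    v2 = pos[2] - pos[0]
    area = 0.5 * abs(v1[0] * v2[1] - v1[1] * v2[0])
    if area < MIN_TRIANGLE_AREA_MM2:
        return TriangleFit(math.nan, math.nan, False, REASON_DEGENERATE)

    a_mat = np.column_stack([pos, np.ones(3)])
    a, b, _ = np.linalg.solve(a_mat, t)
    gnorm = math.hypot(a, b)
    if gnorm < _GRADIENT_FLOOR_MS_PER_MM:
        return TriangleFit(math.nan, math.nan, False, REASON_UNRESOLVABLE)

    speed = 1.0 / gnorm  # mm/ms == m/s
    direction = math.degrees(math.atan2(b, a)) % 360.0
    if direction >= 360.0:  # float wraparound of tiny negative angles
        direction = 0.0
    if speed_bounds is not None and not (speed_bounds[0] <= speed <= speed_bounds[1]):
        return TriangleFit(speed, direction, False, REASON_SPEED_BOUNDS)
    return TriangleFit(speed, direction, True)


@dataclass(frozen=True)
class ConductionField:
    """Per-triangle conduction vectors plus the WPV summary."""

    triangles: np.ndarray  # (n, 3) channel triplets
    speed_mps: np.ndarray
    direction_deg: np.ndarray
    valid: np.ndarray
    reason: tuple[str, ...]
    wpv_mps: float
    speed_sd_mps: float
    n_valid: int
    summary: str  # "mean" | "median"

    def rejection_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.reason:
            if r:
                counts[r] = counts.get(r, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "vertex_a": self.triangles[:, 0],
            "vertex_b": self.triangles[:, 1],
            "vertex_c": self.triangles[:, 2],
            "speed_mps": self.speed_mps,
            "direction_deg": self.direction_deg,
            "valid": self.valid.astype(int),
            "reason": list(self.reason),
        })

    def summary_record(self) -> dict:
        return {"wpv_mps": self.wpv_mps, "speed_sd_mps": self.speed_sd_mps,
                "n_valid": self.n_valid, "n_triangles": int(len(self.reason)),
                "summary": self.summary,
                "rejections": self.rejection_counts()}


def wave_propagation_velocity(activation_map: ActivationMap,
                              geometry: ArrayGeometry,
                              speed_bounds: tuple[float, float] = DEFAULT_SPEED_BOUNDS,
                              min_dt_ms: float = DEFAULT_MIN_DT_MS,
                              summary: str = "mean") -> ConductionField:
    """Fit every geometry triangle with all-valid vertices and summarize.

    Filters (each with a recorded reason): any invalid vertex; activation
    time span across the triangle below ``min_dt_ms``; degenerate
    geometry; fitted speed outside ``speed_bounds``. WPV is the mean of
    valid triangle speeds (or the median, selectable via ``summary``).

    Raises
    ------
    NoEstimateError
        If no triangle survives the filters (e.g. simultaneous activation
        everywhere).
    """
    if summary not in ("mean", "median"):
        raise InvalidParameterError(f"summary must be 'mean' or 'median', got {summary!r}")
    tris = geometry.triangles
    if tris.shape[0] == 0:
        raise NoEstimateError("geometry has no triangles")

    n = tris.shape[0]
    speeds = np.full(n, np.nan)
    dirs = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    reasons: list[str] = []
    pos = geometry.positions()

    for k, tri in enumerate(tris):
        if not activation_map.valid[tri].all():
            reasons.append(REASON_INVALID_VERTEX)
            continue
        t = activation_map.time_ms[tri]
        if t.max() - t.min() < min_dt_ms:
            reasons.append(REASON_TIME_SPAN)
            continue
        fit = fit_triangle_velocity(pos[tri], t, speed_bounds=speed_bounds)
        speeds[k] = fit.speed_mps
        dirs[k] = fit.direction_deg
        valid[k] = fit.valid
        reasons.append(fit.reason)

    if not valid.any():
        raise NoEstimateError("no valid triangle remains after filtering")

    v = speeds[valid]
    wpv = float(np.mean(v)) if summary == "mean" else float(np.median(v))
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return ConductionField(triangles=tris.copy(), speed_mps=speeds,
                           direction_deg=dirs, valid=valid, reason=tuple(reasons),
                           wpv_mps=wpv, speed_sd_mps=sd, n_valid=int(v.size),
                           summary=summary)


@dataclass(frozen=True)
class PhaseMapResult:
    """Per-channel maximal neighbor activation-time differences."""

    channel_id: np.ndarray
    delay_ms: np.ndarray  # NaN where excluded
    valid: np.ndarray

    @property
    def delays(self) -> np.ndarray:
        """Delays of the included channels only."""
        return self.delay_ms[self.valid]

    def histogram(self, bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
        return np.histogram(self.delays, bins=bins)

    def summary_record(self) -> dict:
        d = self.delays
        return {"p5_ms": percentile(d, 5), "p50_ms": percentile(d, 50),
                "p95_ms": percentile(d, 95),
                "chi": conduction_heterogeneity_index(d),
                "n_channels": int(d.size)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"channel_id": self.channel_id,
                             "delay_ms": self.delay_ms,
                             "valid": self.valid.astype(int)})


#: activation times carry at most one-sample resolution (25 kHz default)
DEFAULT_DELAY_RESOLUTION_MS = 0.04


def phase_map(activation_map: ActivationMap, geometry: ArrayGeometry,
              resolution_ms: float | None = DEFAULT_DELAY_RESOLUTION_MS) -> PhaseMapResult:
    """Largest absolute activation-time difference to any valid Moore
    neighbor, per valid channel; channels with no valid neighbor are
    excluded.

    ``resolution_ms`` snaps each delay to the acquisition time lattice
    (sub-resolution differences between delays are measurement noise and
    would otherwise leak rounding error into the percentiles); pass
    ``None`` for raw delays.
    """
    n = geometry.n_channels
    if activation_map.time_ms.size != n:
        raise InvalidParameterError("activation map does not match geometry")
    if resolution_ms is not None and resolution_ms <= 0:
        raise InvalidParameterError("resolution_ms must be > 0 or None")

    delays = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    t = activation_map.time_ms
    for ch in range(n):
        if not activation_map.valid[ch]:
            continue
        nb = [j for j in geometry.neighbors[ch] if activation_map.valid[j]]
        if not nb:
            continue
        delay = np.max(np.abs(t[nb] - t[ch]))
        if resolution_ms is not None:
            delay = np.round(delay / resolution_ms) * resolution_ms
        delays[ch] = delay
        valid[ch] = True

    if not valid.any():
        raise EmptyResultError("no channel has a valid neighbor")
    return PhaseMapResult(channel_id=np.arange(n), delay_ms=delays, valid=valid)


def percentile(values: np.ndarray, p: float) -> float:
    """Empirical percentile by linear interpolation between order statistics.

    The quantile function's endpoints are the extreme order statistics:
    position ``(n - 1) * p / 100`` in the sorted sample, interpolated
    linearly (the classic "linear" convention). This convention is part of
    the CHI definition surface: changing it changes CHI.
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    if v.size == 0:
        raise InvalidParameterError("percentile of empty input is undefined")
    if not 0.0 <= p <= 100.0:
        raise InvalidParameterError(f"percentile p must be in [0, 100], got {p}")
    pos = (v.size - 1) * p / 100.0
    lo = int(np.floor(pos))
    hi = min(lo + 1, v.size - 1)
    frac = pos - lo
    return float(v[lo] + (v[hi] - v[lo]) * frac)


def conduction_heterogeneity_index(delays: np.ndarray) -> float:
    """CHI = (P95 - P5) / P50 of the phase-map delays.

    Raises ``UndefinedIndexError`` when the median delay is zero
    (uniformly zero delays leave the index undefined).
    """
    d = np.asarray(delays, dtype=float).ravel()
    if d.size == 0:
        raise InvalidParameterError("CHI of empty delays is undefined")
    p5 = percentile(d, 5)
    p50 = percentile(d, 50)
    p95 = percentile(d, 95)
    if p50 == 0:
        raise UndefinedIndexError("median delay is zero; CHI undefined")
    return (p95 - p5) / p50
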