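"""Regular electrode-grid geometry and exact ground-truth wavefronts.

Conventions (enforced package-wide): coordinates in mm, times in ms,
speeds in m/s (note mm/ms is numerically identical to m/s). Channels are
0-based and row-major: ``channel = row * cols + col``; ``x = col * pitch``
and ``y = row * pitch``. Row 0 is the "upper" edge of the array, so the
default bipolar stimulation pair sits at the upper-left corner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from ..errors import InvalidParameterError

#: Moore (8-connected) neighborhood offsets as (drow, dcol).
MOORE_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


@dataclass(frozen=True)
class ArrayGeometry:
    """Planar multielectrode array with neighbor and triangle topology.

    Attributes
    ----------
    channel_id, row, col : int arrays of length ``n_channels``
    x_mm, y_mm : float arrays, planar electrode coordinates
    pitch_mm : nominal interelectrode spacing
    stim_channels : channel ids of the bipolar stimulation site
    bad_channels : channels excluded from every analysis
    neighbors : per-channel tuple of Moore-adjacent channel ids (symmetric)
    triangles : (n_triangles, 3) int array; each grid cell is split into
        two triangles with three distinct, non-collinear vertices
    """

    channel_id: np.ndarray
    row: np.ndarray
    col: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    pitch_mm: float
    stim_channels: tuple[int, ...] = ()
    bad_channels: frozenset = frozenset()
    neighbors: tuple[tuple[int, ...], ...] = ()
    triangles: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=int))

    @property
    def n_channels(self) -> int:
        return int(self.channel_id.size)

    @property
    def n_rows(self) -> int:
        return int(self.row.max()) + 1

    @property
    def n_cols(self) -> int:
        return int(self.col.max()) + 1

    def positions(self) -> np.ndarray:
        """(n_channels, 2) array of (x_mm, y_mm)."""
        return np.column_stack([self.x_mm, self.y_mm])

    def with_bad_channels(self, bad: Iterable[int]) -> "ArrayGeometry":
        return replace(self, bad_channels=frozenset(int(b) for b in bad))

    def transformed(self, rotation_deg: float = 0.0,
                    dx_mm: float = 0.0, dy_mm: float = 0.0) -> "ArrayGeometry":
        """Rigidly rotate (about the origin) and translate electrode positions.

        Topology (neighbors, triangles) is preserved; grid row/col indices are
        kept for bookkeeping even though positions are no longer axis-aligned.
        """
        th = math.radians(rotation_deg)
        c, s = math.cos(th), math.sin(th)
        x = c * self.x_mm - s * self.y_mm + dx_mm
        y = s * self.x_mm + c * self.y_mm + dy_mm
        return replace(self, x_mm=x, y_mm=y)


def make_geometry(rows: int, cols: int, pitch_mm: float = 2.7,
                  stim_channels: tuple[int, ...] | None = None,
                  bad_channels: Iterable[int] = ()) -> ArrayGeometry:
    """Build a regular ``rows x cols`` grid with Moore adjacency.

    The triangulation splits each grid cell into two right triangles. The
    default stimulation site is the upper-left corner electrode pair
    (channels 0 and 1), mimicking a bipolar stimulation corner.

    Raises
    ------
    InvalidParameterError
        If ``rows < 2`` or ``cols < 2`` (no 2-D triangles possible) or
        ``pitch_mm <= 0``.
    """
    if rows < 2 or cols < 2:
        raise InvalidParameterError(
            f"need rows >= 2 and cols >= 2 to triangulate, got {rows}x{cols}")
    if pitch_mm <= 0:
        raise InvalidParameterError(f"pitch_mm must be > 0, got {pitch_mm}")

    n = rows * cols
    channel_id = np.arange(n, dtype=int)
    row = channel_id // cols
    col = channel_id % cols
    x_mm = col.astype(float) * pitch_mm
    y_mm = row.astype(float) * pitch_mm

    neighbors: list[tuple[int, ...]] = []
    for r, c in zip(row, col):
        nb = []
        for dr, dc in MOORE_OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols:
                nb.append(int(rr * cols + cc))
        neighbors.append(tuple(nb))

    tris: list[tuple[int, int, int]] = []
    for r in range(rows - 1):
        for c in range(cols - 1):
            i = r * cols + c
            tris.append((i, i + 1, i + cols))
            tris.append((i + 1, i + cols + 1, i + cols))
    triangles = np.array(tris, dtype=int)

    if stim_channels is None:
        stim_channels = (0, 1)

    return ArrayGeometry(
        channel_id=channel_id, row=row, col=col, x_mm=x_mm, y_mm=y_mm,
        pitch_mm=float(pitch_mm), stim_channels=tuple(int(s) for s in stim_channels),
        bad_channels=frozenset(int(b) for b in bad_channels),
        neighbors=tuple(neighbors), triangles=triangles,
    )


_CARDINALS = {0.0: (1.0, 0.0), 90.0: (0.0, 1.0),
              180.0: (-1.0, 0.0), 270.0: (0.0, -1.0)}


def _unit_vector(direction_deg: float) -> tuple[float, float]:
    """Unit vector for a compass angle; exact on the cardinal directions
    (cos/sin of multiples of pi/2 are otherwise off by ~1e-16, which would
    break the exact symmetries of axis-aligned wavefronts)."""
    key = float(direction_deg) % 360.0
    if key in _CARDINALS:
        return _CARDINALS[key]
    th = math.radians(direction_deg)
    return math.cos(th), math.sin(th)


@dataclass(frozen=True)
class ActivationTruth:
    """Exact per-channel activation times for a simulated wavefront.

    ``times_ms`` are relative to the beat onset (i.e. to the stimulus the
    beat is attached to during signal synthesis).
    """

    geometry: ArrayGeometry
    times_ms: np.ndarray
    kind: str  # "planar" | "focal"
    speed_mps: float
    t0_ms: float
    direction_deg: float | None = None
    origin_mm: tuple[float, float] | None = None


def simulate_planar_truth(geometry: ArrayGeometry, speed_mps: float,
                          direction_deg: float, t0_ms: float = 0.0) -> ActivationTruth:
    """Exact planar wavefront: ``t_i = t0 + (r_i . u) / speed``.

    ``u`` is the unit propagation direction (0 deg = +x, 90 deg = +y);
    positions in mm and speed in m/s give times in ms exactly.
    """
    if speed_mps <= 0:
        raise InvalidParameterError(f"speed_mps must be > 0, got {speed_mps}")
    ux, uy = _unit_vector(direction_deg)
    times = t0_ms + (geometry.x_mm * ux + geometry.y_mm * uy) / speed_mps
    return ActivationTruth(geometry=geometry, times_ms=times, kind="planar",
                           speed_mps=float(speed_mps), t0_ms=float(t0_ms),
                           direction_deg=float(direction_deg))


def simulate_focal_truth(geometry: ArrayGeometry, speed_mps: float,
                         origin_mm: tuple[float, float],
                         t0_ms: float = 0.0) -> ActivationTruth:
    """Exact focal (radial) wavefront: ``t_i = t0 + |r_i - origin| / speed``."""
    if speed_mps <= 0:
        raise InvalidParameterError(f"speed_mps must be > 0, got {speed_mps}")
    ox, oy = float(origin_mm[0]), float(origin_mm[1])
    dist = np.hypot(geometry.x_mm - ox, geometry.y_mm - oy)
    times = t0_ms + dist / speed_mps
    return ActivationTruth(geometry=geometry, times_ms=times, kind="focal",
                           speed_mps=float(speed_mps), t0_ms=float(t0_ms),
                           origin_mm=(ox, oy))
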