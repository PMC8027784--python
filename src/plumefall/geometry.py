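"""Source-centered polar geometry: bearings, sectors, and prediction grids.

All angles are compass bearings in degrees (North = 0, East = 90, clockwise)
and are stored reduced to [0, 360). Distances are kilometres. The coordinate
conversion uses a local equirectangular (cos-latitude) planar approximation,
which is accurate to well under a metre at the few-kilometre ranges a
point-source fallout survey covers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius

__all__ = [
    "PolarCoord",
    "Sector",
    "PolarGrid",
    "to_polar",
    "in_sector",
    "make_grid",
    "angular_difference",
]


@dataclass(frozen=True)
class PolarCoord:
    """A location relative to the emission source.

    Parameters
    ----------
    r : float
        Distance from the source in km, >= 0.
    theta : float
        Compass bearing in degrees, reduced to [0, 360).
    """

    r: float
    theta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.r) and np.isfinite(self.theta)):
            raise ValueError("polar coordinates must be finite")
        if self.r < 0:
            raise ValueError(f"distance must be non-negative, got {self.r}")
        object.__setattr__(self, "theta", float(np.mod(self.theta, 360.0)))


@dataclass(frozen=True)
class Sector:
    """An angular wedge (theta_min, theta_max), open at both boundaries.

    The default (260, 310) is the downwind plume sector fixed a priori from
    meteorology, not fitted to the concentration data.
    """

    theta_min: float = 260.0
    theta_max: float = 310.0

    def __post_init__(self) -> None:
        if not (0 <= self.theta_min < self.theta_max <= 360):
            raise ValueError(
                "sector requires 0 <= theta_min < theta_max <= 360, got "
                f"({self.theta_min}, {self.theta_max})"
            )

    @property
    def width(self) -> float:
        return self.theta_max - self.theta_min

    def contains(self, theta):
        """Strict (open-interval) membership; accepts scalars or arrays."""
        t = np.mod(np.asarray(theta, dtype=float), 360.0)
        out = (t > self.theta_min) & (t < self.theta_max)
        return bool(out) if np.isscalar(theta) else out

    def coverage(self, theta_centers, dtheta: float):
        """Fraction of each angular cell [c - dtheta/2, c + dtheta/2] inside.

        Used as exact angular quadrature weights: summing coverage * dtheta
        over a full ring recovers the sector width regardless of how the
        grid aligns with the sector boundaries.
        """
        c = np.mod(np.asarray(theta_centers, dtype=float), 360.0)
        lo = c - dtheta / 2.0
        hi = c + dtheta / 2.0
        frac = np.zeros_like(c)
        # a cell may wrap the 0/360 seam; check both unwrapped images
        for shift in (-360.0, 0.0, 360.0):
            a = np.maximum(lo + shift, self.theta_min)
            b = np.minimum(hi + shift, self.theta_max)
            frac += np.clip(b - a, 0.0, None)
        return frac / dtheta


def angular_difference(theta1, theta2):
    """Minimal absolute angular separation in degrees, in [0, 180]."""
    d = np.abs(np.asarray(theta1, dtype=float) - np.asarray(theta2, dtype=float))
    d = np.mod(d, 360.0)
    return np.where(d > 180.0, 360.0 - d, d)


def to_polar(lon: float, lat: float, origin_lon: float, origin_lat: float) -> PolarCoord:
    """Convert a WGS84 point to source-centered polar coordinates.

    Local planar equirectangular projection: eastings are scaled by
    cos(latitude of the origin). Valid in the near field (r << 100 km).
    """
    vals = np.asarray([lon, lat, origin_lon, origin_lat], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("coordinates must be finite WGS84 degrees")
    dlat = math.radians(lat - origin_lat)
    dlon = math.radians(lon - origin_lon)
    north = EARTH_RADIUS_KM * dlat
    east = EARTH_RADIUS_KM * dlon * math.cos(math.radians(origin_lat))
    r = math.hypot(north, east)
    theta = math.degrees(math.atan2(east, north)) % 360.0
    return PolarCoord(r=r, theta=theta)


def from_polar(p: PolarCoord, origin_lon: float, origin_lat: float) -> tuple[float, float]:
    """Local planar inverse of :func:`to_polar` (lon, lat)."""
    north = p.r * math.cos(math.radians(p.theta))
    east = p.r * math.sin(math.radians(p.theta))
    lat = origin_lat + math.degrees(north / EARTH_RADIUS_KM)
    lon = origin_lon + math.degrees(
        east / (EARTH_RADIUS_KM * math.cos(math.radians(origin_lat)))
    )
    return lon, lat


def in_sector(theta: float, sector: Sector) -> bool:
    """True iff the bearing lies strictly inside the sector."""
    return bool(sector.contains(theta))


@dataclass(frozen=True)
class PolarGrid:
    """A regular polar prediction grid, flattened row-major over (r, theta).

    ``r_values`` and ``theta_values`` are the axis nodes; ``r`` and ``theta``
    are the flattened coordinates of all ``n_r * n_theta`` locations.
    Angular nodes are cell centers of an equal partition of [0, 360).
    """

    r_values: np.ndarray
    theta_values: np.ndarray
    r: np.ndarray = field(repr=False)
    theta: np.ndarray = field(repr=False)

    @property
    def n_locations(self) -> int:
        return self.r.size

    @property
    def dr(self) -> float:
        return float(self.r_values[1] - self.r_values[0]) if self.r_values.size > 1 else 0.0

    @property
    def dtheta(self) -> float:
        return 360.0 / self.theta_values.size

    def coords(self) -> list[PolarCoord]:
        return [PolarCoord(float(a), float(b)) for a, b in zip(self.r, self.theta)]


def make_grid(r_min: float = 0.1, r_max: float = 1.5, n: int = 30) -> PolarGrid:
    """Uniform n x n polar grid with r in [r_min, r_max], theta covering [0, 360).

    The near-source disc (r < r_min, default 100 m) is excluded: no survey
    data exist there and any reconstruction would be pure extrapolation.
    """
    if r_min <= 0:
        raise ValueError(f"r_min must be positive, got {r_min}")
    if r_max <= r_min:
        raise ValueError("require r_min < r_max")
    if n < 2:
        raise ValueError("grid needs at least 2 nodes per axis")
    r_values = np.linspace(r_min, r_max, n)
    theta_values = np.arange(n) * (360.0 / n)
    rr, tt = np.meshgrid(r_values, theta_values, indexing="ij")
    return PolarGrid(
        r_values=r_values,
        theta_values=theta_values,
        r=rr.ravel(),
        theta=tt.ravel(),
    )
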