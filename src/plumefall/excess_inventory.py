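"""Sector excess statistics and the integrated excess-Pb inventory.

"Excess" at a radius is the difference between the angular mean
concentration inside the downwind plume sector and outside it, computed
ring-wise on the reconstructed field so that systematic background is
subtracted at the same distance. The inventory converts the excess
concentration to mass per area (sampling depth x soil bulk density) and
integrates it over the sector by polar quadrature (dA = r dr dtheta).

Quadrature uses exact cell measures: radial cells contribute
(b^2 - a^2)/2 for their clipped extent [a, b], and angular cells contribute
the exact fraction of the cell that overlaps the sector, so a constant
field integrates exactly at any grid resolution. The mass integral runs
from the source (r = 0) outward, carrying the innermost ring's excess over
the small unsampled central disc; pass ``inner_exclusion=True`` to start at
the 0.1 km reconstruction boundary instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Sector
from .prediction import MIN_PREDICT_R_KM, FieldGrid

#: Default sampling depth, m (surface scraping of the top ~1 cm).
DEFAULT_DEPTH_M = 0.01
#: Default dry soil bulk density, kg/m^3.
DEFAULT_BULK_DENSITY = 2000.0

__all__ = [
    "CredibleValue",
    "ExcessProfile",
    "InventorySummary",
    "ring_sector_means",
    "excess_profile",
    "average_excess_within",
    "integrated_excess_mass",
    "inventory_summary",
    "concentration_to_areal",
    "areal_to_concentration",
]


@dataclass(frozen=True)
class CredibleValue:
    """Posterior mean with a central 95% credible interval."""

    mean: float
    lo: float
    hi: float

    @classmethod
    def from_draws(cls, v: np.ndarray) -> "CredibleValue":
        lo, hi = np.percentile(v, [2.5, 97.5])
        return cls(mean=float(np.mean(v)), lo=float(lo), hi=float(hi))


@dataclass
class ExcessProfile:
    """Radial profile of the plume excess (inside minus outside), mg/kg."""

    radii: np.ndarray
    excess_mean: np.ndarray
    excess_q025: np.ndarray
    excess_q975: np.ndarray
    draws: np.ndarray  # (n_draws, n_radii)


@dataclass
class InventorySummary:
    radius: float
    avg_inside: CredibleValue
    avg_outside: CredibleValue
    excess_mass_kg: CredibleValue
    depth: float
    bulk_density: float
    level: str


def _raw_rings(field: FieldGrid, level: str) -> np.ndarray:
    """Back-transformed values reshaped to (n_draws, n_rings, n_theta)."""
    v = field.values(level) ** 4
    return v.reshape(field.n_draws, field.grid.r_values.size, field.grid.theta_values.size)


def _angular_weights(field: FieldGrid, sector: Sector) -> tuple[np.ndarray, np.ndarray]:
    w_in = sector.coverage(field.grid.theta_values, field.grid.dtheta)
    return w_in, 1.0 - w_in


def _wmean(v: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted mean over the trailing axis."""
    return (v * w).sum(axis=-1) / w.sum()


def ring_sector_means(
    field: FieldGrid, sector: Sector, r: float, level: str = "f"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw angular means (inside, outside the sector) at the ring nearest r.

    Values are on the raw mg/kg scale. Angular cells straddling a sector
    boundary contribute fractionally to both sides.
    """
    rv = field.grid.r_values
    if not (rv.min() - field.grid.dr / 2 <= r <= rv.max() + field.grid.dr / 2):
        raise ValueError(f"radius {r} km outside the grid range [{rv.min()}, {rv.max()}]")
    j = int(np.argmin(np.abs(rv - r)))
    ring = _raw_rings(field, level)[:, j, :]
    w_in, w_out = _angular_weights(field, sector)
    return _wmean(ring, w_in), _wmean(ring, w_out)


def excess_profile(field: FieldGrid, sector: Sector, level: str = "f") -> ExcessProfile:
    """Posterior mean and 95% interval of the ring-wise plume excess vs radius."""
    rings = _raw_rings(field, level)
    w_in, w_out = _angular_weights(field, sector)
    diff = _wmean(rings, w_in) - _wmean(rings, w_out)  # (n_draws, n_rings)
    q = np.percentile(diff, [2.5, 97.5], axis=0)
    return ExcessProfile(
        radii=field.grid.r_values.copy(),
        excess_mean=diff.mean(axis=0),
        excess_q025=q[0],
        excess_q975=q[1],
        draws=diff,
    )


def _radial_weights(
    grid_r: np.ndarray, dr: float, r_lo: float, r_hi: float
) -> np.ndarray:
    """Exact measure of int r dr over each clipped radial cell, km^2."""
    a = np.maximum(grid_r - dr / 2.0, r_lo)
    b = np.minimum(grid_r + dr / 2.0, r_hi)
    w = (b ** 2 - a ** 2) / 2.0
    return np.where(b > a, w, 0.0)


def average_excess_within(
    field: FieldGrid,
    sector: Sector,
    R: float,
    level: str = "f",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw area-weighted average concentration inside/outside the sector.

    Averages raw-scale concentrations over the annulus 0.1 km < r < R with
    polar area weights (proportional to r). ``level='y'`` uses the
    observation-level draws (field plus observational noise), representing
    what a new surface sample of a typical soil type would read.
    """
    if R <= MIN_PREDICT_R_KM:
        raise ValueError(f"R must exceed {MIN_PREDICT_R_KM} km")
    if R > field.grid.r_values.max() + field.grid.dr / 2:
        raise ValueError("R outside the reconstructed grid")
    rings = _raw_rings(field, level)
    w_in, w_out = _angular_weights(field, sector)
    w_r = _radial_weights(field.grid.r_values, field.grid.dr, MIN_PREDICT_R_KM, R)

    def _avg(w_theta):
        w = w_r[:, None] * w_theta[None, :]
        return (rings * w).sum(axis=(1, 2)) / w.sum()

    return _avg(w_in), _avg(w_out)


def integrated_excess_mass(
    field: FieldGrid,
    sector: Sector,
    R: float,
    depth: float = DEFAULT_DEPTH_M,
    bulk_density: float = DEFAULT_BULK_DENSITY,
    level: str = "f",
    background: str = "ring",
    inner_exclusion: bool = False,
) -> tuple[CredibleValue, np.ndarray]:
    """Excess Pb mass (kg) deposited in the sector within radius R, per draw.

    The excess concentration at an in-sector location is its raw-scale value
    minus the same-radius outside-sector mean (``background='ring'``, the
    default) or minus nothing (``background='zero'``, for fields already
    expressed as excess over background). The mass integral is

        M = depth * bulk_density * int_sector excess(r, theta) r dr dtheta

    with mg/kg * m * kg/m^3 * km^2 resolving to kg exactly.

    Returns (summary, per-draw masses).
    """
    if depth <= 0 or bulk_density <= 0:
        raise ValueError("depth and bulk_density must be positive")
    if R <= 0 or R > field.grid.r_values.max() + field.grid.dr / 2:
        raise ValueError("R must be positive and inside the reconstructed grid")
    if background not in ("ring", "zero"):
        raise ValueError("background must be 'ring' or 'zero'")

    rings = _raw_rings(field, level)
    w_in, w_out = _angular_weights(field, sector)
    if background == "ring":
        excess = rings - _wmean(rings, w_out)[:, :, None]
    else:
        excess = rings

    r_lo = MIN_PREDICT_R_KM if inner_exclusion else 0.0
    w_r = _radial_weights(field.grid.r_values, field.grid.dr, r_lo, R)
    if not inner_exclusion:
        # extend the innermost ring's cell to the source: the unsampled
        # central disc carries that ring's excess rather than zero
        first = int(np.argmax(w_r > 0)) if (w_r > 0).any() else 0
        a = 0.0
        b = min(field.grid.r_values[first] + field.grid.dr / 2.0, R)
        w_r = w_r.copy()
        w_r[first] = (b ** 2 - a ** 2) / 2.0

    dtheta_rad = np.deg2rad(field.grid.dtheta)
    area = w_r[:, None] * (w_in * dtheta_rad)[None, :]  # km^2 per cell, in-sector part
    mass = depth * bulk_density * (excess * area).sum(axis=(1, 2))
    return CredibleValue.from_draws(mass), mass


def inventory_summary(
    field: FieldGrid,
    sector: Sector,
    R: float = 1.0,
    depth: float = DEFAULT_DEPTH_M,
    bulk_density: float = DEFAULT_BULK_DENSITY,
    level: str = "y",
) -> InventorySummary:
    """Headline inventory at radius R: sector averages and integrated mass.

    Averages default to the observation level (what new samples would read);
    the mass integral always uses the mean-response field, since independent
    observational noise integrates to zero over an area.
    """
    inside, outside = average_excess_within(field, sector, R, level=level)
    mass, _ = integrated_excess_mass(field, sector, R, depth, bulk_density, level="f")
    return InventorySummary(
        radius=R,
        avg_inside=CredibleValue.from_draws(inside),
        avg_outside=CredibleValue.from_draws(outside),
        excess_mass_kg=mass,
        depth=depth,
        bulk_density=bulk_density,
        level=level,
    )


def concentration_to_areal(conc: float, depth: float, bulk_density: float) -> float:
    """mg/kg -> areal loading in ug/m^2 at the given depth and bulk density."""
    if conc <= 0 or depth <= 0 or bulk_density <= 0:
        raise ValueError("all arguments must be positive")
    return conc * depth * bulk_density * 1000.0


def areal_to_concentration(areal: float, depth: float, bulk_density: float) -> float:
    """ug/m^2 -> mg/kg; exact inverse of :func:`concentration_to_areal`."""
    if areal <= 0 or depth <= 0 or bulk_density <= 0:
        raise ValueError("all arguments must be positive")
    return areal / (depth * bulk_density * 1000.0)
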