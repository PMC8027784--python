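"""Survey table I/O, validation, and raw-data summaries.

A survey is a CSV with one row per soil sample: an id, a location given
either as WGS84 (lon, lat) or directly as source-centered polar coordinates
(r_km, bearing_deg), a soil-type category, the Pb concentration in mg/kg,
and optionally a Sn concentration in mg/kg (XRF-measured, used for source
attribution of the high-Pb samples).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import PolarCoord, Sector, to_polar

SOIL_TYPES = ("sidewalk_crack", "garden", "park", "plant_pot", "tree_pit")

#: French health-authority recommended maximum for soil Pb, mg/kg.
DEFAULT_THRESHOLD_MG_KG = 300.0

#: XRF-vs-ICPMS regression slope for Sn; XRF overestimates by this factor.
SN_XRF_SLOPE = 1.6

__all__ = [
    "SOIL_TYPES",
    "SoilSample",
    "SurveySummary",
    "SchemaError",
    "SampleValidationError",
    "read_survey",
    "write_survey",
    "samples_to_frame",
    "summarize",
    "sn_recalibrate_ratio",
]


class SchemaError(ValueError):
    """The survey table lacks a required column."""


class SampleValidationError(ValueError):
    """A survey row violates a sample invariant."""


@dataclass(frozen=True)
class SoilSample:
    sample_id: str
    polar: PolarCoord
    soil_type: str
    pb_mg_kg: float
    sn_mg_kg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.soil_type not in SOIL_TYPES:
            raise SampleValidationError(
                f"unknown soil type {self.soil_type!r}; allowed: {', '.join(SOIL_TYPES)}"
            )
        if not (self.pb_mg_kg > 0):
            raise SampleValidationError(
                f"Pb concentration must be positive, got {self.pb_mg_kg}"
            )
        if not (self.polar.r > 0):
            raise SampleValidationError("sample distance from source must be positive")


@dataclass(frozen=True)
class SurveySummary:
    n_total: int
    mean_pb: float
    median_pb: float
    mean_by_type: dict
    mean_inside_plume: float
    mean_outside_plume: float
    n_exceeding_threshold: int
    n_exceeding_inside: int
    n_exceeding_outside: int


def read_survey(
    path,
    origin: Optional[tuple[float, float]] = None,
    column_map: Optional[dict] = None,
) -> list[SoilSample]:
    """Read and validate a survey CSV.

    The table must carry either ``(lon, lat)`` columns (then ``origin``, as
    an (origin_lon, origin_lat) pair, is required) or precomputed
    ``(r_km, bearing_deg)`` columns. ``column_map`` renames alternative
    headers onto the canonical ones before validation.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    if column_map:
        df = df.rename(columns=column_map)

    if "pb_mg_kg" not in df.columns:
        raise SchemaError("missing required column 'pb_mg_kg'")
    if "soil_type" not in df.columns:
        raise SchemaError("missing required column 'soil_type'")

    has_polar = {"r_km", "bearing_deg"} <= set(df.columns)
    has_lonlat = {"lon", "lat"} <= set(df.columns)
    if not (has_polar or has_lonlat):
        raise SchemaError(
            "missing location columns: need ('r_km', 'bearing_deg') or ('lon', 'lat')"
        )
    if has_lonlat and not has_polar and origin is None:
        raise SchemaError("survey has (lon, lat) columns but no origin was given")

    if "sample_id" not in df.columns:
        df = df.assign(sample_id=[f"s{i:03d}" for i in range(len(df))])

    samples: list[SoilSample] = []
    for idx, row in df.iterrows():
        if has_polar:
            polar = PolarCoord(float(row["r_km"]), float(row["bearing_deg"]))
        else:
            polar = to_polar(float(row["lon"]), float(row["lat"]), origin[0], origin[1])
        sn = row.get("sn_mg_kg", None)
        sn = None if sn is None or pd.isna(sn) else float(sn)
        try:
            samples.append(
                SoilSample(
                    sample_id=str(row["sample_id"]),
                    polar=polar,
                    soil_type=str(row["soil_type"]),
                    pb_mg_kg=float(row["pb_mg_kg"]),
                    sn_mg_kg=sn,
                )
            )
        except SampleValidationError as err:
            raise SampleValidationError(f"row {idx}: {err}") from err
    return samples


def samples_to_frame(samples: Sequence[SoilSample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "r_km": [s.polar.r for s in samples],
            "bearing_deg": [s.polar.theta for s in samples],
            "soil_type": [s.soil_type for s in samples],
            "pb_mg_kg": [s.pb_mg_kg for s in samples],
            "sn_mg_kg": [s.sn_mg_kg for s in samples],
        }
    )


def write_survey(samples: Sequence[SoilSample], path) -> None:
    samples_to_frame(samples).to_csv(path, index=False)


def summarize(
    samples: Sequence[SoilSample],
    sector: Sector = Sector(),
    threshold: float = DEFAULT_THRESHOLD_MG_KG,
) -> SurveySummary:
    """Raw-scale survey summary: means, median, and threshold exceedances.

    Exceedance is strict (> threshold): the threshold is a recommended
    *maximum* level. Counts are split by plume-sector membership.
    """
    if not samples:
        raise ValueError("cannot summarize an empty survey")
    pb = np.array([s.pb_mg_kg for s in samples])
    inside = np.array([sector.contains(s.polar.theta) for s in samples])
    exceed = pb > threshold

    by_type: dict[str, float] = {}
    for t in SOIL_TYPES:
        sel = [s.pb_mg_kg for s in samples if s.soil_type == t]
        if sel:
            by_type[t] = float(np.mean(sel))

    def _mean(mask):
        return float(pb[mask].mean()) if mask.any() else float("nan")

    return SurveySummary(
        n_total=len(samples),
        mean_pb=float(pb.mean()),
        median_pb=float(np.median(pb)),
        mean_by_type=by_type,
        mean_inside_plume=_mean(inside),
        mean_outside_plume=_mean(~inside),
        n_exceeding_threshold=int(exceed.sum()),
        n_exceeding_inside=int((exceed & inside).sum()),
        n_exceeding_outside=int((exceed & ~inside).sum()),
    )


def sn_recalibrate_ratio(
    samples: Sequence[SoilSample],
    pb_min: float = 1000.0,
    xrf_slope: float = SN_XRF_SLOPE,
) -> float:
    """Mean Sn/Pb mass ratio among high-Pb samples, after XRF recalibration.

    XRF overreads Sn by a factor of ``xrf_slope`` (regression against ICP-MS
    digests), so each sample contributes (sn / xrf_slope) / pb. Only samples
    with a Sn value and pb >= pb_min qualify; a stable ratio among them is
    the fingerprint of Pb/Sn solder in the fallout.
    """
    ratios = [
        (s.sn_mg_kg / xrf_slope) / s.pb_mg_kg
        for s in samples
        if s.sn_mg_kg is not None and s.pb_mg_kg >= pb_min
    ]
    if not ratios:
        raise ValueError(f"no sample with Sn data and Pb >= {pb_min} mg/kg")
    return float(np.mean(ratios))
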