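"""Historical-range estimation with planar vector geometry.

Minimum convex polygon (MCP) over occurrence records, habitat buffering and
clipping, areas and occupancy percentages. All geometry is planar on
projected meter coordinates — the caller must supply an equal-area
projection; no geodesic math is performed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from shapely.geometry import MultiPoint, Polygon
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union
from shapely.validation import make_valid

logger = logging.getLogger(__name__)

M2_PER_KM2 = 1e6


class DegenerateGeometryError(ValueError):
    """Raised when a convex hull cannot form a polygon (<3 or collinear points)."""


@dataclass
class RangeScenario:
    """One row of the range analysis: habitat epoch x buffer distance."""

    name: str
    points: Sequence[tuple[float, float]]
    habitat: BaseGeometry
    buffer_distance_m: float = 0.0
    extant_area_km2: float | None = None

    def __post_init__(self) -> None:
        if self.buffer_distance_m < 0:
            raise ValueError("buffer distance must be non-negative")


def _repaired(geom: BaseGeometry) -> BaseGeometry:
    if not geom.is_valid:
        logger.info("repairing invalid geometry via make_valid")
        geom = make_valid(geom)
    return geom


def area_km2(geom: BaseGeometry) -> float:
    """Planar area in km² (coordinates assumed in meters)."""
    return geom.area / M2_PER_KM2


def minimum_convex_polygon(points: Sequence[tuple[float, float]]) -> Polygon:
    """Convex hull of occurrence points; every point lies inside or on it.

    Raises
    ------
    DegenerateGeometryError
        With fewer than three points, or all points collinear.
    """
    if len(points) < 3:
        raise DegenerateGeometryError("MCP needs at least three points")
    hull = MultiPoint(list(points)).convex_hull
    if not isinstance(hull, Polygon):
        raise DegenerateGeometryError("points are collinear; hull is not a polygon")
    return hull


def buffer_habitat(
    habitat: BaseGeometry, distance_m: float, quad_segs: int = 16
) -> BaseGeometry:
    """Dilate the habitat union by a distance (round joins/caps).

    Distance 0 returns the (repaired) union unchanged. ``quad_segs`` sets
    how many segments approximate each quarter-circle corner.
    """
    if distance_m < 0:
        raise ValueError("buffer distance must be non-negative")
    geom = _repaired(unary_union(habitat))
    if distance_m == 0:
        return geom
    return geom.buffer(
        distance_m, quad_segs=quad_segs, join_style="round", cap_style="round"
    )


def clip_range(mcp: BaseGeometry, habitat: BaseGeometry) -> tuple[BaseGeometry, float]:
    """Intersect the MCP with the habitat union; return geometry and km²."""
    inter = _repaired(mcp).intersection(_repaired(unary_union(habitat)))
    return inter, area_km2(inter)


def occupancy_percent(extant_area_km2: float, potential_area_km2: float) -> float:
    """Extant area as a percentage of the potential (clipped) range."""
    if potential_area_km2 <= 0:
        raise ValueError("potential area must be positive")
    return 100.0 * extant_area_km2 / potential_area_km2


def scenario_table(scenarios: Sequence[RangeScenario]) -> pd.DataFrame:
    """Evaluate each scenario: MCP, buffered habitat, clip, occupancy.

    Returns one row per scenario with columns name, buffer_m, mcp_area_km2,
    potential_area_km2 and occupancy_percent (NaN when no extant area was
    given). Raises on an empty scenario list; an empty-habitat scenario
    yields an error row (potential area 0, occupancy NaN).
    """
    if not scenarios:
        raise ValueError("at least one scenario required")
    rows = []
    for sc in scenarios:
        mcp = minimum_convex_polygon(sc.points)
        habitat = buffer_habitat(sc.habitat, sc.buffer_distance_m)
        _, potential = clip_range(mcp, habitat)
        if sc.extant_area_km2 is not None and potential > 0:
            occ = occupancy_percent(sc.extant_area_km2, potential)
        else:
            occ = float("nan")
        rows.append(
            {
                "name": sc.name,
                "buffer_m": sc.buffer_distance_m,
                "mcp_area_km2": area_km2(mcp),
                "potential_area_km2": potential,
                "occupancy_percent": occ,
            }
        )
    return pd.DataFrame(rows)
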