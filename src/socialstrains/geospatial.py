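"""Territories from GPS points: projection, minimum convex polygons, distances.

Stationary-point GPS records per social group are projected from WGS84 to a
UTM zone (39S by default, matching an eastern-Madagascar study area), the
100% minimum convex polygon (MCP100) of each group is taken as its territory,
and territory geometry (area in hectares, pairwise overlap, centroid
distances) feeds the geography-versus-strain-sharing correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point

from . import projection
from .socialnet import correlate

__all__ = [
    "Territory",
    "read_gps",
    "project_to_utm",
    "mcp",
    "territories_from_points",
    "overlap_area",
    "centroid_distances",
    "sharing_vs_distance",
]


@dataclass
class Territory:
    group_id: str
    polygon: object  # shapely geometry (Polygon; Point/LineString when degenerate)
    area_ha: float
    centroid: tuple[float, float]
    degenerate: bool


def read_gps(path: Path | str) -> pd.DataFrame:
    pts = pd.read_csv(path)
    missing = [c for c in ("group_id", "lon", "lat") if c not in pts.columns]
    if missing:
        raise ValueError(f"GPS file {path} is missing columns: {missing}")
    return pts


def project_to_utm(points: pd.DataFrame, zone: int = 39, south: bool = True) -> pd.DataFrame:
    """Add projected easting/northing (meters) to a lon/lat point table."""
    out = points.copy()
    e, n = projection.geographic_to_utm(
        out["lon"].to_numpy(), out["lat"].to_numpy(), zone=zone, south=south
    )
    out["easting"] = e
    out["northing"] = n
    return out


def mcp(xy: np.ndarray, group_id: str = "") -> Territory:
    """Minimum convex polygon over 100% of the projected points (MCP100).

    Degenerate inputs (fewer than 3 distinct points, or collinear points)
    yield area 0 with the degenerate flag set and the point mean as centroid.
    """
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or len(xy) < 1:
        raise ValueError("need an (n, 2) array of projected coordinates")
    hull = MultiPoint([Point(p) for p in xy]).convex_hull
    degenerate = hull.geom_type != "Polygon"
    if degenerate:
        centroid = (float(xy[:, 0].mean()), float(xy[:, 1].mean()))
        area = 0.0
    else:
        centroid = (hull.centroid.x, hull.centroid.y)
        area = hull.area / 10_000.0  # m^2 -> ha
    return Territory(group_id, hull, area, centroid, degenerate)


def territories_from_points(points: pd.DataFrame) -> dict[str, Territory]:
    """Per-group MCP territories from a projected point table."""
    if "easting" not in points.columns:
        points = project_to_utm(points)
    return {
        str(g): mcp(grp[["easting", "northing"]].to_numpy(), group_id=str(g))
        for g, grp in points.groupby("group_id")
    }


def overlap_area(a: Territory, b: Territory) -> float:
    """Intersection area of two territories, in hectares (0 when disjoint)."""
    return a.polygon.intersection(b.polygon).area / 10_000.0


def centroid_distances(territories: dict[str, Territory]) -> pd.DataFrame:
    """Symmetric table of Euclidean centroid-to-centroid distances (meters)."""
    if len(territories) < 2:
        raise ValueError("need at least 2 territories")
    groups = sorted(territories)
    mat = pd.DataFrame(0.0, index=groups, columns=groups)
    for a, b in combinations(groups, 2):
        ca, cb = territories[a].centroid, territories[b].centroid
        d = float(np.hypot(ca[0] - cb[0], ca[1] - cb[1]))
        mat.at[a, b] = mat.at[b, a] = d
    return mat


def sharing_vs_distance(
    rates: pd.DataFrame,
    territories: dict[str, Territory],
    roster: pd.DataFrame,
    include_within_group: bool = True,
) -> dict:
    """Spearman correlation of per-pair shared-strain counts with territory distance.

    Each individual pair maps to its group pair's centroid distance;
    within-group pairs sit at distance 0 and are included by default.
    """
    group_of = dict(zip(roster["individual_id"], roster["social_group"]))
    dist = centroid_distances(territories)
    shared, geo = [], []
    for row in rates.itertuples():
        ga, gb = group_of[row.individual_a], group_of[row.individual_b]
        if ga == gb:
            if not include_within_group:
                continue
            d = 0.0
        else:
            if ga not in dist.index or gb not in dist.index:
                raise ValueError(f"no territory for sampled group {ga!r} or {gb!r}")
            d = dist.at[ga, gb]
        shared.append(row.n_shared_strains)
        geo.append(d)
    result = correlate(shared, geo, method="spearman")
    result["n_pairs"] = len(shared)
    return result
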