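"""Prospecting home-range geometry.

A floater's prospecting area is summarized by the 95% minimum convex polygon
(MCP) of the nest boxes it visited: the convex hull of the visited-box
coordinates after trimming the 5% of points farthest from their arithmetic
mean.  A circle of the colony-wide *median* MCP area, centered on each
polygon's centroid, projects a comparable "prospected area" for every
individual; the boxes inside that circle form the candidate set of the
settlement analysis.

Each box visited counts once, however many detections it produced: inclusion
requires at least 5 *distinct* visited boxes.  All geometry is planar
(meters); lon/lat inputs must pass through :func:`nestprospect.data.project_lonlat`
first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Polygon

__all__ = [
    "ProspectSummary",
    "mcp",
    "polygon_centroid",
    "project_circle",
    "boxes_in_circle",
    "distance",
    "summarize_prospecting",
    "DegenerateGeometryError",
]

MIN_VISITED_BOXES = 5


class DegenerateGeometryError(ValueError):
    """Fewer than 3 non-collinear points remain after trimming."""


@dataclass
class ProspectSummary:
    """Per floater-year prospecting-area summary."""

    tag_id: str
    floater_year: int
    visited_boxes: frozenset[str]
    mcp_vertices: np.ndarray  # (k, 2) closed ring excluded
    area_m2: float
    centroid: tuple[float, float]
    circle_radius_m: float = float("nan")

    @property
    def n_boxes(self) -> int:
        return len(self.visited_boxes)


def mcp(points: np.ndarray, percent: float = 95.0) -> tuple[np.ndarray, float]:
    """Minimum convex polygon of ``points`` after percentile trimming.

    Points whose distance to the arithmetic-mean center exceeds the
    ``percent``-th empirical percentile (linear-interpolation quantile) of
    those distances are discarded; the convex hull of the remainder and its
    area are returned.  Ties at the percentile distance are retained.

    Returns
    -------
    vertices : (k, 2) array in counter-clockwise order (not closed)
    area_m2 : float
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    center = pts.mean(axis=0)
    d = np.hypot(*(pts - center).T)
    cutoff = np.percentile(d, percent)  # linear interpolation between order stats
    kept = pts[d <= cutoff + 1e-12]
    if len(kept) < 3:
        raise DegenerateGeometryError(
            f"only {len(kept)} points retained at percent={percent}; need >= 3")
    hull = MultiPoint(kept).convex_hull
    if not isinstance(hull, Polygon) or hull.area == 0:
        raise DegenerateGeometryError("retained points are collinear")
    ring = np.asarray(hull.exterior.coords)[:-1]
    return ring, float(hull.area)


def polygon_centroid(vertices: np.ndarray) -> tuple[float, float]:
    """Area-weighted centroid of a simple polygon."""
    poly = Polygon(np.asarray(vertices, dtype=float))
    if poly.area == 0:
        raise ValueError("polygon has zero area")
    c = poly.centroid
    return (c.x, c.y)


def project_circle(centroid: tuple[float, float], median_area_m2: float
                   ) -> tuple[tuple[float, float], float]:
    """Circle of the given area centered on ``centroid``: radius = sqrt(A/pi)."""
    if not median_area_m2 > 0:
        raise ValueError("median area must be positive")
    return centroid, math.sqrt(median_area_m2 / math.pi)


def boxes_in_circle(center: tuple[float, float], radius: float,
                    boxes: pd.DataFrame) -> set[str]:
    """Box ids within ``radius`` of ``center`` (boundary inclusive)."""
    d = np.hypot(boxes["x"].to_numpy() - center[0],
                 boxes["y"].to_numpy() - center[1])
    return set(boxes.loc[d <= radius, "box_id"])


def distance(p: tuple[float, float], q: tuple[float, float]) -> float:
    """Planar Euclidean distance in meters."""
    return math.hypot(p[0] - q[0], p[1] - q[1])


def summarize_prospecting(visits: pd.DataFrame, boxes: pd.DataFrame,
                          percent: float = 95.0,
                          min_boxes: int = MIN_VISITED_BOXES,
                          ) -> list[ProspectSummary]:
    """Build one :class:`ProspectSummary` per (tag, year) from visit records.

    ``visits`` needs columns ``tag_id``, ``year``, ``box_id`` (one row per
    visit or per visited box; duplicates collapse).  Individuals visiting
    fewer than ``min_boxes`` distinct boxes are excluded, as are individuals
    whose trimmed point sets are degenerate (collinear).  After all polygons
    are computed, every summary receives the circle radius implied by the
    *median* MCP area across individuals.
    """
    coords = boxes.set_index("box_id")[["x", "y"]]
    summaries: list[ProspectSummary] = []
    for (tag, year), grp in visits.groupby(["tag_id", "year"], sort=True):
        visited = frozenset(grp["box_id"])
        if len(visited) < min_boxes:
            continue
        pts = coords.loc[sorted(visited)].to_numpy()
        try:
            ring, area = mcp(pts, percent=percent)
        except DegenerateGeometryError:
            continue
        cx, cy = polygon_centroid(ring)
        summaries.append(ProspectSummary(tag, int(year), visited, ring, area, (cx, cy)))
    if summaries:
        median_area = float(np.median([s.area_m2 for s in summaries]))
        if median_area > 0:
            _, radius = project_circle((0.0, 0.0), median_area)
            for s in summaries:
                s.circle_radius_m = radius
    return summaries
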