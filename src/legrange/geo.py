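"""Spherical geometry helpers for lon/lat (WGS84 degree) polygons.

All coordinates are (longitude, latitude) in degrees, matching GeoJSON
axis order.  Areas are computed on a sphere of radius 6371 km with the
Chamberlain–Duquette line-integral formula, which is exact for polygons
whose edges follow parallels/meridians closely and accurate to well under
1% for the region-scale rectangles used here.  Distances are great-circle
(haversine) on the same sphere.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import nearest_points

EARTH_RADIUS_KM = 6371.0
#: kilometres per degree of great-circle arc on the reference sphere
KM_PER_DEGREE = EARTH_RADIUS_KM * np.pi / 180.0


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in km between points given in degrees.

    Accepts scalars or broadcastable arrays.
    """
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(np.asarray(lon2) - np.asarray(lon1))
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def _ring_area_km2(coords: Sequence[tuple[float, float]]) -> float:
    """Signed spherical area of a closed ring of (lon, lat) vertices."""
    lon = np.radians([c[0] for c in coords])
    lat = np.radians([c[1] for c in coords])
    if lon[0] != lon[-1] or lat[0] != lat[-1]:
        lon = np.append(lon, lon[0])
        lat = np.append(lat, lat[0])
    # Chamberlain & Duquette: A = -R^2/2 * sum (lam2-lam1)(2 + sin(phi1) + sin(phi2))
    dlam = np.diff(lon)
    s = np.sin(lat)
    total = np.sum(dlam * (2.0 + s[:-1] + s[1:]))
    return -(EARTH_RADIUS_KM**2) * total / 2.0


def spherical_area_km2(geom: Polygon | MultiPolygon) -> float:
    """Spherical surface area (km^2) of a polygon or multipolygon."""
    if isinstance(geom, MultiPolygon):
        return float(sum(spherical_area_km2(g) for g in geom.geoms))
    if geom.is_empty:
        return 0.0
    area = abs(_ring_area_km2(list(geom.exterior.coords)))
    for hole in geom.interiors:
        area -= abs(_ring_area_km2(list(hole.coords)))
    return float(area)


def polygon_centroid(geom: Polygon | MultiPolygon) -> tuple[float, float]:
    """Planar lon/lat centroid returned as (lat, lon) degrees.

    Polygons crossing the antimeridian must be pre-split at +/-180, so
    the planar centroid is well defined at the scales handled here.
    """
    c = geom.centroid
    return float(c.y), float(c.x)


def weighted_centroid(
    geoms: Iterable[Polygon | MultiPolygon],
    weights: Iterable[float] | None = None,
) -> tuple[float, float]:
    """Area-weighted centroid (lat, lon) of several polygons.

    Weights default to spherical areas.
    """
    geoms = list(geoms)
    if not geoms:
        raise ValueError("no geometries supplied")
    if weights is None:
        weights = [spherical_area_km2(g) for g in geoms]
    w = np.asarray(list(weights), dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    lats, lons = zip(*(polygon_centroid(g) for g in geoms))
    return (
        float(np.average(lats, weights=w)),
        float(np.average(lons, weights=w)),
    )


def mean_pairwise_distance_km(centroids: Sequence[tuple[float, float]]) -> float:
    """Mean pairwise great-circle distance between (lat, lon) centroids."""
    if len(centroids) < 2:
        raise ValueError("need at least two centroids")
    dists = [
        haversine_km(a[0], a[1], b[0], b[1]) for a, b in combinations(centroids, 2)
    ]
    return float(np.mean(dists))


def distance_to_boundary_km(lat: float, lon: float, geom) -> float:
    """Great-circle distance from a point to the nearest polygon boundary.

    The nearest boundary point is located in planar lon/lat coordinates
    (adequate away from the poles and the antimeridian) and the distance
    is then measured along the great circle.
    """
    from shapely.geometry import Point

    boundary = geom.boundary
    _, nearest = nearest_points(Point(lon, lat), boundary)
    return float(haversine_km(lat, lon, nearest.y, nearest.x))


def boundary_gap_degrees(g1, g2) -> float:
    """Minimum separation between two geometries in degrees of arc.

    The closest pair of boundary points is found in planar lon/lat and
    their great-circle separation is converted back to degrees.
    """
    if g1.intersects(g2):
        return 0.0
    p1, p2 = nearest_points(g1, g2)
    return float(haversine_km(p1.y, p1.x, p2.y, p2.x) / KM_PER_DEGREE)
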