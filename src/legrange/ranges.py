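"""Turn name-coded occurrence records plus a polygon gazetteer into
species ranges, region-level occupancy and geographic covariates.

The gazetteer mirrors the World Geographical Scheme for Recording Plant
Distributions (WGSRPD/TDWG): a four-level hierarchy of named polygons
(continent > region > area > country).  Occurrence records name a unit at
some level together with its parent unit, carrying a status in
``{"native", "introduced", "unknown"}``.  The analysis grain is the
*region* level; sub-region records roll up to their region ancestor via
the gazetteer's parent chain (never via spatial containment).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon, Point, mapping, shape
from shapely.ops import unary_union

from .geo import (
    distance_to_boundary_km,
    mean_pairwise_distance_km,
    polygon_centroid,
    spherical_area_km2,
    weighted_centroid,
)

LEVELS = ("continent", "region", "area", "country")
_LEVEL_INDEX = {name: i for i, name in enumerate(LEVELS)}

VALID_STATUSES = frozenset({"native", "introduced", "unknown"})


class UnmatchedRecordError(KeyError):
    """An occurrence record's name cannot be matched within one level up."""


class GeometryError(ValueError):
    pass


class CovariateError(ValueError):
    pass


class MappingError(KeyError):
    """A matched polygon has no region-level ancestor."""


@dataclass
class RegionPolygon:
    """One gazetteer unit."""

    id: str
    name: str
    level: str
    parent: str | None
    geometry: Polygon | MultiPolygon
    area_km2: float = field(init=False)
    centroid: tuple[float, float] = field(init=False)  # (lat, lon)

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown hierarchy level {self.level!r}")
        if not self.geometry.is_valid:
            raise GeometryError(f"invalid geometry for unit {self.name!r}")
        self.area_km2 = spherical_area_km2(self.geometry)
        if self.area_km2 <= 0:
            raise GeometryError(f"unit {self.name!r} has non-positive area")
        self.centroid = polygon_centroid(self.geometry)


class Gazetteer:
    """Indexed collection of :class:`RegionPolygon` units."""

    def __init__(self, units: Iterable[RegionPolygon]):
        self.units = list(units)
        self._by_level_name: dict[tuple[str, str], RegionPolygon] = {}
        self._by_id: dict[str, RegionPolygon] = {}
        for u in self.units:
            key = (u.level, u.name)
            if key in self._by_level_name:
                raise ValueError(f"duplicate gazetteer unit {key}")
            self._by_level_name[key] = u
            self._by_id[u.id] = u
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        for u in self.units:
            seen = {u.id}
            cur = u
            while cur.parent is not None:
                cur = self._by_id.get(cur.parent)
                if cur is None:
                    break
                if cur.id in seen:
                    raise ValueError("cyclic parent chain in gazetteer")
                seen.add(cur.id)

    def lookup(self, level: str, name: str) -> RegionPolygon | None:
        return self._by_level_name.get((level, name))

    def by_id(self, unit_id: str) -> RegionPolygon:
        return self._by_id[unit_id]

    def region_ancestor(self, unit: RegionPolygon) -> RegionPolygon:
        """Region-level ancestor of a unit, via the parent chain."""
        cur = unit
        while cur is not None and cur.level != "region":
            cur = self._by_id.get(cur.parent) if cur.parent else None
        if cur is None:
            raise MappingError(f"unit {unit.name!r} has no region ancestor")
        return cur

    @property
    def regions(self) -> list[RegionPolygon]:
        return [u for u in self.units if u.level == "region"]

    # GeoJSON round trip -------------------------------------------------
    def to_geojson(self) -> dict:
        feats = []
        for u in self.units:
            feats.append(
                {
                    "type": "Feature",
                    "geometry": mapping(u.geometry),
                    "properties": {
                        "id": u.id,
                        "name": u.name,
                        "level": u.level,
                        "parent": u.parent,
                    },
                }
            )
        return {"type": "FeatureCollection", "features": feats}

    def write_geojson(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh)

    @classmethod
    def from_geojson(cls, obj_or_path) -> "Gazetteer":
        if isinstance(obj_or_path, (str, bytes)) or hasattr(obj_or_path, "__fspath__"):
            with open(obj_or_path) as fh:
                obj = json.load(fh)
        else:
            obj = obj_or_path
        units = []
        for feat in obj["features"]:
            props = feat["properties"]
            units.append(
                RegionPolygon(
                    id=props["id"],
                    name=props["name"],
                    level=props["level"],
                    parent=props.get("parent"),
                    geometry=shape(feat["geometry"]),
                )
            )
        return cls(units)


@dataclass
class MatchedRecord:
    species_id: str
    unit: RegionPolygon
    status: str
    promoted: bool = False


@dataclass
class RangeComponent:
    """One non-contiguous range: a connected component of touching
    same-status polygons."""

    status: str
    member_ids: list[str]
    geometry: Polygon | MultiPolygon
    area_km2: float
    centroid: tuple[float, float]


@dataclass
class SpeciesRange:
    species_id: str
    components: list[RangeComponent]

    def by_status(self, status: str) -> list[RangeComponent]:
        return [c for c in self.components if c.status == status]


@dataclass
class OccupancyMatrix:
    """Species x region binary non-native presence with status annotations.

    ``Y`` holds 1 where the species has at least one introduced-status
    polygon rolling up to the region; ``status`` holds
    ``{"native", "nonnative", "absent"}`` per cell.
    """

    Y: pd.DataFrame
    status: pd.DataFrame

    def __post_init__(self) -> None:
        if self.Y.shape != self.status.shape:
            raise ValueError("Y and status shapes differ")
        ok = (self.Y.values == 1) == (self.status.values == "nonnative")
        if not ok.all():
            raise ValueError("Y==1 must coincide with status=='nonnative'")

    @property
    def species_ids(self) -> list[str]:
        return list(self.Y.index)

    @property
    def region_ids(self) -> list[str]:
        return list(self.Y.columns)

    def write_csv(self, path) -> None:
        self.Y.to_csv(path, index_label="species_id")


# ---------------------------------------------------------------------------
# operations


def match_name(record: Mapping, gazetteer: Gazetteer) -> MatchedRecord:
    """Match an occurrence record to a gazetteer polygon.

    Exact (level, name) match wins; otherwise the record's parent name at
    the next level up is tried (one level only, flagged ``promoted``).
    """
    level = record["level"]
    name = record["unit_name"]
    status = record["status"]
    if status not in VALID_STATUSES:
        raise ValueError(f"unknown status {status!r}")
    unit = gazetteer.lookup(level, name)
    if unit is not None:
        return MatchedRecord(record["species_id"], unit, status, promoted=False)
    idx = _LEVEL_INDEX[level]
    parent_name = record.get("parent_name")
    if idx > 0 and parent_name:
        parent = gazetteer.lookup(LEVELS[idx - 1], parent_name)
        if parent is not None:
            return MatchedRecord(record["species_id"], parent, status, promoted=True)
    raise UnmatchedRecordError(
        f"no gazetteer match for {name!r} at level {level!r} "
        f"(parent {parent_name!r}) within one level up"
    )


def match_records(records: pd.DataFrame, gazetteer: Gazetteer) -> list[MatchedRecord]:
    return [match_name(row, gazetteer) for row in records.to_dict("records")]


def resolve_levels(
    matched: Sequence[MatchedRecord], gazetteer: Gazetteer | None = None
) -> list[MatchedRecord]:
    """Keep, per species, only records at the lowest available level.

    Unknown-status records are dropped first; species left with only
    unknown records disappear from the dataset entirely.  A record is
    discarded when the same species has another record strictly nested
    below it (its unit is an ancestor of the other record's unit along
    the parent chain).  The gazetteer, when supplied, resolves full
    parent chains; otherwise chains are walked through units present in
    the record set itself.
    """
    known = [m for m in matched if m.status != "unknown"]
    by_species: dict[str, list[MatchedRecord]] = {}
    for m in known:
        by_species.setdefault(m.species_id, []).append(m)

    def ancestors(unit: RegionPolygon, local: dict[str, RegionPolygon]) -> set[str]:
        ids: set[str] = set()
        p = unit.parent
        guard = 0
        while p is not None and guard < len(LEVELS):
            ids.add(p)
            if gazetteer is not None and p in gazetteer._by_id:
                p = gazetteer.by_id(p).parent
            elif p in local:
                p = local[p].parent
            else:
                p = None
            guard += 1
        return ids

    out: list[MatchedRecord] = []
    for recs in by_species.values():
        local = {m.unit.id: m.unit for m in recs}
        superseded: set[str] = set()
        for m in recs:
            superseded |= ancestors(m.unit, local)
        out.extend(m for m in recs if m.unit.id not in superseded)
    return out


def merge_contiguous(
    polygons: Sequence[tuple[str, str, Polygon | MultiPolygon]],
) -> list[RangeComponent]:
    """Merge touching same-status polygons into non-contiguous ranges.

    ``polygons`` is a sequence of (unit_id, status, geometry).  Unknown
    status polygons are excluded before merging.  Connected components
    under the relation "intersects AND same status" become single ranges
    whose area is the spherical area of the geometric union.
    """
    items = [(uid, st, g) for uid, st, g in polygons if st != "unknown"]
    for uid, _, g in items:
        if not g.is_valid:
            raise GeometryError(f"invalid geometry for unit {uid!r}")
    n = len(items)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        for j in range(i + 1, n):
            if items[i][1] == items[j][1] and items[i][2].intersects(items[j][2]):
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    comps = []
    for members in groups.values():
        geoms = [items[i][2] for i in members]
        merged = unary_union(geoms)
        comps.append(
            RangeComponent(
                status=items[members[0]][1],
                member_ids=sorted(items[i][0] for i in members),
                geometry=merged,
                area_km2=spherical_area_km2(merged),
                centroid=polygon_centroid(merged),
            )
        )
    comps.sort(key=lambda c: (c.status, c.member_ids))
    return comps


def build_species_range(
    species_id: str, matched: Sequence[MatchedRecord]
) -> SpeciesRange:
    polys = [(m.unit.id, m.status, m.unit.geometry) for m in matched]
    return SpeciesRange(species_id, merge_contiguous(polys))


def range_covariates(sp_range: SpeciesRange) -> dict:
    """Native-range covariates: total area, absolute centroid latitude.

    The centroid is the area-weighted centroid over all native range
    components; latitude is reported as its absolute value in degrees.
    """
    native = sp_range.by_status("native")
    if not native:
        raise CovariateError(f"species {sp_range.species_id!r} has no native range")
    areas = [c.area_km2 for c in native]
    lat, lon = weighted_centroid([c.geometry for c in native], areas)
    return {
        "species_id": sp_range.species_id,
        "total_native_area_km2": float(sum(areas)),
        "abs_native_centroid_lat": abs(lat),
        "native_centroid": (lat, lon),
        "per_range_areas_km2": areas,
    }


def dispersion(sp_range: SpeciesRange) -> float:
    """Mean pairwise great-circle distance (km) between the centroids of
    a species' non-native (introduced) ranges."""
    intro = sp_range.by_status("introduced")
    if len(intro) < 2:
        raise ValueError(
            f"dispersion undefined for {sp_range.species_id!r}: "
            f"{len(intro)} non-native range(s)"
        )
    return mean_pairwise_distance_km([c.centroid for c in intro])


def build_occupancy(
    resolved: Sequence[MatchedRecord],
    gazetteer: Gazetteer,
    species_ids: Sequence[str] | None = None,
) -> OccupancyMatrix:
    """Region-level occupancy: Y_ij = 1 iff species i has >=1 introduced
    polygon whose region ancestor is region j.

    Native records mark the cell "native"; a cell that is both (should
    not occur in clean data) stays "nonnative" since Y is defined purely
    as found-non-natively.
    """
    regions = gazetteer.regions
    region_ids = [r.id for r in regions]
    if species_ids is None:
        species_ids = sorted({m.species_id for m in resolved})
    sp_index = {s: i for i, s in enumerate(species_ids)}
    rg_index = {r: j for j, r in enumerate(region_ids)}
    Y = np.zeros((len(species_ids), len(region_ids)), dtype=int)
    status = np.full(Y.shape, "absent", dtype=object)
    for m in resolved:
        region = gazetteer.region_ancestor(m.unit)
        i, j = sp_index[m.species_id], rg_index[region.id]
        if m.status == "introduced":
            Y[i, j] = 1
            status[i, j] = "nonnative"
        elif m.status == "native" and status[i, j] != "nonnative":
            status[i, j] = "native"
    return OccupancyMatrix(
        Y=pd.DataFrame(Y, index=list(species_ids), columns=region_ids),
        status=pd.DataFrame(status, index=list(species_ids), columns=region_ids),
    )


def point_validation(
    points: Sequence[tuple[float, float]], sp_range: SpeciesRange
) -> tuple[float, list[float]]:
    """Fraction of (lat, lon) points covered by any polygon of the
    species' range, plus distances (km) from each outside point to the
    nearest range boundary.  Containment is boundary-inclusive."""
    if len(points) == 0:
        raise ValueError("coverage undefined for an empty point set")
    geoms = [c.geometry for c in sp_range.components]
    if not geoms:
        raise ValueError("species range has no polygons")
    whole = unary_union(geoms)
    inside = 0
    out_dists = []
    for lat, lon in points:
        p = Point(lon, lat)
        if whole.covers(p):
            inside += 1
        else:
            out_dists.append(distance_to_boundary_km(lat, lon, whole))
    return inside / len(points), out_dists


def ranges_to_geojson(ranges: Sequence[SpeciesRange]) -> dict:
    feats = []
    for sr in ranges:
        for k, c in enumerate(sr.components):
            feats.append(
                {
                    "type": "Feature",
                    "geometry": mapping(c.geometry),
                    "properties": {
                        "species_id": sr.species_id,
                        "range_index": k,
                        "status": c.status,
                        "area_km2": c.area_km2,
                        "centroid_lat": c.centroid[0],
                        "centroid_lon": c.centroid[1],
                        "members": c.member_ids,
                    },
                }
            )
    return {"type": "FeatureCollection", "features": feats}


def ingest_records(
    records: pd.DataFrame, gazetteer: Gazetteer
) -> tuple[OccupancyMatrix, dict[str, SpeciesRange]]:
    """Full ingestion: match, resolve, merge, and build occupancy."""
    matched = match_records(records, gazetteer)
    resolved = resolve_levels(matched, gazetteer)
    by_species: dict[str, list[MatchedRecord]] = {}
    for m in resolved:
        by_species.setdefault(m.species_id, []).append(m)
    ranges = {
        sid: build_species_range(sid, recs) for sid, recs in by_species.items()
    }
    occ = build_occupancy(resolved, gazetteer)
    return occ, ranges
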