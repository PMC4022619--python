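"""Waterhole layers and study-area polygons: domain types and file I/O.

All coordinates are planar, in a projected metric CRS (meters). The canonical
representation of a waterhole is its centroid plus surface area; an explicit
polygon footprint is optional and, when present, must agree with the stored
centroid and area. Layers are read from CSV (``id,x,y,area_m2``) or GeoJSON
(RFC 7946 Points carrying an ``area_m2`` property, or Polygons from which
centroid and area are derived).
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, mapping, shape

from .errors import ConfigurationError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: relative tolerance between a stored footprint's polygon area and `area`
FOOTPRINT_AREA_RTOL = 0.005
#: absolute tolerance (m) between a footprint centroid and the stored centroid
FOOTPRINT_CENTROID_ATOL = 1.0


@dataclass(frozen=True)
class Waterhole:
    """A single waterhole: network node with a surface-area attribute.

    Parameters
    ----------
    id : unique identifier within a table.
    x, y : centroid coordinates, projected meters.
    area : surface area in m^2, strictly positive.
    footprint : optional polygon outline (projected meters). If given, its
        area must match ``area`` within 0.5% and its centroid must lie within
        1 m of ``(x, y)``.
    in_reserve : whether the centroid falls inside the reserve polygon
        (``None`` until tagged).
    """

    id: str
    x: float
    y: float
    area: float
    footprint: Polygon | None = None
    in_reserve: bool | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"waterhole {self.id!r}: non-finite coordinates")
        if not (self.area > 0) or not math.isfinite(self.area):
            raise ValidationError(
                f"waterhole {self.id!r}: area must be positive, got {self.area}"
            )
        if self.footprint is not None:
            poly_area = self.footprint.area
            if abs(poly_area - self.area) > FOOTPRINT_AREA_RTOL * self.area:
                raise ValidationError(
                    f"waterhole {self.id!r}: footprint area {poly_area:.1f} "
                    f"disagrees with stored area {self.area:.1f}"
                )
            c = self.footprint.centroid
            if math.hypot(c.x - self.x, c.y - self.y) > FOOTPRINT_CENTROID_ATOL:
                raise ValidationError(
                    f"waterhole {self.id!r}: footprint centroid disagrees with (x, y)"
                )

    @property
    def centroid(self) -> Point:
        return Point(self.x, self.y)


@dataclass(frozen=True)
class StudyArea:
    """Study extent and (optionally) the protected-area polygon inside it."""

    boundary: Polygon
    reserve: Polygon | None = None

    def __post_init__(self) -> None:
        if self.boundary.area <= 0:
            raise ValidationError("study-area boundary must have positive area")
        if self.reserve is not None:
            inter = self.reserve.intersection(self.boundary).area
            if abs(inter - self.reserve.area) > 1e-3 * self.reserve.area:
                raise ValidationError("reserve polygon must lie within the boundary")


@dataclass(frozen=True)
class WaterholeTable:
    """Ordered collection of waterholes plus provenance metadata."""

    waterholes: tuple[Waterhole, ...]
    source: str = "<memory>"
    crs_note: str = "projected meters (unspecified CRS)"

    def __post_init__(self) -> None:
        ids = [w.id for w in self.waterholes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate waterhole ids: {dupes}")

    def __len__(self) -> int:
        return len(self.waterholes)

    def __iter__(self) -> Iterator[Waterhole]:
        return iter(self.waterholes)

    def __getitem__(self, i: int) -> Waterhole:
        return self.waterholes[i]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(w.id for w in self.waterholes)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of centroid coordinates in table order."""
        return np.array([(w.x, w.y) for w in self.waterholes], dtype=float).reshape(-1, 2)

    @property
    def areas(self) -> np.ndarray:
        return np.array([w.area for w in self.waterholes], dtype=float)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum()) if len(self) else 0.0

    def subset(self, keep: Sequence[bool] | np.ndarray) -> "WaterholeTable":
        """Order-preserving subset by boolean mask."""
        kept = tuple(w for w, k in zip(self.waterholes, keep) if k)
        return replace(self, waterholes=kept)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"id": w.id, "x": w.x, "y": w.y, "area_m2": w.area, "in_reserve": w.in_reserve}
            for w in self.waterholes
        ]
        return pd.DataFrame(rows, columns=["id", "x", "y", "area_m2", "in_reserve"])


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ("id", "x", "y", "area_m2")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".geojson", ".json"):
        return "geojson"
    raise FormatError(f"cannot infer format from suffix {suffix!r}; pass format=")


def read_waterholes(path: str | Path, format: str | None = None) -> WaterholeTable:
    """Read a waterhole layer from CSV or GeoJSON.

    CSV must have the columns ``id,x,y,area_m2``. GeoJSON features may be
    Points (with an ``area_m2`` property) or Polygons, whose centroid and
    area are computed from the geometry and whose outline is retained as the
    footprint.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        return _read_waterholes_csv(path)
    if fmt == "geojson":
        return _read_waterholes_geojson(path)
    raise FormatError(f"unsupported format {fmt!r}")


def _read_waterholes_csv(path: Path) -> WaterholeTable:
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    holes = []
    for rec in df.itertuples(index=False):
        in_res = None
        if "in_reserve" in df.columns and not pd.isna(getattr(rec, "in_reserve", None)):
            in_res = bool(getattr(rec, "in_reserve"))
        holes.append(
            Waterhole(
                id=str(rec.id), x=float(rec.x), y=float(rec.y),
                area=float(rec.area_m2), in_reserve=in_res,
            )
        )
    return WaterholeTable(tuple(holes), source=str(path))


def _read_waterholes_geojson(path: Path) -> WaterholeTable:
    with open(path) as fh:
        collection = json.load(fh)
    if collection.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    holes = []
    for i, feat in enumerate(collection.get("features", [])):
        geom = shape(feat["geometry"])
        props = feat.get("properties") or {}
        wid = str(props.get("id", i))
        in_res = props.get("in_reserve")
        if isinstance(geom, Point):
            if "area_m2" not in props:
                raise FormatError(
                    f"{path}: point feature {wid!r} lacks the 'area_m2' property"
                )
            holes.append(
                Waterhole(wid, geom.x, geom.y, float(props["area_m2"]), in_reserve=in_res)
            )
        elif isinstance(geom, Polygon):
            c = geom.centroid
            holes.append(
                Waterhole(wid, c.x, c.y, geom.area, footprint=geom, in_reserve=in_res)
            )
        else:
            raise FormatError(
                f"{path}: unsupported geometry type {geom.geom_type!r} in feature {wid!r}"
            )
    return WaterholeTable(tuple(holes), source=str(path))


def read_polygon(path: str | Path) -> Polygon:
    """Read a single polygon (boundary or reserve) from a GeoJSON file."""
    path = Path(path)
    with open(path) as fh:
        obj = json.load(fh)
    if obj.get("type") == "FeatureCollection":
        feats = obj.get("features", [])
        if len(feats) != 1:
            raise FormatError(f"{path}: expected exactly one polygon feature")
        geom = shape(feats[0]["geometry"])
    elif obj.get("type") == "Feature":
        geom = shape(obj["geometry"])
    else:
        geom = shape(obj)
    if not isinstance(geom, Polygon):
        raise FormatError(f"{path}: expected a Polygon, got {geom.geom_type}")
    return geom


# ---------------------------------------------------------------------------
# taggers
# ---------------------------------------------------------------------------

def tag_reserve_membership(table: WaterholeTable, area: StudyArea) -> WaterholeTable:
    """Set ``in_reserve`` per waterhole by centroid point-in-polygon.

    A centroid exactly on the reserve boundary counts as inside (shapely
    ``covers`` semantics).
    """
    if area.reserve is None:
        raise ConfigurationError("study area has no reserve polygon to tag against")
    reserve = area.reserve
    tagged = tuple(
        replace(w, in_reserve=bool(reserve.covers(w.centroid))) for w in table
    )
    return replace(table, waterholes=tagged)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write any tabular result to CSV (UTF-8, '.' decimal, full precision)."""
    path = Path(path)
    if len(records) == 0:
        logger.warning("writing header-only table to %s (no records)", path)
    records.to_csv(path, index=False, float_format="%.17g")


def write_waterholes_csv(table: WaterholeTable, path: str | Path) -> None:
    df = table.to_dataframe()
    if df["in_reserve"].isna().all():
        df = df.drop(columns=["in_reserve"])
    write_table(df, path)


def write_waterholes_geojson(table: WaterholeTable, path: str | Path) -> None:
    feats = []
    for w in table:
        geom = w.footprint if w.footprint is not None else w.centroid
        props = {"id": w.id, "area_m2": w.area}
        if w.in_reserve is not None:
            props["in_reserve"] = w.in_reserve
        feats.append({"type": "Feature", "geometry": mapping(geom), "properties": props})
    _dump_feature_collection(feats, path)


def write_polygon_geojson(poly: Polygon, path: str | Path, **properties) -> None:
    feats = [{"type": "Feature", "geometry": mapping(poly), "properties": properties}]
    _dump_feature_collection(feats, path)


def write_network_geojson(network, path: str | Path) -> None:
    """Export a network: nodes as Points, links as LineStrings.

    Node properties: id, area_m2, in_reserve (when tagged). Link properties:
    endpoint ids, length_m, probability (when assigned).
    """
    feats = []
    for w in network.nodes:
        props = {"id": w.id, "area_m2": w.area, "kind": "node"}
        if w.in_reserve is not None:
            props["in_reserve"] = w.in_reserve
        feats.append(
            {"type": "Feature", "geometry": mapping(w.centroid), "properties": props}
        )
    for link in network.links:
        a = network.nodes[network.index_of(link.a)]
        b = network.nodes[network.index_of(link.b)]
        props = {"kind": "link", "a": link.a, "b": link.b, "length_m": link.length}
        if link.probability is not None:
            props["probability"] = link.probability
        feats.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [[a.x, a.y], [b.x, b.y]],
                },
                "properties": props,
            }
        )
    _dump_feature_collection(feats, path)


def _dump_feature_collection(features: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
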