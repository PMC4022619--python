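"""Waterhole-associated suitable habitat via buffer unions.

Suitable habitat is the union of fixed-radius buffers (1 and 2 km by
default) grown around the edge of each waterhole footprint, clipped to the
study boundary. When no polygon outline is stored, the footprint is
approximated by a 128-segment circle of equal area centered on the
centroid. Overlapping or touching buffers merge into a single connected
habitat patch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from shapely.geometry import MultiPolygon, Point, Polygon
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .errors import ValidationError
from .landscape_io import StudyArea, Waterhole, WaterholeTable
from .scenarios import DroughtScenario, apply_scenario

#: segments used to discretize circular footprints and buffer arcs
DEFAULT_N_SEGMENTS = 128


def footprint(w: Waterhole, n_segments: int = DEFAULT_N_SEGMENTS) -> Polygon:
    """Polygon outline of a waterhole.

    The stored polygon is returned unchanged when present; otherwise a
    regular ``n_segments``-gon circle of radius sqrt(area / pi) centered at
    the centroid (area error < 0.1% at 128 segments).
    """
    if w.footprint is not None:
        return w.footprint
    r = math.sqrt(w.area / math.pi)
    return Point(w.x, w.y).buffer(r, quad_segs=max(1, n_segments // 4))


@dataclass(frozen=True)
class HabitatSummary:
    """Buffer-union habitat for one (scenario, radius)."""

    buffer_radius: float  # m
    geometry: BaseGeometry  # union polygons, clipped to the boundary
    total_area: float  # m^2
    percent_of_study_area: float  # 0..100
    n_patches: int  # disjoint polygons in the union
    scenario: str | None = None


def _count_patches(geom: BaseGeometry) -> int:
    if geom.is_empty:
        return 0
    if isinstance(geom, MultiPolygon):
        return len(geom.geoms)
    return 1


def buffered_habitat(
    table: WaterholeTable,
    radius: float,
    area: StudyArea,
    n_segments: int = DEFAULT_N_SEGMENTS,
    scenario: str | None = None,
) -> HabitatSummary:
    """Union of per-waterhole buffers, clipped to the study boundary."""
    if not radius > 0:
        raise ValidationError(f"buffer radius must be positive, got {radius}")
    quad = max(1, n_segments // 4)
    buffers = [footprint(w, n_segments).buffer(radius, quad_segs=quad) for w in table]
    union = unary_union(buffers) if buffers else Polygon()
    clipped = union.intersection(area.boundary)
    total = clipped.area
    return HabitatSummary(
        buffer_radius=float(radius),
        geometry=clipped,
        total_area=total,
        percent_of_study_area=100.0 * total / area.boundary.area,
        n_patches=_count_patches(clipped),
        scenario=scenario,
    )


def habitat_sweep(
    table: WaterholeTable,
    scenarios: Sequence[DroughtScenario],
    area: StudyArea,
    radii: Sequence[float] = (1_000.0, 2_000.0),
    n_segments: int = DEFAULT_N_SEGMENTS,
) -> list[HabitatSummary]:
    """One summary per (scenario, radius); habitat shrinks along the ladder."""
    summaries = []
    for sc in scenarios:
        survivors = apply_scenario(table, sc)
        for radius in radii:
            summaries.append(
                buffered_habitat(
                    survivors, radius, area, n_segments=n_segments, scenario=sc.label
                )
            )
    return summaries


def habitat_to_dataframe(summaries: Sequence[HabitatSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scenario": s.scenario,
                "buffer_radius_m": s.buffer_radius,
                "total_area_m2": s.total_area,
                "percent_of_study_area": s.percent_of_study_area,
                "n_patches": s.n_patches,
            }
            for s in summaries
        ]
    )
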