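"""Platform layout representation and boarding/alighting classification.

A railway platform is described by a measurement-area polygon plus named
regions where trajectories may legitimately begin or end: *entry* regions
(stair and elevator mouths), *edge* regions (the platform-train interface
where doors open) and *lateral boundaries* (the open ends of the observed
strip).  Obstacles (stair blocks, elevator shafts, information boards) are
carried along for scenario generation and plotting but play no role in
classification.

A boarding passenger's trajectory starts at a platform entry and ends at a
train door; the reverse is an alighting passenger; anything else — typically
a fragmented track — is ``unknown``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from shapely.geometry import Point, Polygon
from shapely.ops import unary_union

__all__ = [
    "GeometryError",
    "PlatformGeometry",
    "BOARDING",
    "ALIGHTING",
    "UNKNOWN",
    "PASSENGER_CLASSES",
    "DEFAULT_SNAP_TOLERANCE",
    "classify_passenger",
    "load_geometry",
    "save_geometry",
    "schematic_platform",
]

#: Points within this distance (m) of a region still count as inside it,
#: allowing for sensor jitter at trajectory endpoints.
DEFAULT_SNAP_TOLERANCE = 0.5

BOARDING = "boarding"
ALIGHTING = "alighting"
UNKNOWN = "unknown"
PASSENGER_CLASSES = (BOARDING, ALIGHTING, UNKNOWN)


class GeometryError(ValueError):
    """Raised for invalid or inconsistent platform geometry."""


def _check_polygon(name: str, poly: Polygon) -> None:
    if not isinstance(poly, Polygon) or poly.is_empty:
        raise GeometryError(f"region {name!r} is not a non-empty polygon")
    if not poly.is_valid:
        raise GeometryError(f"region {name!r} is not a valid (simple) polygon")


@dataclass(frozen=True)
class PlatformGeometry:
    """Measurement area plus the named regions used for classification.

    All coordinates are planar metres with an arbitrary origin.
    """

    measurement_area: Polygon
    entry_regions: Mapping[str, Polygon]
    edge_regions: Mapping[str, Polygon]
    lateral_boundaries: Mapping[str, Polygon] = field(default_factory=dict)
    obstacles: Mapping[str, Polygon] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_polygon("measurement_area", self.measurement_area)
        for group_name, group in (
            ("entry", self.entry_regions),
            ("edge", self.edge_regions),
            ("lateral", self.lateral_boundaries),
            ("obstacle", self.obstacles),
        ):
            for name, poly in group.items():
                _check_polygon(f"{group_name}:{name}", poly)
                if group_name != "obstacle" and not poly.intersects(
                    self.measurement_area
                ):
                    raise GeometryError(
                        f"{group_name} region {name!r} does not intersect "
                        "the measurement area"
                    )
        for en, ep in self.entry_regions.items():
            for dn, dp in self.edge_regions.items():
                if ep.intersection(dp).area > 1e-12:
                    raise GeometryError(
                        f"entry region {en!r} overlaps edge region {dn!r}"
                    )

    # -- region membership -------------------------------------------------

    def boundary_regions(self) -> Iterator[Polygon]:
        """All regions where a complete trajectory may start or end."""
        yield from self.entry_regions.values()
        yield from self.edge_regions.values()
        yield from self.lateral_boundaries.values()

    def boundary_union(self, tol: float = DEFAULT_SNAP_TOLERANCE):
        """Union of all plausible start/end regions, dilated by ``tol``."""
        return unary_union(list(self.boundary_regions())).buffer(tol)

    @staticmethod
    def _in_any(regions: Iterable[Polygon], xy, tol: float) -> bool:
        pt = Point(float(xy[0]), float(xy[1]))
        return any(poly.covers(pt) or poly.distance(pt) <= tol for poly in regions)

    def in_entry(self, xy, tol: float = DEFAULT_SNAP_TOLERANCE) -> bool:
        return self._in_any(self.entry_regions.values(), xy, tol)

    def in_edge(self, xy, tol: float = DEFAULT_SNAP_TOLERANCE) -> bool:
        return self._in_any(self.edge_regions.values(), xy, tol)

    def is_plausible_endpoint(self, xy, tol: float = DEFAULT_SNAP_TOLERANCE) -> bool:
        return self._in_any(self.boundary_regions(), xy, tol)


def classify_passenger(
    traj, geometry: PlatformGeometry, tol: float = DEFAULT_SNAP_TOLERANCE
) -> str:
    """Label a trajectory ``boarding``, ``alighting`` or ``unknown``.

    Classification uses only the first and last sampled positions: entry
    to train door is boarding, door to entry is alighting.  Membership is
    boundary-inclusive with a snap tolerance of ``tol`` metres.
    """
    start = traj.positions[0]
    end = traj.positions[-1]
    if geometry.in_entry(start, tol) and geometry.in_edge(end, tol):
        return BOARDING
    if geometry.in_edge(start, tol) and geometry.in_entry(end, tol):
        return ALIGHTING
    return UNKNOWN


# -- serialisation ---------------------------------------------------------
#
# JSON schema: each region group maps region names to coordinate rings
# (lists of [x, y] pairs in metres); the measurement area is a single ring.
#
# {
#   "measurement_area": [[x, y], ...],
#   "entry_regions":      {"name": [[x, y], ...], ...},
#   "edge_regions":       {"name": [[x, y], ...], ...},
#   "lateral_boundaries": {"name": [[x, y], ...], ...},
#   "obstacles":          {"name": [[x, y], ...], ...}
# }


def _ring(poly: Polygon) -> list[list[float]]:
    return [[float(x), float(y)] for x, y in poly.exterior.coords[:-1]]


def save_geometry(geometry: PlatformGeometry, sink: str | Path) -> None:
    doc = {
        "measurement_area": _ring(geometry.measurement_area),
        "entry_regions": {k: _ring(v) for k, v in geometry.entry_regions.items()},
        "edge_regions": {k: _ring(v) for k, v in geometry.edge_regions.items()},
        "lateral_boundaries": {
            k: _ring(v) for k, v in geometry.lateral_boundaries.items()
        },
        "obstacles": {k: _ring(v) for k, v in geometry.obstacles.items()},
    }
    Path(sink).write_text(json.dumps(doc, indent=2) + "\n")


def load_geometry(source: str | Path) -> PlatformGeometry:
    """Load and validate a platform geometry from its JSON description."""
    try:
        doc = json.loads(Path(source).read_text())
    except json.JSONDecodeError as exc:
        raise GeometryError(f"cannot parse geometry file {source}: {exc}") from exc
    try:
        area = Polygon(doc["measurement_area"])
    except KeyError as exc:
        raise GeometryError("geometry file lacks 'measurement_area'") from exc

    def group(key: str) -> dict[str, Polygon]:
        return {name: Polygon(ring) for name, ring in doc.get(key, {}).items()}

    return PlatformGeometry(
        measurement_area=area,
        entry_regions=group("entry_regions"),
        edge_regions=group("edge_regions"),
        lateral_boundaries=group("lateral_boundaries"),
        obstacles=group("obstacles"),
    )


def _rect(x0: float, y0: float, x1: float, y1: float) -> Polygon:
    return Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])


def schematic_platform() -> PlatformGeometry:
    """A schematic symmetric island platform, roughly 50 m x 10 m.

    Two stair blocks and two elevators sit on the platform axis with an
    information board between them; stair/elevator mouths are the entry
    regions, strips along both long sides are the platform-train interface,
    and thin strips at both open ends are the lateral boundaries.  The
    layout is schematic (proportions of a typical observed platform strip),
    not a surveyed plan.
    """
    area = _rect(-25.0, 0.0, 25.0, 10.0)
    obstacles = {
        "stair_west": _rect(-18.0, 4.0, -9.0, 6.0),
        "stair_east": _rect(9.0, 4.0, 18.0, 6.0),
        "elevator_west": _rect(-6.0, 4.2, -4.0, 5.8),
        "elevator_east": _rect(4.0, 4.2, 6.0, 5.8),
        "info_board": _rect(-1.0, 4.6, 1.0, 5.4),
    }
    entries = {
        "stair_west": _rect(-9.0, 4.0, -8.0, 6.0),
        "stair_east": _rect(8.0, 4.0, 9.0, 6.0),
        "elevator_west": _rect(-6.2, 5.8, -3.8, 6.8),
        "elevator_east": _rect(3.8, 5.8, 6.2, 6.8),
    }
    edges = {
        "track_south": _rect(-25.0, 0.0, 25.0, 0.8),
        "track_north": _rect(-25.0, 9.2, 25.0, 10.0),
    }
    laterals = {
        "west_end": _rect(-25.0, 0.0, -24.5, 10.0),
        "east_end": _rect(24.5, 0.0, 25.0, 10.0),
    }
    return PlatformGeometry(
        measurement_area=area,
        entry_regions=entries,
        edge_regions=edges,
        lateral_boundaries=laterals,
        obstacles=obstacles,
    )
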