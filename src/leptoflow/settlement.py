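"""Settlement zones and the competency-window settlement rule.

Settlement zones are named polygons (GeoJSON, WGS84 lon/lat) grouped by
island; they deliberately extend beyond the shoreline, so boundary
points count as inside.  A larva settles when its post-step position
falls in a zone while its age is inside the closed competency window
(41–71 days post spawn by default).  Presence in a zone before
competency has no effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon, shape, mapping

from .larval_ibm import BioRules, Fate

__all__ = [
    "SettlementZone",
    "SettlementRecord",
    "load_zones",
    "save_zones",
    "point_in_zone",
    "zone_index",
    "settle_check",
]


@dataclass(frozen=True)
class SettlementZone:
    zone_id: str
    island: str
    polygon: Polygon = dc_field(repr=False)

    def __post_init__(self) -> None:
        if not self.island:
            raise ValueError(f"zone {self.zone_id!r} has an empty island name")
        if not self.polygon.is_valid:
            raise ValueError(f"zone {self.zone_id!r} polygon is invalid "
                             "(self-intersecting or degenerate ring)")


@dataclass(frozen=True)
class SettlementRecord:
    larva_id: int
    iteration: int
    island: str
    time: float  # seconds since origin
    dps: float  # days post spawn at settlement
    lon: float
    lat: float


def load_zones(path) -> list[SettlementZone]:
    """Read settlement zones from a GeoJSON FeatureCollection.

    Every feature needs an ``island`` property; ``zone_id`` defaults to
    the feature index.  Invalid rings are rejected with the feature
    index in the error message.
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    zones: list[SettlementZone] = []
    for i, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        if "island" not in props:
            raise ValueError(f"{path}: feature {i} lacks the 'island' property")
        geom = shape(feat["geometry"])
        if geom.geom_type != "Polygon":
            raise ValueError(
                f"{path}: feature {i} geometry is {geom.geom_type}, expected Polygon"
            )
        if not geom.is_valid:
            raise ValueError(f"{path}: feature {i} has a self-intersecting ring")
        zones.append(
            SettlementZone(
                zone_id=str(props.get("zone_id", i)),
                island=str(props["island"]),
                polygon=geom,
            )
        )
    return zones


def save_zones(zones: Sequence[SettlementZone], path) -> None:
    gj = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"island": z.island, "zone_id": z.zone_id},
                "geometry": mapping(z.polygon),
            }
            for z in zones
        ],
    }
    with open(path, "w") as fh:
        json.dump(gj, fh)


def zone_index(lon, lat, zones: Sequence[SettlementZone]) -> np.ndarray:
    """Index of the first containing zone for each point, −1 if none.

    Containment is closed (``covers``): points on a zone boundary are
    inside.  Overlaps resolve by zone order, so assignment is
    deterministic.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    pts = shapely.points(lon, lat)
    out = np.full(lon.shape, -1, dtype=np.int64)
    for k, z in enumerate(zones):
        unassigned = out < 0
        if not unassigned.any():
            break
        hit = shapely.covers(z.polygon, pts[unassigned])
        idx = np.flatnonzero(unassigned)[hit]
        out[idx] = k
    return out


def point_in_zone(lon, lat, zones: Sequence[SettlementZone]):
    """Island name of the first zone covering (lon, lat), else None."""
    k = int(zone_index(lon, lat, zones)[0])
    return zones[k].island if k >= 0 else None


def settle_check(lon, lat, age_days, fate, zones: Sequence[SettlementZone],
                 rules: BioRules = BioRules()) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized settlement rule.

    Returns (new_fate, zone_idx): alive larvae whose age lies in the
    closed competency window and whose position is covered by a zone
    become SETTLED with that zone's index; everyone else is unchanged
    (zone_idx −1).
    """
    fate = np.asarray(fate, dtype=np.int16).copy()
    age = np.asarray(age_days, dtype=float)
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    competent = (
        (fate == Fate.ALIVE)
        & (age >= rules.competency_start)
        & (age <= rules.competency_end)
    )
    zidx = np.full(fate.shape, -1, dtype=np.int64)
    if competent.any() and zones:
        hit_idx = zone_index(lon[competent], lat[competent], zones)
        zidx[competent] = hit_idx
        settled = np.flatnonzero(competent)[hit_idx >= 0]
        fate[settled] = Fate.SETTLED
    zidx[fate != Fate.SETTLED] = -1
    return fate, zidx
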