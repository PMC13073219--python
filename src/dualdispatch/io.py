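"""Plain-text persistence: CSV tables, GeoJSON features, ASCII grids.

All coordinates are written in the planar kilometre system of the synthetic
region. The real-data adapter accepts station GeoJSON and an ESRI
ASCII-grid density raster in any planar CRS whose units are declared in the
run configuration; downstream code is CRS-agnostic.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dispatch import ResponseRecord, records_to_frame
from .errors import ConfigurationError, ReportError
from .events import Event
from .geography import Region, RoadNetwork, Service, Station, StationSet

__all__ = [
    "write_density_csv",
    "read_density_csv",
    "write_ascii_grid",
    "read_ascii_grid",
    "write_network_geojson",
    "write_stations_geojson",
    "read_station_points_geojson",
    "stations_from_points",
    "write_events_csv",
    "write_events_geojson",
    "write_records_csv",
    "read_records_csv",
    "write_records_geojson",
]


# ---------------------------------------------------------------- rasters

def write_density_csv(region: Region, path: str | Path) -> None:
    """Row-major density grid with a header carrying cell size and origin."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# cell_km={region.cell_km}\n")
        fh.write("# origin_km=0,0\n")
        fh.write(f"# width_km={region.width_km} height_km={region.height_km}\n")
        fh.write(f"# total_population={region.total_population}\n")
        np.savetxt(fh, region.density, delimiter=",", fmt="%.8g")


def read_density_csv(path: str | Path) -> Region:
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        lines = fh.readlines()
    data_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        data_start += 1
        for token in line[1:].split():
            if "=" in token:
                k, v = token.split("=", 1)
                meta[k] = v
    density = np.loadtxt(lines[data_start:], delimiter=",", ndmin=2)
    return Region(
        width_km=float(meta["width_km"]),
        height_km=float(meta["height_km"]),
        cell_km=float(meta["cell_km"]),
        density=density,
        total_population=float(meta["total_population"]),
    )


def write_ascii_grid(region: Region, path: str | Path, nodata: float = -9999.0) -> None:
    """ESRI ASCII grid; rows are written north-first per the format."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"ncols {region.n_cols}\n")
        fh.write(f"nrows {region.n_rows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {region.cell_km}\n")
        fh.write(f"NODATA_value {nodata}\n")
        np.savetxt(fh, region.density[::-1], fmt="%.8g")


def read_ascii_grid(
    path: str | Path, total_population: float | None = None
) -> Region:
    """Real-raster adapter: load a density surface from an ESRI ASCII grid.

    NODATA cells become zero density. When ``total_population`` is given the
    raster is renormalised to that mass; otherwise the raster's own mass is
    taken as the population.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ConfigurationError(f"ASCII grid missing header field {key!r}")
    density = np.loadtxt(lines[i:], ndmin=2)[::-1]
    if density.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ConfigurationError("ASCII grid data shape does not match header")
    nodata = header.get("nodata_value")
    if nodata is not None:
        density = np.where(density == nodata, 0.0, density)
    density = np.clip(density, 0.0, None)
    cell = header["cellsize"]
    mass = float(density.sum()) * cell * cell
    if mass <= 0:
        raise ConfigurationError("ASCII grid carries no population mass")
    if total_population is not None:
        density = density * (total_population / mass)
        mass = total_population
    return Region(
        width_km=int(header["ncols"]) * cell,
        height_km=int(header["nrows"]) * cell,
        cell_km=cell,
        density=density,
        total_population=mass,
    )


# ---------------------------------------------------------------- GeoJSON

def _feature_collection(features: list[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def _point(xy: Sequence[float], properties: dict) -> dict:
    return {
        "type": "Feature",
        "geometry": {"type": "Point", "coordinates": [float(xy[0]), float(xy[1])]},
        "properties": properties,
    }


def write_network_geojson(network: RoadNetwork, path: str | Path) -> None:
    """Road edges as LineString features with speed and length properties."""
    features = []
    for (a, b), l, s in zip(network.edges, network.length_km, network.speed_kmh):
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [
                        [float(network.node_xy[a, 0]), float(network.node_xy[a, 1])],
                        [float(network.node_xy[b, 0]), float(network.node_xy[b, 1])],
                    ],
                },
                "properties": {
                    "from_node": int(a),
                    "to_node": int(b),
                    "length_km": float(l),
                    "speed_kmh": float(s),
                },
            }
        )
    Path(path).write_text(json.dumps(_feature_collection(features)))


def write_stations_geojson(stations: StationSet, path: str | Path) -> None:
    features = [
        _point(
            s.location,
            {
                "id": s.id,
                "service": s.service.value,
                "node": s.node,
                "snap_distance_km": s.snap_distance_km,
            },
        )
        for s in stations
    ]
    Path(path).write_text(json.dumps(_feature_collection(features)))


def read_station_points_geojson(path: str | Path) -> list[tuple[Service, float, float]]:
    """Real-data adapter: (service, x, y) triples from a station GeoJSON.

    Each feature must be a Point with a ``service`` property equal to
    ``"EMS"`` or ``"FIRE"``.
    """
    doc = json.loads(Path(path).read_text())
    out = []
    for feat in doc.get("features", []):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise ConfigurationError("station features must be Points")
        service = Service(feat.get("properties", {})["service"])
        x, y = geom["coordinates"][:2]
        out.append((service, float(x), float(y)))
    if not out:
        raise ConfigurationError("station file contains no features")
    return out


def stations_from_points(
    points: Iterable[tuple[Service, float, float]], network: RoadNetwork
) -> StationSet:
    """Snap adapter-loaded station points to the road network."""
    stations = []
    for sid, (service, x, y) in enumerate(points):
        nodes, dists = network.snap(np.array([x, y]))
        stations.append(
            Station(
                id=sid,
                service=service,
                location=(x, y),
                node=int(nodes[0]),
                snap_distance_km=float(dists[0]),
            )
        )
    return StationSet(stations)


def write_events_csv(events: Sequence[Event], path: str | Path) -> None:
    pd.DataFrame(
        {
            "event_id": [e.id for e in events],
            "x_km": [e.location[0] for e in events],
            "y_km": [e.location[1] for e in events],
            "cell_i": [e.cell[0] for e in events],
            "cell_j": [e.cell[1] for e in events],
            "node": [e.node for e in events],
            "local_density": [e.local_density for e in events],
        }
    ).to_csv(path, index=False)


def write_events_geojson(events: Sequence[Event], path: str | Path) -> None:
    features = [
        _point(
            e.location,
            {
                "id": e.id,
                "cell": list(e.cell),
                "node": e.node,
                "local_density": e.local_density,
            },
        )
        for e in events
    ]
    Path(path).write_text(json.dumps(_feature_collection(features)))


def write_records_csv(records: Sequence[ResponseRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ReportError(f"missing records file: {path}")
    return pd.read_csv(path)


def write_records_geojson(records: Sequence[ResponseRecord], path: str | Path) -> None:
    """Per-event map layer: times and first arriver as point properties."""
    features = [
        _point(
            r.location,
            {
                "event_id": r.event_id,
                "local_density": r.local_density,
                "ems_response_min": r.ems_response_min,
                "fire_response_min": r.fire_response_min,
                "dual_response_min": r.dual_response_min,
                "first_arriver": r.first_arriver.value,
            },
        )
        for r in records
    ]
    Path(path).write_text(json.dumps(_feature_collection(features)))
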