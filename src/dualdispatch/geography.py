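"""Synthetic study-region generator.

Produces the three substrates every downstream stage consumes: a
population-density raster (:class:`Region`), a speed-classed road graph
(:class:`RoadNetwork`) and typed responder bases (:class:`StationSet`).
Defaults emulate a large, heterogeneous federal state: ~19,000 km^2,
1.73 million inhabitants, sparse rural background plus dense peri-urban
clusters, 121 ambulance stations and 1590 volunteer fire stations
(a ~13:1 ratio), with station-to-scene driving times spanning roughly
1-25 minutes.

All coordinates are planar Cartesian kilometres; there is no geodesy.
Every generator is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from functools import cached_property
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError, PlacementError

__all__ = [
    "Service",
    "Region",
    "RoadNetwork",
    "Station",
    "StationSet",
    "GeographyConfig",
    "generate_region",
    "generate_road_network",
    "place_stations",
    "generate_geography",
]


class Service(str, Enum):
    """Responder service type."""

    EMS = "EMS"
    FIRE = "FIRE"


@dataclass(eq=False)
class Region:
    """Population-density raster over a rectangular planar study area.

    ``density`` holds inhabitants per km^2 on a regular grid of square cells
    of side ``cell_km``; row index ``i`` runs south->north (y), column ``j``
    west->east (x). Cell (i, j) covers
    ``[j*cell_km, (j+1)*cell_km) x [i*cell_km, (i+1)*cell_km)``.
    """

    width_km: float
    height_km: float
    cell_km: float
    density: np.ndarray  # shape (n_rows, n_cols), inhabitants / km^2
    total_population: float

    @property
    def n_rows(self) -> int:
        return self.density.shape[0]

    @property
    def n_cols(self) -> int:
        return self.density.shape[1]

    @property
    def cell_area_km2(self) -> float:
        return self.cell_km * self.cell_km

    @property
    def cell_population(self) -> np.ndarray:
        """Inhabitants per cell (density x cell area)."""
        return self.density * self.cell_area_km2

    def cell_of(self, x_km: float, y_km: float) -> tuple[int, int]:
        """Raster index (i, j) containing a point; clipped to the grid."""
        j = min(int(x_km / self.cell_km), self.n_cols - 1)
        i = min(int(y_km / self.cell_km), self.n_rows - 1)
        return max(i, 0), max(j, 0)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of all cell centres, each shaped like density."""
        xs = (np.arange(self.n_cols) + 0.5) * self.cell_km
        ys = (np.arange(self.n_rows) + 0.5) * self.cell_km
        return np.meshgrid(xs, ys)

    def validate(self) -> None:
        if self.width_km <= 0 or self.height_km <= 0 or self.cell_km <= 0:
            raise ConfigurationError("region dimensions must be positive")
        if self.total_population <= 0:
            raise ConfigurationError("total_population must be positive")
        expect = (
            math.ceil(self.height_km / self.cell_km),
            math.ceil(self.width_km / self.cell_km),
        )
        if self.density.shape != expect:
            raise ConfigurationError(
                f"density grid {self.density.shape} != expected {expect}"
            )
        if np.any(self.density < 0) or not np.any(self.density > 0):
            raise ConfigurationError("density must be >= 0 with at least one positive cell")
        mass = float(self.density.sum()) * self.cell_area_km2
        if abs(mass - self.total_population) > 1e-3 * self.total_population:
            raise ConfigurationError(
                f"raster mass {mass:.1f} differs from total_population "
                f"{self.total_population:.1f} by more than 0.1%"
            )


@dataclass(eq=False)
class RoadNetwork:
    """Undirected road graph on planar coordinates.

    ``node_xy[i]`` is the (x_km, y_km) position of node ``i``; ``edges`` is an
    (m, 2) integer array of node pairs; ``length_km`` and ``speed_kmh`` are
    per-edge. Edge travel time in minutes is ``60 * length / speed``.
    """

    node_xy: np.ndarray  # (n, 2) float
    edges: np.ndarray  # (m, 2) int
    length_km: np.ndarray  # (m,) float
    speed_kmh: np.ndarray  # (m,) float

    @property
    def n_nodes(self) -> int:
        return self.node_xy.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def travel_time_min(self) -> np.ndarray:
        return 60.0 * self.length_km / self.speed_kmh

    @cached_property
    def kdtree(self) -> cKDTree:
        return cKDTree(self.node_xy)

    def snap(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest node id(s) and Euclidean snap distance(s) for point(s)."""
        dist, idx = self.kdtree.query(np.atleast_2d(xy))
        return idx, dist

    @cached_property
    def csgraph(self):
        """Symmetric sparse adjacency weighted by edge travel time (min)."""
        from scipy.sparse import coo_matrix

        w = self.travel_time_min
        i, j = self.edges[:, 0], self.edges[:, 1]
        n = self.n_nodes
        return coo_matrix(
            (np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(n, n),
        ).tocsr()

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for i, (x, y) in enumerate(self.node_xy):
            g.add_node(i, x_km=float(x), y_km=float(y))
        for (a, b), l, s, t in zip(
            self.edges, self.length_km, self.speed_kmh, self.travel_time_min
        ):
            g.add_edge(int(a), int(b), length_km=float(l), speed_kmh=float(s), weight=float(t))
        return g

    def is_connected(self) -> bool:
        from scipy.sparse.csgraph import connected_components

        n_comp, _ = connected_components(self.csgraph, directed=False)
        return n_comp == 1


@dataclass(frozen=True)
class Station:
    """A responder base snapped to the road network."""

    id: int
    service: Service
    location: tuple[float, float]  # (x_km, y_km)
    node: int
    snap_distance_km: float


@dataclass(eq=False)
class StationSet:
    """All stations of a generated (or loaded) instance."""

    stations: list[Station]

    def of_service(self, service: Service) -> list[Station]:
        return [s for s in self.stations if s.service == service]

    def locations(self, service: Service) -> np.ndarray:
        return np.array([s.location for s in self.of_service(service)], dtype=float)

    def __len__(self) -> int:
        return len(self.stations)

    def __iter__(self):
        return iter(self.stations)


@dataclass(frozen=True)
class GeographyConfig:
    """Parameters of the synthetic-region generator.

    Defaults describe the study-scale region: a 160 x 120 km rectangle
    (19,200 km^2) with 1.73 M inhabitants, 121 EMS and 1590 fire stations.
    ``n_road_nodes`` controls routing resolution; speed classes are
    urban / rural / highway in km/h.
    """

    width_km: float = 160.0
    height_km: float = 120.0
    cell_km: float = 2.0
    total_population: float = 1.73e6

    n_population_clusters: int = 25
    cluster_sigma_km: tuple[float, float] = (2.0, 8.0)
    cluster_mass_sigma: float = 1.0  # lognormal spread of relative cluster masses
    urban_population_fraction: float = 0.6  # share of mass in clusters (pre-renorm)
    rural_background_density: float = 50.0  # inhabitants/km^2 before renormalisation

    n_ems: int = 121
    n_fire: int = 1590
    fire_population_blend: float = 0.5  # 1 = fully population-weighted fire placement
    settled_density_threshold: float = 1.0  # cells above this count as settled

    n_road_nodes: int = 6000
    knn_neighbors: int = 4
    highway_edge_fraction: float = 0.03  # of scaffold edge count
    highway_min_length_km: float = 20.0
    speed_classes_kmh: tuple[float, float, float] = (40.0, 70.0, 100.0)  # urban, rural, highway
    urban_density_threshold: float = 300.0  # inhabitants/km^2
    road_winding_factor: float = 1.2  # edge length = Euclidean * winding
    node_background_weight: float = 50.0  # added to density when sampling node cells

    seed: int = 42

    def validate(self) -> None:
        if min(self.width_km, self.height_km, self.cell_km) <= 0:
            raise ConfigurationError("region dimensions must be positive")
        if self.total_population <= 0:
            raise ConfigurationError("total_population must be positive")
        if self.n_population_clusters < 0:
            raise ConfigurationError("n_population_clusters must be >= 0")
        if self.n_ems < 1 or self.n_fire < 1:
            raise ConfigurationError("station counts must be >= 1")
        if self.n_fire < self.n_ems:
            raise ConfigurationError("n_fire must be >= n_ems (study ratio)")
        if self.n_road_nodes < 2:
            raise ConfigurationError("n_road_nodes must be >= 2")
        if not 0.0 <= self.fire_population_blend <= 1.0:
            raise ConfigurationError("fire_population_blend must be in [0, 1]")
        if self.n_population_clusters > 0 and self.rural_background_density < 0:
            raise ConfigurationError("rural_background_density must be >= 0")
        if any(s <= 0 for s in self.speed_classes_kmh):
            raise ConfigurationError("speed classes must be positive")


def _rng(seed: int, stream: int) -> np.random.Generator:
    # independent substreams so region/network/station draws do not interact
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(8)[stream])


def generate_region(config: GeographyConfig) -> Region:
    """Generate the population-density raster.

    The surface is a uniform rural background plus a mixture of isotropic
    Gaussian clusters (centres uniform in the rectangle, relative masses
    lognormal, spreads uniform in ``cluster_sigma_km``), evaluated at cell
    centres and renormalised so the raster mass equals ``total_population``
    exactly. With zero clusters the result is a uniform raster.
    """
    config.validate()
    rng = _rng(config.seed, 0)

    n_rows = math.ceil(config.height_km / config.cell_km)
    n_cols = math.ceil(config.width_km / config.cell_km)
    xs = (np.arange(n_cols) + 0.5) * config.cell_km
    ys = (np.arange(n_rows) + 0.5) * config.cell_km
    gx, gy = np.meshgrid(xs, ys)

    density = np.full((n_rows, n_cols), float(config.rural_background_density))

    k = config.n_population_clusters
    if k > 0:
        centers_x = rng.uniform(0, config.width_km, size=k)
        centers_y = rng.uniform(0, config.height_km, size=k)
        sigmas = rng.uniform(*config.cluster_sigma_km, size=k)
        masses = rng.lognormal(mean=0.0, sigma=config.cluster_mass_sigma, size=k)
        masses *= (
            config.urban_population_fraction * config.total_population / masses.sum()
        )
        for cx, cy, sig, mass in zip(centers_x, centers_y, sigmas, masses):
            r2 = (gx - cx) ** 2 + (gy - cy) ** 2
            density += mass / (2 * np.pi * sig**2) * np.exp(-r2 / (2 * sig**2))

    if density.sum() <= 0:
        raise ConfigurationError("generated raster has zero mass")
    density *= config.total_population / (density.sum() * config.cell_km**2)

    region = Region(
        width_km=config.width_km,
        height_km=config.height_km,
        cell_km=config.cell_km,
        density=density,
        total_population=config.total_population,
    )
    region.validate()
    return region


def _union_find_components(n: int, edges: np.ndarray) -> np.ndarray:
    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in edges:
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[ra] = rb
    return np.array([find(i) for i in range(n)])


def generate_road_network(region: Region, config: GeographyConfig) -> RoadNetwork:
    """Generate a connected, speed-classed road graph over the region.

    Nodes are sampled in cells with probability increasing in local density
    (plus a floor so the countryside keeps road coverage), positioned
    uniformly within their cell. The edge set is a k-nearest-neighbour
    scaffold, made connected by bridging components at their closest node
    pairs (a spanning tree over components), plus a configured fraction of
    long-range highway edges at the fastest speed class. Local-road speed is
    urban where either endpoint cell is dense, rural otherwise.
    """
    region.validate()
    config.validate()
    if config.n_road_nodes < 2:
        raise ConfigurationError("need at least 2 road nodes")
    rng = _rng(config.seed, 1)

    # --- node placement, density-responsive ---
    weights = (region.density + config.node_background_weight).ravel()
    probs = weights / weights.sum()
    cells = rng.choice(weights.size, size=config.n_road_nodes, replace=True, p=probs)
    ii, jj = np.unravel_index(cells, region.density.shape)
    x = (jj + rng.uniform(0, 1, size=cells.size)) * region.cell_km
    y = (ii + rng.uniform(0, 1, size=cells.size)) * region.cell_km
    x = np.minimum(x, region.width_km)
    y = np.minimum(y, region.height_km)
    node_xy = np.column_stack([x, y])

    # --- kNN scaffold ---
    tree = cKDTree(node_xy)
    kq = min(config.knn_neighbors + 1, config.n_road_nodes)
    _, nbrs = tree.query(node_xy, k=kq)
    nbrs = np.atleast_2d(nbrs)
    pairs = set()
    for i in range(config.n_road_nodes):
        for j in nbrs[i][1:]:
            j = int(j)
            if j != i:
                pairs.add((min(i, j), max(i, j)))
    edges = np.array(sorted(pairs), dtype=np.int64)

    # --- bridge components until connected ---
    comp = _union_find_components(config.n_road_nodes, edges)
    extra = []
    labels = np.unique(comp)
    while labels.size > 1:
        # attach every secondary component to the largest one at the closest pair
        main = labels[np.argmax([np.sum(comp == c) for c in labels])]
        main_idx = np.flatnonzero(comp == main)
        main_tree = cKDTree(node_xy[main_idx])
        for c in labels:
            if c == main:
                continue
            idx = np.flatnonzero(comp == c)
            d, m = main_tree.query(node_xy[idx])
            best = int(np.argmin(d))
            a, b = int(idx[best]), int(main_idx[m[best]])
            extra.append((min(a, b), max(a, b)))
        edges = np.vstack([edges, np.array(extra[-(labels.size - 1):], dtype=np.int64)])
        comp = _union_find_components(config.n_road_nodes, edges)
        labels = np.unique(comp)

    # --- highway shortcuts ---
    n_highway = int(round(config.highway_edge_fraction * edges.shape[0]))
    existing = {(int(a), int(b)) for a, b in edges}
    highway_set: set[tuple[int, int]] = set()
    attempts = 0
    while len(highway_set) < n_highway and attempts < 50 * max(n_highway, 1):
        a, b = rng.integers(0, config.n_road_nodes, size=2)
        attempts += 1
        if a == b:
            continue
        d = float(np.hypot(*(node_xy[a] - node_xy[b])))
        pair = (min(int(a), int(b)), max(int(a), int(b)))
        if d >= config.highway_min_length_km and pair not in existing:
            highway_set.add(pair)
    highway_pairs = sorted(highway_set)

    all_edges = np.vstack([edges, np.array(highway_pairs, dtype=np.int64).reshape(-1, 2)])
    is_highway = np.zeros(all_edges.shape[0], dtype=bool)
    is_highway[edges.shape[0]:] = True
    euclid = np.hypot(
        node_xy[all_edges[:, 0], 0] - node_xy[all_edges[:, 1], 0],
        node_xy[all_edges[:, 0], 1] - node_xy[all_edges[:, 1], 1],
    )
    keep = euclid > 0  # drop degenerate coincident-node edges
    all_edges, euclid, is_highway = all_edges[keep], euclid[keep], is_highway[keep]
    length = euclid * config.road_winding_factor

    urban_kmh, rural_kmh, highway_kmh = config.speed_classes_kmh
    node_i = np.minimum((node_xy[:, 1] / region.cell_km).astype(int), region.n_rows - 1)
    node_j = np.minimum((node_xy[:, 0] / region.cell_km).astype(int), region.n_cols - 1)
    node_density = region.density[node_i, node_j]
    urban = (
        np.maximum(node_density[all_edges[:, 0]], node_density[all_edges[:, 1]])
        >= config.urban_density_threshold
    )
    speed = np.where(is_highway, highway_kmh, np.where(urban, urban_kmh, rural_kmh))

    network = RoadNetwork(
        node_xy=node_xy, edges=all_edges, length_km=length, speed_kmh=speed
    )
    assert network.is_connected()
    return network


def _sample_cells(
    rng: np.random.Generator, probs: np.ndarray, n: int
) -> np.ndarray:
    """Draw n distinct flat cell indices with probability ~ probs."""
    support = int(np.count_nonzero(probs))
    if support < n:
        raise PlacementError(
            f"only {support} cells have positive weight; cannot place {n} stations"
        )
    return rng.choice(probs.size, size=n, replace=False, p=probs / probs.sum())


def _snap_unused(
    tree: cKDTree, xy: np.ndarray, used: set[int]
) -> tuple[int, float]:
    """Nearest network node not in ``used`` (expanding k-NN query)."""
    k = 1
    n = tree.n
    while k <= n:
        d, idx = tree.query(xy, k=min(k, n))
        d, idx = np.atleast_1d(d), np.atleast_1d(idx)
        for dist, node in zip(d, idx):
            if int(node) not in used:
                return int(node), float(dist)
        k *= 4
    raise PlacementError("no unused network node available for snapping")


def place_stations(
    region: Region, network: RoadNetwork, config: GeographyConfig
) -> StationSet:
    """Place EMS and fire stations and snap them to the network.

    EMS bases are drawn population-weighted without replacement over cells,
    emulating demand-driven ambulance planning. Fire stations mix
    population-weighted and uniform-over-settled-cells draws
    (``fire_population_blend``), emulating their municipal-level ubiquity.
    Each station occupies its nearest network node not already taken by a
    station of the same service.
    """
    config.validate()
    if config.n_ems + config.n_fire > network.n_nodes:
        raise PlacementError(
            f"{config.n_ems + config.n_fire} stations exceed "
            f"{network.n_nodes} network nodes"
        )
    rng = _rng(config.seed, 2)

    pop = region.cell_population.ravel()
    if pop.sum() <= 0:
        raise PlacementError("region has no population to weight placement by")
    w_pop = pop / pop.sum()
    settled = (region.density.ravel() >= config.settled_density_threshold).astype(float)
    w_uni = settled / settled.sum() if settled.sum() > 0 else w_pop
    w_fire = config.fire_population_blend * w_pop + (1 - config.fire_population_blend) * w_uni

    stations: list[Station] = []
    sid = 0
    for service, n, w in (
        (Service.EMS, config.n_ems, w_pop),
        (Service.FIRE, config.n_fire, w_fire),
    ):
        cells = _sample_cells(rng, w, n)
        ii, jj = np.unravel_index(cells, region.density.shape)
        x = (jj + rng.uniform(0, 1, size=n)) * region.cell_km
        y = (ii + rng.uniform(0, 1, size=n)) * region.cell_km
        used: set[int] = set()
        for xk, yk in zip(x, y):
            node, dist = _snap_unused(network.kdtree, np.array([xk, yk]), used)
            used.add(node)
            stations.append(
                Station(
                    id=sid,
                    service=service,
                    location=(float(xk), float(yk)),
                    node=node,
                    snap_distance_km=dist,
                )
            )
            sid += 1
    return StationSet(stations)


def generate_geography(
    config: GeographyConfig,
) -> tuple[Region, RoadNetwork, StationSet]:
    """Run all three generators with one config (one shared seed)."""
    region = generate_region(config)
    network = generate_road_network(region, config)
    stations = place_stations(region, network, config)
    return region, network, stations
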