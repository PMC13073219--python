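"""Synthetic-geography generator: rasters, road graphs, station placement."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import spearmanr

from dualdispatch import (
    GeographyConfig,
    Service,
    generate_geography,
    generate_region,
    generate_road_network,
    place_stations,
)
from dualdispatch.errors import ConfigurationError, PlacementError


class TestRegion:
    def test_zero_clusters_gives_uniform_raster(self, uniform_region):
        # renormalisation forces every cell to the background level exactly
        assert uniform_region.density.shape == (10, 10)
        np.testing.assert_allclose(uniform_region.density, 10.0)

    @pytest.mark.parametrize("seed", [0, 1, 42, 12345])
    def test_mass_conservation_at_study_scale(self, seed):
        cfg = GeographyConfig(seed=seed)
        region = generate_region(cfg)
        mass = region.density.sum() * region.cell_area_km2
        assert mass == pytest.approx(1.73e6, rel=1e-3)
        assert np.all(region.density >= 0)

    def test_default_raster_is_heterogeneous(self):
        region = generate_region(GeographyConfig(seed=42))
        assert region.density.max() / np.median(region.density) > 10

    def test_grid_dimensions_are_ceil_of_extent(self):
        cfg = GeographyConfig(width_km=101.0, height_km=55.0, cell_km=10.0)
        region = generate_region(cfg)
        assert region.density.shape == (6, 11)

    @pytest.mark.parametrize(
        "bad",
        [
            {"width_km": -1.0},
            {"cell_km": 0.0},
            {"total_population": 0.0},
            {"n_ems": 0},
            {"n_fire": 5, "n_ems": 10},
        ],
    )
    def test_invalid_configuration_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            generate_region(dataclasses.replace(GeographyConfig(), **bad))


class TestRoadNetwork:
    def test_square_edges_travel_ten_minutes(self, square_network):
        np.testing.assert_allclose(square_network.travel_time_min, 10.0)

    def test_generated_network_is_connected_with_positive_edges(self, small_instance):
        _, network, _ = small_instance
        assert network.is_connected()
        assert np.all(network.length_km > 0)
        assert np.all(network.travel_time_min > 0)

    def test_speeds_come_from_configured_classes(self, small_config, small_instance):
        _, network, _ = small_instance
        assert set(np.unique(network.speed_kmh)) <= set(small_config.speed_classes_kmh)

    def test_mean_degree_within_sanity_envelope(self):
        cfg = GeographyConfig(n_road_nodes=2000, seed=42)
        region = generate_region(cfg)
        network = generate_road_network(region, cfg)
        mean_degree = 2 * network.n_edges / network.n_nodes
        assert 2.5 <= mean_degree <= 6

    def test_node_density_tracks_population_density(self, small_instance, small_config):
        region, network, _ = small_instance
        counts = np.zeros_like(region.density)
        for x, y in network.node_xy:
            i, j = region.cell_of(x, y)
            counts[i, j] += 1
        rho, _ = spearmanr(region.density.ravel(), counts.ravel())
        assert rho > 0

    def test_too_few_nodes_rejected(self, uniform_region):
        cfg = dataclasses.replace(GeographyConfig(), n_road_nodes=1)
        with pytest.raises(ConfigurationError):
            generate_road_network(uniform_region, cfg)


class TestStations:
    def test_counts_match_configuration(self, small_config, small_instance):
        _, _, stations = small_instance
        assert len(stations.of_service(Service.EMS)) == small_config.n_ems
        assert len(stations.of_service(Service.FIRE)) == small_config.n_fire

    def test_study_scale_station_counts(self):
        # the full-scale defaults: 121 ambulance and 1590 fire stations
        cfg = GeographyConfig(seed=3)
        _, _, stations = generate_geography(cfg)
        assert len(stations.of_service(Service.EMS)) == 121
        assert len(stations.of_service(Service.FIRE)) == 1590

    def test_no_shared_node_within_a_service(self, small_instance):
        _, _, stations = small_instance
        for service in Service:
            nodes = [s.node for s in stations.of_service(service)]
            assert len(nodes) == len(set(nodes))

    def test_station_snaps_to_nearest_unused_node(self, small_instance):
        region, network, stations = small_instance
        for service in Service:
            used = set()
            for s in stations.of_service(service):
                d = np.hypot(
                    network.node_xy[:, 0] - s.location[0],
                    network.node_xy[:, 1] - s.location[1],
                )
                free = [i for i in np.argsort(d) if i not in used]
                assert s.node == free[0]
                assert s.snap_distance_km == pytest.approx(d[s.node])
                used.add(s.node)

    def test_degenerate_two_node_placement(self, uniform_region):
        cfg = dataclasses.replace(
            GeographyConfig(),
            width_km=100.0,
            height_km=100.0,
            cell_km=10.0,
            total_population=1e5,
            n_population_clusters=0,
            rural_background_density=10.0,
            n_ems=1,
            n_fire=1,
            n_road_nodes=2,
            seed=5,
        )
        network = generate_road_network(uniform_region, cfg)
        stations = place_stations(uniform_region, network, cfg)
        assert {s.node for s in stations} <= {0, 1}
        assert all(s.snap_distance_km >= 0 for s in stations)

    def test_more_stations_than_nodes_rejected(self, uniform_region):
        cfg = dataclasses.replace(
            GeographyConfig(), n_ems=5, n_fire=10, n_road_nodes=8
        )
        network = generate_road_network(uniform_region, cfg)
        with pytest.raises(PlacementError):
            place_stations(uniform_region, network, cfg)

    def test_fire_coverage_is_denser_than_ems(
        self, small_instance, small_events
    ):
        # 13:1-style count ratio makes the nearest fire base closer on average
        _, _, stations = small_instance
        ems_xy = stations.locations(Service.EMS)
        fire_xy = stations.locations(Service.FIRE)

        def mean_nearest(xy):
            return np.mean(
                [
                    np.hypot(xy[:, 0] - e.location[0], xy[:, 1] - e.location[1]).min()
                    for e in small_events
                ]
            )

        assert mean_nearest(fire_xy) < mean_nearest(ems_xy)


class TestDeterminism:
    def test_identical_seed_reproduces_everything(self, small_config):
        r1, n1, s1 = generate_geography(small_config)
        r2, n2, s2 = generate_geography(small_config)
        np.testing.assert_array_equal(r1.density, r2.density)
        np.testing.assert_array_equal(n1.node_xy, n2.node_xy)
        np.testing.assert_array_equal(n1.edges, n2.edges)
        np.testing.assert_array_equal(n1.speed_kmh, n2.speed_kmh)
        assert s1.stations == s2.stations

    def test_different_seed_changes_the_draw(self, small_config):
        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        r1, _, _ = generate_geography(small_config)
        r2, _, _ = generate_geography(other)
        assert not np.array_equal(r1.density, r2.density)
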