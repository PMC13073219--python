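import numpy as np
import pytest

from dualdispatch import (
    GeographyConfig,
    Region,
    RoadNetwork,
    TurnoutConfig,
    generate_geography,
    sample_events,
    simulate_responses,
)


@pytest.fixture(scope="session")
def small_config():
    """A fast, reduced-scale instance keeping the study's structure.

    Area, population and station counts are scaled down together so the
    fire:EMS ratio and density heterogeneity survive.
    """
    return GeographyConfig(
        width_km=60.0,
        height_km=50.0,
        cell_km=2.0,
        total_population=180_000.0,
        n_population_clusters=6,
        n_ems=12,
        n_fire=90,
        n_road_nodes=900,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_instance(small_config):
    return generate_geography(small_config)


@pytest.fixture(scope="session")
def small_events(small_instance):
    region, network, _ = small_instance
    return sample_events(region, network, 300, seed=11)


@pytest.fixture(scope="session")
def small_records(small_instance, small_events):
    _, network, stations = small_instance
    region, _, _ = small_instance
    return simulate_responses(
        small_events, stations, network, TurnoutConfig(2.0, 5.0), k=10
    )


@pytest.fixture()
def square_network():
    """4-node square, every edge 10 km at 60 km/h (i.e. 10 min)."""
    return RoadNetwork(
        node_xy=np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]]),
        edges=np.array([[0, 1], [1, 2], [2, 3], [3, 0]]),
        length_km=np.full(4, 10.0),
        speed_kmh=np.full(4, 60.0),
    )


@pytest.fixture()
def uniform_region():
    """100x100 km uniform raster, 10 inhabitants/km^2."""
    cfg = GeographyConfig(
        width_km=100.0,
        height_km=100.0,
        cell_km=10.0,
        total_population=100_000.0,
        n_population_clusters=0,
        rural_background_density=10.0,
        seed=1,
    )
    from dualdispatch import generate_region

    return generate_region(cfg)
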