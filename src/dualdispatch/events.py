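"""Population-weighted hypothetical cardiac-arrest locations.

Sampling is two-stage: a raster cell is drawn with probability proportional
to its population (density x cell area), then the event position is uniform
within that cell. Events are snapped to the nearest road node; response
clocks end at curbside arrival, so no off-road time is added. The cell's
density is carried along as the covariate for the density x strategy model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SamplingError
from .geography import Region, RoadNetwork

__all__ = ["Event", "sample_events"]


@dataclass(frozen=True)
class Event:
    id: int
    location: tuple[float, float]  # (x_km, y_km)
    cell: tuple[int, int]  # raster index (i, j)
    node: int  # nearest network node
    local_density: float  # inhabitants / km^2 of the event's cell


def sample_events(
    region: Region, network: RoadNetwork, n: int, seed: int
) -> list[Event]:
    """Draw ``n`` population-weighted event locations; deterministic per seed.

    Cells with zero population receive zero events exactly (their sampling
    weight is zero, not merely small).
    """
    if n < 1:
        raise SamplingError("need at least one event")
    pop = region.cell_population.ravel()
    total = pop.sum()
    if total <= 0:
        raise SamplingError("cannot sample events from an all-zero raster")

    rng = np.random.default_rng(seed)
    cells = rng.choice(pop.size, size=n, replace=True, p=pop / total)
    ii, jj = np.unravel_index(cells, region.density.shape)
    x = (jj + rng.uniform(0, 1, size=n)) * region.cell_km
    y = (ii + rng.uniform(0, 1, size=n)) * region.cell_km
    nodes, _ = network.snap(np.column_stack([x, y]))

    return [
        Event(
            id=k,
            location=(float(x[k]), float(y[k])),
            cell=(int(ii[k]), int(jj[k])),
            node=int(nodes[k]),
            local_density=float(region.density[ii[k], jj[k]]),
        )
        for k in range(n)
    ]
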