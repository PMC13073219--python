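"""Response-time construction for the two dispatch strategies.

Response time = turnout time + travel time, ending at curbside arrival.
Under EMS-only dispatch the response is the ambulance response; under dual
dispatch both services are alerted simultaneously and the effective
response is the earlier arrival. Defaults follow the daytime mandates of
the modelled system: 2 min EMS turnout, 5 min volunteer-fire turnout, with
8 min as the standard sensitivity value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, PipelineError
from .events import Event
from .geography import RoadNetwork, Service, StationSet
from .routing import best_travel_times

__all__ = [
    "TurnoutConfig",
    "ResponseRecord",
    "build_records",
    "simulate_responses",
    "records_to_frame",
    "frame_to_records",
]


@dataclass(frozen=True)
class TurnoutConfig:
    """Alarm-to-departure intervals per service, in minutes."""

    ems_turnout_min: float = 2.0
    fire_turnout_min: float = 5.0

    def validate(self) -> None:
        for v in (self.ems_turnout_min, self.fire_turnout_min):
            if not math.isfinite(v) or v < 0:
                raise ConfigurationError("turnout times must be finite and >= 0")


@dataclass(frozen=True)
class ResponseRecord:
    """Per-event response times under both strategies.

    ``first_arriver`` is FIRE only when the fire response is strictly
    faster; ties count as EMS-first, which makes the reported fire-first
    fraction conservative.
    """

    event_id: int
    location: tuple[float, float]
    local_density: float
    ems_travel_min: float
    fire_travel_min: float
    ems_response_min: float
    fire_response_min: float
    dual_response_min: float
    first_arriver: Service


def build_records(
    events: Sequence[Event],
    ems_travel: Sequence[float],
    fire_travel: Sequence[float],
    turnout: TurnoutConfig,
) -> list[ResponseRecord]:
    """Assemble records from pre-computed per-event best travel times."""
    turnout.validate()
    if len(ems_travel) != len(events) or len(fire_travel) != len(events):
        raise PipelineError("one travel time per event and service is required")
    records = []
    for event, et, ft in zip(events, ems_travel, fire_travel):
        ems_resp = turnout.ems_turnout_min + float(et)
        fire_resp = turnout.fire_turnout_min + float(ft)
        records.append(
            ResponseRecord(
                event_id=event.id,
                location=event.location,
                local_density=event.local_density,
                ems_travel_min=float(et),
                fire_travel_min=float(ft),
                ems_response_min=ems_resp,
                fire_response_min=fire_resp,
                dual_response_min=min(ems_resp, fire_resp),
                first_arriver=Service.FIRE if fire_resp < ems_resp else Service.EMS,
            )
        )
    return records


def simulate_responses(
    events: Sequence[Event],
    stations: StationSet,
    network: RoadNetwork,
    turnout: TurnoutConfig = TurnoutConfig(),
    k: int | str = 10,
) -> list[ResponseRecord]:
    """One response record per event under both strategies.

    Travel times use the k-nearest-candidate fastest-route search per
    service; ``k='all'`` is exact.
    """
    turnout.validate()
    ems = best_travel_times(events, stations, network, Service.EMS, k)
    fire = best_travel_times(events, stations, network, Service.FIRE, k)
    return build_records(
        events,
        [r.best_travel_min for r in ems],
        [r.best_travel_min for r in fire],
        turnout,
    )


def records_to_frame(records: Sequence[ResponseRecord]) -> pd.DataFrame:
    """Tabular view of records (one row per event)."""
    return pd.DataFrame(
        {
            "event_id": [r.event_id for r in records],
            "x_km": [r.location[0] for r in records],
            "y_km": [r.location[1] for r in records],
            "local_density": [r.local_density for r in records],
            "ems_travel_min": [r.ems_travel_min for r in records],
            "fire_travel_min": [r.fire_travel_min for r in records],
            "ems_response_min": [r.ems_response_min for r in records],
            "fire_response_min": [r.fire_response_min for r in records],
            "dual_response_min": [r.dual_response_min for r in records],
            "first_arriver": [r.first_arriver.value for r in records],
        }
    )


def frame_to_records(frame: pd.DataFrame) -> list[ResponseRecord]:
    """Inverse of :func:`records_to_frame`."""
    return [
        ResponseRecord(
            event_id=int(row.event_id),
            location=(float(row.x_km), float(row.y_km)),
            local_density=float(row.local_density),
            ems_travel_min=float(row.ems_travel_min),
            fire_travel_min=float(row.fire_travel_min),
            ems_response_min=float(row.ems_response_min),
            fire_response_min=float(row.fire_response_min),
            dual_response_min=float(row.dual_response_min),
            first_arriver=Service(row.first_arriver),
        )
        for row in frame.itertuples()
    ]
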