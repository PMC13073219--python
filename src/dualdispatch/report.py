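"""Run orchestration and reporting.

``run_pipeline`` executes the whole simulation (geography -> events ->
routing -> dispatch) and persists every intermediate as plain text so that
``build_report`` can reassemble all summary numbers from the files alone:
the report carries no state that is not recomputable from the persisted
CSVs. Figures mirror the study's presentation: boxplots of the arrival-time
distributions per strategy and a map of events coloured by first arriver
(EMS-first red, dual-faster green) over log-scaled density shading.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from types import SimpleNamespace
from typing import Sequence

import numpy as np

from . import io as ddio
from .dispatch import TurnoutConfig, build_records, frame_to_records
from .errors import ReportError
from .events import sample_events
from .geography import GeographyConfig, Service, generate_geography
from .routing import best_travel_times
from .stats import (
    ComparisonResult,
    Strategy,
    StrategySummary,
    SweepResult,
    compare_strategies,
    fit_density_glm,
    summarize,
    sweep_from_travel,
)

__all__ = ["RunReport", "run_pipeline", "build_report", "render_figures"]

SCHEMA_VERSION = 1

RUN_FILES = {
    "config": "config.json",
    "density": "density.csv",
    "density_asc": "density.asc",
    "network": "network.geojson",
    "stations": "stations.geojson",
    "events": "events.csv",
    "events_geojson": "events.geojson",
    "records_base": "records_base.csv",
    "records_base_geojson": "records_base.geojson",
    "records_sensitivity": "records_sensitivity.csv",
}


def _summary_dict(s: StrategySummary) -> dict:
    return {
        "strategy": s.strategy.value,
        "n": s.n,
        "mean_min": s.mean_min,
        "sd_min": s.sd_min,
        "percentiles": {str(k): v for k, v in s.percentiles.items()},
        "frac_within": {str(k): v for k, v in s.frac_within.items()},
        "frac_fire_first": s.frac_fire_first,
    }


def _comparison_dict(c: ComparisonResult) -> dict:
    return {
        "mean_difference_min": c.mean_difference_min,
        "t_statistic": c.t_statistic,
        "p_value": c.p_value,
        "test_kind": c.test_kind,
    }


def _sweep_dict(sw: SweepResult) -> dict:
    return {
        "turnout_grid": list(sw.turnout_grid),
        "alpha": sw.alpha,
        "threshold_turnout": sw.threshold_turnout,
        "points": [
            {
                "fire_turnout_min": p.fire_turnout_min,
                "mean_ems_min": p.summary_ems.mean_min,
                "mean_dual_min": p.summary_dual.mean_min,
                "frac_fire_first": p.summary_dual.frac_fire_first,
                "p_value": p.comparison.p_value,
            }
            for p in sw.points
        ],
    }


@dataclasses.dataclass(frozen=True)
class RunReport:
    """All summary numbers of one simulation run, JSON-serialisable.

    ``scenarios`` maps scenario name (``base``, ``sensitivity``) to the
    per-strategy summaries and the paired-test result at that scenario's
    fire turnout.
    """

    schema_version: int
    config: dict
    scenarios: dict
    sweep: dict
    glm: dict
    manifest: list

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunReport":
        return cls(**doc)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunReport":
        return cls.from_dict(json.loads(Path(path).read_text()))


def run_pipeline(
    config: GeographyConfig,
    out_dir: str | Path,
    n_events: int = 1000,
    events_seed: int | None = None,
    base_turnout: TurnoutConfig = TurnoutConfig(2.0, 5.0),
    sensitivity_fire_turnout_min: float = 8.0,
    k: int | str = 10,
) -> dict[str, Path]:
    """Generate geography, simulate responses, persist all artefacts.

    Returns the file manifest. The base scenario uses the daytime turnout
    pair (2 min EMS / 5 min fire); the sensitivity scenario replaces the
    fire turnout (default 8 min) while keeping travel times fixed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    region, network, stations = generate_geography(config)
    seed = config.seed if events_seed is None else events_seed
    events = sample_events(region, network, n_events, seed=seed)

    ems = best_travel_times(events, stations, network, Service.EMS, k)
    fire = best_travel_times(events, stations, network, Service.FIRE, k)
    ems_t = [r.best_travel_min for r in ems]
    fire_t = [r.best_travel_min for r in fire]

    records_base = build_records(events, ems_t, fire_t, base_turnout)
    records_sens = build_records(
        events,
        ems_t,
        fire_t,
        TurnoutConfig(base_turnout.ems_turnout_min, sensitivity_fire_turnout_min),
    )

    paths = {key: out / name for key, name in RUN_FILES.items()}
    run_config = {
        "geography": dataclasses.asdict(config),
        "n_events": n_events,
        "events_seed": seed,
        "k": k,
        "base_turnout": dataclasses.asdict(base_turnout),
        "sensitivity_fire_turnout_min": sensitivity_fire_turnout_min,
    }
    paths["config"].write_text(json.dumps(run_config, indent=2, sort_keys=True))
    ddio.write_density_csv(region, paths["density"])
    ddio.write_ascii_grid(region, paths["density_asc"])
    ddio.write_network_geojson(network, paths["network"])
    ddio.write_stations_geojson(stations, paths["stations"])
    ddio.write_events_csv(events, paths["events"])
    ddio.write_events_geojson(events, paths["events_geojson"])
    ddio.write_records_csv(records_base, paths["records_base"])
    ddio.write_records_geojson(records_base, paths["records_base_geojson"])
    ddio.write_records_csv(records_sens, paths["records_sensitivity"])
    return paths


def _pseudo_events(frame) -> list:
    """Event stand-ins carrying id/location/density, for turnout re-runs."""
    return [
        SimpleNamespace(
            id=int(r.event_id),
            location=(float(r.x_km), float(r.y_km)),
            local_density=float(r.local_density),
        )
        for r in frame.itertuples()
    ]


def build_report(
    run_dir: str | Path,
    sweep_grid: Sequence[float] = tuple(range(2, 26)),
    alpha: float = 0.05,
    thresholds: Sequence[float] = (10.0,),
    render: bool = True,
) -> RunReport:
    """Recompute every reported number from the persisted run files.

    Raises :class:`ReportError` naming all missing inputs. The sweep reuses
    the travel-time columns of the base records (routing is independent of
    turnout), so regenerating the report from the same files is idempotent.
    """
    run_dir = Path(run_dir)
    required = ["config", "events", "records_base", "records_sensitivity"]
    missing = [RUN_FILES[key] for key in required if not (run_dir / RUN_FILES[key]).exists()]
    if missing:
        raise ReportError(f"missing run files in {run_dir}: {', '.join(sorted(missing))}")

    run_config = json.loads((run_dir / RUN_FILES["config"]).read_text())
    base_frame = ddio.read_records_csv(run_dir / RUN_FILES["records_base"])
    sens_frame = ddio.read_records_csv(run_dir / RUN_FILES["records_sensitivity"])

    scenarios = {}
    for name, frame, fire_turnout in (
        ("base", base_frame, run_config["base_turnout"]["fire_turnout_min"]),
        ("sensitivity", sens_frame, run_config["sensitivity_fire_turnout_min"]),
    ):
        records = frame_to_records(frame)
        scenarios[name] = {
            "fire_turnout_min": float(fire_turnout),
            "ems_only": _summary_dict(summarize(records, Strategy.EMS_ONLY, thresholds)),
            "dual": _summary_dict(summarize(records, Strategy.DUAL, thresholds)),
            "comparison": _comparison_dict(compare_strategies(records)),
        }

    pseudo = _pseudo_events(base_frame)
    sweep = sweep_from_travel(
        pseudo,
        base_frame["ems_travel_min"].to_numpy(),
        base_frame["fire_travel_min"].to_numpy(),
        sweep_grid,
        alpha=alpha,
        ems_turnout_min=run_config["base_turnout"]["ems_turnout_min"],
        thresholds=thresholds,
    )

    glm = fit_density_glm(frame_to_records(base_frame))
    report = RunReport(
        schema_version=SCHEMA_VERSION,
        config=run_config,
        scenarios=scenarios,
        sweep=_sweep_dict(sweep),
        glm={
            "coefficients": glm.coefficients,
            "standard_errors": glm.standard_errors,
            "p_values": glm.p_values,
            "r_squared": glm.r_squared,
            "n_obs": glm.n_obs,
        },
        manifest=sorted(p.name for p in run_dir.iterdir() if p.is_file()),
    )
    report.save(run_dir / "report.json")
    if render:
        render_figures(run_dir)
    return report


def render_figures(run_dir: str | Path) -> dict[str, Path]:
    """Boxplot and first-arriver map as PNG side outputs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    base = ddio.read_records_csv(run_dir / RUN_FILES["records_base"])
    out = {}

    fig, ax = plt.subplots(figsize=(5, 4))
    data = [base["ems_response_min"], base["dual_response_min"]]
    if (run_dir / RUN_FILES["records_sensitivity"]).exists():
        sens = ddio.read_records_csv(run_dir / RUN_FILES["records_sensitivity"])
        data.append(sens["dual_response_min"])
        labels = ["EMS only", "Dual dispatch", "Dual (sens. turnout)"]
    else:
        labels = ["EMS only", "Dual dispatch"]
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("response time at curb (min)")
    fig.tight_layout()
    out["boxplot"] = run_dir / "fig_boxplot.png"
    fig.savefig(out["boxplot"], dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 5))
    density_path = run_dir / RUN_FILES["density"]
    if density_path.exists():
        region = ddio.read_density_csv(density_path)
        ax.imshow(
            np.log10(1.0 + region.density),
            origin="lower",
            extent=(0, region.width_km, 0, region.height_km),
            cmap="Blues",
            alpha=0.8,
        )
    fire_first = base["first_arriver"] == Service.FIRE.value
    ax.scatter(
        base.loc[~fire_first, "x_km"], base.loc[~fire_first, "y_km"],
        s=8, c="red", label="EMS arrived first",
    )
    ax.scatter(
        base.loc[fire_first, "x_km"], base.loc[fire_first, "y_km"],
        s=8, c="green", label="dual dispatch faster",
    )
    ax.set_xlabel("x (km)")
    ax.set_ylabel("y (km)")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    out["map"] = run_dir / "fig_map.png"
    fig.savefig(out["map"], dpi=120)
    plt.close(fig)
    return out
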