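"""End-to-end driver: flood preprocessing, both accessibility engines under
normal and flooded conditions, impact tables, road criticality, comparison.

Given one scenario (synthetic or loaded from files) and one pipeline
configuration, the driver runs the six stages in a fixed order and writes
every product plus a manifest (config hash, stage list, per-file SHA-256)
so identical configurations yield byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as fio
from .floodmask import FloodMask, simplify_mask
from .grids import TimeGrid
from .impact import (
    ComparisonReport,
    access_loss,
    area_within_threshold,
    compare_methods,
    loss_table,
    network_access_grid,
    population_by_bin,
)
from .network import (
    FacilitySet,
    SpeedProfile,
    TravelGraph,
    apply_flood_to_graph,
    build_graph,
    nearest_facility_times,
)
from .raster import apply_flood_to_friction, bin_times, least_cost_time
from .synthetic import Scenario
from .tebc import population_nuclei, tebc_delta, tebc_dispersion, tebc_scores

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    profile: str = "walking"  # walking | driving
    interval_min: float = 10.0
    cap_min: float | None = None  # default: 360 walking, 60 driving
    range_m: float = 20_000.0
    reach_radius_m: float = 500.0
    max_snap_m: float = 2000.0
    connectivity: int = 8
    strict_edge_flooding: bool = False
    simplify_retain: float | None = None  # e.g. 0.01; None = no simplification
    seed: int = 0

    def resolved_cap(self) -> float:
        if self.cap_min is not None:
            return self.cap_min
        return 360.0 if self.profile == "walking" else 60.0

    def __post_init__(self) -> None:
        cap = self.resolved_cap()
        if abs(cap / self.interval_min - round(cap / self.interval_min)) > 1e-9:
            raise ValueError("cap_min must be divisible by interval_min")
        if self.connectivity not in (8, 16):
            raise ValueError("connectivity must be 8 or 16")


@dataclass
class PipelineResult:
    config: PipelineConfig
    flood: FloodMask
    graph_normal: TravelGraph
    graph_flooded: TravelGraph
    node_times_normal: dict[int, float]
    node_times_flooded: dict[int, float]
    net_time_normal: TimeGrid
    net_time_flooded: TimeGrid
    raster_time_normal: TimeGrid
    raster_time_flooded: TimeGrid
    tables: dict
    comparison: ComparisonReport
    tebc_normal: object
    tebc_flooded: object
    tebc_deltas: object
    diagnostics: dict
    stages: list[str] = field(default_factory=list)


def run_pipeline(scenario: Scenario, config: PipelineConfig) -> PipelineResult:
    profile = SpeedProfile.named(config.profile)
    cap = config.resolved_cap()
    stages: list[str] = []
    diagnostics: dict = {}

    # 1. flood preprocessing
    flood = scenario.flood
    if config.simplify_retain is not None and not flood.is_empty:
        flood = simplify_mask(flood, config.simplify_retain)
    stages.append("flood_preprocessing")

    # 2. network engine, normal + flooded
    graph = build_graph(scenario.road_network, profile)
    graph_f = apply_flood_to_graph(
        graph, flood, scenario.road_network, strict=config.strict_edge_flooding
    )
    diagnostics["nodes_removed_by_flood"] = (
        graph.g.number_of_nodes() - graph_f.g.number_of_nodes()
    )
    nt_normal = nearest_facility_times(
        graph, scenario.facilities, scenario.road_network, config.max_snap_m
    )
    nt_flooded = nearest_facility_times(
        graph_f, scenario.facilities, scenario.road_network, config.max_snap_m
    )
    net_grid_normal = network_access_grid(
        nt_normal, scenario.road_network, scenario.population, config.reach_radius_m
    )
    net_grid_flooded = network_access_grid(
        nt_flooded, scenario.road_network, scenario.population, config.reach_radius_m
    )
    stages.append("network_accessibility")

    # 3. raster engine, normal + flooded
    friction_f = apply_flood_to_friction(scenario.friction, flood)
    rast_normal = least_cost_time(
        scenario.friction, scenario.facilities, config.connectivity
    )
    rast_flooded = least_cost_time(friction_f, scenario.facilities, config.connectivity)
    stages.append("raster_accessibility")

    # 4. impact tables
    pop = scenario.population
    bins = {
        "network_normal": bin_times(net_grid_normal, config.interval_min, cap),
        "network_flooded": bin_times(net_grid_flooded, config.interval_min, cap),
        "raster_normal": bin_times(rast_normal, config.interval_min, cap),
        "raster_flooded": bin_times(rast_flooded, config.interval_min, cap),
    }
    tables = {k: population_by_bin(v, pop) for k, v in bins.items()}
    loss_net = access_loss(net_grid_normal, net_grid_flooded, cap)
    loss_rast = access_loss(rast_normal, rast_flooded, cap)
    tables["loss_network"] = loss_table(loss_net, pop, config.interval_min)
    tables["loss_raster"] = loss_table(loss_rast, pop, config.interval_min)
    diagnostics["clamped_cells_network"] = loss_net.clamped_cells
    diagnostics["clamped_cells_raster"] = loss_rast.clamped_cells
    stages.append("impact_tables")

    # 5. TEBC, normal + flooded
    origins = population_nuclei(pop)
    tf_normal = tebc_scores(
        graph, origins, scenario.facilities, config.range_m,
        network=scenario.road_network, max_snap_m=config.max_snap_m,
    )
    tf_flooded = tebc_scores(
        graph_f, origins, scenario.facilities, config.range_m,
        network=scenario.road_network, max_snap_m=config.max_snap_m,
    )
    deltas = tebc_delta(tf_normal, tf_flooded, graph.edge_ids(), graph_f.edge_ids())
    diagnostics["tebc_dispersion_normal"] = tebc_dispersion(tf_normal)
    diagnostics["tebc_dispersion_flooded"] = tebc_dispersion(tf_flooded)
    stages.append("road_criticality")

    # 6. comparison report
    comparison = compare_methods(
        tables["raster_normal"],
        tables["network_normal"],
        raster_area_km2=area_within_threshold(bins["raster_normal"], cap),
        network_area_km2=area_within_threshold(bins["network_normal"], cap),
    )
    stages.append("comparison_report")

    return PipelineResult(
        config,
        flood,
        graph,
        graph_f,
        nt_normal,
        nt_flooded,
        net_grid_normal,
        net_grid_flooded,
        rast_normal,
        rast_flooded,
        tables,
        comparison,
        tf_normal,
        tf_flooded,
        deltas,
        diagnostics,
        stages,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_outputs(result: PipelineResult, scenario: Scenario, out_dir: str | Path) -> Path:
    """Write CSV tables, rasters, GeoJSON layers and the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in result.tables.items():
        table.to_frame().to_csv(out / f"{name}.csv", index=False, float_format="%.6f")
    result.comparison.table.to_csv(
        out / "comparison.csv", index=False, float_format="%.6f"
    )
    fio.write_ascii_grid(result.net_time_normal, out / "network_time_normal.asc")
    fio.write_ascii_grid(result.net_time_flooded, out / "network_time_flooded.asc")
    fio.write_ascii_grid(result.raster_time_normal, out / "raster_time_normal.asc")
    fio.write_ascii_grid(result.raster_time_flooded, out / "raster_time_flooded.asc")
    fio.write_flood_geojson(result.flood, out / "flood_mask.geojson")

    # per-edge criticality table
    import pandas as pd

    rows = [
        {"edge_id": eid, **vals} for eid, vals in sorted(result.tebc_deltas.rows.items())
    ]
    pd.DataFrame(rows).to_csv(out / "tebc.csv", index=False, float_format="%.9f")

    config_json = json.dumps(dataclasses.asdict(result.config), sort_keys=True)
    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": scenario.seed,
        "stages": result.stages,
        "diagnostics": result.diagnostics,
        "outputs": {name: _sha256(out / name) for name in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return out
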