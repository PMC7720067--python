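"""End-to-end microplanning pipeline: village -> (clusters) -> routes ->
campaign scenarios -> Table-style reports.

The pipeline compares door-to-door deployment scenarios on one village:

``current``
    un-optimised delivery — the itinerary is a GPS-tracked visit order if
    one is supplied, otherwise a seeded random order emulating un-mapped
    CHW walking — with the 12.5 min/child treatment time;
``microplan_a``
    optimised itinerary and optimised treatment time (8.5 min/child), with
    the baseline single CHW pair;
``microplan_b``
    as A, but the number of CHW pairs is raised to the unmet-needs
    estimate so the whole village is covered within the campaign window.

All randomness flows from a single top-level seed. Reports are plain CSV /
JSON / GeoJSON and are byte-identical across reruns with the same config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .campaign import (
    CampaignConfig,
    CampaignResult,
    compare_scenarios,
    simulate_campaign,
    time_ledger,
    unmet_needs,
)
from .clustering import constrained_kmeans
from .io import itinerary_to_geojson, write_households, write_itinerary_csv
from .raster import extract_households, read_raster
from .routing import (
    DEFAULT_EXACT_LIMIT,
    Itinerary,
    build_distance_matrix,
    held_karp_path,
    heuristic_path,
    route_distance,
)
from .village import Village, VillageSpec, generate_village
from .io import read_households

logger = logging.getLogger("smcplan")

SCENARIO_MODES = ("current", "microplan_a", "microplan_b")


class ConfigError(ValueError):
    """The pipeline configuration is invalid; the message names the field."""


@dataclasses.dataclass(frozen=True)
class ScenarioSpec:
    """One deployment scenario to simulate."""

    name: str
    mode: str  # current | microplan_a | microplan_b
    treatment_model: str | None = None  # default chosen from mode
    chw_pairs: float | None = None  # default: 1 (current/A) or unmet/2 (B)
    gps_track: str | None = None  # visit-order CSV for `current`
    ceil_pairs: bool = False  # round microplan-B pairs up to an integer

    def __post_init__(self) -> None:
        if self.mode not in SCENARIO_MODES:
            raise ConfigError(
                f"scenario {self.name!r}: mode must be one of {SCENARIO_MODES}"
            )

    def resolved_treatment_model(self) -> str:
        if self.treatment_model is not None:
            return self.treatment_model
        return "current_fixed" if self.mode == "current" else "optimal_fixed"


def load_village(village_cfg: dict, seed: int) -> Village:
    """Build the study village from a config mapping.

    Exactly one of ``synthetic`` (a VillageSpec mapping), ``points`` (a
    CSV/GeoJSON path) or ``raster`` (a GeoTIFF/.asc path) must be given.
    """
    keys = [k for k in ("synthetic", "points", "raster") if k in village_cfg]
    if len(keys) != 1:
        raise ConfigError(
            "village: exactly one of synthetic/points/raster is required, "
            f"got {keys or 'none'}"
        )
    src = keys[0]
    if src == "synthetic":
        params = dict(village_cfg["synthetic"])
        params.setdefault("seed", seed)
        if "origin" in params:
            params["origin"] = tuple(params["origin"])
        try:
            spec = VillageSpec(**params)
        except TypeError as exc:
            raise ConfigError(f"village.synthetic: {exc}") from exc
        return generate_village(spec)
    if src == "points":
        return read_households(village_cfg["points"])
    grid = read_raster(village_cfg["raster"])
    return extract_households(
        grid,
        min_persons=float(village_cfg.get("min_persons", 1.0)),
        under5_fraction=float(village_cfg.get("under5_fraction", 0.18)),
        name=village_cfg.get("name", Path(village_cfg["raster"]).stem),
    )


def optimized_itinerary(
    village: Village, seed: int, exact_limit: int = DEFAULT_EXACT_LIMIT
) -> Itinerary:
    """Shortest-path itinerary: exact when small enough, 2-opt otherwise."""
    dm = build_distance_matrix(village)
    if dm.n <= exact_limit:
        return held_karp_path(dm, exact_limit=exact_limit)
    return heuristic_path(dm, seed=seed)


def tracked_itinerary(
    village: Village, seed: int, gps_track: str | None = None
) -> Itinerary:
    """Itinerary for the `current` scenario.

    A supplied GPS track (CSV with a ``household_id`` column, in visit
    order) is replayed verbatim; otherwise a seeded random visit order
    stands in for un-mapped CHW walking.
    """
    dm = build_distance_matrix(village)
    if gps_track is not None:
        order = tuple(pd.read_csv(gps_track)["household_id"].astype(str))
        if sorted(order) != sorted(village.ids):
            raise ConfigError("gps_track does not cover the village exactly")
    else:
        rng = np.random.default_rng(seed)
        order = tuple(np.array(village.ids)[rng.permutation(dm.n)])
    return Itinerary(order=order, total_km=route_distance(order, dm), exact=False)


def run_scenario(
    village: Village,
    scenario: ScenarioSpec,
    campaign_cfg: dict,
    seed: int,
    exact_limit: int = DEFAULT_EXACT_LIMIT,
) -> tuple[CampaignResult, Itinerary, CampaignConfig]:
    """Simulate one scenario on one village (or cluster)."""
    if scenario.mode == "current":
        itinerary = tracked_itinerary(village, seed, scenario.gps_track)
    else:
        itinerary = optimized_itinerary(village, seed, exact_limit)
    base = dict(campaign_cfg)
    base["treatment_model"] = scenario.resolved_treatment_model()
    base.setdefault("seed", seed)
    pairs = scenario.chw_pairs
    if pairs is None:
        if scenario.mode == "microplan_b":
            probe = CampaignConfig(chw_pairs=1.0, **base)
            needed = unmet_needs(*time_ledger(village, itinerary, probe), probe)
            pairs = needed / 2.0
            if scenario.ceil_pairs:
                pairs = float(np.ceil(pairs))
            pairs = max(pairs, 1e-9)
        else:
            pairs = 1.0
    config = CampaignConfig(chw_pairs=pairs, **base)
    result = simulate_campaign(village, itinerary, config)
    return result, itinerary, config


def result_row(unit: str, scenario: ScenarioSpec, result, config) -> dict:
    """One Table-style report row (times to 2 d.p., coverage to 1 d.p.)."""
    return {
        "village": unit,
        "scenario": scenario.name,
        "mode": scenario.mode,
        "chw_pairs": round(config.chw_pairs, 2),
        "chws_needed": round(result.unmet_chws, 2),
        "visited_households": result.visited_households,
        "treated_children": result.treated_children,
        "total_children": result.total_children,
        "treatment_days": round(result.treatment_days, 2),
        "walking_km": round(result.walking_km, 2),
        "travel_days": round(result.travel_days, 2),
        "coverage_pct": round(result.coverage_pct, 1),
    }


def scenario_compare_report(
    results: dict[str, tuple[CampaignResult, Village]]
) -> pd.DataFrame:
    """Pairwise contrasts between scenarios sharing a village.

    For each ordered pair: chi-square on visited households and on treated
    children (Yates-corrected), the walking-distance change and the
    coverage change in percentage points (with the relative change too).
    """
    names = list(results)
    if len(names) < 2:
        raise ConfigError("need at least 2 scenarios to compare")
    villages = {name: v for name, (_, v) in results.items()}
    first = villages[names[0]]
    for name, v in villages.items():
        if v.n_households != first.n_households or v.total_children != first.total_children:
            raise ConfigError(
                f"scenario {name!r} was run on a different village"
            )
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ra, va = results[a]
            rb, _ = results[b]
            hh = compare_scenarios(
                ra.visited_households,
                va.n_households,
                rb.visited_households,
                va.n_households,
                a,
                b,
            )
            ch = compare_scenarios(
                ra.treated_children,
                va.total_children,
                rb.treated_children,
                va.total_children,
                a,
                b,
            )
            walk_change = (
                100.0 * (rb.walking_km - ra.walking_km) / ra.walking_km
                if ra.walking_km > 0
                else float("nan")
            )
            rows.append(
                {
                    "scenario_a": a,
                    "scenario_b": b,
                    "chi2_households": round(hh.chi2, 2),
                    "p_households": hh.p_value,
                    "chi2_children": round(ch.chi2, 2),
                    "p_children": ch.p_value,
                    "walking_change_pct": round(walk_change, 1),
                    "coverage_change_points": round(
                        rb.coverage_pct - ra.coverage_pct, 1
                    ),
                    "coverage_change_rel_pct": round(
                        100.0 * (rb.coverage_pct - ra.coverage_pct) / ra.coverage_pct, 1
                    )
                    if ra.coverage_pct > 0
                    else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def _load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    return config


def run_pipeline(
    config: dict | str | Path,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict:
    """Run the full pipeline described by a config mapping or YAML path.

    Writes ``report.csv``, ``report.json``, ``comparisons.csv`` (when >= 2
    scenarios), per-scenario itinerary GeoJSON/CSV and, when clustering is
    enabled, a cluster GeoJSON. Returns the JSON report as a dict.
    """
    cfg = _load_config(config)
    if "village" not in cfg:
        raise ConfigError("config.village is required")
    if not cfg.get("scenarios"):
        raise ConfigError("config.scenarios must list at least one scenario")
    seed = int(seed if seed is not None else cfg.get("seed", 0))
    out = Path(out_dir if out_dir is not None else cfg.get("out_dir", "smcplan_out"))
    out.mkdir(parents=True, exist_ok=True)
    campaign_cfg = dict(cfg.get("campaign", {}))
    exact_limit = int(cfg.get("exact_limit", DEFAULT_EXACT_LIMIT))
    logger.info(
        "smcplan %s | seed=%d | campaign=%s", __version__, seed, campaign_cfg
    )

    village = load_village(cfg["village"], seed)
    if village.n_households == 0:
        raise ConfigError("village: no households to plan for")
    write_households(village, out / "households.geojson")

    scenarios = []
    for s in cfg["scenarios"]:
        try:
            scenarios.append(ScenarioSpec(**s))
        except TypeError as exc:
            raise ConfigError(f"scenarios: {exc}") from exc

    units: list[tuple[str, Village]] = []
    cluster_cfg = cfg.get("clustering")
    if cluster_cfg and cluster_cfg.get("enabled", True):
        k = int(cluster_cfg["k"])
        plan = constrained_kmeans(
            village,
            k=k,
            tau=cluster_cfg.get("tau"),
            seed=seed,
        )
        frame = pd.DataFrame(
            {"household_id": village.ids, "cluster": plan.assignment}
        )
        frame.to_csv(out / "clusters.csv", index=False)
        for h in range(k):
            label = chr(ord("A") + h)
            units.append(
                (f"{village.name} {label}", village.subset(plan.indices(h)))
            )
    else:
        units.append((village.name, village))

    rows, comparisons = [], []
    for unit_name, unit_village in units:
        per_scenario: dict[str, tuple[CampaignResult, Village]] = {}
        for scenario in scenarios:
            result, itinerary, conf = run_scenario(
                unit_village, scenario, campaign_cfg, seed, exact_limit
            )
            rows.append(result_row(unit_name, scenario, result, conf))
            stem = f"{unit_name}_{scenario.name}".replace(" ", "_")
            with open(out / f"itinerary_{stem}.geojson", "w") as fh:
                json.dump(itinerary_to_geojson(itinerary, unit_village), fh, indent=1)
            write_itinerary_csv(
                itinerary,
                build_distance_matrix(unit_village),
                out / f"itinerary_{stem}.csv",
            )
            per_scenario[scenario.name] = (result, unit_village)
        if len(per_scenario) >= 2:
            comp = scenario_compare_report(per_scenario)
            comp.insert(0, "village", unit_name)
            comparisons.append(comp)

    report = pd.DataFrame(rows)
    report.to_csv(out / "report.csv", index=False)
    if comparisons:
        pd.concat(comparisons, ignore_index=True).to_csv(
            out / "comparisons.csv", index=False
        )
    summary = {
        "version": __version__,
        "seed": seed,
        "campaign": campaign_cfg,
        "village": {
            "name": village.name,
            "n_households": village.n_households,
            "total_children": village.total_children,
            "total_population": village.total_population,
        },
        "results": rows,
        "comparisons": (
            pd.concat(comparisons, ignore_index=True).to_dict("records")
            if comparisons
            else []
        ),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
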