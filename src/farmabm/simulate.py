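"""Annual simulation loop, Monte-Carlo harness and regional indicators.

One run executes, per simulated year: scenario multipliers, the extreme
event (drawn or replayed), the cumulative event counter and the learning
functions, farm accounts and peer statistics, the satisfaction evaluation,
one decision per unsatisfied active farm in randomized order, the rental
market step, and the capture of the regional indicators.

Random streams are derived from one base seed as separate named substreams
(events / decisions), so replaying a stored event log into a run perturbs
nothing but the event sequence itself.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .constants import (
    CROPLAND,
    FARM_TYPES,
    GRASSLAND_CODES,
    HOLDER_FOREST,
    HOLDER_RENTAL,
    ORGANIC,
    QUADRANTS,
)
from .decisions import (
    DecisionMatrix,
    RentalMarket,
    action_probabilities,
    choose_action,
    default_decision_matrix,
    execute_action,
    market_step,
)
from .economy import (
    EconomyTables,
    annual_accounts,
    compute_peer_stats,
    evaluate_satisfaction,
    update_cattle,
)
from .events import EventLog, draw_event_sequence
from .learning import AdaptationParams, AdaptationState
from .region import RegionState

logger = logging.getLogger("farmabm")

#: column order of the per-year metrics table
METRIC_COLUMNS = [
    "year", "event", "active_farms_total",
    *[f"active_{t}" for t in FARM_TYPES],
    "area_cropland", "area_grassland", "area_rental", "area_forest",
    "extensive_area_share", "organic_farm_share",
    "cycle_share_cr1", "cycle_share_cr2", "cycle_share_cr3",
    "share_farms_gt_20ha", "share_income_insufficient", "share_workload_excess",
]


@dataclass
class RunResult:
    """Metrics series and event log of one simulation run."""

    run_id: str
    scenario: str
    adaptive: bool
    metrics: pd.DataFrame
    event_log: EventLog
    action_counts: pd.DataFrame

    @property
    def final(self) -> pd.Series:
        return self.metrics.iloc[-1]


def _metrics_row(
    region: RegionState, year: int, event: bool, satisfaction, size_threshold: float
) -> dict:
    f, p = region.farms, region.patches
    active = f.active
    n_active = int(active.sum())
    held = p.holder >= 0
    area_crop = float(p.area_ha[held & (p.land_use == CROPLAND)].sum())
    area_grass = float(p.area_ha[held & np.isin(p.land_use, GRASSLAND_CODES)].sum())
    area_rental = float(p.area_ha[p.holder == HOLDER_RENTAL].sum())
    area_forest = float(p.area_ha[p.holder == HOLDER_FOREST].sum())
    agri = area_crop + area_grass
    ext = float(p.area_ha[held & (p.intensity < 3)].sum())
    crop_area = p.area_ha[held & (p.land_use == CROPLAND)]
    crop_cycle = p.crop_cycle[held & (p.land_use == CROPLAND)]
    cyc = [
        float(crop_area[crop_cycle == c].sum()) / area_crop if area_crop > 0 else 0.0
        for c in (1, 2, 3)
    ]
    sizes = region.farm_sizes()
    row = {
        "year": year,
        "event": bool(event),
        "active_farms_total": n_active,
        "area_cropland": area_crop,
        "area_grassland": area_grass,
        "area_rental": area_rental,
        "area_forest": area_forest,
        "extensive_area_share": ext / agri if agri > 0 else 0.0,
        "organic_farm_share": (
            float((f.production[active] == ORGANIC).mean()) if n_active else 0.0
        ),
        "cycle_share_cr1": cyc[0],
        "cycle_share_cr2": cyc[1],
        "cycle_share_cr3": cyc[2],
        "share_farms_gt_20ha": (
            float((sizes[active] > size_threshold).mean()) if n_active else 0.0
        ),
        "share_income_insufficient": (
            float((~satisfaction.income_ok[active]).mean()) if n_active else 0.0
        ),
        "share_workload_excess": (
            float((~satisfaction.workload_ok[active]).mean()) if n_active else 0.0
        ),
    }
    for ti, t in enumerate(FARM_TYPES):
        row[f"active_{t}"] = int((f.farm_type[active] == ti).sum())
    return row


def _farm_patch_lists(region: RegionState) -> dict[int, list[int]]:
    holders = region.patches.holder
    lists: dict[int, list[int]] = {}
    for i in np.flatnonzero(holders >= 0):
        lists.setdefault(int(holders[i]), []).append(int(i))
    return lists


def run_simulation(
    region: RegionState,
    config: ScenarioConfig,
    tables: EconomyTables | None = None,
    matrix: DecisionMatrix | None = None,
    events: EventLog | None = None,
    seed: int = 0,
    adaptation_params: AdaptationParams | None = None,
    run_id: str = "run0",
) -> RunResult:
    """Execute one full run; the input region is copied, not mutated.

    ``events`` replays a stored log (bypassing the event stream); when
    omitted, a fresh sequence is drawn from the event substream of
    ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    events_ss, decisions_ss = ss.spawn(2)
    event_rng = np.random.default_rng(events_ss)
    decision_rng = np.random.default_rng(decisions_ss)

    if events is None:
        log = draw_event_sequence(config, event_rng, run_id=run_id)
    else:
        if events.horizon != config.horizon:
            raise ValueError(
                f"replayed log spans {events.horizon} years, "
                f"configured horizon is {config.horizon}"
            )
        log = events

    region = region.copy()
    region.year = config.start_year
    tables = tables or EconomyTables.from_overrides(config.economy_overrides)
    matrix = matrix if matrix is not None else default_decision_matrix()
    params = adaptation_params or AdaptationParams()
    adaptation = AdaptationState(x=region.cumulative_events, params=params)
    market = RentalMarket.from_region(region, config.afforestation_wait)
    size_threshold = float(region.init_params.get("size_threshold_ha", 20.0))
    neither_code = QUADRANTS.index("neither")
    both_ok_code = QUADRANTS.index("both_ok")

    rows = []
    action_rows = []

    # initial-year snapshot (no event, no decisions)
    update_cattle(region, tables)
    accounts = annual_accounts(region, tables, config, region.year, event=False)
    peers = compute_peer_stats(accounts, region)
    satisfaction = evaluate_satisfaction(accounts, config.thresholds, peers, region)
    rows.append(
        _metrics_row(region, region.year, False, satisfaction, size_threshold)
    )

    for t in range(config.horizon):
        year = config.start_year + 1 + t
        region.year = year
        event = bool(log.event[t])
        if event:
            region.cumulative_events += 1
            adaptation.x = region.cumulative_events

        update_cattle(region, tables)
        accounts = annual_accounts(region, tables, config, year, event)
        peers = compute_peer_stats(accounts, region)
        satisfaction = evaluate_satisfaction(
            accounts, config.thresholds, peers, region
        )

        f = region.farms
        in_neither = f.active & (satisfaction.quadrant == neither_code)
        f.suffer_counter[in_neither] += 1

        unsat = np.flatnonzero(f.active & (satisfaction.quadrant != both_ok_code))
        order = decision_rng.permutation(unsat)
        patch_lists = _farm_patch_lists(region)
        counts = np.zeros(10, dtype=int)
        n_satisfied = int((f.active & (satisfaction.quadrant == both_ok_code)).sum())
        counts[0] += n_satisfied  # satisfied farms implicitly do nothing
        for farm_idx in order:
            farm_idx = int(farm_idx)
            plist = patch_lists.setdefault(farm_idx, [])
            probs = action_probabilities(
                matrix,
                farm_idx,
                region,
                int(satisfaction.quadrant[farm_idx]),
                plist,
                config,
                adaptation=adaptation if config.adaptive else None,
                params=params,
            )
            action = choose_action(probs, decision_rng)
            execute_action(
                farm_idx,
                action,
                region,
                market,
                decision_rng,
                plist,
                tables,
                config,
                income_ok=bool(satisfaction.income_ok[farm_idx]),
                year=year,
            )
            counts[action] += 1

        market_step(market, region, year)
        rows.append(_metrics_row(region, year, event, satisfaction, size_threshold))
        action_rows.append({"year": year} | {f"act{k+1}": int(counts[k]) for k in range(10)})
        logger.info(
            "year=%d event=%d active=%d decisions=%s",
            year, event, int(f.active.sum()), counts.tolist(),
        )

    metrics = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    return RunResult(
        run_id=run_id,
        scenario=config.name,
        adaptive=config.adaptive,
        metrics=metrics,
        event_log=log,
        action_counts=pd.DataFrame(action_rows),
    )


def run_monte_carlo(
    config: ScenarioConfig,
    region: RegionState,
    n_runs: int = 100,
    base_seed: int = 0,
    paired: bool = False,
    tables: EconomyTables | None = None,
    matrix: DecisionMatrix | None = None,
    adaptation_params: AdaptationParams | None = None,
) -> list[RunResult]:
    """Repeat runs with seeds ``base_seed + r``.

    With ``paired=True`` each run is executed twice from the same seed and
    event sequence: once with the given configuration and once with its
    adaptive counterpart replaying the same event log, enabling
    common-random-number comparisons of adaptation effects.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    results = []
    adaptive_config = None
    if paired:
        name = config.name if config.name.endswith("A") else config.name + "A"
        adaptive_config = dataclasses.replace(config, name=name, adaptive=True)
    for r in range(n_runs):
        seed = base_seed + r
        run_id = f"run{r:03d}"
        res = run_simulation(
            region, config, tables=tables, matrix=matrix, seed=seed,
            adaptation_params=adaptation_params, run_id=run_id,
        )
        results.append(res)
        if paired:
            res_a = run_simulation(
                region, adaptive_config, tables=tables, matrix=matrix,
                events=res.event_log, seed=seed,
                adaptation_params=adaptation_params, run_id=run_id,
            )
            results.append(res_a)
    return results


def summarize(results: list[RunResult]) -> dict[str, pd.DataFrame]:
    """Monte-Carlo summaries: final-year statistics, per-year event counts,
    and adaptive-minus-non-adaptive deltas for paired scenario pairs."""
    if not results:
        raise ValueError("no results to summarize")
    finals = pd.DataFrame(
        [
            {"scenario": r.scenario, "run_id": r.run_id}
            | r.final.drop("event").to_dict()
            for r in results
        ]
    )
    stats = finals.drop(columns="run_id").groupby("scenario").agg(
        [
            ("mean", "mean"),
            ("sd", lambda s: s.std(ddof=0)),
            ("q25", lambda s: s.quantile(0.25)),
            ("median", "median"),
            ("q75", lambda s: s.quantile(0.75)),
        ]
    )
    stats.columns = [f"{m}_{n}" for m, n in stats.columns]
    event_rows = []
    for r in results:
        for year, ev in zip(r.event_log.years, r.event_log.event):
            event_rows.append({"scenario": r.scenario, "year": int(year), "event": int(ev)})
    events_by_year = (
        pd.DataFrame(event_rows).groupby(["scenario", "year"])["event"].sum().reset_index()
        .rename(columns={"event": "runs_with_event"})
    )
    # paired deltas: scenario S vs SA matched on run_id
    deltas = []
    by_key = {(r.scenario, r.run_id): r for r in results}
    for (scen, run_id), r in by_key.items():
        partner = by_key.get((scen + "A", run_id))
        if partner is None or scen.endswith("A"):
            continue
        d = partner.final.drop("event") - r.final.drop("event")
        deltas.append({"scenario": scen, "run_id": run_id} | d.to_dict())
    paired_deltas = (
        pd.DataFrame(deltas).drop(columns="run_id").groupby("scenario").mean()
        if deltas
        else pd.DataFrame()
    )
    return {
        "final": stats,
        "events_by_year": events_by_year,
        "paired_deltas": paired_deltas,
    }


def metrics_long(results: list[RunResult]) -> pd.DataFrame:
    """Long-format metrics table (run_id, scenario, year, metric, value)."""
    frames = []
    for r in results:
        m = r.metrics.melt(id_vars="year", var_name="metric", value_name="value")
        m.insert(0, "scenario", r.scenario)
        m.insert(0, "run_id", r.run_id)
        frames.append(m)
    return pd.concat(frames, ignore_index=True)


def save_results(results: list[RunResult], path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    metrics_long(results).to_csv(path / "metrics.csv", index=False)
    summary = summarize(results)
    summary["final"].to_csv(path / "summary_final.csv")
    summary["events_by_year"].to_csv(path / "events_by_year.csv", index=False)
    if len(summary["paired_deltas"]):
        summary["paired_deltas"].to_csv(path / "paired_deltas.csv")
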