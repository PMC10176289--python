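"""Annual farm accounts and the three satisfaction criteria.

Income is the sum over held patches of
``area x gross_margin x price_multiplier x yield_factor`` plus livestock
margins plus ``area x subsidy_rate x subsidy_multiplier``; workload is the
per-ha labor demand plus livestock labor, scaled by the scenario workload
trend.  Per-worker figures divide by the effective labor supply
``fte + hired_hours / 1800``.

Farms are satisfied when (1) income per full-time worker equivalent reaches
the farm-type minimum, (2) annual hours per worker stay at or below 1800,
and (3) hourly income reaches the peer floor — the farming-type mean minus
one population standard deviation, recomputed over active farms each year.
Criteria 1 and 3 jointly form the income criterion; criterion 2 the
workload criterion.  The four combinations define the satisfaction
quadrant that the decision engine conditions on.

The shipped gross-margin / labor / subsidy tables are synthetic defaults in
EUR and hours per ha and year, chosen to give an Austrian-style mixed
region plausible income and workload levels; every entry can be overridden
from the configuration file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ConfigError, SatisfactionThresholds, ScenarioConfig, scenario_factor
from .constants import (
    AGRI_LAND_USES,
    FARM_TYPES,
    FTE_HOURS,
    ORGANIC,
    QUADRANTS,
)
from .region import RegionState

# default per-ha tables, rows = intensity 1..5
_DEFAULT_GM_CONV = {
    "cropland": [300.0, 450.0, 600.0, 750.0, 900.0],
    "meadow": [150.0, 250.0, 350.0, 450.0, 550.0],
    "pasture": [100.0, 180.0, 260.0, 340.0, 420.0],
    "mountain_pasture": [60.0, 110.0, 160.0, 210.0, 260.0],
}
_DEFAULT_GM_ORG = {
    "cropland": [340.0, 500.0, 660.0, 820.0, 980.0],
    "meadow": [170.0, 280.0, 390.0, 500.0, 610.0],
    "pasture": [115.0, 200.0, 285.0, 370.0, 455.0],
    "mountain_pasture": [70.0, 125.0, 180.0, 235.0, 290.0],
}
_DEFAULT_LABOR_CONV = {
    "cropland": [35.0, 45.0, 55.0, 65.0, 75.0],
    "meadow": [25.0, 35.0, 45.0, 55.0, 65.0],
    "pasture": [15.0, 22.0, 29.0, 36.0, 43.0],
    "mountain_pasture": [10.0, 15.0, 20.0, 25.0, 30.0],
}
# organic production needs more labor at equal intensity (roughly +35 %)
_DEFAULT_LABOR_ORG = {
    "cropland": [47.0, 61.0, 74.0, 88.0, 101.0],
    "meadow": [34.0, 47.0, 61.0, 74.0, 88.0],
    "pasture": [20.0, 30.0, 39.0, 49.0, 58.0],
    "mountain_pasture": [14.0, 20.0, 27.0, 34.0, 41.0],
}
_DEFAULT_SUBSIDY_CONV = 250.0  # EUR/ha, flat area payment
_DEFAULT_SUBSIDY_ORG = 450.0  # EUR/ha, area payment plus organic premium


def _table(per_lu: dict[str, list[float]]) -> np.ndarray:
    return np.array([per_lu[lu] for lu in AGRI_LAND_USES], dtype=float)


@dataclass
class EconomyTables:
    """Per-ha and per-livestock-unit economic coefficients.

    Array axes: ``(land_use, intensity 1..5, production)`` with land use
    indexed as in :data:`farmabm.constants.AGRI_LAND_USES`.  Crop-cycle
    modifiers multiply cropland margins/labor per rotation cycle
    (cr1 root crops: high margin, high labor; cr3 rapeseed: lean).
    """

    gross_margin_per_ha: np.ndarray = field(
        default_factory=lambda: np.stack(
            [_table(_DEFAULT_GM_CONV), _table(_DEFAULT_GM_ORG)], axis=-1
        )
    )
    labor_per_ha: np.ndarray = field(
        default_factory=lambda: np.stack(
            [_table(_DEFAULT_LABOR_CONV), _table(_DEFAULT_LABOR_ORG)], axis=-1
        )
    )
    subsidy_per_ha: np.ndarray = field(
        default_factory=lambda: np.stack(
            [
                np.full((4, 5), _DEFAULT_SUBSIDY_CONV),
                np.full((4, 5), _DEFAULT_SUBSIDY_ORG),
            ],
            axis=-1,
        )
    )
    cycle_margin_mult: np.ndarray = field(
        default_factory=lambda: np.array([1.25, 1.0, 0.95])
    )
    cycle_labor_mult: np.ndarray = field(
        default_factory=lambda: np.array([1.30, 1.0, 0.90])
    )
    livestock_margin_per_lu: dict[str, float] = field(
        default_factory=lambda: {"cattle": 500.0, "pig": 300.0}
    )
    livestock_labor_per_lu: dict[str, float] = field(
        default_factory=lambda: {"cattle": 60.0, "pig": 15.0}
    )
    forage_coefficient: float = 0.3

    def validate(self) -> None:
        for name in ("gross_margin_per_ha", "labor_per_ha", "subsidy_per_ha"):
            arr = getattr(self, name)
            if arr.shape != (4, 5, 2):
                raise ConfigError(f"{name} must have shape (4, 5, 2)")
        if np.any(self.labor_per_ha[..., ORGANIC] < self.labor_per_ha[..., 0]):
            raise ConfigError("organic labor must be >= conventional labor")
        conv_gm = self.gross_margin_per_ha[..., 0]
        conv_lab = self.labor_per_ha[..., 0]
        if np.any(np.diff(conv_gm, axis=1) < 0) or np.any(np.diff(conv_lab, axis=1) < 0):
            raise ConfigError(
                "conventional margins and labor must be non-decreasing in intensity"
            )
        if self.forage_coefficient <= 0:
            raise ConfigError("forage_coefficient must be positive")

    @classmethod
    def from_overrides(cls, overrides: dict | None) -> "EconomyTables":
        """Build tables, applying ``{table: {land_use: [5 values]}}`` overrides."""
        tables = cls()
        if overrides:
            key_map = {
                "gross_margin_per_ha": "gross_margin_per_ha",
                "labor_per_ha": "labor_per_ha",
                "subsidy_per_ha": "subsidy_per_ha",
            }
            for key, table_name in key_map.items():
                spec = overrides.get(key)
                if not spec:
                    continue
                arr = getattr(tables, table_name)
                for prod_name, per_lu in spec.items():
                    p = ("conventional", "organic").index(prod_name)
                    for lu, values in per_lu.items():
                        arr[AGRI_LAND_USES.index(lu), :, p] = values
            for key in ("cycle_margin_mult", "cycle_labor_mult"):
                if key in overrides:
                    setattr(tables, key, np.asarray(overrides[key], dtype=float))
            for key in ("livestock_margin_per_lu", "livestock_labor_per_lu"):
                if key in overrides:
                    getattr(tables, key).update(overrides[key])
            if "forage_coefficient" in overrides:
                tables.forage_coefficient = float(overrides["forage_coefficient"])
        tables.validate()
        return tables


@dataclass
class FarmAccountsTable:
    """Per-farm annual accounts (arrays aligned with the farm table)."""

    income: np.ndarray
    workload: np.ndarray
    income_per_fte: np.ndarray
    hours_per_fte: np.ndarray
    hourly_income: np.ndarray
    degenerate: np.ndarray  # True for farms with neither patches nor livestock


@dataclass
class PeerStats:
    """Hourly-income floor per farming type: mean minus one population SD."""

    mean: np.ndarray  # per farm type
    sd: np.ndarray
    floor: np.ndarray


@dataclass
class SatisfactionTable:
    income_ok: np.ndarray
    workload_ok: np.ndarray
    quadrant: np.ndarray  # int8, index into QUADRANTS


def update_cattle(region: RegionState, tables: EconomyTables) -> None:
    """Recompute cattle herds from current meadow/pasture forage provision.

    Forage provision is ``area x intensity`` summed over held meadow and
    pasture patches; only farms of cattle-keeping types carry a herd.
    """
    p = region.patches
    held = p.holder >= 0
    forage_patch = np.where(
        held & np.isin(p.land_use, (1, 2)), p.area_ha * p.intensity, 0.0
    )
    forage = np.bincount(
        p.holder[held], weights=forage_patch[held], minlength=len(region.farms)
    )
    region.farms.cattle_lu = np.where(
        region.farms.has_cattle, forage * tables.forage_coefficient, 0.0
    )


def annual_accounts(
    region: RegionState,
    tables: EconomyTables,
    config: ScenarioConfig,
    year: int,
    event: bool,
) -> FarmAccountsTable:
    """Vectorized accounts for every farm in one year.

    The event shock multiplies the land-based yield factor of every
    agricultural class; subsidies and livestock margins are unaffected by
    events (direct payments are area-based).
    """
    f, p = region.farms, region.patches
    n = len(f)
    held = p.holder >= 0
    lu = p.land_use[held]
    inten = p.intensity[held].astype(int) - 1
    holder = p.holder[held]
    prod = f.production[holder].astype(int)
    area = p.area_ha[held]
    cycle = p.crop_cycle[held].astype(int)

    yield_by_lu = np.array(
        [
            scenario_factor(config, year, "yield_trend", land_use=l)
            for l in AGRI_LAND_USES
        ]
    )
    if event:
        yield_by_lu = yield_by_lu * (1.0 - config.event_yield_shock)
    price_by_prod = np.array(
        [
            scenario_factor(config, year, "price", production=pr)
            for pr in ("conventional", "organic")
        ]
    )
    subsidy_by_prod = np.array(
        [
            scenario_factor(config, year, "subsidy_conv"),
            scenario_factor(config, year, "subsidy_org"),
        ]
    )
    workload_mult = scenario_factor(config, year, "workload")

    cyc_margin = np.where(cycle > 0, tables.cycle_margin_mult[cycle - 1], 1.0)
    cyc_labor = np.where(cycle > 0, tables.cycle_labor_mult[cycle - 1], 1.0)
    margin = (
        area
        * tables.gross_margin_per_ha[lu, inten, prod]
        * cyc_margin
        * price_by_prod[prod]
        * yield_by_lu[lu]
    )
    subsidy = area * tables.subsidy_per_ha[lu, inten, prod] * subsidy_by_prod[prod]
    labor = area * tables.labor_per_ha[lu, inten, prod] * cyc_labor

    income = np.bincount(holder, weights=margin + subsidy, minlength=n).astype(float)
    workload = np.bincount(holder, weights=labor, minlength=n).astype(float)
    income += (
        f.cattle_lu * tables.livestock_margin_per_lu["cattle"]
        + f.pig_lu * tables.livestock_margin_per_lu["pig"]
    )
    workload += (
        f.cattle_lu * tables.livestock_labor_per_lu["cattle"]
        + f.pig_lu * tables.livestock_labor_per_lu["pig"]
    )
    workload *= workload_mult

    eff_fte = f.fte + f.hired_hours / FTE_HOURS
    if np.any(eff_fte[f.active] <= 0):
        raise ConfigError("active farm with zero labor supply")
    with np.errstate(divide="ignore", invalid="ignore"):
        income_per_fte = np.where(eff_fte > 0, income / eff_fte, 0.0)
        hours_per_fte = np.where(eff_fte > 0, workload / eff_fte, 0.0)
        hourly = np.where(workload > 0, income / workload, 0.0)
    n_patches = np.bincount(holder, minlength=n)
    degenerate = (n_patches == 0) & (f.cattle_lu <= 0) & (f.pig_lu <= 0)
    return FarmAccountsTable(
        income=income,
        workload=workload,
        income_per_fte=income_per_fte,
        hours_per_fte=hours_per_fte,
        hourly_income=hourly,
        degenerate=degenerate,
    )


def farm_accounts(
    farm_index: int,
    region: RegionState,
    tables: EconomyTables,
    config: ScenarioConfig,
    year: int,
    event: bool,
) -> dict:
    """Accounts of a single farm, as a plain dict (convenience wrapper)."""
    acc = annual_accounts(region, tables, config, year, event)
    return {
        "income": float(acc.income[farm_index]),
        "workload": float(acc.workload[farm_index]),
        "income_per_fte": float(acc.income_per_fte[farm_index]),
        "hours_per_fte": float(acc.hours_per_fte[farm_index]),
        "hourly_income": float(acc.hourly_income[farm_index]),
        "degenerate": bool(acc.degenerate[farm_index]),
    }


def compute_peer_stats(accounts: FarmAccountsTable, region: RegionState) -> PeerStats:
    """Per-farming-type mean, population SD and floor of hourly income.

    Computed over active farms; a type with a single farm gets SD 0, so its
    floor equals that farm's own hourly income.
    """
    f = region.farms
    if not np.any(f.active):
        raise ConfigError("no active farms")
    n_types = len(FARM_TYPES)
    mean = np.full(n_types, np.nan)
    sd = np.zeros(n_types)
    active = f.active
    counts = np.bincount(f.farm_type[active], minlength=n_types).astype(float)
    sums = np.bincount(
        f.farm_type[active], weights=accounts.hourly_income[active], minlength=n_types
    )
    sq = np.bincount(
        f.farm_type[active],
        weights=accounts.hourly_income[active] ** 2,
        minlength=n_types,
    )
    present = counts > 0
    mean[present] = sums[present] / counts[present]
    var = np.zeros(n_types)
    var[present] = np.maximum(0.0, sq[present] / counts[present] - mean[present] ** 2)
    sd = np.sqrt(var)
    floor = mean - sd
    return PeerStats(mean=mean, sd=sd, floor=floor)


def evaluate_satisfaction(
    accounts: FarmAccountsTable,
    thresholds: SatisfactionThresholds,
    peers: PeerStats,
    region: RegionState,
) -> SatisfactionTable:
    """Evaluate the three criteria for every farm (thresholds inclusive)."""
    f = region.farms
    min_income = np.array(
        [thresholds.min_income_per_fte[t] for t in FARM_TYPES]
    )[f.farm_type]
    floor = peers.floor[f.farm_type]
    # tolerant comparison so a farm exactly at its peer floor (e.g. the only
    # farm of its type) is not tipped over by summation round-off
    above_floor = (accounts.hourly_income >= floor) | np.isclose(
        accounts.hourly_income, floor, rtol=1e-9, atol=1e-9
    )
    income_ok = (accounts.income_per_fte >= min_income) & above_floor
    workload_ok = accounts.hours_per_fte <= thresholds.max_workload_per_fte
    quadrant = np.select(
        [
            income_ok & workload_ok,
            income_ok & ~workload_ok,
            ~income_ok & workload_ok,
        ],
        [
            QUADRANTS.index("both_ok"),
            QUADRANTS.index("income_only"),
            QUADRANTS.index("workload_only"),
        ],
        default=QUADRANTS.index("neither"),
    ).astype(np.int8)
    return SatisfactionTable(
        income_ok=income_ok, workload_ok=workload_ok, quadrant=quadrant
    )
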