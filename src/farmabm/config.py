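"""Scenario parameterization: presets, validation, file I/O and time paths.

Three socio-economic storylines drive the model:

* ``BAU`` — business as usual: constant subsidies, moderate yield decline,
  10 %/a expected extreme-event probability with 40 % yield loss per event.
* ``HS`` — high subsidy: rising prices and stepwise subsidy increases
  (+50 % conventional / +75 % organic by 2030), mild climate impacts
  (7.5 %/a events, 30 % loss).
* ``FM`` — free market: subsidies stepped down to zero by 2030, pronounced
  climate change (15 %/a events, 60 % loss), and the additional option for
  organic farms to revert to conventional production.

Each storyline exists with and without adaptive learning; the adaptive
variants carry an ``A`` suffix (``BAUA``, ``HSA``, ``FMA``).

Deterministic drivers (yield trend, prices, workload) interpolate linearly
from 1.0 at the start year to their scenario endpoint in the final simulated
year; subsidies follow a stepwise schedule that is constant after its last
step.  :func:`scenario_factor` evaluates any of these multipliers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .constants import AGRI_LAND_USES, FARM_TYPES, PRODUCTIONS


class ConfigError(ValueError):
    """Raised for schema or invariant violations in a configuration."""


#: quantities understood by :func:`scenario_factor`
FACTOR_QUANTITIES = ("yield_trend", "price", "subsidy_conv", "subsidy_org", "workload")


@dataclass
class SatisfactionThresholds:
    """Constant satisfaction thresholds.

    ``min_income_per_fte`` is the farm-type-specific minimum annual
    agricultural income (currency units per full-time worker equivalent);
    ``max_workload_per_fte`` caps acceptable annual hours per worker.
    """

    min_income_per_fte: dict[str, float] = field(
        default_factory=lambda: {
            "cash_crop": 6000.0,
            "processing_pig": 18000.0,
            "processing_suckler": 6500.0,
            "livestock_meat": 6500.0,
            "livestock_milk": 7000.0,
        }
    )
    max_workload_per_fte: float = 1800.0

    def validate(self) -> None:
        missing = [t for t in FARM_TYPES if t not in self.min_income_per_fte]
        if missing:
            raise ConfigError(f"min_income_per_fte missing farm types: {missing}")
        if any(v <= 0 for v in self.min_income_per_fte.values()):
            raise ConfigError("min_income_per_fte values must be positive")
        if self.max_workload_per_fte <= 0:
            raise ConfigError("max_workload_per_fte must be positive")


@dataclass
class ScenarioConfig:
    """Complete parameterization of one scenario variant.

    ``yield_trend_endpoints`` maps each agricultural land-use class to the
    fractional yield decrease reached in the final year (0.25 means yields
    end 25 % below the start level).  ``subsidy_schedule`` is an ordered
    list of ``(year, conv_multiplier, org_multiplier)`` steps; before the
    first step the multiplier is 1.0, after the last it is constant.
    """

    name: str = "BAU"
    adaptive: bool = False
    horizon: int = 37
    start_year: int = 2015
    yield_trend_endpoints: dict[str, float] = field(
        default_factory=lambda: {
            "cropland": 0.25,
            "meadow": 0.05,
            "pasture": 0.05,
            "mountain_pasture": 0.05,
        }
    )
    price_multiplier: dict[str, float] = field(
        default_factory=lambda: {"conventional": 1.0, "organic": 1.0}
    )
    subsidy_schedule: list[tuple[int, float, float]] = field(default_factory=list)
    workload_trend: float = 0.10
    event_mu: float = 0.10
    event_sigma: float = 0.025
    event_yield_shock: float = 0.40
    allow_org_to_conv: bool = False
    thresholds: SatisfactionThresholds = field(default_factory=SatisfactionThresholds)
    # model-behaviour knobs not tied to a storyline
    afforestation_wait: int = 5
    suffer_threshold: int = 5
    # free-form overrides consumed by region synthesis / economy tables
    init_overrides: dict = field(default_factory=dict)
    economy_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.subsidy_schedule = [tuple(s) for s in self.subsidy_schedule]
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.horizon < 1:
            raise ConfigError("horizon must be >= 1")
        if not 0.0 <= self.event_mu <= 1.0:
            raise ConfigError(f"event_mu must be in [0, 1], got {self.event_mu}")
        if self.event_sigma < 0.0:
            raise ConfigError(f"event_sigma must be >= 0, got {self.event_sigma}")
        if not 0.0 <= self.event_yield_shock <= 1.0:
            raise ConfigError(
                f"event_yield_shock must be in [0, 1], got {self.event_yield_shock}"
            )
        for lu, v in self.yield_trend_endpoints.items():
            if lu not in AGRI_LAND_USES:
                raise ConfigError(f"unknown land use in yield_trend_endpoints: {lu}")
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"yield_trend_endpoints[{lu}] must be in [0, 1]")
        for prod in self.price_multiplier:
            if prod not in PRODUCTIONS:
                raise ConfigError(f"unknown production system: {prod}")
        years = [s[0] for s in self.subsidy_schedule]
        if years != sorted(years):
            raise ConfigError("subsidy_schedule must be ordered by year")
        for year, conv, org in self.subsidy_schedule:
            if conv < 0 or org < 0:
                raise ConfigError("subsidy multipliers must be nonnegative")
        if self.workload_trend < 0:
            raise ConfigError("workload_trend must be >= 0")
        if self.afforestation_wait < 1:
            raise ConfigError("afforestation_wait must be >= 1")
        if self.suffer_threshold < 1:
            raise ConfigError("suffer_threshold must be >= 1")
        self.thresholds.validate()

    @property
    def final_year(self) -> int:
        return self.start_year + self.horizon


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _hs_schedule() -> list[tuple[int, float, float]]:
    # three equal steps (2020/2025/2030) to +50 % conv. / +75 % org.
    return [
        (2020, 1 + 0.50 / 3, 1.25),
        (2025, 1 + 1.00 / 3, 1.50),
        (2030, 1.50, 1.75),
    ]


def _fm_schedule() -> list[tuple[int, float, float]]:
    # three equal steps down to full subsidy abolition by 2030
    return [
        (2020, 2 / 3, 2 / 3),
        (2025, 1 / 3, 1 / 3),
        (2030, 0.0, 0.0),
    ]


_PRESET_FIELDS: dict[str, dict] = {
    "BAU": {},
    "HS": {
        "yield_trend_endpoints": {
            "cropland": 0.10,
            "meadow": 0.0,
            "pasture": 0.0,
            "mountain_pasture": 0.0,
        },
        "price_multiplier": {"conventional": 1.15, "organic": 1.25},
        "subsidy_schedule": _hs_schedule(),
        "workload_trend": 0.05,
        "event_mu": 0.075,
        "event_yield_shock": 0.30,
    },
    "FM": {
        "yield_trend_endpoints": {
            "cropland": 0.50,
            "meadow": 0.15,
            "pasture": 0.15,
            "mountain_pasture": 0.15,
        },
        "subsidy_schedule": _fm_schedule(),
        "event_mu": 0.15,
        "event_yield_shock": 0.60,
        "allow_org_to_conv": True,
    },
}

PRESET_NAMES = ("BAU", "HS", "FM", "BAUA", "HSA", "FMA")


def preset(name: str) -> ScenarioConfig:
    """Return a built-in scenario configuration by name.

    Names ending in ``A`` are the adaptive (learning-enabled) variants of
    the corresponding base storyline.
    """
    key = name.upper()
    adaptive = key.endswith("A") and key not in _PRESET_FIELDS
    base = key[:-1] if adaptive else key
    if base not in _PRESET_FIELDS:
        raise ConfigError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return ScenarioConfig(name=key, adaptive=adaptive, **_PRESET_FIELDS[base])


# ---------------------------------------------------------------------------
# time-varying multipliers
# ---------------------------------------------------------------------------

def scenario_factor(
    config: ScenarioConfig,
    year: int,
    quantity: str,
    land_use: str | None = None,
    production: str = "conventional",
) -> float:
    """Deterministic multiplier for a scenario-driven quantity in ``year``.

    Trend quantities (``yield_trend``, ``price``, ``workload``) interpolate
    linearly from 1.0 at the start year to their endpoint in the final
    year; subsidies follow the stepwise schedule.  ``yield_trend`` uses the
    endpoint of ``land_use`` when given, otherwise the mean endpoint over
    all agricultural classes.
    """
    if quantity not in FACTOR_QUANTITIES:
        raise ConfigError(f"unknown quantity {quantity!r}")
    if not config.start_year <= year <= config.final_year + 1:
        raise ConfigError(
            f"year {year} outside simulated horizon "
            f"[{config.start_year}, {config.final_year + 1}]"
        )
    frac = min(1.0, (year - config.start_year) / config.horizon)
    if quantity == "yield_trend":
        if land_use is not None:
            endpoint = config.yield_trend_endpoints[land_use]
        else:
            vals = config.yield_trend_endpoints.values()
            endpoint = sum(vals) / len(config.yield_trend_endpoints)
        return 1.0 - endpoint * frac
    if quantity == "price":
        endpoint = config.price_multiplier.get(production, 1.0)
        return 1.0 + (endpoint - 1.0) * frac
    if quantity == "workload":
        return 1.0 + config.workload_trend * frac
    # subsidies: last step with step year <= year; 1.0 before the first step
    col = 1 if quantity == "subsidy_conv" else 2
    value = 1.0
    for step in config.subsidy_schedule:
        if step[0] <= year:
            value = step[col]
    return value


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_SCENARIO_KEYS = {
    "name", "adaptive", "horizon", "start_year", "yield_trend_endpoints",
    "price_multiplier", "subsidy_schedule", "workload_trend", "event_mu",
    "event_sigma", "event_yield_shock", "allow_org_to_conv",
    "afforestation_wait", "suffer_threshold",
}


def load_config(path: str | Path) -> ScenarioConfig:
    """Load a scenario configuration from a YAML file.

    The file holds sections ``scenario``, ``economy``, ``init`` and ``run``
    (all optional except ``scenario``).  A ``preset`` key inside
    ``scenario`` pulls the named built-in defaults, which the remaining
    keys then override.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "scenario" not in raw:
        raise ConfigError(f"{path}: missing [scenario] section")
    sc = dict(raw["scenario"])
    base = preset(sc.pop("preset")) if "preset" in sc else ScenarioConfig()
    unknown = set(sc) - _SCENARIO_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown scenario fields {sorted(unknown)}")
    fields = {f.name: getattr(base, f.name) for f in dataclasses.fields(ScenarioConfig)}
    fields.update(sc)
    run = raw.get("run", {}) or {}
    for key in ("afforestation_wait", "suffer_threshold"):
        if key in run:
            fields[key] = run[key]
    thresholds = raw.get("thresholds", {}) or {}
    if thresholds:
        fields["thresholds"] = SatisfactionThresholds(
            min_income_per_fte={
                **SatisfactionThresholds().min_income_per_fte,
                **thresholds.get("min_income_per_fte", {}),
            },
            max_workload_per_fte=thresholds.get("max_workload_per_fte", 1800.0),
        )
    fields["economy_overrides"] = raw.get("economy", {}) or {}
    fields["init_overrides"] = raw.get("init", {}) or {}
    return ScenarioConfig(**fields)


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    """Serialize a configuration to YAML; round-trips via :func:`load_config`."""
    doc = {
        "scenario": {
            "name": config.name,
            "adaptive": config.adaptive,
            "horizon": config.horizon,
            "start_year": config.start_year,
            "yield_trend_endpoints": dict(config.yield_trend_endpoints),
            "price_multiplier": dict(config.price_multiplier),
            "subsidy_schedule": [list(s) for s in config.subsidy_schedule],
            "workload_trend": config.workload_trend,
            "event_mu": config.event_mu,
            "event_sigma": config.event_sigma,
            "event_yield_shock": config.event_yield_shock,
            "allow_org_to_conv": config.allow_org_to_conv,
        },
        "run": {
            "afforestation_wait": config.afforestation_wait,
            "suffer_threshold": config.suffer_threshold,
        },
        "thresholds": {
            "min_income_per_fte": dict(config.thresholds.min_income_per_fte),
            "max_workload_per_fte": config.thresholds.max_workload_per_fte,
        },
        "economy": config.economy_overrides,
        "init": config.init_overrides,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
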