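"""Stochastic extreme-event sequences and their yield shocks.

Each simulated year draws an event probability from a normal distribution
truncated to [0, 1] (scenario mean ``event_mu``, SD ``event_sigma``) and
then flips a Bernoulli coin with that probability.  Events are region-wide:
in an event year every farm's yields drop by the scenario's
``event_yield_shock`` fraction.  Sequences can be saved to CSV and replayed
into later runs, which bypasses the event random stream entirely — paired
adaptive/non-adaptive experiments rest on this.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .config import ScenarioConfig


class EventLogError(ValueError):
    """Raised for malformed or mismatched event logs."""


@dataclass
class EventLog:
    """Boolean extreme-event sequence for one run, with the drawn probabilities."""

    run_id: str
    scenario_name: str
    years: np.ndarray  # int, length = horizon
    event: np.ndarray  # bool
    drawn_p: np.ndarray  # float in [0, 1]

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.event = np.asarray(self.event, dtype=bool)
        self.drawn_p = np.asarray(self.drawn_p, dtype=float)
        if not (len(self.years) == len(self.event) == len(self.drawn_p)):
            raise EventLogError("years, event and drawn_p must have equal length")
        if np.any((self.drawn_p < 0) | (self.drawn_p > 1)):
            raise EventLogError("drawn_p must lie in [0, 1]")

    @property
    def horizon(self) -> int:
        return len(self.years)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


def draw_event_sequence(
    config: ScenarioConfig, rng: np.random.Generator, run_id: str = "run0"
) -> EventLog:
    """Draw one extreme-event sequence over the configured horizon.

    Uses a dedicated event random stream so decision randomness stays
    untouched when a drawn sequence is later replaced by a replayed log.
    """
    years = config.start_year + 1 + np.arange(config.horizon)
    if config.event_sigma == 0.0:
        p = np.full(config.horizon, float(np.clip(config.event_mu, 0.0, 1.0)))
    else:
        a = (0.0 - config.event_mu) / config.event_sigma
        b = (1.0 - config.event_mu) / config.event_sigma
        p = truncnorm.rvs(
            a, b, loc=config.event_mu, scale=config.event_sigma,
            size=config.horizon, random_state=rng,
        )
    event = rng.random(config.horizon) < p
    return EventLog(
        run_id=run_id, scenario_name=config.name, years=years, event=event, drawn_p=p
    )


def apply_event_shock(
    base_yield_factor: float | np.ndarray, event: bool, config: ScenarioConfig
):
    """Compose the region-wide event shock with a deterministic yield factor."""
    if event:
        return base_yield_factor * (1.0 - config.event_yield_shock)
    return base_yield_factor


def save_event_log(log: EventLog, path: str | Path) -> None:
    pd.DataFrame(
        {
            "run_id": log.run_id,
            "scenario": log.scenario_name,
            "year": log.years,
            "drawn_p": log.drawn_p,
            "event": log.event.astype(int),
        }
    ).to_csv(path, index=False, float_format="%.17g")


def load_event_log(log_or_path: str | Path, horizon: int | None = None) -> EventLog:
    """Read an event log CSV; optionally enforce an expected horizon."""
    df = pd.read_csv(log_or_path, float_precision="round_trip")
    required = {"run_id", "scenario", "year", "drawn_p", "event"}
    missing = required - set(df.columns)
    if missing:
        raise EventLogError(f"event log missing columns: {sorted(missing)}")
    log = EventLog(
        run_id=str(df["run_id"].iloc[0]),
        scenario_name=str(df["scenario"].iloc[0]),
        years=df["year"].to_numpy(int),
        event=df["event"].to_numpy(int).astype(bool),
        drawn_p=df["drawn_p"].to_numpy(float),
    )
    if horizon is not None and log.horizon != horizon:
        raise EventLogError(
            f"event log spans {log.horizon} years, configured horizon is {horizon}"
        )
    return log
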