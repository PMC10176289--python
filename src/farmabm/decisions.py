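"""Action likelihoods, categorical action sampling and action execution.

Unsatisfied farms choose one of ten annual actions (do nothing, hire,
intensify, extensify, convert to organic, change land use, afforest,
expand, reduce, terminate).  Base likelihood vectors depend on the
satisfaction quadrant, farm type and farming style; structurally
impossible actions are zeroed and the vector renormalized before sampling.
Satisfied farms always pick "do nothing".

The published per-style probability tables are not public, so the shipped
matrix encodes the documented qualitative structure — income-stressed
states load intensification / land-use change / expansion / termination,
workload-stressed states load hiring / extensification / reduction, and
styles tilt the weights (traditionalists toward inaction, innovative
toward change).  The matrix serializes to a flat CSV so real tables can be
substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .constants import (
    ACTIONS,
    CONVENTIONAL,
    CROPLAND,
    CYCLE_NONE,
    FARM_TYPES,
    FOREST,
    GRASSLAND_CODES,
    HOLDER_RENTAL,
    HOLDER_FOREST,
    N_ACTIONS,
    ORGANIC,
    QUADRANTS,
    STYLES,
)
from .economy import EconomyTables
from .learning import AdaptationParams, AdaptationState, boosted_weights
from .region import RegionState


class DecisionError(ValueError):
    pass


# base weights per quadrant (actions 1..10); see module docstring
_BASE_WEIGHTS = {
    "both_ok": np.array([1.0, 0, 0, 0, 0, 0, 0, 0, 0, 0]),
    "income_only": np.array([0.20, 0.22, 0.02, 0.16, 0.03, 0.12, 0.04, 0.02, 0.15, 0.04]),
    "workload_only": np.array([0.20, 0.02, 0.22, 0.02, 0.08, 0.16, 0.02, 0.18, 0.06, 0.04]),
    "neither": np.array([0.10, 0.08, 0.08, 0.10, 0.10, 0.12, 0.08, 0.08, 0.16, 0.10]),
}

# multiplicative style tilts on the base weights
_STYLE_TILTS = {
    "innovative": {0: 0.6, 2: 1.5, 4: 1.5, 5: 1.5, 7: 1.5},
    "yield_optimizer": {2: 1.6, 3: 0.8, 4: 0.8, 5: 1.6},
    "support_optimizer": {4: 1.6, 7: 1.6},
    "idealist": {2: 0.8, 4: 1.4, 6: 1.4},
    "traditionalist": {0: 1.8, 4: 0.5, 5: 0.5, 7: 0.5},
}


@dataclass
class DecisionMatrix:
    """Likelihood vectors indexed by (quadrant, farm type, farming style)."""

    weights: np.ndarray  # shape (4, 5, 5, 10), rows sum to 1

    def __post_init__(self) -> None:
        if self.weights.shape != (len(QUADRANTS), len(FARM_TYPES), len(STYLES), N_ACTIONS):
            raise DecisionError(f"bad decision matrix shape {self.weights.shape}")
        if np.any(self.weights < 0):
            raise DecisionError("decision matrix weights must be nonnegative")
        sums = self.weights.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise DecisionError("decision matrix rows must sum to 1")

    def vector(self, quadrant: int, farm_type: int, style: int) -> np.ndarray:
        return self.weights[quadrant, farm_type, style]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for qi, q in enumerate(QUADRANTS):
            for ti, t in enumerate(FARM_TYPES):
                for si, s in enumerate(STYLES):
                    rows.append(
                        {"quadrant": q, "farm_type": t, "style": s}
                        | {f"act{k + 1}": self.weights[qi, ti, si, k] for k in range(N_ACTIONS)}
                    )
        return pd.DataFrame(rows)

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DecisionMatrix":
        w = np.zeros((len(QUADRANTS), len(FARM_TYPES), len(STYLES), N_ACTIONS))
        seen = np.zeros(w.shape[:3], dtype=bool)
        for _, row in df.iterrows():
            qi = QUADRANTS.index(row["quadrant"])
            ti = FARM_TYPES.index(row["farm_type"])
            si = STYLES.index(row["style"])
            w[qi, ti, si] = [row[f"act{k + 1}"] for k in range(N_ACTIONS)]
            seen[qi, ti, si] = True
        if not seen.all():
            raise DecisionError("decision matrix table is incomplete")
        return cls(weights=w)

    @classmethod
    def load(cls, path: str | Path) -> "DecisionMatrix":
        return cls.from_frame(pd.read_csv(path))


def default_decision_matrix() -> DecisionMatrix:
    """Build the shipped qualitative default matrix."""
    w = np.zeros((len(QUADRANTS), len(FARM_TYPES), len(STYLES), N_ACTIONS))
    for qi, q in enumerate(QUADRANTS):
        base = _BASE_WEIGHTS[q]
        for ti in range(len(FARM_TYPES)):
            for si, s in enumerate(STYLES):
                v = base.copy()
                if q != "both_ok":
                    for k, m in _STYLE_TILTS[s].items():
                        v[k] *= m
                w[qi, ti, si] = v / v.sum()
    return DecisionMatrix(weights=w)


# ---------------------------------------------------------------------------
# rental market
# ---------------------------------------------------------------------------

@dataclass
class RentalMarket:
    """Pool of relinquished patches; unclaimed ones convert to forest."""

    region: RegionState
    afforestation_wait: int = 5
    pool: list[int] = field(default_factory=list)

    @classmethod
    def from_region(cls, region: RegionState, afforestation_wait: int) -> "RentalMarket":
        pool = list(np.flatnonzero(region.patches.holder == HOLDER_RENTAL))
        return cls(region=region, afforestation_wait=afforestation_wait, pool=pool)

    def release(self, patch_idx: int) -> None:
        p = self.region.patches
        p.holder[patch_idx] = HOLDER_RENTAL
        p.intensity[patch_idx] = 0
        p.years_on_market[patch_idx] = 0
        self.pool.append(patch_idx)

    def claim_random(self, rng: np.random.Generator) -> int | None:
        if not self.pool:
            return None
        j = int(rng.integers(len(self.pool)))
        return self.pool.pop(j)


def market_step(market: RentalMarket, region: RegionState, year: int) -> dict:
    """Age the rental pool; convert overdue patches to forest permanently."""
    p = region.patches
    afforested = []
    remaining = []
    for idx in market.pool:
        p.years_on_market[idx] += 1
        if p.years_on_market[idx] > market.afforestation_wait:
            p.holder[idx] = HOLDER_FOREST
            p.land_use[idx] = FOREST
            p.crop_cycle[idx] = CYCLE_NONE
            p.intensity[idx] = 0
            afforested.append(idx)
        else:
            remaining.append(idx)
    market.pool = remaining
    return {"year": year, "afforested": afforested, "pool_size": len(remaining)}


# ---------------------------------------------------------------------------
# probabilities and sampling
# ---------------------------------------------------------------------------

def possible_actions(
    farm_idx: int,
    region: RegionState,
    patch_idx: list[int],
    config: ScenarioConfig,
) -> np.ndarray:
    """Structural feasibility mask over the ten actions."""
    f = region.farms
    p = region.patches
    idx = np.asarray(patch_idx, dtype=int)
    inten = p.intensity[idx] if len(idx) else np.empty(0, dtype=np.int8)
    lu = p.land_use[idx] if len(idx) else np.empty(0, dtype=np.int8)
    mask = np.ones(N_ACTIONS, dtype=bool)
    mask[2] = bool(np.any((inten >= 1) & (inten <= 4)))  # intensify
    mask[3] = bool(np.any(inten >= 2))  # extensify
    if f.org_switch_used[farm_idx]:
        mask[4] = False
    elif f.production[farm_idx] == ORGANIC:
        mask[4] = bool(config.allow_org_to_conv)
    mask[5] = bool(np.any(lu == CROPLAND))  # land-use change
    mask[6] = bool(np.any(np.isin(lu, GRASSLAND_CODES)))  # afforest
    mask[8] = len(idx) >= 2  # reduction keeps at least one patch
    return mask


def action_probabilities(
    matrix: DecisionMatrix,
    farm_idx: int,
    region: RegionState,
    quadrant: int,
    patch_idx: list[int],
    config: ScenarioConfig,
    adaptation: AdaptationState | None = None,
    params: AdaptationParams | None = None,
) -> np.ndarray:
    """Final action probability vector for one farm in one year.

    Looks up the base vector, zeroes structurally impossible actions,
    applies the learning boost in adaptive runs, restricts persistently
    suffering farms to reduction/termination, and renormalizes.
    """
    f = region.farms
    if quadrant == QUADRANTS.index("both_ok"):
        out = np.zeros(N_ACTIONS)
        out[0] = 1.0
        return out
    base = matrix.vector(quadrant, int(f.farm_type[farm_idx]), int(f.style[farm_idx]))
    w = base * possible_actions(farm_idx, region, patch_idx, config)
    if config.adaptive and adaptation is not None:
        params = params or adaptation.params
        atype = int(params.style_code_types()[f.style[farm_idx]])
        w = boosted_weights(w, adaptation.alpha_by_type[atype])
    if f.suffer_counter[farm_idx] >= config.suffer_threshold:
        keep = np.zeros(N_ACTIONS, dtype=bool)
        keep[8] = len(patch_idx) >= 2
        keep[9] = True
        w = w * keep
        if w.sum() <= 0:
            w = keep.astype(float)
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        raise DecisionError(f"degenerate action vector for farm {farm_idx}")
    return w / total


def choose_action(probs: np.ndarray, rng: np.random.Generator) -> int:
    """Sample an action index (0-based) from a probability vector."""
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (N_ACTIONS,) or probs.sum() <= 0:
        raise DecisionError("invalid action probability vector")
    return int(rng.choice(N_ACTIONS, p=probs))


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------

def _modal_intensity(region: RegionState, patch_idx: list[int]) -> int:
    if not patch_idx:
        return 3
    vals = region.patches.intensity[np.asarray(patch_idx, dtype=int)]
    return int(np.bincount(vals, minlength=6)[1:].argmax()) + 1


def execute_action(
    farm_idx: int,
    action: int,
    region: RegionState,
    market: RentalMarket,
    rng: np.random.Generator,
    patch_idx: list[int],
    tables: EconomyTables,
    config: ScenarioConfig,
    income_ok: bool = True,
    year: int | None = None,
) -> dict:
    """Apply one action to the region state; returns an effect record.

    ``patch_idx`` (the farm's held patch indices) is updated in place so a
    later farm acting in the same year sees a consistent rental pool.
    """
    f = region.farms
    p = region.patches
    record = {"farm": farm_idx, "action": ACTIONS[action]}
    idx = np.asarray(patch_idx, dtype=int)

    if action == 0:  # nothing
        pass
    elif action == 1:  # hire one tenth of an fte
        f.hired_hours[farm_idx] += 180.0
    elif action == 2:  # intensification, whole farm, cap 5
        sel = idx[(p.intensity[idx] >= 1) & (p.intensity[idx] <= 4)]
        p.intensity[sel] += 1
        record["patches_changed"] = len(sel)
    elif action == 3:  # extensification, floor 1
        sel = idx[p.intensity[idx] >= 2]
        p.intensity[sel] -= 1
        record["patches_changed"] = len(sel)
    elif action == 4:  # production-system switch, once per farm
        if f.org_switch_used[farm_idx]:
            raise DecisionError("organic switch already used")
        new = ORGANIC if f.production[farm_idx] == CONVENTIONAL else CONVENTIONAL
        if new == CONVENTIONAL and not config.allow_org_to_conv:
            raise DecisionError("org->conv switch not allowed in this scenario")
        f.production[farm_idx] = new
        f.org_switch_used[farm_idx] = True
        record["production"] = ("conventional", "organic")[new]
    elif action == 5:  # land-use change between crop cycles
        target = (
            int(tables.cycle_margin_mult.argmax()) + 1
            if not income_ok
            else int(tables.cycle_labor_mult.argmin()) + 1
        )
        sel = idx[p.land_use[idx] == CROPLAND]
        p.crop_cycle[sel] = target
        record["cycle"] = target
        record["patches_changed"] = len(sel)
    elif action == 6:  # afforest one grassland patch
        grass = idx[np.isin(p.land_use[idx], GRASSLAND_CODES)]
        if len(grass) == 0:
            raise DecisionError("afforestation without grassland")
        chosen = int(grass[rng.integers(len(grass))])
        p.holder[chosen] = HOLDER_FOREST
        p.land_use[chosen] = FOREST
        p.intensity[chosen] = 0
        p.crop_cycle[chosen] = CYCLE_NONE
        patch_idx.remove(chosen)
        f.suffer_counter[farm_idx] = max(0, f.suffer_counter[farm_idx] - 1)
        record["patch"] = chosen
    elif action == 7:  # expansion from the rental market
        claimed = market.claim_random(rng)
        if claimed is None:
            record["claimed"] = None  # attempt recorded, pool empty
        else:
            p.holder[claimed] = farm_idx
            p.intensity[claimed] = _modal_intensity(region, patch_idx)
            p.years_on_market[claimed] = 0
            patch_idx.append(int(claimed))
            record["claimed"] = int(claimed)
    elif action == 8:  # reduction: dismiss workers, shed one patch
        f.hired_hours[farm_idx] = 0.0
        if len(idx) < 2:
            raise DecisionError("reduction requires at least two patches")
        chosen = int(idx[rng.integers(len(idx))])
        market.release(chosen)
        patch_idx.remove(chosen)
        record["patch"] = chosen
    elif action == 9:  # termination
        for pi in list(patch_idx):
            market.release(int(pi))
        patch_idx.clear()
        f.hired_hours[farm_idx] = 0.0
        f.active[farm_idx] = False
        f.death_year[farm_idx] = region.year if year is None else year
        f.death_reason[farm_idx] = 1
        record["released"] = len(idx)
    else:
        raise DecisionError(f"unknown action {action}")
    return record
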