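"""Synthetic region initializer.

Builds a 2015-style regional snapshot — farms, land parcels ("patches") and
livestock — whose aggregate structure matches the study region the model is
calibrated to: 2,990 farms cultivating 76,220 patches on 87,545 ha, three
broad farming types (cash crop, processing, cattle livestock), five farming
styles assigned uniformly at random, conventional/organic production with
five management-intensity levels, cropland in three rotation cycles and
grassland in meadow/pasture/mountain-pasture classes, with cattle herds
bound to grassland forage.

Farm sizes follow a log-normal distribution whose two parameters are fixed
analytically by the regional mean farm size (total area / farm count) and
the share of farms larger than 20 ha (44 %).  Patch areas are a Dirichlet
split of each farm's area, so per-farm patch-area sums reproduce the drawn
farm sizes exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .constants import (
    CATTLE_TYPES,
    CONVENTIONAL,
    CROP_CYCLES,
    CROPLAND,
    CYCLE_NONE,
    DEATH_REASONS,
    FARM_TYPES,
    GRASSLAND_CODES,
    HOLDER_FOREST,
    HOLDER_RENTAL,
    LAND_USES,
    ORGANIC,
    STYLES,
)


class RegionError(ValueError):
    """Raised for invalid synthesis parameters or corrupt snapshots."""


#: default initialization parameters of the synthetic region
DEFAULT_INIT: dict = {
    "n_farms": 2990,
    "n_patches": 76220,
    "total_area_ha": 87545.0,
    "share_gt_20ha": 0.44,
    "size_threshold_ha": 20.0,
    # farm-type shares (sum to 1); free parameters of the generator
    "farm_type_shares": {
        "cash_crop": 0.45,
        "processing_pig": 0.09,
        "processing_suckler": 0.06,
        "livestock_meat": 0.22,
        "livestock_milk": 0.18,
    },
    # probability that a patch of a farm of the given type is cropland
    "cropland_share_by_type": {
        "cash_crop": 0.95,
        "processing_pig": 0.70,
        "processing_suckler": 0.50,
        "livestock_meat": 0.20,
        "livestock_milk": 0.20,
    },
    "grassland_split": {"meadow": 0.50, "pasture": 0.35, "mountain_pasture": 0.15},
    "crop_cycle_shares": {"cr1": 1 / 3, "cr2": 1 / 3, "cr3": 1 / 3},
    "organic_share": 0.18,
    "intensity_choices": [2, 3, 4],
    # family labor endowment grows mildly with farm size
    "fte_base": 0.8,
    "fte_per_ha": 0.02,
    "fte_sd": 0.25,
    "fte_min": 0.5,
    "pig_lu_range": [20.0, 80.0],
    "forage_coefficient": 0.3,
    "dirichlet_concentration": 3.0,
    # degenerate symmetric mode: identical farm sizes / equal patch areas
    "equal_sizes": False,
    "equal_patch_areas": False,
}


@dataclass
class FarmTable:
    """Column-oriented table of farm agents."""

    farm_id: np.ndarray  # str
    farm_type: np.ndarray  # int8, index into FARM_TYPES
    style: np.ndarray  # int8, index into STYLES
    production: np.ndarray  # int8, 0 conventional / 1 organic
    org_switch_used: np.ndarray  # bool
    fte: np.ndarray  # float64, full-time worker equivalents
    hired_hours: np.ndarray  # float64
    cattle_lu: np.ndarray  # float64
    pig_lu: np.ndarray  # float64
    has_cattle: np.ndarray  # bool, herd recomputed from forage each year
    suffer_counter: np.ndarray  # int16
    active: np.ndarray  # bool
    death_year: np.ndarray  # int32, -1 = none
    death_reason: np.ndarray  # int8, index into DEATH_REASONS

    def __len__(self) -> int:
        return len(self.farm_id)

    def copy(self) -> "FarmTable":
        return FarmTable(**{k: v.copy() for k, v in self.__dict__.items()})


@dataclass
class PatchTable:
    """Column-oriented table of land parcels."""

    patch_id: np.ndarray  # str
    area_ha: np.ndarray  # float64
    land_use: np.ndarray  # int8, index into LAND_USES
    crop_cycle: np.ndarray  # int8, index into CROP_CYCLES
    intensity: np.ndarray  # int8, 0 for rental/forest, else 1..5
    holder: np.ndarray  # int32, farm index or HOLDER_RENTAL/HOLDER_FOREST
    years_on_market: np.ndarray  # int16

    def __len__(self) -> int:
        return len(self.patch_id)

    def copy(self) -> "PatchTable":
        return PatchTable(**{k: v.copy() for k, v in self.__dict__.items()})


@dataclass
class RegionState:
    """Full mutable state of the simulated region at one point in time."""

    year: int
    farms: FarmTable
    patches: PatchTable
    cumulative_events: int = 0
    init_params: dict = field(default_factory=dict)

    @property
    def total_area(self) -> float:
        return float(self.patches.area_ha.sum())

    def farm_sizes(self) -> np.ndarray:
        """Summed held patch area per farm (ha), zero for landless farms."""
        held = self.patches.holder >= 0
        return np.bincount(
            self.patches.holder[held],
            weights=self.patches.area_ha[held],
            minlength=len(self.farms),
        )

    def copy(self) -> "RegionState":
        return RegionState(
            year=self.year,
            farms=self.farms.copy(),
            patches=self.patches.copy(),
            cumulative_events=self.cumulative_events,
            init_params=dict(self.init_params),
        )

    def validate(self) -> None:
        p, f = self.patches, self.farms
        if np.any(p.area_ha <= 0):
            raise RegionError("patch areas must be positive")
        if np.any((p.holder >= len(f))):
            raise RegionError("patch holder references a missing farm")
        cropland = p.land_use == CROPLAND
        if np.any(cropland != (p.crop_cycle != CYCLE_NONE)):
            raise RegionError("crop_cycle must be set iff land use is cropland")
        pooled = p.holder < 0
        if np.any(p.intensity[pooled] != 0):
            raise RegionError("rental/forest patches must have intensity 0")
        if np.any(p.intensity[~pooled] < 1) or np.any(p.intensity > 5):
            raise RegionError("held patches must have intensity in 1..5")
        held_per_farm = np.bincount(
            p.holder[p.holder >= 0], minlength=len(f)
        )
        if np.any(held_per_farm[~f.active] > 0):
            raise RegionError("inactive farms must hold zero patches")


# ---------------------------------------------------------------------------
# synthesis
# ---------------------------------------------------------------------------

def solve_lognormal(mean_size: float, threshold: float, share_above: float):
    """Log-normal ``(mu, sigma)`` with given mean and P(size > threshold).

    With ``z`` the standard-normal quantile of ``1 - share_above`` the two
    constraints reduce to a quadratic in sigma; the positive root is
    returned.
    """
    z = norm.ppf(1.0 - share_above)
    disc = z * z - 2.0 * np.log(threshold / mean_size)
    if disc < 0:
        raise RegionError(
            f"no log-normal has mean {mean_size} and "
            f"P(>{threshold}) = {share_above}"
        )
    sigma = z + np.sqrt(disc)
    if sigma <= 0:
        raise RegionError("degenerate farm-size distribution (sigma <= 0)")
    mu = np.log(threshold) - z * sigma
    return mu, sigma


def _allocate_patch_counts(sizes: np.ndarray, n_patches: int) -> np.ndarray:
    """Integer patch counts per farm, proportional to size, each >= 1."""
    n_farms = len(sizes)
    if n_patches < n_farms:
        raise RegionError("patch count must be >= farm count")
    quota = sizes / sizes.sum() * (n_patches - n_farms)
    counts = np.floor(quota).astype(np.int64)
    remainder = n_patches - n_farms - counts.sum()
    order = np.argsort(quota - counts)[::-1]
    counts[order[:remainder]] += 1
    return counts + 1


def synthesize_region(
    init_params: dict | None = None, seed: int = 0, start_year: int = 2015
) -> RegionState:
    """Generate a synthetic regional snapshot; reproducible given ``seed``.

    ``init_params`` overrides entries of :data:`DEFAULT_INIT`.  Total area
    matches the requested total exactly (farm sizes are rescaled after
    sampling), every patch belongs to exactly one active farm, and cattle
    herds are computed from meadow/pasture forage
    (area x intensity x forage coefficient).
    """
    params = {**DEFAULT_INIT, **(init_params or {})}
    n_farms = int(params["n_farms"])
    n_patches = int(params["n_patches"])
    total = float(params["total_area_ha"])
    if n_farms < 1:
        raise RegionError("n_farms must be >= 1")
    if n_patches < n_farms:
        raise RegionError("patch count must be >= farm count")
    type_shares = params["farm_type_shares"]
    share_sum = sum(type_shares.values())
    if abs(share_sum - 1.0) > 1e-9:
        raise RegionError(f"farm_type_shares sum to {share_sum}, expected 1")

    rng = np.random.default_rng(np.random.SeedSequence(seed))

    # farm sizes: log-normal pinned to the regional mean and the >20 ha share
    if params["equal_sizes"]:
        sizes = np.full(n_farms, total / n_farms)
    else:
        mu, sigma = solve_lognormal(
            total / n_farms, params["size_threshold_ha"], params["share_gt_20ha"]
        )
        sizes = rng.lognormal(mu, sigma, n_farms)
        sizes *= total / sizes.sum()

    # farm attributes
    type_probs = np.array([type_shares[t] for t in FARM_TYPES])
    farm_type = rng.choice(len(FARM_TYPES), size=n_farms, p=type_probs).astype(np.int8)
    style = rng.integers(0, len(STYLES), n_farms).astype(np.int8)
    production = np.where(
        rng.random(n_farms) < params["organic_share"], ORGANIC, CONVENTIONAL
    ).astype(np.int8)
    intensity_farm = rng.choice(
        np.asarray(params["intensity_choices"], dtype=np.int8), size=n_farms
    )
    fte = np.maximum(
        params["fte_min"],
        params["fte_base"]
        + params["fte_per_ha"] * sizes
        + rng.normal(0.0, params["fte_sd"], n_farms),
    )

    # patches: counts proportional to size, Dirichlet area split within farms
    counts = _allocate_patch_counts(sizes, n_patches)
    holder = np.repeat(np.arange(n_farms, dtype=np.int32), counts)
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
    if params["equal_patch_areas"]:
        area = np.repeat(sizes / counts, counts)
    else:
        gamma = rng.gamma(params["dirichlet_concentration"], 1.0, n_patches)
        farm_gamma_sum = np.add.reduceat(gamma, offsets)
        area = gamma / np.repeat(farm_gamma_sum, counts) * np.repeat(sizes, counts)

    # land use: per-type cropland probability; first patch of a cash-crop
    # farm is forced to cropland so every cash-crop farm carries cropland
    p_crop = np.array([params["cropland_share_by_type"][t] for t in FARM_TYPES])
    is_crop = rng.random(n_patches) < p_crop[farm_type[holder]]
    cash_first = offsets[farm_type == 0]
    is_crop[cash_first] = True

    gs = params["grassland_split"]
    grass_probs = np.array([gs["meadow"], gs["pasture"], gs["mountain_pasture"]])
    grass_probs = grass_probs / grass_probs.sum()
    land_use = np.where(
        is_crop,
        CROPLAND,
        rng.choice(np.array(GRASSLAND_CODES, dtype=np.int8), n_patches, p=grass_probs),
    ).astype(np.int8)

    cs = params["crop_cycle_shares"]
    cyc_probs = np.array([cs["cr1"], cs["cr2"], cs["cr3"]])
    cyc_probs = cyc_probs / cyc_probs.sum()
    crop_cycle = np.where(
        is_crop, rng.choice(np.array([1, 2, 3], dtype=np.int8), n_patches, p=cyc_probs), 0
    ).astype(np.int8)

    intensity = intensity_farm[holder].astype(np.int8)

    # livestock: cattle from forage for cattle farm types, pigs assigned
    has_cattle = np.isin(farm_type, CATTLE_TYPES)
    forage_patch = np.isin(land_use, (1, 2)) * area * intensity
    forage_farm = np.bincount(holder, weights=forage_patch, minlength=n_farms)
    cattle_lu = np.where(has_cattle, forage_farm * params["forage_coefficient"], 0.0)
    lo, hi = params["pig_lu_range"]
    pig_lu = np.where(farm_type == 1, rng.uniform(lo, hi, n_farms), 0.0)

    width_f = len(str(n_farms))
    width_p = len(str(n_patches))
    farms = FarmTable(
        farm_id=np.array([f"F{i:0{width_f}d}" for i in range(n_farms)]),
        farm_type=farm_type,
        style=style,
        production=production,
        org_switch_used=np.zeros(n_farms, dtype=bool),
        fte=fte,
        hired_hours=np.zeros(n_farms),
        cattle_lu=cattle_lu,
        pig_lu=pig_lu,
        has_cattle=has_cattle,
        suffer_counter=np.zeros(n_farms, dtype=np.int16),
        active=np.ones(n_farms, dtype=bool),
        death_year=np.full(n_farms, -1, dtype=np.int32),
        death_reason=np.zeros(n_farms, dtype=np.int8),
    )
    patches = PatchTable(
        patch_id=np.array([f"P{i:0{width_p}d}" for i in range(n_patches)]),
        area_ha=area,
        land_use=land_use,
        crop_cycle=crop_cycle,
        intensity=intensity,
        holder=holder,
        years_on_market=np.zeros(n_patches, dtype=np.int16),
    )
    region = RegionState(
        year=start_year, farms=farms, patches=patches, init_params=params
    )
    region.validate()
    return region


# ---------------------------------------------------------------------------
# snapshot I/O (two flat CSV tables)
# ---------------------------------------------------------------------------

_FARM_COLUMNS = [
    "farm_id", "farm_type", "style", "production", "org_switch_used", "fte",
    "hired_hours", "cattle_lu", "pig_lu", "has_cattle", "suffer_counter",
    "active", "death_year", "death_reason",
]
_PATCH_COLUMNS = [
    "patch_id", "area_ha", "land_use", "crop_cycle", "intensity", "holder",
    "years_on_market",
]


def farms_frame(farms: FarmTable) -> pd.DataFrame:
    df = pd.DataFrame({c: getattr(farms, c) for c in _FARM_COLUMNS})
    df["farm_type"] = df["farm_type"].map(lambda i: FARM_TYPES[i])
    df["style"] = df["style"].map(lambda i: STYLES[i])
    df["production"] = df["production"].map(lambda i: ("conventional", "organic")[i])
    df["death_reason"] = df["death_reason"].map(lambda i: DEATH_REASONS[i])
    return df


def patches_frame(patches: PatchTable, farm_ids: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame({c: getattr(patches, c) for c in _PATCH_COLUMNS})
    df["land_use"] = df["land_use"].map(lambda i: LAND_USES[i])
    df["crop_cycle"] = df["crop_cycle"].map(lambda i: CROP_CYCLES[i])
    holder = np.where(
        patches.holder == HOLDER_RENTAL,
        "RENTAL",
        np.where(patches.holder == HOLDER_FOREST, "FOREST", farm_ids[
            np.clip(patches.holder, 0, None)
        ]),
    )
    df["holder"] = holder
    return df


def save_region(region: RegionState, path: str | Path) -> None:
    """Write the snapshot as ``farms.csv`` and ``patches.csv`` under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = pd.DataFrame(
        {"key": ["year", "cumulative_events"],
         "value": [region.year, region.cumulative_events]}
    )
    farms_frame(region.farms).to_csv(
        path / "farms.csv", index=False, float_format="%.17g"
    )
    patches_frame(region.patches, region.farms.farm_id).to_csv(
        path / "patches.csv", index=False, float_format="%.17g"
    )
    meta.to_csv(path / "meta.csv", index=False)


def load_region(path: str | Path) -> RegionState:
    """Load a snapshot written by :func:`save_region`; invariants are checked."""
    path = Path(path)
    for name in ("farms.csv", "patches.csv"):
        if not (path / name).exists():
            raise FileNotFoundError(path / name)
    fdf = pd.read_csv(path / "farms.csv", float_precision="round_trip")
    pdf = pd.read_csv(path / "patches.csv", float_precision="round_trip")
    missing = set(_FARM_COLUMNS) - set(fdf.columns)
    if missing:
        raise RegionError(f"farms.csv missing columns: {sorted(missing)}")
    missing = set(_PATCH_COLUMNS) - set(pdf.columns)
    if missing:
        raise RegionError(f"patches.csv missing columns: {sorted(missing)}")

    def _code(series, labels, what):
        lookup = {label: i for i, label in enumerate(labels)}
        bad = set(series) - set(lookup)
        if bad:
            raise RegionError(f"unknown {what} labels: {sorted(bad)}")
        return series.map(lookup).to_numpy()

    farms = FarmTable(
        farm_id=fdf["farm_id"].astype(str).to_numpy(),
        farm_type=_code(fdf["farm_type"], FARM_TYPES, "farm_type").astype(np.int8),
        style=_code(fdf["style"], STYLES, "style").astype(np.int8),
        production=_code(
            fdf["production"], ("conventional", "organic"), "production"
        ).astype(np.int8),
        org_switch_used=fdf["org_switch_used"].to_numpy(bool),
        fte=fdf["fte"].to_numpy(float),
        hired_hours=fdf["hired_hours"].to_numpy(float),
        cattle_lu=fdf["cattle_lu"].to_numpy(float),
        pig_lu=fdf["pig_lu"].to_numpy(float),
        has_cattle=fdf["has_cattle"].to_numpy(bool),
        suffer_counter=fdf["suffer_counter"].to_numpy(np.int16),
        active=fdf["active"].to_numpy(bool),
        death_year=fdf["death_year"].to_numpy(np.int32),
        death_reason=_code(fdf["death_reason"], DEATH_REASONS, "death_reason").astype(
            np.int8
        ),
    )
    id_to_idx = {fid: i for i, fid in enumerate(farms.farm_id)}
    holder_raw = pdf["holder"].astype(str)
    holder = np.empty(len(pdf), dtype=np.int32)
    for i, h in enumerate(holder_raw):
        if h == "RENTAL":
            holder[i] = HOLDER_RENTAL
        elif h == "FOREST":
            holder[i] = HOLDER_FOREST
        elif h in id_to_idx:
            holder[i] = id_to_idx[h]
        else:
            raise RegionError(f"patch {pdf['patch_id'][i]} references missing farm {h}")
    patches = PatchTable(
        patch_id=pdf["patch_id"].astype(str).to_numpy(),
        area_ha=pdf["area_ha"].to_numpy(float),
        land_use=_code(pdf["land_use"], LAND_USES, "land_use").astype(np.int8),
        crop_cycle=_code(pdf["crop_cycle"], CROP_CYCLES, "crop_cycle").astype(np.int8),
        intensity=pdf["intensity"].to_numpy(np.int8),
        holder=holder,
        years_on_market=pdf["years_on_market"].to_numpy(np.int16),
    )
    meta_path = path / "meta.csv"
    year, cum = 2015, 0
    if meta_path.exists():
        meta = pd.read_csv(meta_path).set_index("key")["value"]
        year = int(meta.get("year", 2015))
        cum = int(meta.get("cumulative_events", 0))
    region = RegionState(year=year, farms=farms, patches=patches, cumulative_events=cum)
    region.validate()
    return region
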