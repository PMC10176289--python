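import numpy as np
import pytest

from farmabm.constants import (
    CROP_CYCLES,
    DEATH_REASONS,
    FARM_TYPES,
    LAND_USES,
    PRODUCTIONS,
    STYLES,
)
from farmabm.region import FarmTable, PatchTable, RegionState

#: small synthetic-region parameters used across the suite; the >20 ha share
#: is lowered because a 15 ha mean farm cannot have 44 % of farms above 20 ha
TOY_INIT = {
    "n_farms": 200,
    "n_patches": 1600,
    "total_area_ha": 5000.0,
    "share_gt_20ha": 0.44,
}


def build_region(farm_specs, patch_specs, year=2015):
    """Construct a region from plain dicts; unspecified fields get defaults.

    Farm keys: farm_type, style, production, fte, hired_hours, pig_lu,
    has_cattle, suffer_counter, org_switch_used.  Patch keys: area,
    land_use, crop_cycle, intensity, holder (farm index, or "RENTAL"/"FOREST").
    """
    n = len(farm_specs)
    farms = FarmTable(
        farm_id=np.array([f"F{i}" for i in range(n)]),
        farm_type=np.array(
            [FARM_TYPES.index(s.get("farm_type", "cash_crop")) for s in farm_specs],
            dtype=np.int8,
        ),
        style=np.array(
            [STYLES.index(s.get("style", "innovative")) for s in farm_specs],
            dtype=np.int8,
        ),
        production=np.array(
            [PRODUCTIONS.index(s.get("production", "conventional")) for s in farm_specs],
            dtype=np.int8,
        ),
        org_switch_used=np.array(
            [s.get("org_switch_used", False) for s in farm_specs], dtype=bool
        ),
        fte=np.array([s.get("fte", 1.0) for s in farm_specs], dtype=float),
        hired_hours=np.array([s.get("hired_hours", 0.0) for s in farm_specs]),
        cattle_lu=np.zeros(n),
        pig_lu=np.array([s.get("pig_lu", 0.0) for s in farm_specs], dtype=float),
        has_cattle=np.array([s.get("has_cattle", False) for s in farm_specs], dtype=bool),
        suffer_counter=np.array(
            [s.get("suffer_counter", 0) for s in farm_specs], dtype=np.int16
        ),
        active=np.array([s.get("active", True) for s in farm_specs], dtype=bool),
        death_year=np.full(n, -1, dtype=np.int32),
        death_reason=np.zeros(n, dtype=np.int8),
    )
    m = len(patch_specs)
    holder = np.array(
        [
            {"RENTAL": -1, "FOREST": -2}.get(s.get("holder", 0), s.get("holder", 0))
            for s in patch_specs
        ],
        dtype=np.int32,
    )
    patches = PatchTable(
        patch_id=np.array([f"P{i}" for i in range(m)]),
        area_ha=np.array([s.get("area", 1.0) for s in patch_specs], dtype=float),
        land_use=np.array(
            [LAND_USES.index(s.get("land_use", "cropland")) for s in patch_specs],
            dtype=np.int8,
        ),
        crop_cycle=np.array(
            [CROP_CYCLES.index(s.get("crop_cycle", "cr1")) for s in patch_specs],
            dtype=np.int8,
        ),
        intensity=np.array(
            [s.get("intensity", 3) for s in patch_specs], dtype=np.int8
        ),
        holder=holder,
        years_on_market=np.array(
            [s.get("years_on_market", 0) for s in patch_specs], dtype=np.int16
        ),
    )
    return RegionState(year=year, farms=farms, patches=patches)


def one_patch_farm_region(margin_tables=False):
    """One 1-ha conventional cropland farm at intensity 3 with 1 fte."""
    return build_region(
        [{"farm_type": "cash_crop", "fte": 1.0}],
        [{"area": 1.0, "land_use": "cropland", "crop_cycle": "cr1", "intensity": 3}],
    )


@pytest.fixture(scope="session")
def toy_region():
    from farmabm import synthesize_region

    return synthesize_region(TOY_INIT, seed=3)


@pytest.fixture(scope="session")
def default_region():
    from farmabm import synthesize_region

    return synthesize_region(seed=1)
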