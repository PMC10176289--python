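"""Categorical codes shared across the model.

All agent and parcel attributes are stored as small integer codes in
column-oriented arrays; the tuples below fix the code -> label mapping used
for configuration files and CSV snapshots.
"""

from __future__ import annotations

# Land-use classes of a parcel. The rental pool is a *holder* state, not a
# land-use class: a pooled parcel keeps its agronomic class until it is
# either claimed or converts to forest.
LAND_USES = ("cropland", "meadow", "pasture", "mountain_pasture", "forest")
CROPLAND = 0
MEADOW = 1
PASTURE = 2
MOUNTAIN_PASTURE = 3
FOREST = 4
GRASSLAND_CODES = (MEADOW, PASTURE, MOUNTAIN_PASTURE)
#: land-use classes that carry an economic table entry (forest does not)
AGRI_LAND_USES = ("cropland", "meadow", "pasture", "mountain_pasture")

# Crop rotation cycles of cropland; 0 = not cropland.
CROP_CYCLES = ("none", "cr1", "cr2", "cr3")
CYCLE_NONE = 0

PRODUCTIONS = ("conventional", "organic")
CONVENTIONAL = 0
ORGANIC = 1

FARM_TYPES = (
    "cash_crop",
    "processing_pig",
    "processing_suckler",
    "livestock_meat",
    "livestock_milk",
)
#: farm types whose cattle herd is recomputed from grassland forage
CATTLE_TYPES = (2, 3, 4)

STYLES = (
    "innovative",
    "yield_optimizer",
    "support_optimizer",
    "idealist",
    "traditionalist",
)

# Ten possible annual actions, indexed 0..9 internally (Act1..Act10).
ACTIONS = (
    "act1_nothing",
    "act2_hire",
    "act3_intensify",
    "act4_extensify",
    "act5_organic",
    "act6_landuse_change",
    "act7_afforest",
    "act8_expand",
    "act9_reduce",
    "act10_terminate",
)
N_ACTIONS = 10
#: 0-based indices of the four adaptation-sensitive actions
#: (extensification, organic conversion, land-use change, expansion)
ADAPTIVE_ACTIONS = (3, 4, 5, 7)

QUADRANTS = ("both_ok", "income_only", "workload_only", "neither")

# Holder sentinels in the patch table.
HOLDER_RENTAL = -1
HOLDER_FOREST = -2

#: annual working hours of one full-time worker equivalent
FTE_HOURS = 1800.0

DEATH_REASONS = ("none", "termination")
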