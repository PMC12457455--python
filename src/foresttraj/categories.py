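"""IPCC land categories used throughout the pipeline.

Annual land-cover maps are reclassified to eight aggregated IPCC-style
categories before any change detection, because categorical change in the
source product is only considered reliable at this level of aggregation.
Sparse vegetation is folded into ``bare``.
"""

from __future__ import annotations

# Fixed category order; integer codes are 1-based positions in this tuple.
# The order also serves as the deterministic tie-break order for dominant
# transitions.
CATEGORY_ORDER = (
    "cropland",
    "forest",
    "grassland",
    "wetland",
    "settlement",
    "shrubland",
    "bare",
    "water",
)

CATEGORY_CODES = {name: i + 1 for i, name in enumerate(CATEGORY_ORDER)}
CODE_NAMES = {code: name for name, code in CATEGORY_CODES.items()}

CROPLAND = CATEGORY_CODES["cropland"]
FOREST = CATEGORY_CODES["forest"]
GRASSLAND = CATEGORY_CODES["grassland"]
WETLAND = CATEGORY_CODES["wetland"]
SETTLEMENT = CATEGORY_CODES["settlement"]
SHRUBLAND = CATEGORY_CODES["shrubland"]
BARE = CATEGORY_CODES["bare"]
WATER = CATEGORY_CODES["water"]

#: Default mapping from the 22-class CCI-LC legend to the 8 IPCC categories,
#: following the CCI user-guide aggregation; sparse vegetation (140-153) and
#: permanent snow/ice (220) are mapped to ``bare``.  Fully overridable.
DEFAULT_CCI_RECLASS = {
    10: CROPLAND, 11: CROPLAND, 12: CROPLAND, 20: CROPLAND,
    30: CROPLAND, 40: CROPLAND,
    50: FOREST, 60: FOREST, 61: FOREST, 62: FOREST,
    70: FOREST, 71: FOREST, 72: FOREST,
    80: FOREST, 81: FOREST, 82: FOREST,
    90: FOREST, 100: FOREST, 160: FOREST, 170: FOREST,
    110: GRASSLAND, 130: GRASSLAND,
    120: SHRUBLAND, 121: SHRUBLAND, 122: SHRUBLAND,
    140: BARE, 150: BARE, 151: BARE, 152: BARE, 153: BARE,
    180: WETLAND,
    190: SETTLEMENT,
    200: BARE, 201: BARE, 202: BARE, 220: BARE,
    210: WATER,
}
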