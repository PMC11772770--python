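# Mapping from IAM (GCAM-style) land types to the four land-system services,
# plus the excluded types treated as unchanging. Lookup is case-insensitive.
services:
  cropland:
    - Corn
    - Fibre crop
    - Fodder grass
    - Fodder herb
    - Misc crop
    - Oil crop
    - Palm fruit
    - Rice
    - Root tuber
    - Sugar crop
    - Wheat
    - Biomass grass
    - Biomass tree
    - Other grain
    - Other arable land
  forest:
    - Unmanaged forest
    - Protected unmanaged forest
    - Forest
  grassland:
    - Unmanaged pasture
    - Protected grassland
    - Protected unmanaged pasture
    - Pasture
    - Grassland
  shrubland:
    - Protected shrubland
    - Shrubland
excluded:
  - Tundra
  - Urban
  - Rocky
  - Rock and desert
  - Snow or ice
  - Desert
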