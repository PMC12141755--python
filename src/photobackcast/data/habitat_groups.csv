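species,group
Canada Jay,coniferous forest
Golden-crowned Kinglet,coniferous forest
Ruby-crowned Kinglet,coniferous forest
Hermit Thrush,coniferous forest
Pine Siskin,coniferous forest
Dark-eyed Junco,coniferous forest
Yellow-rumped Warbler,coniferous forest
Swainson's Thrush,coniferous forest
Varied Thrush,coniferous forest
American Robin,generalist
American Pipit,alpine tundra
Golden-crowned Sparrow,alpine shrub
Chipping Sparrow,open woodland
Savannah Sparrow,grassland
Wilson's Warbler,shrub/wetland
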