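{
  "description": "Neuropil volumes (µm³) of the Bombus terrestris standard brain atlas (shape-based average of ten worker brains, 3.9 µm isotropic voxels), with the group membership table for composite structures.",
  "voxel_size_um": 3.9,
  "standard_brain_volumes_um3": {
    "RN": 2.31e8,
    "OC": 2.40e7,
    "AOTu-r": 1.93e6,
    "AOTu-l": 1.92e6,
    "AL-r": 1.67e7,
    "AL-l": 1.71e7,
    "PB": 3.50e5,
    "CBU": 2.71e6,
    "CBL": 6.61e5,
    "NO": 1.89e5,
    "LA-r": 2.48e7,
    "LA-l": 2.44e7,
    "ME-l": 6.86e7,
    "ME-r": 6.75e7,
    "LO-r": 2.21e7,
    "LO-l": 2.27e7,
    "LCO-l": 1.56e7,
    "LCO-r": 1.61e7,
    "MCO-r": 1.25e7,
    "MCO-l": 1.28e7,
    "LBR-r": 2.88e6,
    "LBR-l": 2.96e6,
    "MBR-r": 2.76e6,
    "MBR-l": 2.47e6,
    "PED_LOB-l": 2.62e7,
    "PED_LOB-r": 2.57e7,
    "LLIP-r": 4.70e6,
    "LLIP-l": 5.78e6,
    "MLIP-r": 5.36e6,
    "MLIP-l": 5.89e6
  },
  "groups": {
    "CX": ["PB", "CBU", "CBL", "NO"],
    "OL": ["LA-r", "LA-l", "ME-l", "ME-r", "LO-r", "LO-l"],
    "MB": ["LCO-l", "LCO-r", "MCO-r", "MCO-l", "LBR-r", "LBR-l", "MBR-r", "MBR-l", "PED_LOB-l", "PED_LOB-r", "LLIP-r", "LLIP-l", "MLIP-r", "MLIP-l"]
  },
  "exclude_for_comparison": ["LA-l", "LA-r", "OC"]
}
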