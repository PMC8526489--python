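{
  "description": "Voxel counts and voxel sizes (x, y, z) of published hymenopteran standard brain models, measured as absolute extent of the image data.",
  "atlases": [
    {"name": "Apis mellifera", "voxel_counts": [471, 269, 83], "voxel_size_um": [3.9, 3.9, 8.1]},
    {"name": "Nasonia vitripennis", "voxel_counts": [1362, 796, 134], "voxel_size_um": [0.45, 0.45, 1.9]},
    {"name": "Bombus terrestris (without OC, LA)", "voxel_counts": [602, 353, 191], "voxel_size_um": [3.9, 3.9, 3.9]},
    {"name": "Bombus terrestris (including OC, LA)", "voxel_counts": [704, 452, 191], "voxel_size_um": [3.9, 3.9, 3.9]}
  ]
}
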