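"""Compartment volumes and cross-sectional areas from a label mask."""

from myorelax import (
    build_labelmap, compartment_volume, cross_sectional_area, study,
)

labelmap = build_labelmap(
    study.default_phantom(lesion_fraction=0.1, seed=3)
)
for code in (1, 2, 3, 4):
    v = compartment_volume(labelmap, code, include_children=False)
    print(f"{labelmap.code_table[code]:10s}: {v:8.2f} mm^3")
mid = labelmap.shape[0] // 2
csa = cross_sectional_area(labelmap, 2, mid, include_children=False)
print(f"posterior CSA at mid-slice {mid}: {csa:.2f} mm^2")
# Volumes are voxel counts times the voxel volume (here 1.0 x 0.2 x 0.2 mm);
# lesion voxels are reported separately because they replace muscle.
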