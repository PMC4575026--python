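"""Compartment volumetry from label masks.

Volumes count voxel centres (no partial-volume weighting), matching how a
manually outlined mask is tallied. Child codes — e.g. lesions embedded in a
muscle compartment — can be folded into their parent compartment via the
label map's ``parents`` mapping.
"""

from __future__ import annotations

import numpy as np

from .images import LabelMap

__all__ = ["compartment_volume", "cross_sectional_area"]


def _codes_for(mask: LabelMap, label: int, include_children: bool) -> list[int]:
    if label not in mask.code_table:
        raise KeyError(f"label {label} not in code table {sorted(mask.code_table)}")
    codes = [label]
    if include_children:
        codes += [child for child, parent in mask.parents.items() if parent == label]
    return codes


def compartment_volume(
    mask: LabelMap, label: int, include_children: bool = True
) -> float:
    """Volume (mm^3) of one labelled compartment.

    Counts voxels carrying ``label`` (plus any codes whose parent is
    ``label`` when ``include_children``) times the voxel volume.
    """
    codes = _codes_for(mask, label, include_children)
    return int(mask.mask_of(codes).sum()) * mask.voxel_volume_mm3


def cross_sectional_area(
    mask: LabelMap, label: int, slice_index: int, include_children: bool = True
) -> float:
    """In-plane area (mm^2) of a compartment on one axial slice."""
    n = mask.shape[mask.slice_axis]
    if not 0 <= slice_index < n:
        raise IndexError(f"slice {slice_index} out of range for {n} slices")
    codes = _codes_for(mask, label, include_children)
    plane = np.take(mask.labels, slice_index, axis=mask.slice_axis)
    in_plane_sizes = [
        v for ax, v in enumerate(mask.voxel_size) if ax != mask.slice_axis
    ]
    pixel_area = float(np.prod(in_plane_sizes))
    return int(np.isin(plane, codes).sum()) * pixel_area
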