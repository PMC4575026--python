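"""Shared in-memory image containers.

All image-like data live on a common 3D voxel grid. By convention axis 0 is
the slice (axial) axis unless a container says otherwise; voxel sizes are in
millimetres, ordered like the array axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LabelMap", "DualEchoVolume", "T2Map"]


@dataclass
class LabelMap:
    """Integer segmentation sharing the image grid.

    Code 0 is reserved for background. ``code_table`` maps each positive code
    to a human-readable name; ``parents`` optionally maps a child code (e.g. a
    lesion) to the compartment code whose volume it should count toward.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    slice_axis: int = 0
    code_table: dict[int, str] = field(default_factory=dict)
    parents: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.min() < 0:
            raise ValueError("label codes must be non-negative")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive lengths (mm)")
        if not 0 <= self.slice_axis < 3:
            raise ValueError("slice_axis must index one of the three axes")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def mask_of(self, labels) -> np.ndarray:
        """Boolean mask of voxels whose code is in ``labels``."""
        return np.isin(self.labels, np.atleast_1d(list(labels)))


@dataclass
class DualEchoVolume:
    """Paired magnitude volumes acquired at two echo times on one grid."""

    si_te1: np.ndarray
    si_te2: np.ndarray
    te1: float
    te2: float
    voxel_size: tuple[float, float, float]
    slice_axis: int = 0

    def __post_init__(self) -> None:
        self.si_te1 = np.asarray(self.si_te1, dtype=float)
        self.si_te2 = np.asarray(self.si_te2, dtype=float)
        if self.si_te1.shape != self.si_te2.shape:
            raise ValueError("echo volumes must share a grid")
        if not (0 < self.te1 < self.te2):
            raise ValueError("echo times must satisfy te2 > te1 > 0")
        if self.si_te1.min() < 0 or self.si_te2.min() < 0:
            raise ValueError("magnitude images are non-negative")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.si_te1.shape

    @property
    def te_delta(self) -> float:
        return self.te2 - self.te1


@dataclass
class T2Map:
    """Per-pixel transverse relaxation time in ms with a validity mask.

    ``t2`` holds NaN wherever ``valid`` is False; valid pixels are finite and
    strictly positive.
    """

    t2: np.ndarray
    valid: np.ndarray
    te_delta: float
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    slice_axis: int = 0

    def __post_init__(self) -> None:
        self.t2 = np.asarray(self.t2, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.t2.shape != self.valid.shape:
            raise ValueError("t2 and valid must share a shape")
        vals = self.t2[self.valid]
        if vals.size and not (np.all(np.isfinite(vals)) and np.all(vals > 0)):
            raise ValueError("valid pixels must carry finite positive T2")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.t2.shape
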