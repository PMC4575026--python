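"""Synthetic murine-hindlimb MR phantom.

Generates dual-echo spin-echo image volumes, single-voxel STEAM decays and
whole-cohort tables with known ground truth, so every downstream stage of
the pipeline (T2 mapping, hyperintense-pixel classification, volumetry,
relaxometry, group statistics) can be tested without scanner data.

Signal model: per-voxel spin-echo magnitude S(TE) = PD * exp(-TE/T2), with
T1 weighting ignored (TR treated as >> T1, consistent with a pure
mono-exponential TE dependence). Noise is Rician: independent Gaussian noise
of a common sigma on each quadrature before taking the magnitude, with sigma
anchored so the muscle-ROI SNR at the first echo matches ``snr_te14``
(33:1 in the emulated acquisition).

Geometry is deliberately simple — stacked elliptical anterior/posterior
muscle compartments with a bone core across axial 1 mm slices. Lesions
(hyperintense, long-T2 tissue) replace a requested fraction of muscle
voxels, either scattered voxel-wise or grown as clusters from random seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import DualEchoVolume, LabelMap
from .relaxometry import DecayCurve

__all__ = [
    "TissueSpec",
    "AcquisitionSpec",
    "EllipseRegion",
    "PhantomSpec",
    "CohortSpec",
    "AnimalPhantom",
    "GeometryError",
    "LABEL_BACKGROUND",
    "LABEL_ANTERIOR",
    "LABEL_POSTERIOR",
    "LABEL_LESION",
    "LABEL_BONE",
    "MUSCLE_LABELS",
    "CODE_TABLE",
    "build_labelmap",
    "simulate_dual_echo",
    "simulate_steam_decay",
    "simulate_cohort",
]

LABEL_BACKGROUND = 0
LABEL_ANTERIOR = 1
LABEL_POSTERIOR = 2
LABEL_LESION = 3
LABEL_BONE = 4
MUSCLE_LABELS = (LABEL_ANTERIOR, LABEL_POSTERIOR)

CODE_TABLE = {
    LABEL_BACKGROUND: "background",
    LABEL_ANTERIOR: "anterior",
    LABEL_POSTERIOR: "posterior",
    LABEL_LESION: "lesion",
    LABEL_BONE: "bone",
}


class GeometryError(ValueError):
    """Compartment regions overlap or exceed the grid."""


@dataclass(frozen=True)
class TissueSpec:
    """One tissue class: relative proton density and T2 in ms."""

    label: int
    name: str
    proton_density: float
    t2: float
    volume_fraction_hint: float = 0.0

    def __post_init__(self) -> None:
        if self.t2 <= 0:
            raise ValueError(f"{self.name}: t2 must be > 0")
        if self.proton_density < 0:
            raise ValueError(f"{self.name}: proton density must be >= 0")
        if not 0 <= self.volume_fraction_hint <= 1:
            raise ValueError("volume_fraction_hint must lie in [0, 1]")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Pulse-sequence timing and geometry parameters.

    ``fov`` and ``matrix`` share a length (2 for multislice imaging plus
    ``slice_thickness``, 3 for a true 3D acquisition); the voxel size is
    fov/matrix per axis.
    """

    te_list: tuple[float, ...]
    tr: float
    fov: tuple[float, ...]
    matrix: tuple[int, ...]
    slice_thickness: float | None = None
    tm: float | None = None
    flip_angle: float | None = None
    n_averages: int = 1

    def __post_init__(self) -> None:
        te = np.asarray(self.te_list, dtype=float)
        if te.size == 0 or np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError("te_list must be positive and strictly increasing")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if len(self.fov) != len(self.matrix):
            raise ValueError("fov and matrix must have the same length")
        if any(f <= 0 for f in self.fov) or any(m <= 0 for m in self.matrix):
            raise ValueError("geometry must be strictly positive")
        if len(self.fov) == 2 and (
            self.slice_thickness is None or self.slice_thickness <= 0
        ):
            raise ValueError("2D acquisitions need a positive slice_thickness")

    @property
    def in_plane_voxel_mm(self) -> tuple[float, ...]:
        return tuple(f / m for f, m in zip(self.fov, self.matrix))

    def voxel_size(self) -> tuple[float, float, float]:
        """(slice, row, col) voxel size in mm."""
        if len(self.fov) == 3:
            vx = self.in_plane_voxel_mm
            return (vx[2], vx[0], vx[1])  # third axis as slice direction
        r, c = self.in_plane_voxel_mm
        return (float(self.slice_thickness), r, c)


@dataclass(frozen=True)
class EllipseRegion:
    """In-plane ellipse, replicated across all slices (a stacked cylinder)."""

    label: int
    center: tuple[float, float]  # (row, col) in voxels
    semi_axes: tuple[float, float]  # (row, col) in voxels

    def mask(self, plane_shape: tuple[int, int]) -> np.ndarray:
        cy, cx = self.center
        a, b = self.semi_axes
        yy, xx = np.mgrid[: plane_shape[0], : plane_shape[1]]
        return ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0


def _default_compartments() -> tuple[EllipseRegion, ...]:
    return (
        EllipseRegion(LABEL_ANTERIOR, center=(17.0, 32.0), semi_axes=(9.0, 16.0)),
        EllipseRegion(LABEL_POSTERIOR, center=(45.0, 32.0), semi_axes=(11.0, 18.0)),
        EllipseRegion(LABEL_BONE, center=(30.0, 32.0), semi_axes=(3.0, 3.0)),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Complete description of one synthetic hindlimb.

    ``lesion_fraction`` is the fraction of muscle voxels replaced by lesion
    tissue; ``snr_te14`` anchors the Rician noise level (0 or inf means
    noise-free); a fixed ``seed`` makes the phantom bit-reproducible.
    """

    grid: tuple[int, int, int] = (10, 64, 64)
    voxel_size: tuple[float, float, float] = (1.0, 0.2, 0.2)
    compartments: tuple[EllipseRegion, ...] = field(
        default_factory=_default_compartments
    )
    tissues: tuple[TissueSpec, ...] = ()
    lesion_fraction: float = 0.0
    snr_te14: float = np.inf
    seed: int = 0
    lesion_cluster_radius: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.lesion_fraction <= 1:
            raise ValueError("lesion_fraction must lie in [0, 1]")
        labels = [t.label for t in self.tissues]
        if len(labels) != len(set(labels)):
            raise ValueError("tissue labels must be unique within a phantom")
        if self.snr_te14 < 0:
            raise ValueError("snr_te14 must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """Group-level distributions every per-animal scalar is drawn from."""

    group: str
    n: int
    weight_mean: float
    weight_sd: float
    muscle_t2_mean: float
    muscle_t2_sd: float
    lesion_fraction_mean: float
    mac1_mean: float
    mac1_sd: float
    ct_params: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        sds = [self.weight_sd, self.muscle_t2_sd, self.mac1_sd] + [
            sd for _, sd in self.ct_params.values()
        ]
        if any(sd < 0 for sd in sds):
            raise ValueError("all SDs must be >= 0")


@dataclass
class AnimalPhantom:
    """One simulated animal: images plus its ground-truth scalars."""

    animal: str
    group: str
    labelmap: LabelMap
    dual_echo: DualEchoVolume
    truth: dict


def build_labelmap(spec: PhantomSpec) -> LabelMap:
    """Rasterise the phantom geometry and place lesions inside muscle.

    The achieved lesion voxel count is round(lesion_fraction * n_muscle),
    i.e. exact to within one voxel of rounding. With
    ``lesion_cluster_radius > 0`` lesions grow as dilated clusters around
    random seed voxels instead of being scattered voxel-wise.
    """
    ns, ny, nx = spec.grid
    plane = np.zeros((ny, nx), dtype=np.int16)
    for region in spec.compartments:
        m = region.mask((ny, nx))
        cy, cx = region.center
        a, b = region.semi_axes
        if cy - a < 0 or cy + a > ny - 1 or cx - b < 0 or cx + b > nx - 1:
            raise GeometryError(f"region {region.label} exceeds the grid")
        if np.any(plane[m] != 0):
            raise GeometryError(f"region {region.label} overlaps another region")
        plane[m] = region.label
    labels = np.repeat(plane[None, :, :], ns, axis=0).copy()

    rng = np.random.default_rng(spec.seed)
    muscle = np.isin(labels, MUSCLE_LABELS)
    n_muscle = int(muscle.sum())
    n_lesion = int(round(spec.lesion_fraction * n_muscle))
    if n_lesion > 0:
        flat_idx = np.flatnonzero(muscle.ravel())
        if spec.lesion_cluster_radius > 0:
            chosen = _clustered_lesions(
                muscle, n_lesion, spec.lesion_cluster_radius, rng
            )
        else:
            chosen = rng.choice(flat_idx, size=n_lesion, replace=False)
        np.put(labels, chosen, LABEL_LESION)

    return LabelMap(
        labels=labels,
        voxel_size=spec.voxel_size,
        slice_axis=0,
        code_table=dict(CODE_TABLE),
    )


def _clustered_lesions(
    muscle: np.ndarray, n_lesion: int, radius: int, rng: np.random.Generator
) -> np.ndarray:
    """Grow lesion clusters from random seeds; exact count via trim/top-up."""
    flat_idx = np.flatnonzero(muscle.ravel())
    ball_vox = max(1, int(4 / 3 * np.pi * radius**3))
    n_seeds = max(1, n_lesion // ball_vox)
    seeds = rng.choice(flat_idx, size=n_seeds, replace=False)
    seed_mask = np.zeros(muscle.shape, dtype=bool)
    np.put(seed_mask, seeds, True)
    grown = seed_mask
    while grown.sum() < n_lesion:
        bigger = ndimage.binary_dilation(grown) & muscle
        if bigger.sum() == grown.sum():  # muscle exhausted
            break
        grown = bigger
    chosen = np.flatnonzero(grown.ravel())
    if chosen.size > n_lesion:
        chosen = rng.choice(chosen, size=n_lesion, replace=False)
    elif chosen.size < n_lesion:
        rest = np.setdiff1d(flat_idx, chosen)
        extra = rng.choice(rest, size=n_lesion - chosen.size, replace=False)
        chosen = np.concatenate([chosen, extra])
    return chosen


def simulate_dual_echo(
    labelmap: LabelMap,
    tissues: Sequence[TissueSpec],
    acq: AcquisitionSpec,
    snr_te14: float = np.inf,
    seed: int = 0,
    muscle_labels: Sequence[int] = MUSCLE_LABELS,
) -> DualEchoVolume:
    """Simulate paired spin-echo magnitude volumes at two echo times.

    Noise-free signal per voxel is PD * exp(-TE/T2) of the voxel's tissue;
    background (label 0) carries zero signal. Rician noise is added so that
    mean muscle signal / sigma at the first echo equals ``snr_te14``;
    ``snr_te14`` of 0 or inf yields noise-free images.
    """
    if len(acq.te_list) != 2:
        raise ValueError("dual-echo simulation needs exactly two echo times")
    te1, te2 = acq.te_list
    tissue_by_label = {t.label: t for t in tissues}
    present = np.unique(labelmap.labels)
    missing = [int(l) for l in present if l != 0 and l not in tissue_by_label]
    if missing:
        raise KeyError(f"labels without a TissueSpec: {missing}")

    max_label = int(present.max()) if present.size else 0
    pd_lut = np.zeros(max_label + 1)
    r2_lut = np.zeros(max_label + 1)  # 1/T2; background stays 0
    for lbl in present:
        if lbl == 0:
            continue
        t = tissue_by_label[int(lbl)]
        pd_lut[lbl] = t.proton_density
        r2_lut[lbl] = 1.0 / t.t2

    s1 = pd_lut[labelmap.labels] * np.exp(-te1 * r2_lut[labelmap.labels])
    s2 = pd_lut[labelmap.labels] * np.exp(-te2 * r2_lut[labelmap.labels])
    s1[labelmap.labels == 0] = 0.0
    s2[labelmap.labels == 0] = 0.0

    if snr_te14 not in (0, np.inf):
        muscle = labelmap.mask_of(muscle_labels)
        if not muscle.any():
            raise ValueError("no muscle voxels to anchor the SNR")
        sigma = float(s1[muscle].mean()) / snr_te14
        rng = np.random.default_rng(seed)
        for arr in (s1, s2):
            re = arr + rng.normal(0.0, sigma, arr.shape)
            im = rng.normal(0.0, sigma, arr.shape)
            arr[...] = np.hypot(re, im)

    return DualEchoVolume(
        si_te1=s1,
        si_te2=s2,
        te1=float(te1),
        te2=float(te2),
        voxel_size=labelmap.voxel_size,
        slice_axis=labelmap.slice_axis,
    )


def simulate_steam_decay(
    components: Sequence[tuple[float, float]],
    acq: AcquisitionSpec,
    noise_sd: float = 0.0,
    seed: int = 0,
    phase: float = 0.0,
) -> DecayCurve:
    """Multi-exponential single-voxel decay with complex Gaussian noise.

    signal(TE) = sum_i a_i * exp(-TE/T2_i), rotated by a global ``phase``
    (radians), with independent Gaussian noise of sd ``noise_sd`` added to
    each quadrature. The voxel is treated as a single well-mixed source.
    """
    if len(components) == 0:
        raise ValueError("need at least one (amplitude, t2) component")
    amps = np.asarray([a for a, _ in components], dtype=float)
    t2s = np.asarray([t for _, t in components], dtype=float)
    if np.any(amps < 0) or np.any(t2s <= 0):
        raise ValueError("amplitudes must be >= 0 and t2 > 0")
    te = np.asarray(acq.te_list, dtype=float)
    clean = (amps[None, :] * np.exp(-te[:, None] / t2s[None, :])).sum(axis=1)
    signal = clean.astype(complex) * np.exp(1j * phase)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0, noise_sd, te.size) + 1j * rng.normal(
            0, noise_sd, te.size
        )
    return DecayCurve(te=te, signal=signal)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size=None
) -> np.ndarray | float:
    """Normal draw with negative values truncated to 0."""
    return np.maximum(rng.normal(mean, sd, size), 0.0)


def simulate_cohort(
    specs: Sequence[CohortSpec],
    phantom_template: PhantomSpec | None = None,
    seed: int = 0,
    imaging_acq: AcquisitionSpec | None = None,
    render_volumes: bool = True,
) -> tuple[list[AnimalPhantom], pd.DataFrame]:
    """Draw a whole cohort of animals from group-level distributions.

    Every scalar (body weight, muscle T2, lesion fraction, three Mac-1 field
    counts, per-gene Ct values) is drawn from its group's normal distribution
    truncated at 0. The long-format cohort table carries one row per
    (animal, measurement) and is identical whether or not image volumes are
    rendered; ``render_volumes=False`` skips the per-animal phantom images
    (useful for large-n recovery checks).

    Returns (animals, table): a list of :class:`AnimalPhantom` (empty when
    not rendering) and a DataFrame with columns
    (animal, group, measurement, value, units).
    """
    from . import study  # deferred: study imports this module's types

    if phantom_template is None:
        phantom_template = PhantomSpec(tissues=study.default_tissues())
    if imaging_acq is None:
        imaging_acq = study.DUAL_ECHO_ACQ
    rng = np.random.default_rng(seed)
    animals: list[AnimalPhantom] = []
    rows: list[dict] = []
    for spec in specs:
        for i in range(spec.n):
            animal = f"{spec.group}-{i + 1:04d}"
            weight = float(_truncated_normal(rng, spec.weight_mean, spec.weight_sd))
            t2 = float(
                np.maximum(
                    _truncated_normal(rng, spec.muscle_t2_mean, spec.muscle_t2_sd),
                    1e-3,
                )
            )
            # Between-animal lesion-burden spread: CV 25% of the group mean.
            lesion_sd = 0.25 * spec.lesion_fraction_mean
            lesion_frac = float(
                np.clip(
                    rng.normal(spec.lesion_fraction_mean, lesion_sd), 0.0, 1.0
                )
            )
            mac1_fields = _truncated_normal(rng, spec.mac1_mean, spec.mac1_sd, 3)
            cts = {
                gene: float(_truncated_normal(rng, m, sd))
                for gene, (m, sd) in spec.ct_params.items()
            }
            phantom_seed = int(rng.integers(0, 2**31 - 1))

            scalars = {
                "weight_g": (weight, "g"),
                "muscle_t2_ms": (t2, "ms"),
                "lesion_fraction": (lesion_frac, "unitless"),
                "mac1_field_1": (float(mac1_fields[0]), "cells/field"),
                "mac1_field_2": (float(mac1_fields[1]), "cells/field"),
                "mac1_field_3": (float(mac1_fields[2]), "cells/field"),
                "mac1_cells_per_field": (
                    float(np.mean(mac1_fields)),
                    "cells/field",
                ),
            }
            for gene, ct in cts.items():
                scalars[f"ct_{gene}"] = (ct, "cycles")
            for name, (value, units) in scalars.items():
                rows.append(
                    {
                        "animal": animal,
                        "group": spec.group,
                        "measurement": name,
                        "value": value,
                        "units": units,
                    }
                )

            if render_volumes:
                tissues = study.default_tissues(muscle_t2=t2)
                pspec = replace(
                    phantom_template,
                    tissues=tissues,
                    lesion_fraction=lesion_frac,
                    seed=phantom_seed,
                )
                lm = build_labelmap(pspec)
                vol = simulate_dual_echo(
                    lm,
                    tissues,
                    imaging_acq,
                    snr_te14=pspec.snr_te14,
                    seed=phantom_seed,
                )
                truth = {k: v for k, (v, _) in scalars.items()}
                animals.append(
                    AnimalPhantom(
                        animal=animal,
                        group=spec.group,
                        labelmap=lm,
                        dual_echo=vol,
                        truth=truth,
                    )
                )
    table = pd.DataFrame(rows, columns=["animal", "group", "measurement", "value", "units"])
    return animals, table
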