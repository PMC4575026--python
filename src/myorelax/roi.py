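"""Hyperintense-pixel classification and muscle-only T2 statistics.

Dystrophic muscle shows two opposing T2 signatures: inflammation/edema raises
T2, fibrosis lowers it. Pixels more than ``k`` SD above the control-muscle
mean (the study cutoff is 27 ms, strict ``>``) are classified hyperintense;
removing them from the ROI yields the "muscle-only" mean whose depression
below control is the fibrosis readout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .images import T2Map
from .t2map import RoiStats

__all__ = [
    "HyperintensityRule",
    "DEFAULT_THRESHOLD_MS",
    "threshold_from_controls",
    "classify_hyperintense",
    "muscle_only_t2",
    "MuscleOnlyStats",
]

#: Printed control-derived cutoff (ms): control mean + 2 SD.
DEFAULT_THRESHOLD_MS = 27.0


@dataclass(frozen=True)
class HyperintensityRule:
    """Cutoff above which a pixel counts as hyperintense.

    ``source`` is "fixed" for a directly supplied threshold or
    "control-derived" when computed as control_mean + k_sd * control_sd.
    """

    threshold: float = DEFAULT_THRESHOLD_MS
    source: str = "fixed"
    control_mean: float | None = None
    control_sd: float | None = None
    k_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.source not in ("fixed", "control-derived"):
            raise ValueError("source must be 'fixed' or 'control-derived'")
        if self.source == "control-derived":
            expected = self.control_mean + self.k_sd * self.control_sd
            if not np.isclose(self.threshold, expected):
                raise ValueError(
                    "control-derived threshold must equal mean + k_sd * sd"
                )


class MuscleOnlyStats(NamedTuple):
    mean: float
    sd: float
    n_pixels: int
    excluded_fraction: float


def threshold_from_controls(
    control_pixel_t2: Sequence[float], k_sd: float = 2.0
) -> HyperintensityRule:
    """Derive the cutoff from pooled control-muscle pixel T2 values.

    threshold = mean + k_sd * sample SD over the pooled pixels (all control
    animals pooled; a single study-wide cutoff).
    """
    vals = np.asarray(control_pixel_t2, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 control pixel values")
    mean = float(vals.mean())
    sd = float(np.std(vals, ddof=1))
    return HyperintensityRule(
        threshold=mean + k_sd * sd,
        source="control-derived",
        control_mean=mean,
        control_sd=sd,
        k_sd=k_sd,
    )


def classify_hyperintense(t2_map: T2Map, rule: HyperintensityRule) -> np.ndarray:
    """Boolean mask, true exactly where a valid pixel's T2 > threshold."""
    with np.errstate(invalid="ignore"):
        return t2_map.valid & (t2_map.t2 > rule.threshold)


def muscle_only_t2(
    t2_map: T2Map,
    slices: Sequence[int] | None = None,
    rule: HyperintensityRule = HyperintensityRule(),
) -> MuscleOnlyStats:
    """ROI statistics after excluding hyperintense pixels.

    Returns the mean, sample SD and count over surviving pixels in the
    selected slices, plus the fraction of valid pixels that were excluded.
    Raises if the exclusion empties the ROI.
    """
    hyper = classify_hyperintense(t2_map, rule)
    if slices is None:
        sel_valid, sel_hyper, sel_t2 = t2_map.valid, hyper, t2_map.t2
    else:
        idx = np.asarray(slices, dtype=int)
        ax = t2_map.slice_axis
        sel_valid = np.take(t2_map.valid, idx, axis=ax)
        sel_hyper = np.take(hyper, idx, axis=ax)
        sel_t2 = np.take(t2_map.t2, idx, axis=ax)
    n_valid = int(sel_valid.sum())
    if n_valid == 0:
        raise ValueError("empty ROI: no valid pixels in the selected slices")
    keep = sel_valid & ~sel_hyper
    vals = sel_t2[keep]
    if vals.size == 0:
        raise ValueError("empty ROI: every valid pixel was excluded")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return MuscleOnlyStats(
        mean=float(vals.mean()),
        sd=sd,
        n_pixels=int(vals.size),
        excluded_fraction=float(sel_hyper.sum()) / n_valid,
    )
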