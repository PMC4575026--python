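"""Two-echo T2 mapping.

For a spin echo at long TR the signal is S(TE) = S0 * exp(-TE/T2), so two
echoes determine T2 in closed form:

    T2 = (TE2 - TE1) / ln(S1 / S2)

With TE1 = 14 ms and TE2 = 40 ms the numerator is the familiar 26 ms. A pixel
is mappable only when S1 > S2 > 0 (monotone decay with positive signal);
anything else — noise floors, zero signal, S1 <= S2 — is flagged invalid
rather than clamped, so downstream ROI statistics are computed over honestly
estimable pixels only.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np

from .images import DualEchoVolume, LabelMap, T2Map

__all__ = [
    "two_echo_t2",
    "make_t2_map",
    "select_middle_slices",
    "roi_mean_t2",
    "RoiStats",
]


class RoiStats(NamedTuple):
    """ROI summary: arithmetic mean, sample SD and pixel count."""

    mean: float
    sd: float
    n_pixels: int


def two_echo_t2(si1, si2, te1: float, te2: float):
    """Per-pixel T2 (ms) from two echo intensities.

    Parameters
    ----------
    si1, si2
        Magnitude intensities at the shorter and longer echo time; scalars or
        arrays of a common shape. Negative intensities are a caller error.
    te1, te2
        Echo times in ms with ``te2 > te1``.

    Returns
    -------
    (t2, valid)
        ``t2`` carries (te2-te1)/ln(si1/si2) where ``si1 > si2 > 0`` and NaN
        elsewhere; ``valid`` is the corresponding boolean mask. Scalar inputs
        yield scalars.
    """
    if not te2 > te1 > 0:
        raise ValueError("echo times must satisfy te2 > te1 > 0")
    s1 = np.asarray(si1, dtype=float)
    s2 = np.asarray(si2, dtype=float)
    if np.any(s1 < 0) or np.any(s2 < 0):
        raise ValueError("magnitude intensities must be non-negative")
    valid = (s1 > s2) & (s2 > 0)
    t2 = np.full(np.broadcast(s1, s2).shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(valid, s1 / np.where(valid, s2, 1.0), np.nan)
        t2 = np.where(valid, (te2 - te1) / np.log(ratio), np.nan)
    if np.isscalar(si1) and np.isscalar(si2):
        return float(t2), bool(valid)
    return t2, valid


def make_t2_map(vol: DualEchoVolume, mask: LabelMap, labels: Sequence[int]) -> T2Map:
    """Apply the two-echo estimator to every pixel whose label is selected.

    Pixels outside ``labels``, and selected pixels where the estimator is
    undefined, are invalid in the returned map.
    """
    if mask.shape != vol.shape:
        raise ValueError(
            f"label grid {mask.shape} does not match image grid {vol.shape}"
        )
    t2, valid = two_echo_t2(vol.si_te1, vol.si_te2, vol.te1, vol.te2)
    selected = mask.mask_of(labels)
    valid &= selected
    t2 = np.where(valid, t2, np.nan)
    return T2Map(
        t2=t2,
        valid=valid,
        te_delta=vol.te_delta,
        voxel_size=vol.voxel_size,
        slice_axis=vol.slice_axis,
    )


def select_middle_slices(n_slices: int, k: int) -> np.ndarray:
    """Indices of the ``k`` slices centred in a stack of ``n_slices``.

    When the parity of ``n_slices - k`` forces an asymmetric window the
    window is shifted toward the lower index.
    """
    if not 1 <= k <= n_slices:
        raise ValueError(f"need 1 <= k <= n_slices, got k={k}, n={n_slices}")
    start = (n_slices - k) // 2
    return np.arange(start, start + k)


def roi_mean_t2(t2_map: T2Map, slices: Sequence[int] | None = None) -> RoiStats:
    """Mean and sample SD of valid T2 pixels pooled over the selected slices.

    ``slices`` indexes the map's slice axis; ``None`` pools every slice.
    Raises if the selection contains no valid pixel.
    """
    if slices is None:
        sel_valid = t2_map.valid
        sel_t2 = t2_map.t2
    else:
        idx = np.asarray(slices, dtype=int)
        sel_valid = np.take(t2_map.valid, idx, axis=t2_map.slice_axis)
        sel_t2 = np.take(t2_map.t2, idx, axis=t2_map.slice_axis)
    vals = sel_t2[sel_valid]
    if vals.size == 0:
        raise ValueError("empty ROI: no valid pixels in the selected slices")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return RoiStats(mean=float(vals.mean()), sd=sd, n_pixels=int(vals.size))
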