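"""Localized water (1H2O) relaxometry from multi-TE STEAM decays.

Three stages mirror a standard single-voxel T2 workflow:

1. :func:`cpca_extract` — complex principal-component analysis collapses a
   (samples x TEs) complex matrix (phase-cycled averages or spectral points)
   to one real decay amplitude per TE.
2. :func:`fit_monoexp` — nonlinear least squares for S0 * exp(-TE/T2).
3. :func:`fit_nnls` — non-negative least squares inversion onto a log-spaced
   T2 grid, resolving multi-compartment water without assuming a component
   count.

Fits operate on cpca-extracted real amplitudes when complex data exist,
otherwise on magnitudes; Rician bias in magnitude data is not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "DecayCurve",
    "MonoExpFit",
    "T2Spectrum",
    "SpectrumSummary",
    "default_t2_grid",
    "cpca_extract",
    "fit_monoexp",
    "fit_nnls",
    "spectrum_summary",
]

#: Mono-exponential fit bounds (ms) and iteration cap.
T2_BOUNDS_MS = (1.0, 2000.0)
MAX_FIT_EVALS = 500

#: Amplitude floor (relative to the max) below which a grid node counts as
#: zero when splitting a spectrum into contiguous components.
COMPONENT_FLOOR = 1e-12


@dataclass
class DecayCurve:
    """A (TE, signal) series from a single voxel; signal may be complex."""

    te: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.te = np.asarray(self.te, dtype=float)
        self.signal = np.asarray(self.signal)
        if self.te.ndim != 1 or self.te.shape != self.signal.shape:
            raise ValueError("te and signal must be 1D of equal length")
        if self.te.size == 0:
            raise ValueError("empty decay curve")
        if np.any(self.te <= 0) or np.any(np.diff(self.te) <= 0):
            raise ValueError("echo times must be positive and strictly increasing")

    @property
    def is_complex(self) -> bool:
        return np.iscomplexobj(self.signal)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.signal)

    @property
    def real_amplitude(self) -> np.ndarray:
        """Real fit target: real part for real data, magnitude for complex."""
        return self.magnitude if self.is_complex else np.asarray(
            self.signal, dtype=float
        )


@dataclass
class MonoExpFit:
    s0: float
    t2: float
    rss: float
    converged: bool

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValueError("rss must be non-negative")


@dataclass
class T2Spectrum:
    """NNLS amplitude distribution over a T2 grid."""

    grid: np.ndarray
    amplitude: np.ndarray
    rss: float
    mu: float = 0.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.grid.shape != self.amplitude.shape:
            raise ValueError("grid and amplitude must match")
        if np.any(self.amplitude < 0):
            raise ValueError("spectrum amplitudes must be non-negative")


class SpectrumSummary(NamedTuple):
    geometric_mean_t2: float
    n_components: int
    fractions: list


def default_t2_grid(
    t2_min: float = 5.0, t2_max: float = 500.0, n: int = 40
) -> np.ndarray:
    """Log-spaced T2 grid (ms); 40 nodes over [5, 500] by default."""
    return np.geomspace(t2_min, t2_max, n)


def cpca_extract(echo_matrix: np.ndarray, te: Sequence[float]) -> DecayCurve:
    """Water decay via complex PCA of a (samples x TEs) matrix.

    Each TE column is projected onto the first (complex) principal component
    of the stacked matrix; the global phase is chosen so the earliest-TE
    amplitude is real and positive. For rank-1 noise-free data this recovers
    the true decay up to scale, and an overall phase factor on the input
    leaves the output unchanged.
    """
    m = np.asarray(echo_matrix, dtype=complex)
    if m.ndim != 2:
        raise ValueError("echo_matrix must be 2D (samples x TEs)")
    if m.shape[0] < 2:
        raise ValueError("need at least 2 samples per TE")
    if not np.any(np.abs(m) > 0):
        raise ValueError("degenerate all-zero input")
    # First left singular vector = dominant spatial/spectral profile.
    u, s, vh = np.linalg.svd(m, full_matrices=False)
    proj = np.conj(u[:, 0]) @ m  # per-TE complex amplitude
    phase = np.angle(proj[0])
    aligned = proj * np.exp(-1j * phase)
    return DecayCurve(te=np.asarray(te, dtype=float), signal=aligned.real)


def fit_monoexp(curve: DecayCurve, t2_init: float | None = None) -> MonoExpFit:
    """Least-squares fit of S0 * exp(-TE/T2) to a decay curve.

    T2 is bounded to (1, 2000) ms with at most 500 residual evaluations.
    Initialisation defaults to the two-point log-ratio of the first and last
    TEs. Non-convergence returns the best iterate with ``converged=False``
    rather than raising.
    """
    if curve.te.size < 2:
        raise ValueError("need at least 2 points to fit")
    te = curve.te
    y = curve.real_amplitude
    if t2_init is None:
        s_first, s_last = y[0], y[-1]
        if s_first > s_last > 0:
            t2_init = (te[-1] - te[0]) / np.log(s_first / s_last)
        else:
            t2_init = float(np.median(te))
    t2_init = float(np.clip(t2_init, *T2_BOUNDS_MS))
    s0_init = max(float(y[0]) * float(np.exp(te[0] / t2_init)), 1e-12)

    def resid(p):
        return p[0] * np.exp(-te / p[1]) - y

    res = optimize.least_squares(
        resid,
        x0=[s0_init, t2_init],
        bounds=([0.0, T2_BOUNDS_MS[0]], [np.inf, T2_BOUNDS_MS[1]]),
        max_nfev=MAX_FIT_EVALS,
        method="trf",
    )
    s0, t2 = res.x
    at_bound = np.isclose(t2, T2_BOUNDS_MS[1]) or np.isclose(t2, T2_BOUNDS_MS[0])
    return MonoExpFit(
        s0=float(s0),
        t2=float(t2),
        rss=float(np.sum(res.fun**2)),
        converged=bool(res.status > 0 and not at_bound),
    )


def fit_nnls(
    curve: DecayCurve, grid: np.ndarray | None = None, mu: float = 0.0
) -> T2Spectrum:
    """Non-negative least squares T2 spectrum.

    Minimises ||A x - s||^2 + mu^2 ||x||^2 subject to x >= 0 with
    A[i, j] = exp(-te_i / grid_j). ``rss`` is always the unregularised
    residual of the returned spectrum.
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    if grid is None:
        grid = default_t2_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2:
        raise ValueError("grid must have at least 2 nodes")
    y = curve.real_amplitude
    a = np.exp(-curve.te[:, None] / grid[None, :])
    if mu > 0:
        a_fit = np.vstack([a, mu * np.eye(grid.size)])
        y_fit = np.concatenate([y, np.zeros(grid.size)])
    else:
        a_fit, y_fit = a, y
    x, _ = optimize.nnls(a_fit, y_fit)
    rss = float(np.sum((a @ x - y) ** 2))
    return T2Spectrum(grid=grid, amplitude=x, rss=rss, mu=mu)


def spectrum_summary(spec: T2Spectrum) -> SpectrumSummary:
    """Amplitude-weighted geometric-mean T2, component count and fractions.

    Components are maximal contiguous runs of grid nodes with amplitude above
    a 1e-12-of-max floor; fractions are each run's amplitude share.
    """
    a = spec.amplitude
    total = a.sum()
    if total <= 0:
        raise ValueError("all-zero spectrum")
    gm = float(np.exp(np.sum(a * np.log(spec.grid)) / total))
    positive = a > COMPONENT_FLOOR * a.max()
    fractions: list[float] = []
    run_sum = 0.0
    in_run = False
    for amp, pos in zip(a, positive):
        if pos:
            run_sum += amp
            in_run = True
        elif in_run:
            fractions.append(run_sum / total)
            run_sum, in_run = 0.0, False
    if in_run:
        fractions.append(run_sum / total)
    return SpectrumSummary(
        geometric_mean_t2=gm,
        n_components=len(fractions),
        fractions=[float(f) for f in fractions],
    )
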