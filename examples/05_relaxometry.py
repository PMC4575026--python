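"""Single-voxel water relaxometry: complex PCA, mono-exponential and NNLS.

A two-pool water decay (70% at 20 ms, 30% at 80 ms) sampled at the 29
non-linearly spaced STEAM echo times. The mono-exponential fit returns a
single compromise T2; the NNLS spectrum resolves both pools.
"""

import numpy as np

from myorelax import (
    DecayCurve, cpca_extract, fit_monoexp, fit_nnls, simulate_steam_decay,
    spectrum_summary, study,
)

te = np.asarray(study.STEAM_TE_MS, dtype=float)

# phase-cycled complex acquisition -> one real decay via complex PCA
profile = np.array([1.0 + 0.3j, 0.6 - 0.2j, 0.9 + 0.5j, 0.4 + 0.1j])
clean = 0.7 * np.exp(-te / 20.0) + 0.3 * np.exp(-te / 80.0)
matrix = np.outer(profile, clean) * np.exp(1j * 0.8)  # arbitrary global phase
curve = cpca_extract(matrix, te)
curve = DecayCurve(te=te, signal=curve.signal / curve.signal[0] * clean[0])

mono = fit_monoexp(curve)
print(f"mono-exponential: T2 = {mono.t2:.2f} ms (rss {mono.rss:.2e})")

spectrum = fit_nnls(curve)
summary = spectrum_summary(spectrum)
print(f"NNLS: {summary.n_components} components, "
      f"fractions {[round(f, 3) for f in summary.fractions]}, "
      f"gm-T2 {summary.geometric_mean_t2:.1f} ms (rss {spectrum.rss:.2e})")
# The single-pool fit lands between 20 and 80 ms; NNLS recovers both pools
# and their 0.7/0.3 amplitude split, with a strictly smaller residual.
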