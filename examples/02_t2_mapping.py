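"""Two-echo T2 mapping of a healthy phantom.

T2 = (TE2 - TE1) / ln(SI1/SI2) per pixel; the ROI summary pools valid
pixels over the 7 middle slices, mirroring a multi-slice acquisition where
edge slices are discarded.
"""

import numpy as np

from myorelax import (
    build_labelmap, make_t2_map, roi_mean_t2, select_middle_slices,
    simulate_dual_echo, study, two_echo_t2,
)

# the estimator itself, on one pixel: a ratio of e exposes the 26 ms constant
t2, valid = two_echo_t2(float(np.e), 1.0, 14.0, 40.0)
print(f"single pixel, SI14/SI40 = e  ->  T2 = {t2:.1f} ms")

spec = study.default_phantom(muscle_t2=study.T2_WT_MS, snr_te14=33.0, seed=1)
labelmap = build_labelmap(spec)
volume = simulate_dual_echo(
    labelmap, spec.tissues, study.DUAL_ECHO_ACQ, snr_te14=33.0, seed=1
)
t2_map = make_t2_map(volume, labelmap, [2])  # posterior compartment
slices = select_middle_slices(10, 7)
stats = roi_mean_t2(t2_map, slices)
print(
    f"posterior ROI: {stats.mean:.2f} +/- {stats.sd:.2f} ms "
    f"over {stats.n_pixels} pixels (truth {study.T2_WT_MS} ms)"
)
# The ROI mean sits near the simulated 24.83 ms; the ~2 ms pixel SD is the
# noise propagated through the log-ratio, not biological spread.
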