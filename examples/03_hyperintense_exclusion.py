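"""Separate inflammation from fibrosis by hyperintense-pixel exclusion.

A dystrophic phantom mixes low-T2 fibrotic muscle (21.2 ms) with high-T2
lesions (40 ms). The whole-ROI mean is pulled up by the lesions; removing
pixels above the 27 ms cutoff (control mean + 2 SD) recovers the depressed
muscle-only T2 — the fibrosis signature.
"""

import numpy as np

from myorelax import (
    HyperintensityRule, build_labelmap, make_t2_map, muscle_only_t2,
    roi_mean_t2, simulate_dual_echo, study, threshold_from_controls,
)

spec = study.default_phantom(
    muscle_t2=study.T2_DYW_MUSCLE_ONLY_MS, lesion_fraction=0.20, seed=2
)
labelmap = build_labelmap(spec)
volume = simulate_dual_echo(labelmap, spec.tissues, study.DUAL_ECHO_ACQ,
                            snr_te14=np.inf)
t2_map = make_t2_map(volume, labelmap, [1, 2, 3])

whole = roi_mean_t2(t2_map)
rule = HyperintensityRule()  # fixed 27 ms, strict >
muscle = muscle_only_t2(t2_map, rule=rule)
print(f"whole-muscle mean T2:   {whole.mean:.2f} ms")
print(f"muscle-only mean T2:    {muscle.mean:.2f} ms "
      f"(excluded {100 * muscle.excluded_fraction:.1f}% of pixels)")

derived = threshold_from_controls([24.0, 25.0, 26.0], k_sd=2.0)
print(f"control-derived cutoff from pixel pool {{24,25,26}}: "
      f"{derived.threshold:.1f} ms")
# The exclusion strips exactly the simulated 20% lesion burden and exposes
# the 21.2 ms fibrotic muscle underneath the elevated whole-ROI mean.
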