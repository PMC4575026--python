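"""Simulate a synthetic dystrophic hindlimb and inspect its raw echoes.

Builds a 10-slice phantom with fibrotic muscle (T2 21.2 ms) carrying a 20%
burden of hyperintense lesions (T2 40 ms), imaged at TE 14/40 ms with
Rician noise at muscle SNR 33:1.
"""

import numpy as np

from myorelax import build_labelmap, simulate_dual_echo, study

spec = study.default_phantom(
    muscle_t2=study.T2_DYW_MUSCLE_ONLY_MS, lesion_fraction=0.20,
    snr_te14=study.SNR_TE14, seed=0,
)
labelmap = build_labelmap(spec)
volume = simulate_dual_echo(
    labelmap, spec.tissues, study.DUAL_ECHO_ACQ,
    snr_te14=spec.snr_te14, seed=0,
)

for code, name in sorted(labelmap.code_table.items()):
    n = int((labelmap.labels == code).sum())
    print(f"label {code} ({name:10s}): {n:6d} voxels")
muscle = labelmap.mask_of([1, 2])
print(f"muscle mean signal TE14: {volume.si_te1[muscle].mean():.4f}")
print(f"muscle mean signal TE40: {volume.si_te2[muscle].mean():.4f}")
print(f"background floor (Rician): {volume.si_te1[labelmap.labels == 0].mean():.4f}")
# The TE14/TE40 ratio encodes T2; the noisy background floor is non-zero
# because magnitude images rectify complex noise.
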