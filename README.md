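# myorelax

Quantitative muscle-MRI analysis for preclinical dystrophy studies. The
package implements the full in vivo quantification chain used to track
muscle pathology in laminin-deficient (DyW) mice — a model of congenital
muscular dystrophy type 1A — and its response to anti-fibrotic treatment:

- **Two-echo T2 mapping.** For a spin echo at long TR, S(TE) = S0·e^(−TE/T2),
  so two echoes at TE₁ = 14 ms and TE₂ = 40 ms give per-pixel
  **T2 = 26 ms / ln(SI₁₄/SI₄₀)**. ROI means pool valid pixels over the middle
  slices of the stack.
- **Hyperintense-pixel classification.** Pixels with T2 strictly above the
  control-derived cutoff (mean + 2 SD of control muscle pixels; 27 ms by
  default) mark inflammation/edema. The **muscle-only T2** — the ROI mean
  after excluding those pixels — drops below control when collagen builds
  up, giving an MR fibrosis readout.
- **Compartment volumetry.** Voxel-count volumes (mm³) and per-slice
  cross-sectional areas (mm²) of anterior/posterior hindlimb compartments
  from integer label masks on 3D T1-weighted geometry.
- **Water relaxometry.** Single-voxel STEAM decays over 29 non-linearly
  spaced TEs (5–200 ms): complex-PCA signal extraction, mono-exponential
  nonlinear fitting, and a non-negative least-squares (NNLS) T2 spectrum
  that resolves multiple water pools.
- **Cohort statistics.** One-way ANOVA with Tukey (Tukey–Kramer) pairwise
  comparisons, ΔΔCt fold changes (2^(−ΔΔCt)) against an 18s endogenous
  control, three-field Mac-1 cell-count averaging, and a deterministic
  report bundle.
- **Synthetic hindlimb phantom.** Because no scanner data ship with the
  package, a generator produces dual-echo volumes (Rician noise anchored to
  muscle SNR 33:1 at TE 14 ms), STEAM decays and whole cohorts with known
  ground truth, so every stage is verifiable end to end.

## Worked example

```python
import numpy as np
from myorelax import (build_labelmap, simulate_dual_echo, make_t2_map,
                      muscle_only_t2, roi_mean_t2, HyperintensityRule, study)

# fibrotic muscle (T2 21.2 ms) with a 20% burden of 40 ms lesions
spec = study.default_phantom(muscle_t2=21.20, lesion_fraction=0.20, seed=2)
lm = build_labelmap(spec)
vol = simulate_dual_echo(lm, spec.tissues, study.DUAL_ECHO_ACQ, snr_te14=np.inf)
t2map = make_t2_map(vol, lm, [1, 2, 3])

print(roi_mean_t2(t2map).mean)                       # 24.96  (whole muscle, ms)
print(muscle_only_t2(t2map, rule=HyperintensityRule()))
# MuscleOnlyStats(mean=21.20, sd=0.0, n_pixels=8560, excluded_fraction=0.20)
```

The whole-muscle mean (24.96 ms) is inflated by the hyperintense lesions;
excluding pixels above 27 ms recovers the depressed fibrotic-muscle T2
(21.20 ms) and the exact simulated lesion burden (20%). The
`examples/` directory has one short script per capability, including the
full simulate → map → classify → volume → relax → report chain
(`examples/07_full_study.py`) and the same chain as a CLI
(`myorelax run --out DIR`).

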