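# Methods

## Signal model and T2 estimation

Every imaging voxel is modelled as a single tissue with relative proton
density PD and transverse relaxation time T2 (ms); the spin-echo magnitude
at echo time TE is S(TE) = PD·exp(−TE/T2). T1 weighting is ignored: at
TR = 2000 ms the longitudinal recovery factor is treated as saturated, which
is the assumption under which the two-point estimator

    T2 = (TE₂ − TE₁) / ln(S₁/S₂)

is exact. With TE 14/40 ms the numerator is 26 ms. The estimator is applied
only where S₁ > S₂ > 0; other pixels (noise floor, zero signal, inverted
decay) are flagged invalid and **excluded** from ROI statistics rather than
clamped — clamping would bias means toward the clamp value. ROI summaries
pool pixels across the selected slices (pixel-by-pixel analysis, not
per-slice means of means) and report mean ± sample SD (ddof = 1).

Middle-slice selection takes the k slices centred on n/2, shifting toward
the lower index when parity forces a choice; the default k = 7 is the
midpoint of the 6–8 slices typically analysed, and is configurable.

## Hyperintensity rule

A pixel is hyperintense when its T2 is **strictly** greater than the
threshold. The default threshold is the fixed 27 ms cutoff; a
control-derived mode computes mean + k·SD (k = 2) over a pooled
control-muscle pixel population, yielding a single study-wide cutoff rather
than per-animal thresholds. Note the reported ROI-level control statistics
(24.83 ± 0.66 ms) do not reproduce 27 ms at k = 2; a pixel-level SD does.
Under this package's noise model the propagated pixel-level T2 SD at muscle
SNR 33:1 (TE 14) is ≈ 2.2 ms, and 24.83 + 2.2 ≈ 27 — i.e. the fixed cutoff
sits roughly one-to-two pixel-noise SDs above control. The package does not
guess which population produced the printed value: it defaults to the
printed constant and exposes the control-derived rule separately.

Consequences worth knowing: on noisy healthy data a noticeable tail of
muscle pixels (on the order of 10–15% at SNR 33) exceeds 27 ms purely from
noise, so non-zero excluded fractions in healthy animals are expected
behaviour, not a defect. Noise-free phantoms separate cleanly and are used
for the exact recovery checks.

## Volumetry

Volumes count voxel centres times the voxel volume (product of per-axis
sizes); there is no partial-volume weighting, matching how a manual outline
is tallied. Lesion voxels can be folded into an enclosing compartment via
the label map's parent mapping when the attribution is unambiguous.
Cross-sectional area uses the in-plane pixel area at a chosen axial slice
(default: the middle slice). Ellipse-phantom checks confirm discretised
areas converge to πab within 2% at the default resolution and that volumes
change by <1% when the matrix is doubled at fixed FOV.

## Water relaxometry

The STEAM voxel is treated as a single well-mixed signal source (the
acquisition's nominal 1.5×3.0×1.5 voxel, units taken as mm). The 29-TE
schedule (5, 6, 7, 8, 9, 10, then 15–70 in steps of 5, 80–170 in steps of
10, and 200 ms) is the default.

- **Complex PCA**: the (samples × TEs) complex matrix is decomposed by SVD;
  per-TE amplitudes are the projections onto the first left singular
  vector, phase-rotated so the earliest-TE amplitude is real and positive.
  Real parts are returned without clipping: for physical decays they are
  non-negative, and clipping would bias later fits under noise. Rank-1
  noise-free input is recovered exactly (up to scale) and a global phase
  factor is invisible.
- **Mono-exponential fit**: trust-region least squares for (S0, T2) with
  T2 bounded to (1, 2000) ms, at most 500 residual evaluations, and
  initialisation from the two-point log-ratio of the first and last TEs.
  Non-convergence (including a bound-riding T2 on non-decaying input)
  returns the best iterate flagged `converged=False`.
- **NNLS spectrum**: amplitudes minimise ‖Ax − s‖² (+ μ²‖x‖² when μ > 0)
  subject to x ≥ 0, A[i,j] = exp(−TEᵢ/gridⱼ), on a default grid of 40
  log-spaced nodes over [5, 500] ms with μ = 0 (plain NNLS). The reported
  rss is always the unregularised residual. Components are maximal
  contiguous runs of nodes above 10⁻¹² of the peak amplitude; the summary
  reports the amplitude-weighted geometric-mean T2 and per-run fractions.
  Because the spectrum nests the single exponential, its rss never exceeds
  the mono-exponential rss. No GCV/χ² regularisation sweeps are provided.
- Fits operate on cpca-extracted real amplitudes when complex data exist,
  else on magnitudes; Rician bias in magnitude fits is uncorrected and
  matters only at low SNR.

## Synthetic phantom and what it does (not) emulate

Geometry: 10 axial slices of 1 mm on a 64×64 plane (0.2 mm in-plane),
holding stacked-ellipse anterior and posterior muscle compartments and a
bone core. The shapes are plumbing — chosen disjoint and grid-contained,
validated as such — not anatomy. Lesions replace
round(lesion_fraction·n_muscle) randomly chosen muscle voxels (exact to one
voxel of rounding); an optional cluster mode grows dilated blobs from
random seeds, off by default since no lesion geometry is specified by the
emulated study.

Noise is Rician: independent Gaussian draws of a common σ on each
quadrature before the magnitude, with σ = (mean noise-free muscle signal at
TE 14)/snr_te14. The same σ applies to the second echo, which reproduces
the reported TE 40 SNR of ≈12:1 as a consequence (33·e^(−26/24.83) ≈ 11.7)
rather than as a second knob. snr 0 or ∞ means noise-free. Seeds are
threaded explicitly through every stochastic call; identical seeds give
bit-identical outputs.

Cohort generation draws each animal's body weight, muscle T2, lesion
fraction, three Mac-1 field counts and per-gene Ct values from the group's
normal distributions truncated at 0. Group means/SDs for weight, muscle T2
and Mac-1 means come from the emulated study's reported statistics
(`myorelax.study`); quantities it does not print were fixed once at
realistic values: Mac-1 field-count SDs of 1.5/4.0/2.5 cells per field
(healthy/dystrophic/treated), lesion burdens of 0/0.20/0.05 with a 25%
between-animal CV, and Ct levels placing COL1a ≈8-fold over-expressed in
dystrophic muscle against an invariant 18s control (Ct SD 0.5/0.2). The
cohort table is identical whether or not image volumes are rendered, so
large-n recovery checks (n = 10⁴) skip rendering.

Not emulated: k-space/coil effects, B1 and slice-profile imperfections,
partial-volume mixtures within a voxel, T1 weighting, stimulated-echo
contamination, motion, and any real anatomical shape or histology image
content. Passing tests therefore certify the analysis chain's correctness
on data that obey the stated signal model, not scanner robustness.

## Statistics

One-way ANOVA (F and p) and Tukey HSD adjusted pairwise p-values via the
studentized-range distribution, using the Tukey–Kramer form for unequal
group sizes (the emulated design is n = 6/8/4). Zero within-group variance
yields an undefined F surfaced as NaN, never an exception. ΔΔCt averages
technical replicates before differencing; fold change is 2^(−ΔΔCt).
Reports serialise ms-scale summaries at 2 decimals (full precision kept in
memory) with stable row ordering, so identical inputs give byte-identical
files.

## Problem sizes and determinism

Unit and acceptance checks run on the desk-scale phantom (≈41k voxels,
≈10k muscle voxels), 29-point decays, 100–200 simulation repeats for
detection-rate and recovery properties, and n = 10⁴ scalar-only cohorts;
the whole suite completes in well under a minute. All randomness flows
through explicit integer seeds on numpy Generators.
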