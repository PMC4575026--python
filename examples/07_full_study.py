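"""Run the whole study end to end: simulate -> map -> classify -> report.

Simulates all three cohorts with rendered image volumes, analyses every
animal (whole and muscle-only T2, compartment volumes, water relaxometry)
and assembles the group report.
"""

from myorelax.pipeline import run_study

bundle = run_study(seed=0, out_dir="scratch/full_study")

summ = bundle.group_summary.set_index(["measurement", "group"])
for meas in ("whole_t2_ms", "muscle_only_t2_ms", "excluded_fraction"):
    row = summ.loc[meas]
    parts = ", ".join(
        f"{g}: {row.loc[g, 'mean']:.2f}+/-{row.loc[g, 'sd']:.2f}"
        for g in ("WT", "DyW", "DyW-Los")
    )
    print(f"{meas:20s} {parts}")
for c in bundle.comparisons:
    if c.measurement == "whole_t2_ms":
        for p in c.pairwise:
            print(f"whole T2 {p.group_a} vs {p.group_b}: adj p = {p.p_adj:.4f}"
                  f"{' *' if p.significant else ''}")
# Dystrophic whole-compartment T2 is elevated (inflammation); the muscle-only
# mean after hyperintense exclusion drops below control (fibrosis); treatment
# normalises both, echoing the ground-truth cohort parameters.
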