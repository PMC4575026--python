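"""Group statistics and report assembly.

One-way ANOVA with Tukey's (Tukey-Kramer, for the study's unequal group
sizes 6/8/4) all-pairs comparisons; relative qPCR quantification by the
delta-delta-Ct method against an endogenous control; the three-field Mac-1
count average; and a deterministic per-study report bundle. Summaries
follow the mean +/- sample SD convention.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairwiseComparison",
    "GroupSummary",
    "ComparisonResult",
    "anova_tukey",
    "ddct_fold_change",
    "mac1_average",
    "build_report",
    "ReportBundle",
]


@dataclass(frozen=True)
class GroupSummary:
    group: str
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_diff: float  # mean(a) - mean(b)
    p_adj: float
    significant: bool


@dataclass(frozen=True)
class ComparisonResult:
    measurement: str
    f_statistic: float
    p_anova: float
    alpha: float
    summaries: tuple[GroupSummary, ...]
    pairwise: tuple[PairwiseComparison, ...]


def anova_tukey(
    table: pd.DataFrame, measurement: str, alpha: float = 0.05
) -> ComparisonResult:
    """Classical one-way ANOVA followed by Tukey HSD on one measurement.

    ``table`` is the long-format cohort table with columns
    (animal, group, measurement, value). Adjusted pairwise p-values use the
    studentized-range distribution with the Tukey-Kramer unequal-n
    correction; significance is flagged at ``alpha``.
    """
    sub = table[table["measurement"] == measurement]
    if sub.empty:
        raise ValueError(f"measurement {measurement!r} not present in table")
    groups = sorted(sub["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for a comparison")
    samples = []
    for g in groups:
        vals = sub.loc[sub["group"] == g, "value"].to_numpy(dtype=float)
        if vals.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 animals")
        samples.append(vals)

    f_stat, p_anova = sps.f_oneway(*samples)
    hsd = sps.tukey_hsd(*samples)
    summaries = tuple(
        GroupSummary(
            group=g,
            mean=float(v.mean()),
            sd=float(np.std(v, ddof=1)),
            n=int(v.size),
        )
        for g, v in zip(groups, samples)
    )
    pairwise = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            p_adj = float(np.clip(hsd.pvalue[i, j], 0.0, 1.0))
            pairwise.append(
                PairwiseComparison(
                    group_a=groups[i],
                    group_b=groups[j],
                    mean_diff=float(samples[i].mean() - samples[j].mean()),
                    p_adj=p_adj,
                    significant=p_adj < alpha,
                )
            )
    return ComparisonResult(
        measurement=measurement,
        f_statistic=float(f_stat),
        p_anova=float(p_anova),
        alpha=alpha,
        summaries=summaries,
        pairwise=tuple(pairwise),
    )


def ddct_fold_change(
    ct_target_sample,
    ct_ref_sample,
    ct_target_calib,
    ct_ref_calib,
) -> float:
    """Relative expression 2^(-ddCt) against an endogenous control.

    ddCt = (Ct_target - Ct_ref)_sample - (Ct_target - Ct_ref)_calibrator.
    Each argument may be a scalar or a sequence of technical replicates
    (replicates are averaged before differencing).
    """
    cts = [
        float(np.mean(np.asarray(c, dtype=float)))
        for c in (ct_target_sample, ct_ref_sample, ct_target_calib, ct_ref_calib)
    ]
    if not all(np.isfinite(cts)):
        raise ValueError("all Ct values must be finite")
    ddct = (cts[0] - cts[1]) - (cts[2] - cts[3])
    return float(2.0 ** (-ddct))


def mac1_average(
    field_counts: Sequence[float], expected_fields: int | None = 3
) -> float:
    """Mean Mac-1-positive cells over 40x field views (three per sample)."""
    counts = np.asarray(field_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty field-count list")
    if np.any(counts < 0):
        raise ValueError("field counts must be >= 0")
    if expected_fields is not None and counts.size != expected_fields:
        raise ValueError(
            f"expected {expected_fields} field counts, got {counts.size}"
        )
    return float(counts.mean())


@dataclass
class ReportBundle:
    per_animal: pd.DataFrame
    group_summary: pd.DataFrame
    comparisons: tuple[ComparisonResult, ...]
    provenance: dict


def build_report(
    cohort_table: pd.DataFrame,
    image_summaries: pd.DataFrame | None = None,
    alpha: float = 0.05,
    out_dir: str | Path | None = None,
    provenance: dict | None = None,
) -> ReportBundle:
    """Merge per-animal measurements and compute all group comparisons.

    ``image_summaries`` (optional) adds pipeline-derived per-animal rows in
    the same long format; its animal ids must all exist in the cohort table,
    otherwise a reconciliation error lists the orphans. Every measurement
    observed in at least 2 groups with >= 2 animals each gets an ANOVA +
    Tukey comparison. When ``out_dir`` is given the bundle is written to
    disk (summary.csv, comparisons.csv, report.json) with stable ordering,
    so identical inputs produce byte-identical files.
    """
    required = {"animal", "group", "measurement", "value"}
    if cohort_table.empty:
        raise ValueError("empty cohort table")
    if not required.issubset(cohort_table.columns):
        raise ValueError(f"cohort table needs columns {sorted(required)}")
    merged = cohort_table.copy()
    if image_summaries is not None and not image_summaries.empty:
        known = set(cohort_table["animal"])
        orphans = sorted(set(image_summaries["animal"]) - known)
        if orphans:
            raise ValueError(f"image summaries reference unknown animals: {orphans}")
        merged = pd.concat([merged, image_summaries], ignore_index=True)
    dup = merged.duplicated(subset=["animal", "measurement"])
    if dup.any():
        pairs = merged.loc[dup, ["animal", "measurement"]].values.tolist()
        raise ValueError(f"duplicate (animal, measurement) rows: {pairs[:5]}")
    merged = merged.sort_values(
        ["measurement", "group", "animal"], kind="mergesort"
    ).reset_index(drop=True)

    comparisons = []
    summary_rows = []
    for meas in sorted(merged["measurement"].unique()):
        sub = merged[merged["measurement"] == meas]
        sizes = sub.groupby("group")["value"].size()
        for g in sorted(sizes.index):
            vals = sub.loc[sub["group"] == g, "value"].to_numpy(dtype=float)
            summary_rows.append(
                {
                    "measurement": meas,
                    "group": g,
                    "mean": float(vals.mean()),
                    "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
                    "n": int(vals.size),
                }
            )
        if (sizes >= 2).sum() >= 2 and (sizes >= 2).all():
            comparisons.append(anova_tukey(merged, meas, alpha=alpha))
    group_summary = pd.DataFrame(summary_rows)
    bundle = ReportBundle(
        per_animal=merged,
        group_summary=group_summary,
        comparisons=tuple(comparisons),
        provenance=dict(provenance or {}),
    )
    if out_dir is not None:
        _write_report(bundle, Path(out_dir))
    return bundle


def _comparison_rows(comparisons: Sequence[ComparisonResult]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        for p in c.pairwise:
            rows.append(
                {
                    "measurement": c.measurement,
                    "f_statistic": round(c.f_statistic, 6),
                    "p_anova": c.p_anova,
                    "group_a": p.group_a,
                    "group_b": p.group_b,
                    "mean_diff": round(p.mean_diff, 6),
                    "p_adj": p.p_adj,
                    "significant": p.significant,
                }
            )
    return pd.DataFrame(rows)


def _write_report(bundle: ReportBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    # ms-scale numbers serialized at 2 decimals; full precision kept in memory
    summary = bundle.group_summary.copy()
    summary["mean"] = summary["mean"].round(2)
    summary["sd"] = summary["sd"].round(2)
    summary.to_csv(out_dir / "summary.csv", index=False)
    _comparison_rows(bundle.comparisons).to_csv(
        out_dir / "comparisons.csv", index=False
    )
    report = {
        "provenance": bundle.provenance,
        "comparisons": [asdict(c) for c in bundle.comparisons],
    }
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=float) + "\n"
    )
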