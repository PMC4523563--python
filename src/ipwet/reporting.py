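"""Rendering of evaluation and recalibration results as tables.

Every renderer returns a pandas DataFrame (the machine-readable form, written
as CSV by the CLI); :func:`render_text` formats any of them as an aligned
human-readable table.  Rendering never feeds back into computation: values
are rounded here, for display, and nowhere else.

Sign convention note: percent differences are computed as 100*(B - A)/A
(positive = the tape overestimates).  Study reports sometimes label the same
quantity "(actual - predicted)" with the opposite sign; the cohort summary
prints both labels explicitly.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .cohort import ExclusionLog
from .metrics import (
    CohortSummary,
    PercentDifferenceSummary,
    ZoneMetrics,
    ZoneWeightSummary,
)
from .recalibrate import ValidationReport
from .tape import TapeSpec

__all__ = [
    "cohort_summary_frame",
    "percent_difference_frame",
    "zone_weight_frame",
    "zone_metrics_frame",
    "validation_frame",
    "tape_frame",
    "tape_comparison_frame",
    "exclusion_frame",
    "render_text",
]

P_FLOOR = 0.0005  # p-values below this render as "<0.0005"


def cohort_summary_frame(s: CohortSummary) -> pd.DataFrame:
    rows = [
        ("n", s.n, None),
        ("age (months)", s.mean_age, s.sd_age),
        ("actual height (cm)", s.mean_height, s.sd_height),
        ("actual weight (kg)", s.mean_weight, s.sd_weight),
        ("predicted weight (kg)", s.mean_predicted, s.sd_predicted),
        ("percent diff, predicted - actual (%)", s.mean_d, s.sd_d),
        ("percent diff, actual - predicted (%)", -s.mean_d, s.sd_d),
        ("corr(weight, height)", s.corr_weight_height, None),
        ("corr(weight, predicted)", s.corr_weight_predicted, None),
        ("corr(height, predicted)", s.corr_height_predicted, None),
        ("corr(weight, age)", s.corr_weight_age, None),
    ]
    for sex, r2 in sorted(s.r2_by_sex.items()):
        rows.append((f"R2 weight~height, sex={sex}", r2, None))
    return pd.DataFrame(rows, columns=["characteristic", "value", "sd"])


def percent_difference_frame(
    rows: Sequence[PercentDifferenceSummary],
    overall: PercentDifferenceSummary | None = None,
    corrected: Sequence[PercentDifferenceSummary] | None = None,
) -> pd.DataFrame:
    all_rows = list(rows) + ([overall] if overall is not None else [])
    df = pd.DataFrame(
        {
            "zone": [r.zone for r in all_rows],
            "n": [r.n for r in all_rows],
            "mean_pct_diff": [r.mean_d for r in all_rows],
            "sd_pct_diff": [r.sd_d for r in all_rows],
        }
    )
    if corrected is not None:
        by_zone = {r.zone: r for r in corrected}
        df["mean_pct_diff_corrected"] = [
            by_zone[z].mean_d if z in by_zone else None for z in df["zone"]
        ]
        df["sd_pct_diff_corrected"] = [
            by_zone[z].sd_d if z in by_zone else None for z in df["zone"]
        ]
    return df


def zone_weight_frame(rows: Sequence[ZoneWeightSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "zone": [r.zone for r in rows],
            "n": [r.n for r in rows],
            "mean_measured": [r.mean_measured for r in rows],
            "sd_measured": [r.sd_measured for r in rows],
            "mean_predicted": [r.mean_predicted for r in rows],
            "sd_predicted": [r.sd_predicted for r in rows],
            "mean_corrected": [r.mean_corrected for r in rows],
            "sd_corrected": [r.sd_corrected for r in rows],
            "p_measured_vs_predicted": [r.p_uncorrected for r in rows],
            "p_measured_vs_corrected": [r.p_corrected for r in rows],
        }
    )


def zone_metrics_frame(rows: Sequence[ZoneMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "zone": [r.zone for r in rows],
            "n": [r.n for r in rows],
            "sensitivity": [r.sensitivity for r in rows],
            "specificity": [r.specificity for r in rows],
            "kappa": [r.kappa for r in rows],
            "chi2_p": [r.chi2_p for r in rows],
        }
    )


def validation_frame(report: ValidationReport) -> pd.DataFrame:
    """Per-zone metrics per cohort side by side, plus the pooled columns."""
    out = None
    for i, metrics in enumerate(report.per_cohort, start=1):
        df = zone_metrics_frame(metrics)
        df = df.rename(
            columns={
                c: f"{c}_cohort{i}" for c in df.columns if c not in ("zone",)
            }
        )
        out = df if out is None else out.merge(df, on="zone")
    pooled = zone_metrics_frame(report.pooled).rename(
        columns={
            c: f"{c}_pooled"
            for c in ("n", "sensitivity", "specificity", "kappa", "chi2_p")
        }
    )
    return out.merge(pooled, on="zone")


def tape_frame(tape: TapeSpec) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "zone": [z.name for z in tape.zones],
            "height_lo": [z.height_lo for z in tape.zones],
            "height_hi": [z.height_hi for z in tape.zones],
            "weight_lo": [z.weight_lo for z in tape.zones],
            "weight_hi": [z.weight_hi for z in tape.zones],
        }
    )


def tape_comparison_frame(base: TapeSpec, new: TapeSpec) -> pd.DataFrame:
    """Side-by-side zone ranges of two tapes (base vs recalibrated)."""
    rows = []
    for zb, zn in zip(base.zones, new.zones):
        rows.append(
            {
                "zone": zb.name,
                "base_height_range": f"{zb.height_lo:g}-{zb.height_hi:g}",
                "base_weight_range": f"{zb.weight_lo:g}-{zb.weight_hi:g}",
                "new_height_range": f"{zn.height_lo:.1f}-{zn.height_hi:.1f}",
                "new_weight_range": f"{zn.weight_lo:g}-{zn.weight_hi:g}",
            }
        )
    return pd.DataFrame(rows)


def exclusion_frame(log: ExclusionLog) -> pd.DataFrame:
    return pd.DataFrame(
        [
            ("input", log.n_input),
            ("kept", log.n_kept),
            ("excluded", log.n_excluded),
            ("height_below_range", log.height_below_range),
            ("height_above_range", log.height_above_range),
            ("weight_above_max", log.weight_above_max),
        ],
        columns=["criterion", "count"],
    )


def _fmt(value, col: str) -> str:
    if value is None or (isinstance(value, float) and value != value):
        return "-"
    if isinstance(value, float):
        if col.startswith("p_") or col.startswith("chi2_p") or "chi2_p" in col:
            return f"<{P_FLOOR}" if value < P_FLOOR else f"{value:.4f}"
        return f"{value:.2f}"
    return str(value)


def render_text(df: pd.DataFrame, title: str | None = None) -> str:
    """Aligned text table with 2-dp rounding and floored p-values."""
    shown = df.copy()
    for col in shown.columns:
        shown[col] = [_fmt(v, col) for v in shown[col]]
    body = shown.to_string(index=False)
    return (f"{title}\n{body}\n" if title else body + "\n")
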