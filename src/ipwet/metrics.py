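"""Evaluation statistics for a tape on a cohort.

Everything here is built on the directed percent difference

    d = 100 * (B - A) / A

where ``B`` is the tape-predicted weight for the measured height and ``A``
the measured actual weight; positive values mean the tape overestimates.

The module computes per-zone bias/precision summaries, within-tolerance
accuracy, one-vs-rest confusion matrices with sensitivity, specificity,
Cohen's kappa and Pearson chi-square, zone weight tables with paired t-tests,
cohort-level descriptives, and the closed-form effect of a fractional
correction factor ``f`` on all of them:

    d' = (1 - f) * d - 100 * f        (percent-difference scale)
    B' = (1 - f) * B                  (weight scale)
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import IpwetError, OutOfRangeError
from .tape import (
    TapeSpec,
    _height_zone_indices,
    _weight_zone_indices,
    predicted_weight,
)

__all__ = [
    "PercentDifferenceSummary",
    "ZoneConfusion",
    "ZoneMetrics",
    "ZoneWeightSummary",
    "CohortSummary",
    "percent_difference",
    "summarize_percent_difference_by_zone",
    "corrected_summary",
    "within_tolerance_accuracy",
    "confusion_by_zone",
    "zone_metrics",
    "pooled_sensitivity",
    "zone_weight_table",
    "cohort_summary",
]


# ---------------------------------------------------------------------------
# Percent differences
# ---------------------------------------------------------------------------

def percent_difference(predicted, actual):
    """Directed percent difference 100*(predicted - actual)/actual.

    Positive = overestimation.  ``actual`` must be strictly positive.
    Accepts scalars or arrays.
    """
    pred = np.asarray(predicted, dtype=float)
    act = np.asarray(actual, dtype=float)
    if np.any(~(act > 0)):
        raise OutOfRangeError("actual weight must be strictly positive")
    out = 100.0 * (pred - act) / act
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PercentDifferenceSummary:
    """Per-zone mean/SD of the directed percent difference."""

    zone: str
    n: int
    mean_d: float
    sd_d: float
    degenerate: bool = False  # single-child zone: SD reported as 0


def _zone_indices_checked(cohort: pd.DataFrame, tape: TapeSpec) -> np.ndarray:
    h = cohort["height_cm"].to_numpy(dtype=float)
    idx = _height_zone_indices(h, tape)
    if np.any(idx < 0):
        ids = cohort.loc[idx < 0, "child_id"].astype(str).tolist()
        raise OutOfRangeError(
            f"children outside tape {tape.tape_name!r} height range: {ids}"
        )
    return idx


def _percent_differences(cohort: pd.DataFrame, tape: TapeSpec) -> np.ndarray:
    b = predicted_weight(cohort["height_cm"].to_numpy(dtype=float), tape)
    return percent_difference(b, cohort["weight_kg"].to_numpy(dtype=float))


def summarize_percent_difference_by_zone(
    cohort: pd.DataFrame, tape: TapeSpec
) -> tuple[list[PercentDifferenceSummary], PercentDifferenceSummary]:
    """Mean/SD of d per height zone, plus the overall (all-children) row.

    The overall row's mean is the plain mean of all d_i, which equals the
    n-weighted mean of the zone means.  SDs use the sample (n-1) denominator;
    single-child zones report SD 0 with ``degenerate=True``.
    """
    idx = _zone_indices_checked(cohort, tape)
    d = _percent_differences(cohort, tape)
    rows = []
    for i, name in enumerate(tape.zone_names):
        di = d[idx == i]
        if di.size == 0:
            continue
        rows.append(
            PercentDifferenceSummary(
                zone=name,
                n=int(di.size),
                mean_d=float(di.mean()),
                sd_d=float(di.std(ddof=1)) if di.size > 1 else 0.0,
                degenerate=di.size == 1,
            )
        )
    overall = PercentDifferenceSummary(
        zone="total",
        n=int(d.size),
        mean_d=float(d.mean()),
        sd_d=float(d.std(ddof=1)) if d.size > 1 else 0.0,
        degenerate=d.size == 1,
    )
    return rows, overall


def corrected_summary(
    summary: PercentDifferenceSummary, f: float
) -> PercentDifferenceSummary:
    """Exact effect of scaling predictions by (1 - f) on a d-summary.

    Since d'_i = 100*((1-f)B_i - A_i)/A_i = (1-f)d_i - 100f for every child,
    the zone mean maps to (1-f)*mean - 100f and the SD to (1-f)*sd.
    """
    if not 0.0 <= f < 1.0:
        raise IpwetError(f"correction fraction must lie in [0, 1), got {f}")
    return replace(
        summary,
        mean_d=(1.0 - f) * summary.mean_d - 100.0 * f,
        sd_d=(1.0 - f) * summary.sd_d,
    )


def within_tolerance_accuracy(
    cohort: pd.DataFrame, tape: TapeSpec, tol: float = 0.10
) -> tuple[float, dict[str, float]]:
    """Fraction of children with |d| <= 100*tol, overall and per height zone."""
    if not tol > 0:
        raise IpwetError("tolerance must be > 0")
    idx = _zone_indices_checked(cohort, tape)
    d = _percent_differences(cohort, tape)
    hit = np.abs(d) <= 100.0 * tol
    per_zone = {
        name: float(hit[idx == i].mean())
        for i, name in enumerate(tape.zone_names)
        if np.any(idx == i)
    }
    return float(hit.mean()), per_zone


# ---------------------------------------------------------------------------
# Zone agreement: confusion, Se/Sp/kappa/chi-square
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZoneConfusion:
    """One-vs-rest 2x2 counts for one zone.

    Condition positive: actual weight in the zone's weight range.  Test
    positive: measured height assigned to the zone.  Children whose weight
    falls outside every weight range are condition-negative for every zone.
    """

    zone: str
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_by_zone(
    cohort: pd.DataFrame, tape: TapeSpec
) -> tuple[list[ZoneConfusion], int]:
    """Per-zone one-vs-rest confusion counts.

    Returns the list of per-zone counts (every zone of the tape, in order)
    and the number of children whose actual weight was unclassifiable (in a
    weight gap or off the tape) and therefore condition-negative everywhere.
    """
    hz = _zone_indices_checked(cohort, tape)
    w = cohort["weight_kg"].to_numpy(dtype=float)
    wz = _weight_zone_indices(w, tape)
    out = []
    for i, name in enumerate(tape.zone_names):
        test = hz == i
        cond = wz == i
        out.append(
            ZoneConfusion(
                zone=name,
                tp=int(np.sum(test & cond)),
                fp=int(np.sum(test & ~cond)),
                fn=int(np.sum(~test & cond)),
                tn=int(np.sum(~test & ~cond)),
            )
        )
    return out, int(np.sum(wz < 0))


@dataclass(frozen=True)
class ZoneMetrics:
    """Sensitivity, specificity, Cohen's kappa and chi-square p for a zone.

    A metric whose margin is empty is reported as ``None`` (undefined), never
    as NaN.
    """

    zone: str
    n: int
    sensitivity: float | None
    specificity: float | None
    kappa: float | None
    chi2_p: float | None


def zone_metrics(confusion: ZoneConfusion) -> ZoneMetrics:
    """Standard 2x2 diagnostic metrics for one zone.

    Se = tp/(tp+fn); Sp = tn/(fp+tn); kappa = (p_o - p_e)/(1 - p_e) with
    p_o = (tp+tn)/N and p_e from the margins; chi-square is Pearson without
    continuity correction, p from the 1-df distribution.  Kappa is defined
    as 1 for perfect agreement even when p_e = 1 (all mass in one cell).
    """
    tp, fp, fn, tn = confusion.tp, confusion.fp, confusion.fn, confusion.tn
    n = confusion.n
    se = tp / (tp + fn) if (tp + fn) > 0 else None
    sp = tn / (fp + tn) if (fp + tn) > 0 else None
    kappa = None
    chi2_p = None
    r1, r0 = tp + fp, fn + tn  # test margins
    c1, c0 = tp + fn, fp + tn  # condition margins
    if n > 0:
        p_o = (tp + tn) / n
        p_e = (r1 * c1 + r0 * c0) / (n * n)
        if p_e < 1.0:
            kappa = (p_o - p_e) / (1.0 - p_e)
        elif p_o == 1.0:
            kappa = 1.0
    if min(r1, r0, c1, c0) > 0:
        expected = np.array([r1 * c1, r1 * c0, r0 * c1, r0 * c0]) / n
        observed = np.array([tp, fp, fn, tn])
        chi2 = float(np.sum((observed - expected) ** 2 / expected))
        chi2_p = float(stats.chi2.sf(chi2, df=1))
    return ZoneMetrics(
        zone=confusion.zone,
        n=n,
        sensitivity=se,
        specificity=sp,
        kappa=kappa,
        chi2_p=chi2_p,
    )


def pooled_sensitivity(confusions: Sequence[ZoneConfusion]) -> float:
    """Zone-match sensitivity pooled over zones: sum tp / sum (tp+fn).

    Equals the match fraction among weight-classifiable children.
    """
    tp = sum(c.tp for c in confusions)
    pos = sum(c.tp + c.fn for c in confusions)
    if pos == 0:
        raise IpwetError("no weight-classifiable children to pool over")
    return tp / pos


# ---------------------------------------------------------------------------
# Zone weight table (measured vs predicted vs corrected)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZoneWeightSummary:
    """Per-zone means/SDs of measured, predicted and corrected weights."""

    zone: str
    n: int
    mean_measured: float
    sd_measured: float
    mean_predicted: float
    sd_predicted: float
    mean_corrected: float
    sd_corrected: float
    p_uncorrected: float | None  # paired t, measured vs predicted
    p_corrected: float | None  # paired t, measured vs (1-f)*predicted


def zone_weight_table(
    cohort: pd.DataFrame, tape: TapeSpec, f: float
) -> list[ZoneWeightSummary]:
    """Per height zone: A, B and (1-f)*B summaries with paired t-tests.

    The corrected weight is computed per child then averaged, so exactly
    mean_corrected = (1-f)*mean_predicted and sd_corrected =
    (1-f)*sd_predicted.  Zones with n < 2 report the t-test p-values as
    ``None`` (undefined).
    """
    if not 0.0 <= f < 1.0:
        raise IpwetError(f"correction fraction must lie in [0, 1), got {f}")
    idx = _zone_indices_checked(cohort, tape)
    a = cohort["weight_kg"].to_numpy(dtype=float)
    b = predicted_weight(cohort["height_cm"].to_numpy(dtype=float), tape)
    c = (1.0 - f) * b
    rows = []
    for i, name in enumerate(tape.zone_names):
        m = idx == i
        if not np.any(m):
            continue
        ai, bi, ci = a[m], b[m], c[m]
        n = int(m.sum())
        if n >= 2 and (np.std(ai - bi) > 0 or not np.allclose(ai, bi)):
            p_unc = float(stats.ttest_rel(ai, bi).pvalue)
            p_cor = float(stats.ttest_rel(ai, ci).pvalue)
        elif n >= 2:
            p_unc = p_cor = 1.0  # identical pairs: no evidence of difference
        else:
            p_unc = p_cor = None
        sd = lambda x: float(np.std(x, ddof=1)) if n > 1 else 0.0
        rows.append(
            ZoneWeightSummary(
                zone=name,
                n=n,
                mean_measured=float(ai.mean()),
                sd_measured=sd(ai),
                mean_predicted=float(bi.mean()),
                sd_predicted=sd(bi),
                mean_corrected=float(ci.mean()),
                sd_corrected=sd(ci),
                p_uncorrected=p_unc,
                p_corrected=p_cor,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# Cohort descriptives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level moments, correlations and per-sex regression fit."""

    n: int
    mean_age: float
    sd_age: float
    mean_height: float
    sd_height: float
    mean_weight: float
    sd_weight: float
    mean_predicted: float
    sd_predicted: float
    mean_d: float
    sd_d: float
    corr_weight_height: float
    corr_weight_predicted: float
    corr_height_predicted: float
    corr_weight_age: float
    r2_by_sex: dict[str, float]


def cohort_summary(cohort: pd.DataFrame, tape: TapeSpec) -> CohortSummary:
    """Descriptive statistics of a cohort against a tape (needs n >= 3)."""
    if len(cohort) < 3:
        raise IpwetError("cohort_summary needs at least 3 children")
    _zone_indices_checked(cohort, tape)
    h = cohort["height_cm"].to_numpy(dtype=float)
    a = cohort["weight_kg"].to_numpy(dtype=float)
    age = cohort["age_months"].to_numpy(dtype=float)
    b = predicted_weight(h, tape)
    d = percent_difference(b, a)

    def corr(x, y):
        if np.std(x) == 0 or np.std(y) == 0:
            return float("nan")
        return float(np.corrcoef(x, y)[0, 1])

    r2 = {}
    for sex in ("M", "F"):
        m = (cohort["sex"] == sex).to_numpy()
        if m.sum() >= 3 and np.std(h[m]) > 0:
            fit = stats.linregress(h[m], a[m])
            r2[sex] = float(fit.rvalue**2)
    sd = lambda x: float(np.std(x, ddof=1))
    return CohortSummary(
        n=len(cohort),
        mean_age=float(age.mean()),
        sd_age=sd(age),
        mean_height=float(h.mean()),
        sd_height=sd(h),
        mean_weight=float(a.mean()),
        sd_weight=sd(a),
        mean_predicted=float(b.mean()),
        sd_predicted=sd(b),
        mean_d=float(d.mean()),
        sd_d=sd(d),
        corr_weight_height=corr(a, h),
        corr_weight_predicted=corr(a, b),
        corr_height_predicted=corr(h, b),
        corr_weight_age=corr(a, age),
        r2_by_sex=r2,
    )
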