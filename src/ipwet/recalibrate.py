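"""Tape recalibration pipeline.

Given a derivation cohort and a base tape, the pipeline

1. estimates the *correction factor*: the overall mean directed percent
   difference, truncated toward zero to an integer percent;
2. optionally scales the base tape's weight ranges down by that factor;
3. re-bins the zone *height* boundaries from per-zone confidence intervals
   of the measured heights (interior boundaries are midpoints between
   adjacent zones' interval edges, outer boundaries cover the observed
   height range);
4. derives new *weight* ranges by regressing actual weight on height (a
   Gaussian GLM with identity link is exactly OLS) and evaluating the fit
   at the new height boundaries, snapping to a half-kilogram grid.  Because
   pediatric weight-for-height is convex, the pipeline fits the model
   *locally* around each boundary (on the two adjacent zones) rather than
   once globally; a single global line misses both ends of the tape badly
   enough to undo the recalibration's benefit (see docs/methods.md);
5. assembles the recalibrated tape and an audit trail.

A separate helper plans the validation sample size from a two-proportion
power computation, and ``validate_tape`` scores any cohort(s) against any
tape, pooling confusion counts across cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import IpwetError, RecalibrationError
from .metrics import (
    ZoneConfusion,
    ZoneMetrics,
    confusion_by_zone,
    pooled_sensitivity,
    zone_metrics,
    _percent_differences,
    _zone_indices_checked,
)
from .tape import ColorZone, TapeSpec

__all__ = [
    "CorrectionFactor",
    "RegressionFit",
    "RecalibrationResult",
    "SampleSizePlan",
    "ValidationReport",
    "estimate_correction_factor",
    "apply_correction",
    "rebin_heights",
    "fit_height_weight_regression",
    "boundary_regressions",
    "derive_weight_ranges",
    "recalibrate_tape",
    "sample_size_plan",
    "validate_tape",
]


# ---------------------------------------------------------------------------
# Correction factor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrectionFactor:
    """Overall mean percent difference and its truncated integer form."""

    raw_mean_pct: float
    f_pct: int

    @property
    def f(self) -> float:
        """The factor as a fraction (f_pct / 100)."""
        return self.f_pct / 100.0

    @classmethod
    def from_raw_mean(cls, raw_mean_pct: float) -> "CorrectionFactor":
        """Truncate (toward zero, not round) the raw mean to a whole percent.

        Only overestimation is correctable: raw means at or below -1% (the
        tape *under*estimating) have no admissible factor and raise; raw
        means above 50% are rejected as implausible.
        """
        f_pct = math.trunc(raw_mean_pct)
        if f_pct < 0:
            raise RecalibrationError(
                f"mean percent difference {raw_mean_pct:.2f} indicates "
                "underestimation; no correction factor is defined"
            )
        if f_pct > 50:
            raise RecalibrationError(
                f"correction factor {f_pct}% exceeds the supported range"
            )
        return cls(raw_mean_pct=float(raw_mean_pct), f_pct=f_pct)


def estimate_correction_factor(
    cohort: pd.DataFrame, tape: TapeSpec
) -> CorrectionFactor:
    """Overall mean of 100*(B-A)/A over the cohort, truncated to an integer %."""
    if len(cohort) == 0:
        raise RecalibrationError("cannot estimate a factor from an empty cohort")
    d = _percent_differences(cohort, tape)
    return CorrectionFactor.from_raw_mean(float(d.mean()))


def apply_correction(tape: TapeSpec, f: float) -> TapeSpec:
    """Scale every zone's weight range by (1 - f); heights unchanged."""
    if not 0.0 <= f < 1.0:
        raise IpwetError(f"correction fraction must lie in [0, 1), got {f}")
    zones = tuple(
        ColorZone(
            name=z.name,
            height_lo=z.height_lo,
            height_hi=z.height_hi,
            weight_lo=(1.0 - f) * z.weight_lo,
            weight_hi=(1.0 - f) * z.weight_hi,
        )
        for z in tape.zones
    )
    return TapeSpec(f"{tape.tape_name}_corrected_{round(f * 100)}pct", zones)


# ---------------------------------------------------------------------------
# Height re-binning
# ---------------------------------------------------------------------------

def rebin_heights(
    cohort: pd.DataFrame, tape: TapeSpec, ci_level: float = 0.95
) -> tuple[list[tuple[float, float]], dict]:
    """New reference height intervals from per-zone CIs of measured heights.

    Step 1: per height zone, the normal-approximation interval
    mean +/- z(ci_level) * sd / sqrt(n) of the measured heights.
    Step 2: interval edges of adjacent zones rarely meet, so each interior
    boundary is the midpoint between zone i's upper and zone i+1's lower
    interval edge.  Step 3: the outer boundaries are extended to the
    cohort's observed height range, rounded outward to whole centimetres.
    The result is a strict partition with one interval per zone; the audit
    records the raw CIs and every adjustment.
    """
    if not 0.0 < ci_level < 1.0:
        raise RecalibrationError("ci_level must lie in (0, 1)")
    idx = _zone_indices_checked(cohort, tape)
    h = cohort["height_cm"].to_numpy(dtype=float)
    z = float(stats.norm.ppf(0.5 + ci_level / 2.0))
    per_zone = []
    for i, name in enumerate(tape.zone_names):
        hi_ = h[idx == i]
        if hi_.size < 2:
            raise RecalibrationError(
                f"zone {name!r} has {hi_.size} child(ren); re-binning needs "
                "at least 2 per zone"
            )
        m, s = float(hi_.mean()), float(hi_.std(ddof=1))
        half = z * s / math.sqrt(hi_.size)
        per_zone.append(
            {
                "zone": name,
                "n": int(hi_.size),
                "mean": m,
                "sd": s,
                "ci_lo": m - half,
                "ci_hi": m + half,
            }
        )
    k = len(per_zone)
    boundaries = np.empty(k + 1)
    boundaries[0] = math.floor(h.min())
    boundaries[-1] = math.ceil(h.max())
    for i in range(1, k):
        boundaries[i] = 0.5 * (per_zone[i - 1]["ci_hi"] + per_zone[i]["ci_lo"])
    if np.any(np.diff(boundaries) <= 0):
        raise RecalibrationError(
            "re-binned boundaries are not strictly increasing; zone height "
            "distributions overlap too strongly"
        )
    intervals = [
        (float(boundaries[i]), float(boundaries[i + 1])) for i in range(k)
    ]
    audit = {
        "ci_level": ci_level,
        "per_zone": per_zone,
        "observed_range": [float(h.min()), float(h.max())],
        "boundaries": boundaries.tolist(),
    }
    return intervals, audit


# ---------------------------------------------------------------------------
# Height-weight regression and weight ranges
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of actual weight (kg) on height (cm)."""

    intercept: float
    slope: float
    r2: float

    def predict(self, h) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(h, dtype=float)


def fit_height_weight_regression(cohort: pd.DataFrame) -> RegressionFit:
    """Ordinary least squares of measured weight on measured height."""
    if len(cohort) < 3:
        raise RecalibrationError("regression needs at least 3 children")
    h = cohort["height_cm"].to_numpy(dtype=float)
    w = cohort["weight_kg"].to_numpy(dtype=float)
    if np.std(h) == 0:
        raise RecalibrationError("regression needs height variance > 0")
    fit = stats.linregress(h, w)
    return RegressionFit(
        intercept=float(fit.intercept),
        slope=float(fit.slope),
        r2=float(fit.rvalue**2),
    )


def boundary_regressions(
    cohort: pd.DataFrame,
    height_intervals: Sequence[tuple[float, float]],
) -> list[RegressionFit]:
    """One local weight-on-height OLS fit per height boundary.

    For boundary ``j`` the fit uses the children whose heights fall in the
    two intervals adjacent to it (one interval at the tape's ends), so each
    evaluated boundary weight tracks the local, not global, weight-for-height
    slope.
    """
    h = cohort["height_cm"].to_numpy(dtype=float)
    w = cohort["weight_kg"].to_numpy(dtype=float)
    k = len(height_intervals)
    fits = []
    for j in range(k + 1):
        lo = height_intervals[max(j - 1, 0)][0]
        hi = height_intervals[min(j, k - 1)][1]
        m = (h >= lo) & (h <= hi)
        if m.sum() < 3 or np.std(h[m]) == 0:
            raise RecalibrationError(
                f"too few children ({int(m.sum())}) around boundary "
                f"{j} ({lo}-{hi} cm) for a local fit"
            )
        f = stats.linregress(h[m], w[m])
        fits.append(
            RegressionFit(
                intercept=float(f.intercept),
                slope=float(f.slope),
                r2=float(f.rvalue**2),
            )
        )
    return fits


def derive_weight_ranges(
    fit: RegressionFit | Sequence[RegressionFit],
    height_intervals: Sequence[tuple[float, float]],
    grid: float = 0.5,
) -> tuple[list[tuple[float, float]], dict]:
    """Weight range per zone from the regression fit(s) at the zone boundaries.

    ``fit`` is either one global fit, evaluated at every height boundary, or
    a sequence of ``len(height_intervals) + 1`` local fits (one per
    boundary, see :func:`boundary_regressions`), each evaluated at its own
    boundary.  Each resulting weight edge is snapped to the nearest ``grid``
    (half-kilogram) step, with a floor of one grid step so bounds stay
    positive.  Zone i's range is [edge_i, edge_{i+1}) — upper bound shared
    with the next zone's lower, so the ranges are contiguous and monotone by
    construction.
    """
    for (lo, hi), (lo2, _) in zip(height_intervals, height_intervals[1:]):
        if not math.isclose(hi, lo2, abs_tol=1e-9):
            raise RecalibrationError("height intervals must form a partition")
    bounds = [height_intervals[0][0]] + [hi for _, hi in height_intervals]
    if isinstance(fit, RegressionFit):
        if fit.slope <= 0:
            raise RecalibrationError(
                f"non-increasing height-weight fit (slope {fit.slope}); "
                "cannot derive weight ranges"
            )
        raw = fit.predict(bounds)
    else:
        fits = list(fit)
        if len(fits) != len(bounds):
            raise RecalibrationError(
                f"need one fit per boundary ({len(bounds)}), got {len(fits)}"
            )
        raw = np.array([f.predict(b) for f, b in zip(fits, bounds)])
        if np.any(np.diff(raw) <= 0):
            raise RecalibrationError(
                "local boundary fits produce non-increasing weight edges"
            )
    snapped = np.maximum(np.round(raw / grid) * grid, grid)
    if np.any(np.diff(snapped) <= 0):
        raise RecalibrationError(
            "snapped weight edges collide; zones too narrow for the "
            f"{grid} kg grid"
        )
    ranges = [
        (float(snapped[i]), float(snapped[i + 1]))
        for i in range(len(height_intervals))
    ]
    audit = {
        "height_boundaries": [float(b) for b in bounds],
        "pre_rounding_weights": raw.tolist(),
        "snapped_weights": snapped.tolist(),
        "grid": grid,
    }
    return ranges, audit


# ---------------------------------------------------------------------------
# End-to-end recalibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecalibrationResult:
    correction: CorrectionFactor
    reference_heights: list[tuple[float, float]]
    fit: RegressionFit
    new_tape: TapeSpec
    audit: list[dict]


def recalibrate_tape(
    cohort: pd.DataFrame,
    base_tape: TapeSpec,
    ci_level: float = 0.95,
    tape_name: str | None = None,
) -> RecalibrationResult:
    """Run the full pipeline on a (pre-filtered) derivation cohort.

    Chains correction-factor estimation, height re-binning, the
    height-weight regression and weight-range derivation, and assembles a
    new tape with the base tape's zone names.  Stage failures are re-raised
    with the stage name attached; the audit has one entry per stage.
    """
    audit: list[dict] = []

    def stage(name, fn):
        try:
            return fn()
        except IpwetError as exc:
            raise RecalibrationError(f"stage {name!r}: {exc}") from exc

    correction = stage(
        "correction_factor", lambda: estimate_correction_factor(cohort, base_tape)
    )
    audit.append(
        {
            "stage": "correction_factor",
            "raw_mean_pct": correction.raw_mean_pct,
            "f_pct": correction.f_pct,
        }
    )
    intervals, rebin_audit = stage(
        "rebin_heights", lambda: rebin_heights(cohort, base_tape, ci_level)
    )
    audit.append({"stage": "rebin_heights", **rebin_audit})
    fit = stage("regression", lambda: fit_height_weight_regression(cohort))
    audit.append(
        {
            "stage": "regression",
            "intercept": fit.intercept,
            "slope": fit.slope,
            "r2": fit.r2,
        }
    )
    local_fits = stage(
        "boundary_regressions", lambda: boundary_regressions(cohort, intervals)
    )
    audit.append(
        {
            "stage": "boundary_regressions",
            "fits": [
                {"intercept": f.intercept, "slope": f.slope, "r2": f.r2}
                for f in local_fits
            ],
        }
    )
    ranges, range_audit = stage(
        "weight_ranges", lambda: derive_weight_ranges(local_fits, intervals)
    )
    audit.append({"stage": "weight_ranges", **range_audit})
    zones = tuple(
        ColorZone(name, h_lo, h_hi, w_lo, w_hi)
        for name, (h_lo, h_hi), (w_lo, w_hi) in zip(
            base_tape.zone_names, intervals, ranges
        )
    )
    name = tape_name or f"{base_tape.tape_name}_recalibrated"
    new_tape = stage("assemble", lambda: TapeSpec(name, zones))
    audit.append({"stage": "assemble", "tape_name": name, "n_zones": len(zones)})
    return RecalibrationResult(
        correction=correction,
        reference_heights=intervals,
        fit=fit,
        new_tape=new_tape,
        audit=audit,
    )


# ---------------------------------------------------------------------------
# Validation-phase helpers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleSizePlan:
    alpha: float
    power: float
    p_baseline: float
    p_target: float
    n_per_zone: int
    n_zones: int

    @property
    def n_total(self) -> int:
        return self.n_per_zone * self.n_zones


def sample_size_plan(
    alpha: float = 0.05,
    power: float = 0.80,
    n_zones: int = 9,
    overlap_exclusion: float = 0.20,
    detectable_difference: float = 0.25,
) -> SampleSizePlan:
    """Per-zone validation sample size from a two-proportion power formula.

    Zone membership overlaps into neighbouring zones near the boundaries;
    excluding a fraction ``overlap_exclusion`` of each zone on both sides
    leaves a middle core of share ``1 - 2*overlap_exclusion``, which is
    taken as the baseline per-zone match proportion.  The plan sizes each
    zone to detect an improvement of ``detectable_difference`` over that
    baseline with a two-sided normal-approximation test.
    """
    if not 0.0 < alpha < 1.0:
        raise IpwetError("alpha must lie in (0, 1)")
    if not 0.0 < power < 1.0:
        raise IpwetError("power must lie in (0, 1)")
    if not 0.0 < overlap_exclusion < 0.5:
        raise IpwetError("overlap_exclusion must lie in (0, 0.5)")
    if n_zones < 1:
        raise IpwetError("n_zones must be >= 1")
    p1 = 1.0 - 2.0 * overlap_exclusion
    p2 = min(p1 + detectable_difference, 0.99)
    if p2 <= p1:
        raise IpwetError("detectable difference must be positive")
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(power)
    pbar = 0.5 * (p1 + p2)
    num = z_a * math.sqrt(2.0 * pbar * (1.0 - pbar)) + z_b * math.sqrt(
        p1 * (1.0 - p1) + p2 * (1.0 - p2)
    )
    n = math.ceil((num / (p2 - p1)) ** 2)
    return SampleSizePlan(
        alpha=alpha,
        power=power,
        p_baseline=p1,
        p_target=p2,
        n_per_zone=n,
        n_zones=n_zones,
    )


@dataclass(frozen=True)
class ValidationReport:
    tape_name: str
    per_cohort: list[list[ZoneMetrics]]
    pooled_confusions: list[ZoneConfusion]
    pooled: list[ZoneMetrics]
    pooled_sensitivity: float
    n_total: int


def validate_tape(
    cohorts: pd.DataFrame | Sequence[pd.DataFrame], tape: TapeSpec
) -> ValidationReport:
    """Per-zone diagnostic metrics for one or more cohorts against a tape.

    With several cohorts, pooled metrics are computed from summed confusion
    counts (not by averaging the per-cohort statistics).
    """
    if isinstance(cohorts, pd.DataFrame):
        cohorts = [cohorts]
    cohorts = [c for c in cohorts if len(c) > 0]
    if not cohorts:
        raise IpwetError("validate_tape needs at least one non-empty cohort")
    per_cohort = []
    pooled: dict[str, dict[str, int]] = {
        name: {"tp": 0, "fp": 0, "fn": 0, "tn": 0} for name in tape.zone_names
    }
    n_total = 0
    for c in cohorts:
        confusions, _ = confusion_by_zone(c, tape)
        per_cohort.append([zone_metrics(cf) for cf in confusions])
        for cf in confusions:
            for k in ("tp", "fp", "fn", "tn"):
                pooled[cf.zone][k] += getattr(cf, k)
        n_total += len(c)
    pooled_conf = [
        ZoneConfusion(zone=name, **pooled[name]) for name in tape.zone_names
    ]
    return ValidationReport(
        tape_name=tape.tape_name,
        per_cohort=per_cohort,
        pooled_confusions=pooled_conf,
        pooled=[zone_metrics(cf) for cf in pooled_conf],
        pooled_sensitivity=pooled_sensitivity(pooled_conf),
        n_total=n_total,
    )
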