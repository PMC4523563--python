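"""Evaluating a tape on a cohort: bias by zone, correction, agreement.

Computes the per-zone mean percent differences before and after an 8%
correction, the within-10% accuracy, and the per-zone diagnostic metrics
(sensitivity, specificity, Cohen's kappa).
"""

from ipwet import (
    CohortConfig,
    builtin_tape,
    corrected_summary,
    generate_cohort,
    summarize_percent_difference_by_zone,
    validate_tape,
    within_tolerance_accuracy,
)
from ipwet.reporting import percent_difference_frame, render_text, zone_metrics_frame

tape = builtin_tape("broselow_2007b")
cohort = generate_cohort(CohortConfig(n=769, seed=1))

rows, overall = summarize_percent_difference_by_zone(cohort, tape)
after = [corrected_summary(r, 0.08) for r in rows + [overall]]
print(render_text(
    percent_difference_frame(rows, overall, after),
    title="Percent difference by zone, before/after an 8% correction",
))

accuracy, _ = within_tolerance_accuracy(cohort, tape, tol=0.10)
print(f"within-10% accuracy: {accuracy:.3f}")
print("(fraction of children whose tape prediction is within 10% of their "
      "measured weight)\n")

report = validate_tape(cohort, tape)
print(render_text(zone_metrics_frame(report.pooled),
                  title="Per-zone agreement with the actual weight class"))
print(f"pooled zone-match sensitivity: {report.pooled_sensitivity:.3f}")
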