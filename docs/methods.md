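# Methods

## The problem and the model

A length-based weight-estimation tape partitions supine height (cm) into
nine ordered color zones, each paired with a weight range (kg). Reading the
tape at a measured height yields a predicted weight `B`; the child's
measured weight is `A`. All evaluation statistics derive from the directed
percent difference

    d = 100 · (B − A) / A,

positive when the tape overestimates. Some reports label the same quantity
"(actual − predicted)" with the opposite sign; the renderers print both
labels, computation uses the formula above throughout.

### Interval convention

Zones are half-open `[lo, hi)` in both height and weight, with the last zone
closed at the top. Printed upper edges of the form "64.99"/"8.49" are
canonicalized to exclusive bounds (65, 8.5), which turns the printed
contiguous ranges into a true partition and resolves the boundary shared in
print by the pink and red zones (66.5 cm belongs to red). The original
tape's printed integer weight bins (3–5, 6–7, …) are kept as printed, so
weights in inter-zone gaps are *unclassifiable*: such children are
condition-negative for every zone and are excluded from pooled sensitivity
denominators. The recalibrated tape's half-kilogram classification bins
(<6.5, 6.5–8.5, …) are contiguous; its integer "display" ranges seen in
print are treated as labels, not as the operative classification bins. The
printed orange bin edge 24.4 is read as 24.5 so the partition closes.

### Within-zone predicted weight

The physical tape prints a weight per length graduation, but only the zone
ranges are published. The package models the within-zone prediction as
linear interpolation between the zone's weight endpoints, rounded to 0.1 kg
(the tape's printed granularity; pass `rounding=None` for the exact
interpolant). This is the simplest model consistent with the zone ranges; it
is continuous within zones and monotone non-decreasing across the tape, and
every zone-level statistic depends on it only through zone means.

## The synthetic cohort generator

No raw study data are deposited, so every downstream stage is exercised on
synthetic cohorts that reproduce the derivation study's statistical
structure. Defaults are the study conditions: n = 769, ages 1 month–12
years, height 96.64 ± 26.06 cm, 52.9% boys, mean overestimation 8.49% with
percent-difference SD 14.59 (`bias_sd = 0.1459` on the fractional scale),
reference tape `broselow_2007b`.

Per child:

1. **Height** is drawn from a normal truncated to the tape's height range.
   The configured mean/SD describe the *observed* (post-truncation) cohort,
   so the parent normal's parameters are solved (scipy `truncnorm` moments +
   root find) so that the truncated distribution has exactly the configured
   moments; naive truncation of N(96.64, 26.06²) to [46, 146.5] would shrink
   the SD by ~14%.
2. **Weight** is `A = B/(1 + δ)` with `B` the tape prediction at the child's
   height and `δ ~ N(loc, bias_sd)`; this makes `d = 100·δ` exact by
   construction. Because the exclusion criteria (weight > tape maximum) clip
   the underestimated tail, the raw location would leave the kept cohort's
   mean `d` about 0.3 points above target; the generator therefore
   calibrates `loc` on the fixed draws until the kept sample mean lies in
   `[target, target + tol]`, `tol = max(0.02, 40/n)` percentage points. The
   window is one-sided so a bias configured at a whole percent truncates to
   that percent instead of sitting on the truncation knife edge.
3. **Age** is back-filled by inverting a monotone piecewise-linear
   height-for-age curve anchored at (1 mo, 54 cm), (12 mo, 75 cm),
   (60 mo, 109 cm), (144 mo, 149 cm), plus N(0, 6 months) noise, clipped to
   [1, 144]. Age feeds only descriptive statistics.
4. **Sex** is Bernoulli(`sex_ratio`). Heights are recorded to 0.1 cm and
   weights to 0.1 kg, the granularity of a tape and a digital scale.

Children violating the exclusion criteria are replaced so exactly n survive;
a single seeded PRNG stream makes the cohort (and its CSV) byte-reproducible.

**What the generator does not emulate**: real clinic height distributions
are mixtures (often bimodal), weight-for-height dispersion is
age- and sex-dependent, and growth references (WHO/IAP z-scores) are not
used. Passing tests therefore demonstrate that the *pipeline* recovers the
structure it is fed — bias magnitude, factor truncation, zone re-binning,
sensitivity gains — not that any particular real population has these
parameters.

## Evaluation statistics

- Per-zone summaries use the sample (n−1) SD; single-child zones report
  SD 0 with a degeneracy flag.
- Confusion matrices are one-vs-rest per zone: condition = actual weight in
  the zone's weight bin, test = height assigned to the zone. Se = tp/(tp+fn),
  Sp = tn/(fp+tn), Cohen's κ = (p_o − p_e)/(1 − p_e) from the 2×2 margins,
  χ² is Pearson **without** Yates continuity correction with p from the 1-df
  distribution; any metric with an empty margin is reported as undefined
  (`None`), never NaN. Rendered p-values floor at "<0.0005".
- Zone weight tables compute measured, predicted and `(1−f)`-corrected
  weights per child and then average, so `mean_corrected =
  (1−f)·mean_predicted` holds to machine precision; two-sided *paired*
  t-tests compare measured vs predicted and measured vs corrected (paired
  because both numbers belong to the same child; the alternative unpaired
  reading of the published tables is noted but not used).
- The correction transform on percent differences is the exact identity
  `d' = (1−f)·d − 100·f` per child, hence also on zone means and SDs.
  Published after-correction cells occasionally differ from the closed form
  by ±0.01–0.02 (per-child rounding before averaging); the tests compare at
  each cell's printed precision.

## Recalibration pipeline

1. **Correction factor**: the overall mean `d` truncated *toward zero* to an
   integer percent (8.49 → 8). Negative means at or below −1% (an
   underestimating tape) are rejected rather than given a negative factor.
2. **Height re-binning**: per zone, the normal-approximation interval
   `mean ± z(0.95)·sd/√n` of measured heights ("ANOVA" read as per-group
   interval estimation — only the interval edges are consumed). CI edges of
   adjacent zones do not meet, so each interior boundary becomes the
   midpoint between adjacent zones' interval edges, and the outer boundaries
   extend to the cohort's observed height range rounded outward to whole cm.
   This bridging rule is a reconstruction (the original report does not say
   how contiguity was enforced) and is fully logged in the audit trail.
3. **Weight ranges**: the "univariate generalized linear model" is a
   Gaussian GLM with identity link, i.e. ordinary least squares of weight on
   height. Pediatric weight-for-height is convex, so a *single global* line
   under-predicts both tape ends badly enough (≈1.5 kg at 50 cm, ≈30.5 kg at
   150 cm on study-structured cohorts) that a tape built from it loses
   zone-match sensitivity to the original in every seed tested. The pipeline
   therefore fits the model **locally around each boundary** (children of
   the two adjacent zones, ≥3 required) and evaluates each fit at its own
   boundary; the global fit is still computed and reported (its R² matches
   the published scatter fits, ~0.9). Boundary weights are snapped to the
   half-kilogram classification grid with a 0.5 kg floor; zone i's bin is
   `[edge_i, edge_{i+1})`, contiguous and monotone by construction.
   `derive_weight_ranges` accepts either form — one global fit or one fit
   per boundary.
4. **Validation**: any cohort(s) against any tape; with several cohorts the
   pooled metrics come from summed confusion counts, not averaged
   statistics (count-pooling is the only rule that makes the pooled
   sensitivity equal the pooled match fraction). Pooled zone-match
   sensitivity is Σtp / Σ(tp+fn).
5. **Sample-size plan**: a reconstruction (the original effect size is not
   stated). Excluding a fraction 0.20 of each zone on both sides leaves a
   middle 60% core, taken as the baseline per-zone match proportion
   p₁ = 0.60; the plan sizes each zone to detect a +0.25 improvement
   (p₂ = 0.85) with a two-sided two-proportion normal-approximation formula
   at α = 0.05, power 0.80 → 49 per zone, 441 total, satisfying the study's
   stated minimums of 40 and 360.

## Numerical choices and degenerate inputs

- Tolerances: zone contiguity compared at 1e-9; the generator's bias window
  `max(0.02, 40/n)` percentage points; truncated-normal moment matching to
  1e-6.
- Tie-breaks: shared printed boundaries belong to the upper zone (half-open
  rule); κ is defined as 1 when observed agreement is perfect even if
  p_e = 1.
- Degenerate inputs: empty cohorts, single-child zones, zero height
  variance, inverted or gapped zone ranges, and non-positive heights/weights
  all raise typed errors (`TapeValidationError`, `CohortFormatError`,
  `OutOfRangeError`, `RecalibrationError`) naming the offending zone, row or
  stage.
- Problem sizes: property checks (factor recovery, bias elimination, tape
  improvement) run on 20 seeded cohorts of n = 10,000; structural fuzzing
  uses 100 cohorts of n = 600–1,500 with biases 0–12% and realistic height
  moments. At the study's own n (769 derivation / 416 validation) the
  rebuilt tape's sensitivity gain (~+0.02–0.03) is of the same order as the
  validation sampling noise, so single-cohort comparisons at that size can
  go either way — as they can in a real replication.

## Known limitations

- Zone-exact sensitivities/specificities/κ of the original study are not
  reproducible without its raw data; the package reproduces the pipeline's
  structure and its qualitative conclusions on matched synthetic cohorts.
- The rebuilt tape's weight span tracks the *generated* population's curve
  (~3–33 kg under the default bias), not the published 4–36 kg endpoints,
  which reflect the original cohort's real anthropometry.
- The within-zone linear weight model and the single truncated-normal height
  distribution are simplifications; both are documented above.
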