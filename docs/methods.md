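# Methods

This note documents the models, rules and numerical choices implemented in
`actcomp`, the rationale behind design decisions that were genuinely open,
and what the synthetic-data tests do and do not establish about real data.

## Data model

The pipeline operates on gap-free streams of non-negative vertical-axis
activity counts at a fixed epoch length. Timestamps are naive local
wall-clock time; a "day" is a calendar date in that clock. Daylight-saving
shifts are not modelled — the analysis windows are wall-clock-defined, so a
naive clock is the faithful representation. Counts arriving at sub-minute
epochs (e.g. 1 s) are re-integrated to 60 s by exact integer summation
before any classification, because both the non-wear rule and the intensity
cut-points are defined on counts per minute (cpm). Which accelerometer axis
the counts come from is outside the package's control; the vertical axis is
assumed, matching the convention of the cut-point calibration used.

## Non-wear detection

A minute is non-wear when it lies inside an accepted bout:

* a bout is ≥ `window_min` (default **90**) consecutive sub-100-cpm minutes;
* at most `tolerance_min` (default **2**) of those minutes may be
  interruptions of 1–99 cpm, counted in total per bout (the stricter of the
  possible readings; configurable);
* every maximal interruption stretch must be flanked by ≥ `flank_min`
  (default **30**) consecutive zero-cpm minutes on both sides, inside the
  bout;
* a minute ≥ 100 cpm is always wear and terminates any bout. Tolerated
  interruption minutes inside an accepted bout are marked non-wear.

The implementation decomposes each maximal sub-100-cpm run into zero
segments and interruption groups and marks the union of all qualifying
stretches; the test suite checks it minute-for-minute against two
independently written brute-force window-enumeration scanners, including an
incremental one fast enough to run on 10,000 randomized series.

Bouts may span midnight: detection runs over the whole series, and minutes
are attributed to dates only afterwards, since wear physiology ignores
calendar boundaries.

## Validity and windows

A participant's week is valid with ≥ `min_wear_min` (default **480**) worn
minutes on ≥ 3 weekdays and ≥ 1 weekend day. Wear anywhere in the 24 h day
counts toward the 8 h — the criterion screens device compliance, not
window coverage, and the windows get their own per-segment minimum below.

Weekdays carry a morning [07:00, 13:00) and afternoon [13:00, 21:00) window;
weekend days a single [07:00, 21:00) window. Intervals are half-open: the
minute starting 12:59 is morning, the minute starting 13:00 is afternoon.

## Intensity classification and exposures

Cut-points default to ST ≤ 180, LPA 181–3360, MVPA ≥ 3361 cpm. The published
ranges ("< 180", "181–3360") leave cpm = 180 unassigned; it is mapped to ST,
closing the gap conservatively toward sedentary. All four bounds are
configurable but must remain contiguous so every cpm has exactly one
category.

Per (participant, date, window), worn minutes are counted per category and
expressed both as minutes and as proportions of worn time. A segment needs
≥ `min_segment_wear_min` (default **60**) worn minutes to be valid;
proportions from near-empty windows are statistically meaningless. Setting
the knob to 0 disables the guard (the literal behaviour when no per-segment
minimum is stated). Category minutes always partition worn minutes exactly,
and proportions sum to 1 up to 1e-12.

## Comparison units

Observation points pair a valid morning with a valid afternoon of the same
weekday; a girl-week summary pools worn minutes over all valid weekday
segments (reference) and all valid weekend segments (response), then
recomputes proportions. Pooling is wear-time weighted — minutes are summed
before dividing — because daily proportions of unequal-length windows are
not exchangeable; this is the one aggregation step where a
mean-of-daily-proportions convention would give (slightly) different
results. A summary requires ≥ 3 contributing weekday dates and ≥ 1 weekend
date; girls lacking a valid weekend day yield no week unit and are logged.

## The compensation rule

With PA = LPA + MVPA proportions, Δ = PA_response − PA_reference and
threshold t = z·σ̂ (z default **1.645**, a 90% band):

* ST_response < ST_reference (eligible positive): positive iff Δ > t;
* ST_response > ST_reference (eligible negative): under the default
  `paper_literal` variant, negative iff Δ < **+**t — the inequality with the
  threshold on the positive side, under which every eligible-negative unit
  with Δ ≤ 0 is negative. This asymmetry is deliberate: it is the rule as
  published, and its signature (all eligible-negative units with
  non-positive Δ classified negative) is preserved as an invariant. A
  `symmetric` variant (negative iff Δ < −t) is provided, never as default;
* exact ST ties: neither branch applies; eligibility "tie", label "none".

σ̂ is the sample SD (n−1) of PA_reference pooled across **all** valid units
of the analysis — one value per analysis, since the descriptive criterion is
applied cohort-wide. A within-girl SD reading is arithmetically impossible
for the week analysis (one unit per girl) and is not implemented. The rule
is homogeneous of degree 1, so proportions vs percentages with a matching
σ̂ rescale give identical labels (property-tested).

## Prevalence and descriptives

Percentages are computed from exact integer ratios and rounded half-up to
one decimal. Reported denominators are both all units and the
eligibility-restricted subsets (e.g. positive among eligible-positive).
Descriptive tables report mean (SD) per girl-averaged segment minutes and
participant covariates; a single contributing value yields SD 0 with an
explicit degeneracy flag rather than an error, so tiny cohorts run end to
end.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
raw biomechanics:

* seven consecutive days per girl, device "worn" 06:00–23:00 (configurable),
  zero counts overnight — which the non-wear detector then finds, exactly as
  in real data; an optional extra 95-minute evening bout is planted with
  probability `nonwear_bouts_per_day` (default **0.3**), always outside the
  analysis windows;
* within each window, minutes are scheduled from category counts and cpm is
  drawn from ranges strictly inside the categories (ST 0–150, LPA 300–3000,
  MVPA 3600–8000), so boundary conventions cannot flip a synthetic minute;
* all planted proportions live on a 1/120 grid. The windows are 360, 480
  and 840 minutes — all multiples of 120 — so grid proportions realise
  exactly as whole-minute schedules and the ground truth is exact at the
  level the classifier consumes;
* baseline profile ST/LPA/MVPA = 0.66/0.24/0.10 in every segment (weekday
  morning ST ≈ 66%, matching the magnitudes such cohorts report). Keeping
  the baselines equal across segments makes planted compensation the only
  systematic between-segment difference; a weekend sedentary elevation then
  emerges from the predominantly negative phenotype mix rather than being
  baked in;
* day-to-day jitter of SD `noise_sd` (default **0.02**) is applied to the
  reference period: weekday mornings draw independent jitter (so the
  observation analysis's implied reference SD *is* `noise_sd`), afternoons
  carry the planted shift exactly, and the two weekend days draw antithetic
  (mean-preserving) jitter around the planted weekly target so the pooled
  weekend aggregate carries the planted shift up to grid quantisation
  (< half a grid step);
* phenotypes (default mix positive/negative/none = 0.15/0.55/0.30, drawn
  independently for the weekday and weekend analyses) shift response-period
  PA by ± `effect_size` (default **3.0**) implied reference SDs, with ST
  absorbing the shift. A weekday "none" is an exact morning/afternoon tie;
  a weekend "none" cannot tie exactly (the weekday and weekend aggregates
  have incompatible minute denominators 4200 vs 1680), so it is planted as
  a sub-threshold PA increase of `none_shift_frac` (default **0.5**) times
  the planned threshold — which the classifier must also label "none";
* the week analysis's implied reference SD is computed analytically from
  the config (jitter averaged over five days plus the between-girl variance
  contributed by the weekday phenotype mix through the afternoon windows)
  and is verified empirically to within 20% on a 200-girl cohort;
* infeasible configurations — planted proportions outside (0, 1) — raise
  immediately rather than clip silently. All randomness flows from one
  seed; identical configs produce byte-identical files.

What passing recovery tests show: the pipeline's arithmetic, unit
construction and thresholding are correct, and phenotypes three reference
SDs strong are recovered essentially perfectly through the full
file-to-label path. What they do not show: performance on real data, where
baselines drift between segments, wear is ragged, jitter is not Gaussian or
independent, school/class clustering induces correlated behaviour, and
compensation is graded rather than planted. The generator also makes no
attempt at raw 30 Hz acceleration realism; counts are taken as given.

## Problem sizes and numerics

The standard verification runs use 200-girl cohorts for recovery (about
2 million minutes, a few seconds end to end), 50 girls for conservation
checks, and 10,000 block-structured random series of ≤ 200 minutes for
non-wear oracle equivalence. Proportion identities are asserted at 1e-12;
unit-triplet validation tolerates 1e-9 to absorb float division. Exact ST
ties are detected by float equality, which is safe here because equal
underlying rationals divide to identical IEEE doubles.

## Known limitations

* No imputation of non-wear periods and no alternative non-wear algorithms.
* No energy-expenditure modelling, no bouted-MVPA metrics, no
  vigorous-only category.
* No multilevel/Bayesian covariate modelling of the labels — the package
  ends at descriptive prevalence; its label CSVs are intended as input for
  such models elsewhere.
* Counts are accepted as produced by the device toolchain; the proprietary
  raw-to-counts step is out of scope.
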