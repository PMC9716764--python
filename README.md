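# actcomp

Accelerometer epoch processing and **compensatory physical-activity
behaviour (CPB)** classification for youth cohorts.

The ActivityStat hypothesis proposes that an imposed change of physical
activity in one timespan is offset in another, keeping overall activity
roughly stable. `actcomp` implements a complete, tested pipeline for the
descriptive version of that question in hip-worn accelerometer data from
schoolgirls: from raw per-epoch activity counts, through non-wear detection
and wear-time validity filtering, to time-of-day segmentation, cut-point
intensity classification, and a threshold rule that labels every comparison
unit as *positive*, *negative* or *no* compensation. Because raw cohort data
of this kind are typically shareable only on request, the package ships a
first-class synthetic-cohort generator with planted compensation phenotypes,
so every stage is testable end to end without any download.

It is aimed at physical-activity epidemiologists and methods researchers who
want a reproducible, scriptable implementation of this analysis (or a
simulation bench for it) rather than a GUI toolchain.

## The model

For each comparison unit, behaviour is summarised as proportions of worn
time spent in sedentary time (ST), light (LPA) and moderate-to-vigorous
(MVPA) physical activity, with active time PA = LPA + MVPA. Two designs are
built:

* **observation points** — one unit per weekday with a valid morning
  [07:00, 13:00) and afternoon [13:00, 21:00) segment (reference: morning,
  response: afternoon);
* **girl weeks** — one unit per girl, pooling worn minutes over valid
  weekdays (reference) and valid weekend days [07:00, 21:00) (response).

With Δ = PA_response − PA_reference and σ̂ the pooled sample SD of
PA_reference across all units of the analysis, the default rule is

* eligible positive (ST_response < ST_reference): **positive** iff
  Δ > 1.645 σ̂;
* eligible negative (ST_response > ST_reference): **negative** iff
  Δ < 1.645 σ̂ (the *literal* variant — note the threshold stays on the
  positive side, so any eligible-negative unit with Δ ≤ 0 is negative; a
  `symmetric` variant using −1.645 σ̂ is available);
* ties and sub-threshold units: **none**.

Upstream, non-wear is a Choi-style rule (≥ 90 min of zero cpm, up to 2
interruption minutes of 1–99 cpm each flanked by ≥ 30 zero minutes), a valid
week needs ≥ 8 h wear on ≥ 3 weekdays and ≥ 1 weekend day, and intensities
use youth hip cut-points ST ≤ 180 < LPA ≤ 3360 < MVPA cpm.

## Worked example

```python
from actcomp import classify_observation, generate_worked_example

units, expected, sd_ref = generate_worked_example()
for u in units:
    lb = classify_observation(u, sd_ref)
    print(f"{u.participant_id:17s} delta={lb.delta:+.3f} "
          f"threshold={lb.threshold:.5f} eligibility={lb.eligibility:17s} label={lb.label}")
```

prints

```
example_positive  delta=+0.200 threshold=0.08225 eligibility=eligible_positive label=positive
example_negative  delta=-0.150 threshold=0.08225 eligibility=eligible_negative label=negative
example_none      delta=+0.010 threshold=0.08225 eligibility=eligible_positive label=none
```

The first girl-day has less sedentary time in the afternoon and an active-time
increase of 20 percentage points — far beyond the 1.645 × 0.05 ≈ 8.2-point
threshold, hence positive compensation. The second is its mirror image
(negative). The third is eligible for positive compensation but the 1-point
increase is sub-threshold, hence no compensation.

The same pipeline runs from the shell:

```bash
actcomp simulate --config examples/cohort.yaml --out sim/
actcomp process  --input sim/  --out proc/
actcomp classify --input proc/ --out cls/
actcomp summarize --labels cls/labels.csv --out summary/ --plot
# or: actcomp run-all --config examples/cohort.yaml --out run/
```

Each stage materialises its outputs (epoch CSVs, per-segment exposure table,
per-unit labels with Δ, threshold and eligibility, prevalence JSON/CSV) and
writes the resolved configuration alongside for provenance.

## Layout

| Module | Role |
| --- | --- |
| `actcomp.accel_io` | epoch CSV read/write, epoch re-integration |
| `actcomp.preprocessing` | non-wear detection, day wear summaries, validity |
| `actcomp.exposure` | windows, cut-point classification, exposures |
| `actcomp.compensation` | comparison units and the CPB threshold rule |
| `actcomp.summaries` | prevalence reports, descriptive tables, plots |
| `actcomp.synthetic_data` | cohort generator with planted phenotypes |
| `actcomp.cli` | `actcomp` command (simulate/process/classify/summarize/run-all) |

See `docs/methods.md` for the full methodological account, including every
tunable parameter, the generator's design and its known limitations.
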