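# A small synthetic cohort plus default analysis settings.
cohort:
  n_girls: 20
  seed: 7
  # start_date: 2018-10-01        # any 7 consecutive days (5 weekdays + 2 weekend days)
  # epoch_length: 60              # 1 or 60 s
  # effect_size: 3.0              # planted |PA shift| in reference-sd units
  # noise_sd: 0.02                # day-to-day jitter of reference-period PA proportion
  # nonwear_bouts_per_day: 0.3    # probability of an extra evening non-wear bout
  # weekday_mix: {positive: 0.15, negative: 0.55, none: 0.30}
  # weekend_mix: {positive: 0.15, negative: 0.55, none: 0.30}

analysis:
  nonwear: {window_min: 90, tolerance_min: 2, flank_min: 30}
  validity: {min_wear_min: 480, min_weekdays: 3, min_weekend_days: 1}
  cuts: {sedentary_max: 180, light_min: 181, light_max: 3360, mvpa_min: 3361}
  exposure: {min_segment_wear_min: 60}
  threshold: {z: 1.645, variant: paper_literal}
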