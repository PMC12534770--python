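# Demonstration pipeline config: fully synthetic, desk-scale.
output_dir: climaffect_demo
seed: 42
exposure: extreme_hot
percentile_window: year
n_boot: 200
ci_level: 0.95
moderation_exposure: temp_change
moderation_moderator: season
simulate:
  n_regions: 4
  date_start: "2022-01-01"
  date_end: "2022-12-31"
  baseline_years: 5
  posts_per_region_day_mean: 3.0
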