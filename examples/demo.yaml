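# One config drives every stage; CLI flags override these values.
seed: 7
outdir: bvitals_out
simulation:
  n_participants: 20
  n_weeks: 16
  phq_waves: [2, 4, 6, 8, 10, 12, 14, 16]
  day_missing_prob: 0.0
  wave_missing_prob: 0.0
extraction:
  min_coverage: 0.0
  sleep:
    bridge_max_min: 20.0
    interruption_min_min: 2.0
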