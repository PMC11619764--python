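# bvitals

Passive-sensing behavioral features and between/within-person
mixed-effects models for repeatedly measured depressive symptoms
(PHQ-8), with a synthetic cohort generator for end-to-end validation.

Smartphones passively record location visits, step counts, activity
bouts and screen on/off events. From these streams the package derives
daily behavioral proxies for sleep (bedtime, wake time, time in bed,
interruptions), activity (step count, walking rate) and social
engagement (normalized location entropy, time at home, distances
traveled), summarizes them over the week preceding each biweekly PHQ-8
assessment, and asks two distinct questions with one model:

- **Who is at risk?** Does a person's *global* feature level
  `X̄_i` (their mean weekly feature across the study) predict their
  average symptom burden relative to other people?
- **When is a person at risk?** Does a weekly *deviation* from one's own
  global level, `ΔX_it = X_it − X̄_i`, track symptom changes within a
  person?

Both enter one linear mixed-effects model per feature,

    PHQ_it = β0 + βB·X̄_i + βW·ΔX_it + γ·covariates + b0_i + b1_i√t + ε_it,

fit by REML with a per-participant random intercept and √week slope,
Wald 95% CIs, and Nakagawa–Schielzeth marginal R² / ΔR² for the feature
block. It is aimed at digital-phenotyping and mental-health researchers
who need a tested, reproducible reference pipeline; since cohorts of
this kind are rarely deposited, a configurable synthetic study
generator (traits → daily features → event streams → PHQ-8) makes every
stage verifiable, including a round-trip guarantee that feature
extraction inverts event rendering.

## Worked example

Simulate the default 131-participant, 16-week study and fit the
wake-time-variability model:

```python
import bvitals as bv
from bvitals.model import build_design, fit_mixed_model, marginal_r2, delta_r2

cfg = bv.SimulationConfig(n_participants=131, seed=11)
study = bv.simulate_dataset(cfg, include_profiles=False)
data = build_design(study.triples, study.traits, study.phq, "wake_time", "sd")
full = fit_mixed_model(data)
reduced = fit_mixed_model(data, feature_terms=())
print(f"between B = {full.params['x_between']:.2f} "
      f"[{full.ci_low['x_between']:.2f}, {full.ci_high['x_between']:.2f}]")
print(f"within  B = {full.params['x_within']:.2f} "
      f"[{full.ci_low['x_within']:.2f}, {full.ci_high['x_within']:.2f}]")
print(f"marginal R2 = {marginal_r2(full):.3f}, delta R2 = {delta_r2(full, reduced):.3f}")
```

prints

```
between B = 0.81 [-0.44, 2.06]
within  B = 0.03 [-0.63, 0.69]
marginal R2 = 0.151, delta R2 = 0.006
```

Read: in this simulated cohort (generating between-effect 1.5 PHQ
points per hour of wake-time SD), people with one hour more global
wake-time variability score an estimated 0.81 PHQ-8 points higher than
other people (a single-cohort estimate whose CI covers the generating
value), weekly fluctuations of wake-time variability carry no
within-person signal (as generated), and the feature block adds ΔR² =
0.006 of explained variance over the covariates.

The same pipeline runs from the shell, stage by stage or end to end:

```bash
bvitals all --config examples/demo.yaml          # simulate → extract → aggregate → screen → report
bvitals fit --outdir out --feature step_count_k --statistic mean
```

`bvitals report` writes a markdown report with the missing-data audit,
the Spearman correlation screen of global features (pairs |r| ≥ 0.70
flagged), the 18-feature between/within table, and per-participant
figures overlaying PHQ-8 on weekly feature deviations.

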