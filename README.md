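# headcrit

Head injury criteria for vulnerable-road-user (VRU) impact accidents, and
their evaluation against recorded injury outcomes.

When a car strikes a pedestrian or cyclist, accident reconstruction yields
two kinds of signal: the head centre-of-gravity kinematics (linear and
rotational acceleration, rotational velocity) and — when a finite-element
brain model is coupled in — per-element strain and pressure histories of the
brain. A family of scalar criteria condenses these signals into injury
predictors:

* **kinematics-based** — HIC15, RIC, GAMBIT, HIP, BrIC;
* **deformation-based** — MPS (peak first principal strain), CSDM_0.15 /
  CSDM_0.25 (volume fraction ever straining past a threshold), DDM (volume
  fraction ever in tension past −100 kPa).

This package computes all eight from delimited time-history files, maps them
through configurable injury-risk curves, and evaluates their predictive
effectiveness against AIS/MAIS injury records via the sample Pearson
correlation

    r = Σ(Xᵢ−X̄)(Yᵢ−Ȳ) / √( Σ(Xᵢ−X̄)² · Σ(Yᵢ−Ȳ)² )

It ships the published tables of a 31-case car-to-VRU accident study
(case metadata, AIS/MAIS records, per-case criterion values, DAI and
contusion sub-tables) as checksum-verified fixtures, plus synthetic-data
generators (crash pulses, brain element fields, accident cohorts) with known
ground truth for everything the study did not release. The core definitions,
e.g. HIC15 with window endpoints on sample times,

    HIC15 = max over t2−t1 ≤ 15 ms of (t2−t1)·[ (1/(t2−t1)) ∫ a(t) dt ]^2.5,

are documented in [docs/methods.md](docs/methods.md).

## Worked example

Reproduce the study's correlation analysis from the packaged tables:

```python
>>> from headcrit import reproduce_table5
>>> report, cmp = reproduce_table5()
>>> print(cmp.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
criterion  r_computed  r_published  abs_diff
      HIC      0.6058       0.6060    0.0002
   GAMBIT      0.3316       0.3320    0.0004
     BrIC      0.3397       0.3400    0.0003
      RIC      0.3978       0.3980    0.0002
      HIP      0.4030       0.4030    0.0000
>>> report.ranking
('HIC', 'HIP', 'RIC', 'BrIC', 'GAMBIT')
```

Each row is the Pearson correlation between one criterion's 31 per-case
values and the 31 recorded head-injury MAIS scores; the computed
coefficients agree with the published ones to within 0.0004. The ranking
says HIC — the oldest, purely linear-acceleration criterion — tracks overall
head-injury severity best in this cohort, followed by head impact power;
the rotational criteria trail.

Criteria from a signal, with a generated pulse as the signal source:

```python
>>> from headcrit import PulseSpec, synth_pulse, compute_all_kinematic
>>> rec, truth = synth_pulse(PulseSpec(shape="constant", peak_lin=100.0,
...                                    peak_rot_acc=0.0, peak_rot_vel=0.0,
...                                    duration=0.020, dt=1e-4))
>>> [(r.name, round(r.value, 2)) for r in compute_all_kinematic(rec)]
[('HIC', 1500.0), ('GAMBIT', 0.29), ('BrIC', 0.0), ('RIC', 0.0), ('HIP', 86.61)]
```

A constant 100 g pulse held 20 ms gives HIC = 100^2.5 × 0.015 s = 1500
exactly — the generator's `truth["values"]["HIC"]` states the same closed
form, which is how the criteria are verified end to end.

## Analysis scripts

The `analysis/` directory holds numbered narrative drivers that write their
tables to `results/`:

1. `01_reproduce_correlations.py` — the correlation table above.
2. `02_verify_criteria_closed_forms.py` — criterion ops vs closed-form and
   high-resolution ground truth on three pulse shapes.
3. `03_deformation_metrics.py` — constructed-target CSDM/DDM checks and a
   summary of the packaged deformation sub-tables.
4. `04_risk_report.py` — predicted injury probabilities beside recorded AIS
   using the packaged (approximate) risk curves.

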