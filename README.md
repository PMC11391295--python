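# ritualsync

Interpersonal synchrony analysis for leader-led collective rituals, built
around the measurement setting of an Islamic congregational prayer
(*Salat al Jama'ah*): an imam performs repeated movement cycles (*Rak'ah*)
while worshippers, arranged in grids in two spatially separated spaces,
follow his movements. The package answers three questions from wearable
1 Hz recordings of body posture (degrees from vertical), heart rate (bpm)
and pairwise proximity (metres):

1. **Does the leader lead?** — diagonal cross-recurrence profiles give the
   lag at which each worshipper's signal trails the imam's.
2. **Is synchrony local?** — pair-category regressions and proximity-network
   models test whether neighbours synchronize more than distant or
   spatially separated pairs.
3. **Is it more than the ritual's script?** — Fourier phase-randomization
   surrogates give the chance-level baseline implied by each signal's own
   temporal structure.

It is aimed at researchers of interpersonal physiological/behavioural
coordination who want a tested, reproducible CRQA pipeline with an
explicit synthetic-data model standing in for (non-public) sensor data.

## Method

For each pair of z-scored series the pipeline performs continuous
cross-recurrence quantification analysis (CRQA). Each series is delay
embedded, `x_i = (x_i, x_{i+d}, …, x_{i+(m−1)d})`, with the delay `d`
chosen at the first local minimum of the average mutual information and
the dimension `m` by the false-nearest-neighbour criterion; a pair uses
the componentwise maximum of its two members' parameters. The
cross-recurrence plot is

    CR_{ij} = Θ(ε − ‖x_i − y_j‖),

with one global radius `ε` per signal type, bisection-calibrated so the
mean recurrence rate across all pairs sits in the 2–5% band. From the CRP
the pipeline reports **%REC** (share of recurrent points: overlap of the
two systems' visited states) and **%DET** (share of recurrent points on
diagonal runs of length ≥ 2: stability of the coupling), plus the
**DCRP** — recurrence per diagonal in a ±15 s band around the line of
synchrony, whose peak lag is positive when the first-listed series (the
imam) leads.

The statistical layer mirrors the study design: five pair categories
(imam + colocated, imam + non-colocated, neighbours, distant, separated =
reference) in OLS regressions; linear mixed models (pair random
intercept, REML) contrasting true against 10 phase-randomized surrogate
replicates; node-distance regressions on the ≤ 2 m proximity graph; a
one-sample t-test of imam lead lags; a Mann–Whitney comparison of
nearest-neighbour spacing between the two spaces; and questionnaire
summaries.

A seeded synthetic-session generator (`ritualsync.synthetic`) provides the
leader-driven, spatially structured data all of this is tested against —
see `docs/methods.md` for the generative model and its limits.

## Worked example

```python
from ritualsync import RunConfig, run_pipeline

result = run_pipeline(RunConfig(seed=1, out_dir="report"))
```

or, from a shell, `ritualsync analyze --out report --seed 1`. The same run
is scripted in `examples/full_pipeline.py`, which prints:

```
28 participants -> 378 pairs per signal; 10 surrogate replicates each
calibrated radii (z-units): posture 0.523, hr 0.897
mean %REC across true pairs: posture 3.51, hr 3.51 (calibration band 2-5%)
imam lead lag [posture]: mean 1.44 s, t(26) = 10.75, p = 4.58e-11 (significant)
imam lead lag [hr]: mean -0.56 s, t(26) = -0.60, p = 0.553 (not significant)
nearest-neighbour spacing, colocated vs separated: U = 115.0, p = 0.253 (similar arrangements in both spaces)
```

Reading: the global radii place the mean recurrence rate on the 3.5%
calibration target; the congregation's posture trails the imam by ~1.5 s
(strongly non-zero), while heart-rate leadership is not resolvable at this
sample size; the two prayer spaces have statistically indistinguishable
nearest-neighbour spacing. The emitted `report/` bundle contains the
per-pair metrics CSV, the DCRP table, all model tables (category,
surrogate-contrast, network), and a JSON manifest of every selected
parameter; every model number is recomputable from the pair-metrics CSV
alone. The other scripts in `examples/` each demonstrate one capability
(simulation, single-pair CRQA, lag profiling, surrogate baselines,
proximity gradients).

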