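# Methods

This note documents the models and numerical choices behind `ritualsync`:
the synthetic session generator, the CRQA stack, the surrogate baseline,
the network layer, and the statistical models. It states defaults, units,
and the reasoning behind choices that were genuinely open.

## 1. The synthetic session generator

The generator (`ritualsync.synthetic`) emulates wearable recordings of a
congregational prayer well enough that every downstream stage — embedding,
radius calibration, DCRP lag profiling, surrogate contrasts, network
gradients — can be exercised and validated without access to sensor data.
It is a first-class, tested component, not a fixture.

### Movement model

The imam's posture trace cycles through the Rak'ah sequence
standing → bowing → standing → prostration → sitting, `n_rakah` times
(default 3 cycles of 120 s in a 360 s session at 1 Hz). State angles
default to {standing 0°, bowing 90°, prostration 135°, sitting 45°}:
bowing at 90° is the posture the ritual prescribes; the other angles are
chosen to be monotone-distinct within the sensor's ±180° range. State
transitions are logistic ramps with scale `1/ln 9` s (half→90% in 1 s), so
1 Hz sampling still shows clear dwell plateaus — a 1 Hz sensor blurs
transitions but not postures.

Each worshipper `i` follows a personal target trace `D_i(t)`: the Rak'ah
trace delayed by a lag drawn once per person from N(1.65 s, 0.75 s),
rounded to the 1 Hz grid and clipped to [0, 5] s. The 1.65 s centre is the
observed scale of congregational following; the spread is kept tight
enough that negative (anticipatory) lags are rare on a 1 s grid. The
realized posture couples to the neighbourhood:

    f_i(t) = (1 − w)·D_i(t) + w·mean_{j∈N(i)} f_j(t−1) + ε_i(t),

with `local_coupling_weight` w = 0.25, 4-neighbourhood N(i) on the
worshipper's own grid, and i.i.d. Gaussian noise ε (sd 3°).

**Movement style.** Temporal blending alone cannot produce the local
synchrony gradient that motivates the proximity analysis: after
z-scoring, the recurrence rate of plateau-dominated signals is governed
by their marginal state distributions, and a neighbour's state entering at
weight w/|N(i)| ≈ 0.1 leaves those marginals essentially untouched. The
mechanism that does carry a spatial signal is idiosyncratic movement
*style*: how deeply one bows, prostrates or sits. Each worshipper gets
per-state angle offsets drawn N(0, 10°) and — when coupling is on —
spatially smoothed over the grid (3 neighbour-averaging passes at mixing
weight 0.6, variance-restored), modelling visual mimicry of nearby
bodies. Style similarity then decays with grid distance, which is exactly
what %REC is sensitive to. With all noise, style and coupling switched
off, a follower is a pure delay line of the leader (a tested contract).

### Heart-rate model

HR_i(t) = baseline_i + 0.25·movement_i(t) + 5·arousal(t − lag_i) + AR1_i(t),
with baseline_i ~ N(75, 8) bpm, movement intensity the 5 s moving average
of |Δposture| (deg/sample), a session-long shared arousal profile
(rise-and-ease sinusoid plus drift, scaled by `hr_arousal_gain` = 5 bpm)
delayed by each person's movement lag so the imam also leads
physiologically, and AR(1) noise (coefficient 0.8, innovation sd 1 bpm).
No generative HR model is prescribed by the setting; this is the simplest
construction with the two features the analysis needs — movement-driven
HR and a leader-linked slow component.

### Space, proximity, missingness

Worshippers occupy two identical `grid_rows × grid_cols` grids (default
2×7 at 1.22 m pitch) holding 13 colocated and 14 separated worshippers;
the imam stands one pitch in front of the colocated grid's centre column
(the ritual prescribes roughly one footstep). Proximity records Euclidean
within-space distances plus N(0, 0.05 m) noise, symmetrized; cross-space
pairs are *missing* (radio-range semantics), never a large number.
Missingness is Bernoulli per sample at rate 5·10⁻⁵ (the sparse-dropout
regime of chest-strap wearables). Everything is reproducible from a
single seed via independent child streams.

### What the generator does not emulate

Biomechanically realistic kinematics; breathing or recitation; ECG-level
heart-rate variability; device-specific posture algorithms; time-varying
proximity. Passing tests therefore show that the *pipeline* recovers
structure of this kind when present; they do not validate claims about
real congregations.

## 2. Preprocessing

Series-mean imputation first (missing samples replaced by the observed
mean of the same series — exact mean preservation, appropriate for the
sparse-dropout regime; a warning is logged above 10% missing), then
z-scoring with the sample (n−1) standard deviation. Constant series and
all-missing series raise typed errors.

## 3. Embedding parameter selection

AMI uses equiprobable binning with ⌈N^(1/3)⌉ bins (8 bins at N = 360) —
a robust estimator at session lengths of a few hundred samples; duplicate
quantile edges from plateau-heavy signals are collapsed. The delay is the
first strict local minimum of the AMI curve, falling back to the first
drop below AMI(1)/e, then to 1 with a warning. The quarter-period AMI
minimum of an oscillation is an asymptotic property of *noisy*
oscillations; a noiseless binned sine stays fully informative at every
lag, which the tests respect.

FNN uses the Kennel criteria with Rtol = 10, Atol = 2, selecting the
first dimension with fewer than 10% false neighbours (cap 10, further
capped so N − m·d ≥ 10). Coincident embedded points (periodic signals
revisit states exactly) carry no distance-ratio information and are
judged by the attractor-size test alone. Per-pair parameters are the
componentwise maximum of the two series' selections — conservative in the
sense that neither series is under-embedded; both per-series and unified
values are logged.

## 4. CRQA

Distances are Euclidean (the default of standard CRQA tooling). The CRP
orients rows along series A and columns along series B, so diagonal
offset k collects entries with j − i = k and a positive DCRP peak lag
means A leads; in imam pairs the imam is always listed first. %DET uses
minimum line length 2 (standard convention), with an O(N²) vectorized
shift formulation for that default and a run-length scan for general
minimum lengths (both validated against exhaustive enumeration). A pair
with no recurrent points has undefined %DET and is dropped listwise per
model, logged. The DCRP band halfwidth defaults to ±15 s, configurable.
Peak-lag ties break toward the smallest |lag|, then the positive side.

One global radius per signal type is bisection-calibrated on the monotone
mean-%REC curve toward 3.5%, the centre of the required 2–5% band; the
band is interpreted as a constraint on the *mean* across pairs (the
per-pair distribution is logged and the achievable range reported when
calibration fails). Per-pair recalibration was rejected: the radius is
global by design so that %REC differences between pairs remain
interpretable.

## 5. Surrogates

Plain Fourier phase randomization: positive-frequency phases i.i.d.
uniform(−π, π), conjugate symmetry by construction, DC and Nyquist kept
real — amplitude spectrum, mean, variance and (circular) autocorrelation
preserved to numerical precision. Amplitude-adjusted variants (IAAFT)
are deliberately out of scope: the baseline specified for this analysis
is amplitude-spectrum preservation only. Each participant's posture and
HR are randomized independently; surrogate CRQA reuses the embeddings and
radii selected on the true data (the baseline must answer "how much
recurrence would these exact parameters find by chance"), and both
members of a surrogate pair are randomized. Ten replicates per
participant by default.

## 6. Proximity network

Edges join same-space pairs whose recorded mean distance is ≤ 2 m
(closed threshold). Node distance is the unweighted BFS shortest-path
length; cross-space pairs are unreachable and excluded from node-distance
regressions (only finite path lengths are modelled). The five pair
categories partition all pairs, with pairs involving the imam never
classed as neighbours/distant/separated. Note a geometric consequence of
the default layout: a 2×7 grid at 1.22 m pitch with a 2 m threshold has
within-space diameter 6, whereas a compact 3×3 cluster has diameter 2 —
small sensed subsets of a dense crowd can show much shorter network
diameters than a full row-grid of the same size, and the tests cover
both configurations.

## 7. Statistical models

Category models are OLS with separated pairs as the reference level;
should listwise %DET drops empty the reference category, the first
present category takes over as reference with a warning. Surrogate
contrasts and network type-interactions are linear mixed models with a
random intercept per pair, fitted by REML, with normal-approximation
(z-based) p-values — the df convention is otherwise unspecified for this
design; non-convergent fits fall back to OLS with cluster-robust (by
pair) standard errors and are flagged in the table's `model_id`. No
multiple-testing correction is applied by default (per-model stars only,
thresholds 0.05/0.01/0.001); a Holm adjustment is available but off. The
lag test is a one-sample t against zero (df = n−1, degenerate-variance
flagged); spacing uses the two-sided Mann–Whitney U with midrank ties on
per-worshipper nearest-neighbour distances; questionnaire summaries are
yes-counts with percentages rounded to one decimal.

## 8. Problem sizes and determinism

The default session (28 participants, 360 samples, 378 pairs per signal,
10 surrogate replicates) runs end-to-end in well under a minute on one
CPU and is the configuration the acceptance checks use. Multi-seed
properties use deliberately reduced layouts chosen for statistical
adequacy at small cost: lag recovery runs 20 sessions of a single 2×4
colocated grid (160 imam-follower pairs pooled), and surrogate-contrast
sign checks use 12-participant sessions. Identical configuration and seed
give byte-identical report bundles; all randomness flows through numpy
`SeedSequence` spawning.

## 9. Known limitations

* The generator's coupling is stationary; it cannot express drifting or
  phase-dependent leadership within a session.
* %DET at min-line 2 on 1 Hz data saturates high for smooth signals;
  between-category %DET contrasts are correspondingly compressed.
* Mixed-model p-values use the normal approximation; with few pairs per
  category they are anti-conservative relative to Satterthwaite-type
  corrections.
* HR surrogates retain the slow arousal component's spectrum, so the
  HR true-vs-chance contrast is intrinsically smaller than the posture
  one — a property of the baseline, not a defect.
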