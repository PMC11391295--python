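"""Chance-level synchrony via Fourier phase-randomization surrogates.

A surrogate keeps each signal's amplitude spectrum (hence its
autocorrelation) but scrambles the phases, destroying any cross-series
alignment. Comparing true-pair CRQA metrics against surrogate pairs at the
same radius shows how much synchrony exceeds what the signals' individual
structure produces by chance.
"""

import numpy as np

from ritualsync import RitualConfig, generate_session, phase_randomize
from ritualsync.pipeline import RunConfig, analyze_session

rng = np.random.default_rng(0)
x = np.sin(np.arange(128) / 4.0) + rng.normal(0, 0.2, 128)
s = phase_randomize(x, rng).values
spec_err = np.abs(np.abs(np.fft.rfft(s)) - np.abs(np.fft.rfft(x))).max()
print(f"amplitude-spectrum preservation: max |Delta| = {spec_err:.2e} (machine precision)")

cfg = RitualConfig(duration_s=240, n_rakah=2, grid_rows=2, grid_cols=3,
                   n_colocated=5, n_separated=6, seed=8)
result = analyze_session(generate_session(cfg), RunConfig(seed=8, n_surrogates=5))
pm = result.pair_metrics
for sig in ("posture", "hr"):
    sub = pm[pm.signal == sig]
    t = sub[sub.type == "true"].rec_pct.mean()
    s_ = sub[sub.type == "surrogate"].rec_pct.mean()
    print(f"{sig}: mean %REC true = {t:.2f} vs surrogate = {s_:.2f} "
          f"(true synchrony exceeds chance by {t - s_:.2f} points)")
table = result.model_tables["surrogate_contrast:posture:rec"]
row = table[table.term == "type"].iloc[0]
print(f"mixed-model type effect (posture %REC): {row.estimate:.2f} "
      f"(SE {row.std_error:.2f}){row.stars} — true pairs above the surrogate baseline")
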