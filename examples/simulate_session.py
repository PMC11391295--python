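"""Simulate one synthetic prayer session and write it as CSV files.

The generator emulates a ~6 minute congregational prayer: an imam cycles
through the Rak'ah movement sequence while 27 worshippers on two separated
1.22 m grids follow him with a ~1-2 s lag, plus local neighbour coupling,
idiosyncratic movement style, sensor noise and sparse missingness.
"""

from ritualsync import RitualConfig, generate_session, write_session

config = RitualConfig(seed=42)
session = generate_session(config)

print(f"participants: {len(session.participants)} "
      f"({sum(p.group == 'colocated' for p in session.participants)} colocated incl. imam, "
      f"{sum(p.group == 'separated' for p in session.participants)} separated)")
imam = session.participant("imam")
print(f"imam posture range: {imam.posture.values.min():.0f}..{imam.posture.values.max():.0f} deg "
      "(0 = upright, 90 = bowing, 135 = prostration)")
print(f"samples per series: {len(imam.posture)} at {imam.posture.sample_hz:.0f} Hz")
n_missing = sum(p.posture.n_missing + p.hr.n_missing for p in session.participants)
print(f"missing samples injected: {n_missing}")
print(f"nearest-neighbour spacing (noisy): "
      f"{session.proximity.loc['c01', 'c02']:.2f} m around the 1.22 m grid pitch")

paths = write_session(session, "scratch/example_session")
print(f"wrote {len(paths)} CSV files to scratch/example_session/")
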