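"""Cross-recurrence quantification for a single pair of worshippers.

Preprocess (impute + z-score), select embedding parameters by average
mutual information and false nearest neighbours, unify them for the pair,
build the cross-recurrence plot at a radius calibrated to the 2-5% band,
and quantify it with %REC (shared states) and %DET (how often shared
states form sustained runs).
"""

from ritualsync import (
    RitualConfig,
    calibrate_global_radius,
    cross_recurrence_matrix,
    embed,
    generate_session,
    quantify,
    select_embedding_params,
    unify_pair_params,
)
from ritualsync.preprocess import preprocess_series

session = generate_session(RitualConfig(seed=3))
a = preprocess_series(session.participant("c01").posture)
b = preprocess_series(session.participant("c02").posture)

pa = select_embedding_params(a.values)
pb = select_embedding_params(b.values)
pair = unify_pair_params(pa, pb)
print(f"embedding: c01 (d={pa.delay}, m={pa.dimension}), c02 (d={pb.delay}, m={pb.dimension})"
      f" -> unified (d={pair.delay}, m={pair.dimension})")

ta, tb = embed(a.values, pair), embed(b.values, pair)
radius = calibrate_global_radius([(ta, tb)])
crp = quantify(cross_recurrence_matrix(ta, tb, radius))
print(f"radius {radius:.3f} (z-units) -> %REC = {crp.rec_rate_pct:.2f} "
      "(fraction of phase-space states the two share)")
print(f"%DET = {crp.determinism_pct:.1f} "
      "(share of recurrences inside diagonal runs: coupling stability)")
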