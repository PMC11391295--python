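"""Fourier phase-randomization surrogates.

A surrogate keeps each series' amplitude spectrum — hence its mean,
variance and autocorrelation function — while replacing the Fourier phases
with i.i.d. uniform draws. Cross-series phase alignment is thereby
destroyed, so CRQA metrics on surrogate pairs estimate the synchrony
expected by chance from the signals' individual temporal structure alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SizingError
from .series import TimeSeries
from .synthetic import ParticipantRecord, SessionData


@dataclass
class SurrogateSet:
    """Phase-randomized replicates of one source signal."""

    source_id: str
    replicates: list
    n_replicates: int
    seed: int


def phase_randomize(series, rng: np.random.Generator) -> TimeSeries:
    """One phase-randomized surrogate of a (fully observed) series.

    Positive-frequency phases are drawn i.i.d. uniform(-pi, pi); conjugate
    symmetry is enforced by construction (real FFT), and the DC and (for
    even length) Nyquist components stay real, so the output is real-valued
    with the source's amplitude spectrum to numerical precision.
    """
    if isinstance(series, TimeSeries):
        if series.missing_mask.any():
            raise ValueError("phase_randomize requires an imputed series")
        x, template = series.values, series
    else:
        x, template = np.asarray(series, dtype=float), None
    n = x.size
    if n < 4:
        raise SizingError(f"series of length {n} too short to phase-randomize (need >= 4)")

    spectrum = np.fft.rfft(x)
    amplitudes = np.abs(spectrum)
    if np.all(amplitudes[1:] < 1e-12 * max(amplitudes[0], 1.0)):
        surrogate = x.copy()  # constant series: nothing to randomize
    else:
        phases = np.angle(spectrum)
        hi = spectrum.size - 1 if n % 2 == 0 else spectrum.size  # keep Nyquist real
        phases[1:hi] = rng.uniform(-np.pi, np.pi, size=hi - 1)
        surrogate = np.fft.irfft(amplitudes * np.exp(1j * phases), n=n)
    if template is not None:
        return template.copy_with(surrogate)
    return TimeSeries(surrogate)


def make_surrogate_set(series: TimeSeries, n_replicates: int, seed: int) -> SurrogateSet:
    """n independent surrogates of one series, reproducible from seed."""
    rng = np.random.default_rng(seed)
    reps = [phase_randomize(series, rng) for _ in range(n_replicates)]
    return SurrogateSet(source_id=series.label, replicates=reps, n_replicates=n_replicates, seed=seed)


def make_surrogate_session(session: SessionData, n_replicates: int = 10, seed: int = 0) -> list:
    """Replicate sessions with every participant's posture and HR independently
    phase-randomized.

    The caller re-runs CRQA on these with the parameters (embeddings, radius)
    selected on the true data; surrogates never trigger re-selection.
    """
    streams = np.random.SeedSequence(seed).spawn(n_replicates)
    out = []
    for rep_seed in streams:
        rng = np.random.default_rng(rep_seed)
        participants = [
            ParticipantRecord(
                id=p.id,
                role=p.role,
                group=p.group,
                grid_position=p.grid_position,
                posture=phase_randomize(p.posture, rng),
                hr=phase_randomize(p.hr, rng),
            )
            for p in session.participants
        ]
        out.append(SessionData(participants=participants, proximity=session.proximity,
                               config_used=session.config_used))
    return out
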