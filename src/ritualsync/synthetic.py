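"""Seeded generator of synthetic congregational-prayer sensor sessions.

Emulates the measurement setting the analysis pipeline was designed for:
an imam performs repeated movement cycles (Rak'ah: standing, bowing at 90°,
standing, prostration, sitting) for roughly six minutes; worshippers stand
on two spatially separated but identically laid-out grids (one colocated
with the imam, one separated, with auditory access only) and follow his
posture with a one-to-two-second lag plus some blending with their immediate
neighbours; heart rate rides on movement intensity and a slow, leader-linked
arousal component; a proximity radio records pairwise mean distances within
each space. Posture is in degrees from vertical (±180), heart rate in bpm,
everything sampled at 1 Hz, with sparse missingness as wearables produce.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import SizingError
from .series import TimeSeries

logger = logging.getLogger(__name__)

#: order of posture states within one Rak'ah movement cycle
RAKAH_SEQUENCE = ("standing", "bowing", "standing", "prostration", "sitting")

#: logistic ramp scale (s) giving a ~1 s half-to-90% transition, so that
#: 1 Hz sampling still resolves plateaus between movements
_RAMP_SCALE_S = 1.0 / math.log(9.0)


@dataclass
class RitualConfig:
    """All knobs of the synthetic session generator.

    Defaults describe a ~6 min prayer of three Rak'ah cycles performed by
    an imam plus 27 worshippers (13 colocated with him, 14 in a separated
    space) on 1.22 m grids, which is the configuration every downstream
    default assumes.
    """

    duration_s: int = 360
    sample_hz: float = 1.0
    n_rakah: int = 3
    phase_durations_s: dict = field(
        default_factory=lambda: {"standing": 40, "bowing": 15, "prostration": 15, "sitting": 10}
    )
    state_angles_deg: dict = field(
        default_factory=lambda: {"standing": 0.0, "bowing": 90.0, "prostration": 135.0, "sitting": 45.0}
    )
    leader_lag_mean_s: float = 1.65
    leader_lag_sd_s: float = 0.75
    max_lag_s: int = 5
    local_coupling_weight: float = 0.25
    posture_noise_sd_deg: float = 3.0
    posture_style_sd_deg: float = 10.0
    style_smoothing: float = 0.6
    style_passes: int = 3
    hr_baseline_mean_bpm: float = 75.0
    hr_baseline_sd_bpm: float = 8.0
    hr_movement_gain: float = 0.25
    hr_arousal_gain: float = 5.0
    hr_ar1_coef: float = 0.8
    hr_noise_sd_bpm: float = 1.0
    n_colocated: int = 13
    n_separated: int = 14
    grid_rows: int = 2
    grid_cols: int = 7
    grid_spacing_m: float = 1.22
    proximity_noise_sd_m: float = 0.05
    missing_rate: float = 0.00005
    seed: int = 1

    def __post_init__(self) -> None:
        if self.duration_s * self.sample_hz < 60:
            raise ValueError("session must contain at least 60 samples")
        if not (0.0 <= self.local_coupling_weight <= 1.0):
            raise ValueError("local_coupling_weight must be in [0, 1]")
        if abs(self.hr_ar1_coef) >= 1.0:
            raise ValueError("hr_ar1_coef must have magnitude < 1")
        for name in (
            "sample_hz",
            "leader_lag_sd_s",
            "posture_noise_sd_deg",
            "hr_baseline_sd_bpm",
            "proximity_noise_sd_m",
            "missing_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_rakah < 0:
            raise ValueError("n_rakah must be non-negative")
        unknown = set(self.phase_durations_s) - set(RAKAH_SEQUENCE)
        if unknown:
            raise ValueError(f"unknown posture states in phase_durations_s: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_hz))

    def rakah_duration_s(self) -> float:
        return sum(self.phase_durations_s[state] for state in RAKAH_SEQUENCE)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RitualConfig":
        return cls(**d)


@dataclass
class ParticipantRecord:
    id: str
    role: str  # "imam" | "worshipper"
    group: str  # "colocated" | "separated"
    grid_position: Optional[tuple]  # (row, col), None for the imam
    posture: TimeSeries
    hr: TimeSeries

    def __post_init__(self) -> None:
        if self.role == "imam" and self.group != "colocated":
            raise ValueError("the imam is colocated by definition")


@dataclass
class SessionData:
    """One recorded (or simulated) session: participants plus proximity table."""

    participants: list
    proximity: pd.DataFrame  # symmetric, metres; NaN for cross-group pairs
    config_used: Optional[RitualConfig] = None

    @property
    def ids(self) -> list:
        return [p.id for p in self.participants]

    def participant(self, pid: str) -> ParticipantRecord:
        for p in self.participants:
            if p.id == pid:
                return p
        raise KeyError(pid)

    @property
    def metadata(self) -> pd.DataFrame:
        rows = []
        for p in self.participants:
            r, c = (p.grid_position if p.grid_position is not None else (None, None))
            rows.append({"id": p.id, "role": p.role, "group": p.group, "row": r, "col": c})
        return pd.DataFrame(rows).set_index("id")


def _state_schedule(config: RitualConfig) -> list:
    """(state, start_s, end_s) dwell intervals covering [0, duration_s)."""
    cycle = [(s, float(config.phase_durations_s[s])) for s in RAKAH_SEQUENCE]
    total = config.n_rakah * sum(d for _, d in cycle)
    if total > config.duration_s:
        raise SizingError(
            f"{config.n_rakah} Rak'ah of {sum(d for _, d in cycle):.0f} s each "
            f"({total:.0f} s) do not fit in duration_s={config.duration_s}"
        )
    schedule = []
    t = 0.0
    for _ in range(config.n_rakah):
        for state, dwell in cycle:
            schedule.append((state, t, t + dwell))
            t += dwell
    if t < config.duration_s:  # remainder of the session spent standing
        schedule.append(("standing", t, float(config.duration_s)))
    return schedule


def _posture_trace(config: RitualConfig, angles: dict) -> np.ndarray:
    """Rak'ah cycle trace for a given per-state angle map, with logistic ramps."""
    schedule = _state_schedule(config)
    t = np.arange(config.n_samples, dtype=float) / config.sample_hz
    signal = np.full_like(t, angles[schedule[0][0]])
    prev_angle = angles[schedule[0][0]]
    for state, start, _ in schedule[1:]:
        a = angles[state]
        if a != prev_angle:
            signal += (a - prev_angle) * expit((t - start) / _RAMP_SCALE_S)
        prev_angle = a
    return signal


def generate_leader_posture(config: RitualConfig) -> TimeSeries:
    """Noise-free imam posture: the Rak'ah cycle with logistic transition ramps.

    The angle trace is piecewise constant at the configured state angles,
    with each transition smoothed by a logistic ramp centred on the state
    boundary, so that samples in the middle of a dwell sit exactly on the
    state angle while the 1 Hz samples nearest a boundary show the ramp.
    """
    return TimeSeries(
        values=_posture_trace(config, config.state_angles_deg),
        sample_hz=config.sample_hz,
        label="imam:posture",
    )


def _smooth_field(values: np.ndarray, neighbours: list, lam: float, passes: int) -> np.ndarray:
    """Neighbour-average smoothing of a per-person scalar field, variance-preserving.

    Models visual mimicry of movement style: repeated local averaging makes
    the field spatially autocorrelated with a correlation decaying in grid
    distance, then rescales so the marginal spread is unchanged.
    """
    v = values.copy()
    for _ in range(passes):
        nxt = v.copy()
        for i, nb in enumerate(neighbours):
            if nb:
                nxt[i] = (1.0 - lam) * v[i] + lam * np.mean(v[nb])
        v = nxt
    sd0, sd1 = values.std(), v.std()
    if sd0 > 0 and sd1 > 0:
        v *= sd0 / sd1
    return v


def _grid_positions(config: RitualConfig, n: int) -> list:
    capacity = config.grid_rows * config.grid_cols
    if n > capacity:
        raise SizingError(
            f"grid {config.grid_rows}x{config.grid_cols} holds {capacity} worshippers, {n} requested"
        )
    return [(r, c) for r in range(config.grid_rows) for c in range(config.grid_cols)][:n]


def _grid_xy(config: RitualConfig, position: tuple) -> np.ndarray:
    r, c = position
    return np.array([c * config.grid_spacing_m, r * config.grid_spacing_m])


def _imam_xy(config: RitualConfig) -> np.ndarray:
    # one spacing unit in front of the first row, at the column centre
    centre_col = (config.grid_cols - 1) / 2.0
    return np.array([centre_col * config.grid_spacing_m, -config.grid_spacing_m])


def _neighbour_indices(positions: list) -> list:
    """4-neighbourhood adjacency (indices) within one grid."""
    index_of = {pos: i for i, pos in enumerate(positions)}
    out = []
    for r, c in positions:
        nbrs = [
            index_of[p]
            for p in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
            if p in index_of
        ]
        out.append(nbrs)
    return out


def _delayed(leader: np.ndarray, lag: int) -> np.ndarray:
    if lag <= 0:
        return leader.copy()
    out = np.empty_like(leader)
    out[:lag] = leader[0]
    out[lag:] = leader[:-lag]
    return out


def _follower_postures(
    delayed: np.ndarray, neighbours: list, config: RitualConfig, rng: np.random.Generator
) -> np.ndarray:
    """Followers blend their own delayed target trace with neighbours' last state."""
    n, T = delayed.shape
    noise = rng.normal(0.0, config.posture_noise_sd_deg, size=(n, T))
    w = config.local_coupling_weight
    post = np.empty((n, T))
    post[:, 0] = delayed[:, 0] + noise[:, 0]
    for t in range(1, T):
        for i in range(n):
            if w > 0.0 and neighbours[i]:
                local = np.mean(post[neighbours[i], t - 1])
                post[i, t] = (1.0 - w) * delayed[i, t] + w * local + noise[i, t]
            else:
                post[i, t] = delayed[i, t] + noise[i, t]
    return np.clip(post, -180.0, 180.0)


def _movement_intensity(posture: np.ndarray, window: int = 5) -> np.ndarray:
    """Smoothed absolute posture change (deg/sample), the HR movement driver."""
    speed = np.abs(np.diff(posture, prepend=posture[0]))
    kernel = np.ones(window) / window
    return np.convolve(speed, kernel, mode="same")


def _arousal_profile(T: int) -> np.ndarray:
    """Slow shared arousal: a session-long rise-and-ease sinusoid plus drift, in [0, ~1.3]."""
    t = np.arange(T) / max(T - 1, 1)
    return 0.5 * (1.0 + np.sin(2.0 * np.pi * t - np.pi / 2.0)) + 0.3 * t


def _ar1(T: int, coef: float, innovation_sd: float, rng: np.random.Generator) -> np.ndarray:
    e = rng.normal(0.0, innovation_sd, size=T)
    x = np.empty(T)
    x[0] = e[0] / math.sqrt(max(1.0 - coef**2, 1e-12))
    for t in range(1, T):
        x[t] = coef * x[t - 1] + e[t]
    return x


def _heart_rate(
    posture: np.ndarray, lag: int, baseline: float, config: RitualConfig, rng: np.random.Generator
) -> np.ndarray:
    arousal = _delayed(_arousal_profile(posture.size), lag)
    hr = (
        baseline
        + config.hr_movement_gain * _movement_intensity(posture)
        + config.hr_arousal_gain * arousal
        + _ar1(posture.size, config.hr_ar1_coef, config.hr_noise_sd_bpm, rng)
    )
    return hr


def _inject_missing(values: np.ndarray, rate: float, rng: np.random.Generator) -> tuple:
    mask = rng.random(values.size) < rate
    vals = values.copy()
    vals[mask] = np.nan
    return vals, mask


def generate_session(config: RitualConfig) -> SessionData:
    """Simulate a full session: imam + two worshipper grids + proximity table.

    Fully reproducible from ``config.seed``; every noise source draws from
    an independent child stream of that seed.
    """
    root = np.random.SeedSequence(config.seed)
    rngs = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ("lags", "posture", "hr", "proximity", "missing"), root.spawn(5)
        )
    }

    leader = generate_leader_posture(config)
    T = config.n_samples

    groups = {"colocated": config.n_colocated, "separated": config.n_separated}
    ids, roles, group_of, grid_pos = ["imam"], {"imam": "imam"}, {"imam": "colocated"}, {"imam": None}
    positions_by_group = {}
    for prefix, (group, n) in zip(("c", "s"), groups.items()):
        positions = _grid_positions(config, n)
        positions_by_group[group] = positions
        for k, pos in enumerate(positions):
            pid = f"{prefix}{k + 1:02d}"
            ids.append(pid)
            roles[pid] = "worshipper"
            group_of[pid] = group
            grid_pos[pid] = pos

    # follower lags: drawn once per worshipper, rounded to the 1 Hz grid
    worshippers = ids[1:]
    raw = rngs["lags"].normal(config.leader_lag_mean_s, config.leader_lag_sd_s, size=len(worshippers))
    lag_of = {
        pid: int(np.clip(np.rint(l), 0, config.max_lag_s)) for pid, l in zip(worshippers, raw)
    }

    postures = {"imam": leader.values.copy()}
    for group in groups:
        members = [pid for pid in worshippers if group_of[pid] == group]
        if not members:
            continue
        nbrs = _neighbour_indices([grid_pos[pid] for pid in members])
        # idiosyncratic movement style: per-state angle offsets (how deep one
        # bows, prostrates, sits), locally smoothed when neighbour coupling is
        # on — visual mimicry makes nearby worshippers' styles alike
        styles = {}
        for state in set(RAKAH_SEQUENCE) - {"standing"}:
            offsets = rngs["posture"].normal(0.0, config.posture_style_sd_deg, len(members))
            if config.local_coupling_weight > 0 and config.posture_style_sd_deg > 0:
                offsets = _smooth_field(offsets, nbrs, config.style_smoothing, config.style_passes)
            styles[state] = offsets
        delayed = np.stack(
            [
                _delayed(
                    _posture_trace(
                        config,
                        {
                            st: config.state_angles_deg[st] + (styles[st][i] if st in styles else 0.0)
                            for st in config.state_angles_deg
                        },
                    ),
                    lag_of[pid],
                )
                for i, pid in enumerate(members)
            ]
        )
        block = _follower_postures(delayed, nbrs, config, rngs["posture"])
        for i, pid in enumerate(members):
            postures[pid] = block[i]

    baselines = {
        pid: rngs["hr"].normal(config.hr_baseline_mean_bpm, config.hr_baseline_sd_bpm)
        for pid in ids
    }
    hrs = {
        pid: _heart_rate(postures[pid], lag_of.get(pid, 0), baselines[pid], config, rngs["hr"])
        for pid in ids
    }

    participants = []
    for pid in ids:
        pv, pm = _inject_missing(postures[pid], config.missing_rate, rngs["missing"])
        hv, hm = _inject_missing(hrs[pid], config.missing_rate, rngs["missing"])
        participants.append(
            ParticipantRecord(
                id=pid,
                role=roles[pid],
                group=group_of[pid],
                grid_position=grid_pos[pid],
                posture=TimeSeries(pv, config.sample_hz, pm, f"{pid}:posture"),
                hr=TimeSeries(hv, config.sample_hz, hm, f"{pid}:hr"),
            )
        )

    xy = {"imam": _imam_xy(config)}
    for pid in worshippers:
        xy[pid] = _grid_xy(config, grid_pos[pid])

    prox = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
    for i, a in enumerate(ids):
        prox.loc[a, a] = 0.0
        for b in ids[i + 1 :]:
            if group_of[a] != group_of[b]:
                continue  # cross-group pairs out of radio range: missing
            d = float(np.linalg.norm(xy[a] - xy[b]))
            if config.proximity_noise_sd_m > 0:
                d = max(d + rngs["proximity"].normal(0.0, config.proximity_noise_sd_m), 0.01)
            prox.loc[a, b] = prox.loc[b, a] = d

    n_missing = sum(p.posture.n_missing + p.hr.n_missing for p in participants)
    logger.info(
        "generated session: %d participants, %d samples, %d missing samples",
        len(participants), T, n_missing,
    )
    return SessionData(participants=participants, proximity=prox, config_used=config)
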