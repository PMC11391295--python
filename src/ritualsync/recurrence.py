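"""Cross-recurrence quantification: plots, %REC/%DET, global-radius
calibration, and diagonal cross-recurrence profiles.

Orientation and sign conventions
--------------------------------
The recurrence matrix has rows indexed by series A's trajectory and columns
by series B's: entry (i, j) = 1 when the two embedded points are within the
radius. Diagonal offset k therefore collects entries with j - i = k, and a
*positive* DCRP peak lag means series A (listed first; the imam in
imam-pairs) leads series B.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import CalibrationError, SizingError

logger = logging.getLogger(__name__)


@dataclass
class CRPResult:
    """A cross-recurrence plot plus its quantification."""

    recurrence_matrix: np.ndarray  # boolean, rows = A, cols = B
    radius: float
    rec_rate_pct: Optional[float] = None
    determinism_pct: Optional[float] = None  # None when undefined (no recurrent points)
    min_line: int = 2


@dataclass
class DCRPProfile:
    """Recurrence-by-lag in a band around the line of synchrony."""

    lags: np.ndarray  # integer sample offsets, -L..L
    rec_pct_by_lag: np.ndarray
    peak_lag: int
    band_halfwidth_s: int


def cross_recurrence_matrix(traj_a: np.ndarray, traj_b: np.ndarray, radius: float) -> CRPResult:
    """Binary CRP: (i, j) = 1 iff ||A_i - B_j|| <= radius (Euclidean)."""
    traj_a = np.atleast_2d(np.asarray(traj_a, float))
    traj_b = np.atleast_2d(np.asarray(traj_b, float))
    if traj_a.shape[1] != traj_b.shape[1]:
        raise SizingError(
            f"embedding mismatch: trajectories have dimensions {traj_a.shape[1]} and {traj_b.shape[1]}"
        )
    if radius <= 0:
        raise ValueError("radius must be positive")
    matrix = cdist(traj_a, traj_b) <= radius
    return CRPResult(recurrence_matrix=matrix, radius=radius)


def _matrix(crp) -> np.ndarray:
    if isinstance(crp, CRPResult):
        return crp.recurrence_matrix
    return np.asarray(crp, dtype=bool)


def recurrence_rate(crp) -> float:
    """%REC: percentage of recurrent cells over the whole plot."""
    m = _matrix(crp)
    if m.size == 0:
        raise ValueError("empty recurrence matrix")
    return 100.0 * float(m.sum()) / m.size


def _diagonal_line_points(m: np.ndarray, min_line: int) -> int:
    """Recurrent points lying on diagonal runs of length >= min_line."""
    rows, cols = m.shape
    if min_line <= 1:
        return int(m.sum())
    if min_line == 2:
        # a point is on a line iff it has a recurrent diagonal neighbour
        core = m[1:, 1:] & m[:-1, :-1]
        on_line = np.zeros_like(m)
        on_line[1:, 1:] |= core
        on_line[:-1, :-1] |= core
        return int(on_line.sum())
    total = 0
    for k in range(-(rows - 1), cols):
        d = np.diagonal(m, offset=k).astype(np.int8)
        padded = np.concatenate(([0], d, [0]))
        changes = np.flatnonzero(np.diff(padded))
        run_lengths = changes[1::2] - changes[::2]
        total += int(run_lengths[run_lengths >= min_line].sum())
    return total


def determinism(crp, min_line: int = 2) -> Optional[float]:
    """%DET: share of recurrent points on diagonal lines of length >= min_line.

    Returns ``None`` (undefined) when the plot has no recurrent points at
    all; callers exclude such pairs from aggregation.
    """
    m = _matrix(crp)
    n_rec = int(m.sum())
    if n_rec == 0:
        return None
    return 100.0 * _diagonal_line_points(m, min_line) / n_rec


def quantify(crp: CRPResult, min_line: int = 2) -> CRPResult:
    """Fill the %REC / %DET fields of a CRPResult in place (and return it)."""
    crp.rec_rate_pct = recurrence_rate(crp)
    crp.determinism_pct = determinism(crp, min_line)
    crp.min_line = min_line
    return crp


def diagonal_profile(crp, band_halfwidth_s: int, sample_hz: float = 1.0) -> DCRPProfile:
    """Recurrence per diagonal for lags within +/- band_halfwidth_s.

    Peak-lag ties are broken toward the smallest absolute lag, then toward
    the positive (A-leads) side.
    """
    m = _matrix(crp)
    L = int(round(band_halfwidth_s * sample_hz))
    if L >= min(m.shape):
        raise SizingError(f"band halfwidth {L} exceeds matrix size {m.shape}")
    lags = np.arange(-L, L + 1)
    rec = np.array([100.0 * np.diagonal(m, offset=k).mean() for k in lags])
    order = sorted(range(lags.size), key=lambda i: (-rec[i], abs(lags[i]), -np.sign(lags[i])))
    peak = int(lags[order[0]])
    return DCRPProfile(lags=lags, rec_pct_by_lag=rec, peak_lag=peak, band_halfwidth_s=band_halfwidth_s)


def calibrate_global_radius(
    pair_trajectories: Sequence,
    target_band: tuple = (2.0, 5.0),
    target_point: float = 3.5,
    tol: float = 0.02,
    max_iter: int = 80,
) -> float:
    """One shared radius such that the *mean* %REC across pairs sits in the band.

    Bisection toward ``target_point`` on the (monotone) mean recurrence
    curve. ``pair_trajectories`` is a sequence of (traj_a, traj_b) tuples,
    all embedded with their unified per-pair parameters.

    Raises
    ------
    CalibrationError
        If the returned radius cannot place the mean %REC inside
        ``target_band`` (degenerate signals); the message reports the
        achievable range.
    """
    if not pair_trajectories:
        raise ValueError("need at least one pair to calibrate")
    lo_band, hi_band = target_band
    if not (0.0 < lo_band < hi_band <= 100.0):
        raise ValueError("target_band must satisfy 0 < lo < hi <= 100")
    if not (lo_band <= target_point <= hi_band):
        raise ValueError("target_point must lie inside target_band")

    sorted_dists = []
    for a, b in pair_trajectories:
        d = cdist(np.atleast_2d(a), np.atleast_2d(b)).ravel()
        d.sort()
        sorted_dists.append(d)

    def mean_rec(radius: float) -> float:
        fracs = [np.searchsorted(d, radius, side="right") / d.size for d in sorted_dists]
        return 100.0 * float(np.mean(fracs))

    lo, hi = 0.0, float(max(d[-1] for d in sorted_dists))
    if mean_rec(hi) < target_point:
        raise CalibrationError(
            f"mean %REC at maximal radius is {mean_rec(hi):.3f}, below target {target_point}"
        )
    radius = hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if mid <= 0 or mid == lo or mid == hi:
            break
        if mean_rec(mid) < target_point:
            lo = mid
        else:
            hi = mid
        radius = hi
        if abs(mean_rec(radius) - target_point) < tol:
            break

    achieved = mean_rec(radius)
    per_pair = [100.0 * np.searchsorted(d, radius, side="right") / d.size for d in sorted_dists]
    logger.info(
        "calibrated radius %.4f: mean %%REC %.3f (per-pair range %.3f-%.3f over %d pairs)",
        radius, achieved, min(per_pair), max(per_pair), len(per_pair),
    )
    if not (lo_band <= achieved <= hi_band):
        lo_reach = mean_rec(np.nextafter(0, 1))
        raise CalibrationError(
            f"mean %REC {achieved:.3f} outside band [{lo_band}, {hi_band}]; "
            f"achievable range is [{lo_reach:.3f}, {mean_rec(float(max(d[-1] for d in sorted_dists))):.3f}]"
        )
    return float(radius)
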