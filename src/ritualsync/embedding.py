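"""Phase-space reconstruction: AMI delay selection, FNN dimension selection,
and uniform delay embedding.

The delay is chosen at the first local minimum of the average mutual
information between the series and its lagged copy; the embedding dimension
at the first dimension where the false-nearest-neighbour fraction falls
below threshold (Kennel criteria). For a cross-recurrence pair the two
series' parameters are unified by componentwise maximum, which never
under-embeds either member.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import SizingError
from .series import TimeSeries

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingParams:
    """Delay-embedding parameters, optionally carrying the shared CRQA radius."""

    delay: int
    dimension: int
    radius: Optional[float] = None
    rescale_norm: str = "euclidean"

    def __post_init__(self) -> None:
        if self.delay < 1:
            raise ValueError("delay must be >= 1")
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")
        if self.radius is not None and self.radius <= 0:
            raise ValueError("radius must be positive once set")


def _values(series) -> np.ndarray:
    if isinstance(series, TimeSeries):
        if series.missing_mask.any():
            raise ValueError("embedding functions require imputed series")
        return series.values
    return np.asarray(series, dtype=float)


def _bin_indices(x: np.ndarray, n_bins: int) -> tuple:
    """Equiprobable binning; collapses duplicate quantile edges (plateau-heavy data)."""
    edges = np.unique(np.quantile(x, np.linspace(0.0, 1.0, n_bins + 1)))
    n = max(len(edges) - 1, 1)
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n - 1)
    return idx, n


def _mutual_information_bits(ix: np.ndarray, iy: np.ndarray, n_bins: int) -> float:
    joint = np.bincount(ix * n_bins + iy, minlength=n_bins * n_bins).astype(float)
    joint = joint.reshape(n_bins, n_bins) / ix.size
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))


def average_mutual_information(series, max_lag: int) -> list:
    """AMI (bits) between the series and its lag-k copy for k = 0..max_lag.

    Uses equiprobable binning with ceil(N^(1/3)) bins — robust for the few
    hundred samples a single session provides. AMI(0) is the binned
    self-information and bounds the whole curve from above.
    """
    x = _values(series)
    n = x.size
    if n <= 4 * max_lag:
        raise SizingError(f"series of length {n} too short for max_lag={max_lag} (need > 4*max_lag)")
    n_bins = math.ceil(n ** (1.0 / 3.0))
    idx, n_bins = _bin_indices(x, n_bins)
    curve = []
    for k in range(max_lag + 1):
        a = idx[: n - k] if k else idx
        b = idx[k:] if k else idx
        curve.append((k, _mutual_information_bits(a, b, n_bins)))
    return curve


def _curve_values(ami_curve) -> np.ndarray:
    arr = np.asarray(ami_curve, dtype=float)
    if arr.ndim == 2:  # sequence of (lag, value) pairs
        arr = arr[np.argsort(arr[:, 0]), 1]
    return arr


def select_delay(ami_curve) -> int:
    """First local minimum of the AMI curve; 1/e-drop fallback; last resort 1.

    Accepts either the (lag, value) pairs from
    :func:`average_mutual_information` or a bare value sequence indexed by lag.
    """
    v = _curve_values(ami_curve)
    if v.size == 0:
        raise ValueError("empty AMI curve")
    for k in range(1, v.size - 1):
        if v[k] < v[k - 1] and v[k] < v[k + 1]:
            return k
    if v.size > 1:
        threshold = v[1] / math.e
        below = np.nonzero(v[1:] < threshold)[0]
        if below.size:
            return int(below[0] + 1)
    logger.warning("AMI curve has no local minimum or 1/e crossing; falling back to delay 1")
    return 1


def embed(series, params: EmbeddingParams) -> np.ndarray:
    """Uniform delay embedding: point i = (x_i, x_{i+d}, ..., x_{i+(m-1)d})."""
    x = _values(series)
    d, m = params.delay, params.dimension
    n_pts = x.size - (m - 1) * d
    if n_pts < 1:
        raise SizingError(f"series of length {x.size} too short to embed with m={m}, d={d}")
    return np.column_stack([x[j * d : j * d + n_pts] for j in range(m)])


def false_nearest_neighbours(
    series,
    delay: int,
    max_dim: int = 10,
    rtol: float = 10.0,
    atol: float = 2.0,
) -> list:
    """FNN fraction per dimension m = 1..max_dim (Kennel criteria).

    A nearest neighbour in dimension m is false when the extra (m+1)-th
    coordinate blows the pair apart relative to their m-dimensional distance
    (rtol test) or relative to the attractor size (atol test).
    """
    x = _values(series)
    n = x.size
    sigma = x.std(ddof=1)
    if sigma == 0:
        raise SizingError("constant series has no neighbour structure")
    if n - max_dim * delay < 10:
        raise SizingError(
            f"series of length {n} too short for FNN up to m={max_dim} at delay {delay}"
        )
    out = []
    for m in range(1, max_dim + 1):
        n_pts = n - m * delay  # points whose (m+1)-th coordinate also exists
        pts = np.column_stack([x[j * delay : j * delay + n_pts] for j in range(m)])
        dist, idx = cKDTree(pts).query(pts, k=2)
        r = dist[:, 1]
        nn = idx[:, 1]
        extra = np.abs(x[m * delay : m * delay + n_pts] - x[nn + m * delay])
        # coincident points (periodic signals revisit states exactly) carry no
        # distance-ratio information; judge those by the attractor-size test only
        degenerate = r < 1e-8 * sigma
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(degenerate, 0.0, extra / r)
        false = (ratio > rtol) | (np.sqrt(r**2 + extra**2) / sigma > atol)
        out.append((m, float(np.mean(false))))
    return out


def select_dimension(fnn_curve: Sequence, threshold: float = 0.10) -> int:
    """First dimension whose FNN fraction drops below threshold; max_dim fallback."""
    for m, frac in fnn_curve:
        if frac < threshold:
            return int(m)
    max_dim = int(fnn_curve[-1][0])
    logger.warning("FNN fraction never fell below %.0f%%; falling back to max_dim=%d",
                   100 * threshold, max_dim)
    return max_dim


def select_embedding_params(
    series,
    max_lag: int = 20,
    max_dim: int = 10,
    fnn_threshold: float = 0.10,
) -> EmbeddingParams:
    """Full per-series parameter selection: AMI delay, then FNN dimension."""
    x = _values(series)
    max_lag = min(max_lag, max(1, x.size // 5))
    delay = select_delay(average_mutual_information(x, max_lag))
    # keep the embedding feasible for this series length
    feasible_dim = max(1, min(max_dim, (x.size - 10) // delay))
    if feasible_dim < 2:
        return EmbeddingParams(delay=delay, dimension=1)
    fnn = false_nearest_neighbours(x, delay, max_dim=feasible_dim)
    return EmbeddingParams(delay=delay, dimension=select_dimension(fnn, fnn_threshold))


def unify_pair_params(params_a: EmbeddingParams, params_b: EmbeddingParams) -> EmbeddingParams:
    """Componentwise maximum: the conservative shared parameters for a pair."""
    if params_a.rescale_norm != params_b.rescale_norm:
        raise ValueError("cannot unify parameters with different distance norms")
    return EmbeddingParams(
        delay=max(params_a.delay, params_b.delay),
        dimension=max(params_a.dimension, params_b.dimension),
        rescale_norm=params_a.rescale_norm,
    )
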