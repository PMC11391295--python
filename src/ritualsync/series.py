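"""The 1 Hz per-participant signal container used throughout the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class TimeSeries:
    """One participant's uniformly sampled signal with a missing-sample mask.

    Parameters
    ----------
    values
        Ordered real samples (posture in degrees, or heart rate in bpm).
        Missing samples may be encoded as NaN; they are absorbed into
        ``missing_mask``.
    sample_hz
        Sampling rate in Hz. The wearable emulation and all lag bookkeeping
        assume 1 Hz.
    missing_mask
        Boolean per-sample mask, ``True`` where the sample is missing. Any
        NaN in ``values`` is always treated as missing as well.
    label
        Free-form signal name, e.g. ``"c03:posture"``.
    """

    values: np.ndarray
    sample_hz: float = 1.0
    missing_mask: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        nan_mask = np.isnan(self.values)
        if self.missing_mask is None:
            self.missing_mask = nan_mask
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool) | nan_mask
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask length must equal values length")

    def __len__(self) -> int:
        return self.values.size

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    @property
    def missing_fraction(self) -> float:
        return self.n_missing / max(len(self), 1)

    @property
    def observed(self) -> np.ndarray:
        """Samples not flagged as missing."""
        return self.values[~self.missing_mask]

    def copy_with(self, values: np.ndarray, missing_mask: np.ndarray | None = None) -> "TimeSeries":
        return TimeSeries(
            values=np.array(values, dtype=float),
            sample_hz=self.sample_hz,
            missing_mask=None if missing_mask is None else np.array(missing_mask, dtype=bool),
            label=self.label,
        )
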