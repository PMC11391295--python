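"""Missing-value imputation and standardization applied before CRQA.

The order is fixed: series-mean imputation first, z-scoring second. Mean
imputation is appropriate here because wearable dropouts in this setting are
sparse (well under the 10% rule of thumb for simple imputation), and it
preserves the observed-sample mean exactly.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import DegenerateSeriesError, UnprocessableSeriesError
from .series import TimeSeries

logger = logging.getLogger(__name__)


def impute_series_mean(series: TimeSeries) -> TimeSeries:
    """Replace each missing sample by the mean of the series' observed samples."""
    mask = series.missing_mask
    if mask.all():
        raise UnprocessableSeriesError(f"{series.label or 'series'}: every sample is missing")
    if not mask.any():
        return series.copy_with(series.values, np.zeros(len(series), bool))
    if series.missing_fraction >= 0.10:
        logger.warning(
            "%s: %.1f%% of samples missing (>=10%%); mean imputation may distort dynamics",
            series.label or "series", 100 * series.missing_fraction,
        )
    values = series.values.copy()
    values[mask] = series.observed.mean()
    logger.debug("%s: imputed %d samples", series.label or "series", int(mask.sum()))
    return series.copy_with(values, np.zeros(len(series), bool))


def zscore(series: TimeSeries) -> TimeSeries:
    """Standardize to mean 0, sample (n-1) standard deviation 1."""
    if series.missing_mask.any():
        raise ValueError("zscore requires an imputed series with no missing samples")
    sd = series.values.std(ddof=1)
    if sd == 0:
        raise DegenerateSeriesError(f"{series.label or 'series'}: constant series cannot be standardized")
    return series.copy_with((series.values - series.values.mean()) / sd)


def preprocess_series(series: TimeSeries) -> TimeSeries:
    """Imputation followed by z-scoring: the standard pre-CRQA pipeline step."""
    return zscore(impute_series_mean(series))
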