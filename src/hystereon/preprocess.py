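"""Stream cleaning before model input: outlier replacement, smoothing,
z-score normalization.

Outliers are handled with a Hampel filter: a sample deviating from its
centered window median by more than ``nsigma * 1.4826 * MAD`` is replaced by
that median.  Windows shrink at the record edges.  Smoothing is a centered
moving average with the same edge truncation.  Normalization is a per-record
z-score with the population SD; the (mean, sd) pair is retained so model
outputs can be mapped back to physical units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import DegenerateInputError, InvalidArgumentError
from .streams import SensorStream

__all__ = ["PreprocessConfig", "NormParams", "remove_outliers", "normalize", "smooth"]

logger = logging.getLogger(__name__)

MAD_SCALE = 1.4826  # consistency factor: MAD -> SD under normality


@dataclass
class PreprocessConfig:
    """Parameters of the cleaning pipeline applied to heart-rate streams."""

    hampel_window: int = 11
    hampel_nsigma: float = 3.0
    smooth_window: int = 5
    normalization: str = "zscore"

    def __post_init__(self) -> None:
        if self.hampel_window < 3 or self.hampel_window % 2 == 0:
            raise InvalidArgumentError("hampel_window must be odd and >= 3")
        if self.hampel_nsigma <= 0:
            raise InvalidArgumentError("hampel_nsigma must be > 0")
        if self.smooth_window < 1:
            raise InvalidArgumentError("smooth_window must be >= 1")
        if self.normalization not in ("zscore", "none"):
            raise InvalidArgumentError(
                f"normalization must be 'zscore' or 'none', got {self.normalization!r}"
            )


@dataclass
class NormParams:
    """Stored z-score transform, invertible to machine precision."""

    mean: float
    sd: float

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, float) - self.mean) / self.sd

    def invert(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, float) * self.sd + self.mean


def remove_outliers(series: SensorStream, cfg: PreprocessConfig | None = None) -> SensorStream:
    """Hampel-filter a stream; timestamps are unchanged.

    Series shorter than the window are returned unchanged with a logged
    warning.  A zero-MAD window flags only samples that differ from the
    window median at all (the constant-window case replaces nothing).
    """
    cfg = cfg or PreprocessConfig()
    x = series.values
    n = x.size
    if n == 0:
        raise InvalidArgumentError("remove_outliers: empty series")
    w = cfg.hampel_window
    if n < w:
        logger.warning(
            "remove_outliers: series '%s' (%d samples) shorter than window %d; unchanged",
            series.name, n, w,
        )
        return series.with_values(x.copy())

    half = w // 2
    out = x.copy()
    # interior: vectorized over all full windows
    win = sliding_window_view(x, w)  # (n - w + 1, w)
    med = np.median(win, axis=1)
    mad = np.median(np.abs(win - med[:, None]), axis=1)
    centers = np.arange(half, n - half)
    dev = np.abs(x[centers] - med)
    bad = dev > cfg.hampel_nsigma * MAD_SCALE * mad
    out[centers[bad]] = med[bad]
    # edges: shrinking centered windows
    for i in list(range(half)) + list(range(n - half, n)):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        m = np.median(x[lo:hi])
        s = MAD_SCALE * np.median(np.abs(x[lo:hi] - m))
        if np.abs(x[i] - m) > cfg.hampel_nsigma * s:
            out[i] = m
    return series.with_values(out)


def normalize(series: SensorStream) -> tuple[SensorStream, NormParams]:
    """Z-score a stream (population SD); returns the stream and the transform."""
    x = series.values
    if x.size == 0:
        raise InvalidArgumentError("normalize: empty series")
    mean = float(np.mean(x))
    sd = float(np.std(x))  # population convention, ddof=0
    if sd <= 1e-12 * max(1.0, abs(mean)):
        raise DegenerateInputError(f"normalize: series '{series.name}' has zero variance")
    params = NormParams(mean, sd)
    return series.with_values(params.apply(x)), params


def smooth(series: SensorStream, window: int = 5) -> SensorStream:
    """Centered moving average with shrinking windows at the boundaries.

    For sample ``i`` the window is ``[i - (w-1)//2, i + w//2]`` clipped to the
    record, so ``window=1`` is the identity and constants are fixed points.
    """
    if window < 1:
        raise InvalidArgumentError("smooth: window must be >= 1")
    x = series.values
    if x.size == 0:
        raise InvalidArgumentError("smooth: empty series")
    n = x.size
    if window == 1:
        return series.with_values(x.copy())
    lo = np.maximum(np.arange(n) - (window - 1) // 2, 0)
    hi = np.minimum(np.arange(n) + window // 2 + 1, n)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return series.with_values(out)
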