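"""Coarse-graining and traditional signal measures.

The raw device signal arrives at 5-second epochs; the main analysis runs
on 1-minute epochs obtained by averaging non-overlapping blocks of 12
values.  The traditional measures are the mean, sample standard
deviation, coefficient of variation and lag-1 autocorrelation of the
analysis-scale series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace import ActivityTrace, ValidationError

__all__ = ["TraditionalFeatures", "coarse_grain", "traditional_measures"]


@dataclass(frozen=True)
class TraditionalFeatures:
    """Mean, spread and short-range memory of an activity series.

    ``cov`` is sd/avg; ``ac1`` the lag-1 autocorrelation at the series'
    epoch scale.  Undefined quantities (zero mean, constant series) are
    NaN with the reason recorded in ``flags``.
    """

    avg: float
    sd: float
    cov: float
    ac1: float
    flags: tuple[str, ...] = ()


def coarse_grain(trace: ActivityTrace, block_size: int) -> ActivityTrace:
    """Average non-overlapping blocks of ``block_size`` consecutive epochs.

    Output value k is the arithmetic mean of input block k; the epoch
    length scales by ``block_size``.  A trailing partial block is dropped
    (at most one epoch of signal per recording), so the output length is
    ``floor(n / block_size)``.
    """
    if int(block_size) != block_size or block_size < 1:
        raise ValidationError(f"block_size must be a positive integer, got {block_size}")
    block_size = int(block_size)
    n = trace.n
    if block_size > n:
        raise ValidationError(f"block_size {block_size} exceeds trace length {n}")
    if block_size == 1:
        return trace.with_values(trace.values.copy())
    m = n // block_size
    out = trace.values[: m * block_size].reshape(m, block_size).mean(axis=1)
    return trace.with_values(out, epoch_seconds=trace.epoch_seconds * block_size)


def traditional_measures(trace: ActivityTrace) -> TraditionalFeatures:
    """Mean, sample SD (n-1 denominator), CoV and lag-1 autocorrelation.

    The autocorrelation is the lag-1 autocovariance divided by the
    variance, both centred on the global mean:

        ac1 = sum_{t<n} (x_t - xbar)(x_{t+1} - xbar) / sum_t (x_t - xbar)^2

    For a constant series ac1 is undefined (flagged NaN); for a
    zero-mean series the CoV is undefined (flagged NaN).
    """
    x = trace.values
    n = x.size
    if n < 3:
        raise ValidationError(f"traditional measures need at least 3 epochs, got {n}")
    avg = float(x.mean())
    sd = float(x.std(ddof=1))
    flags: list[str] = []
    if avg != 0.0:
        cov = sd / avg
    else:
        cov = float("nan")
        flags.append("cov_undefined")
    dev = x - avg
    ss = float(dev @ dev)
    if ss > 0.0:
        ac1 = float(dev[:-1] @ dev[1:]) / ss
    else:
        ac1 = float("nan")
        flags.append("ac1_undefined")
    return TraditionalFeatures(avg=avg, sd=sd, cov=cov, ac1=ac1, flags=tuple(flags))
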