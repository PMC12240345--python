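"""Correlation-integral analysis of delay-embedded time series.

Implements the Grassberger–Procaccia construction: a series
``[x_1, ..., x_n]`` is embedded into d-dimensional delay vectors
``X_i = (x_i, x_{i+tau}, ..., x_{i+(d-1)tau})`` and the correlation
integral

    C_d(r) = 2 / (N (N - 1)) * #{ (i, j), i < j : |X_i - X_j| <= r }

is evaluated on a grid of radii, with N the number of embedded vectors
(``N = n - d + 1`` for tau = 1).  C_d(r) is the mean probability that
length-d segments of the series repeat within tolerance r.  For small r
it follows a power law ``C_d(r) ~ r^nu``; the correlation dimension nu
is the slope of log C against log r.  Low nu indicates a repetitive,
regular signal; for noise nu grows with the embedding dimension.

Radii are specified in units of the series' own standard deviation
(sample SD), so that signals of different amplitude are probed at
comparable relative tolerances; absolute radii are recorded in outputs.
Pair counting is exact: a blocked O(N^2) kernel evaluates every pair,
with the tie convention that a pair at distance exactly r counts as a
neighbor.

The sample entropy ``ln(C_d(r) / C_{d+1}(r))`` is provided as an
auxiliary regularity measure; it uses the Chebyshev metric and the
common convention of counting templates of both lengths over the same
``n - d`` starting positions, which makes it nonnegative by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numba as nb
import numpy as np
from scipy import stats

from .trace import ValidationError

__all__ = [
    "EmbeddingConfig",
    "CorrelationIntegralCurve",
    "CorrDimResult",
    "delay_embed",
    "correlation_sum",
    "correlation_integral_curve",
    "estimate_correlation_dimension",
    "sample_entropy",
]

METRICS = ("euclidean", "chebyshev")


def _default_r_grid() -> np.ndarray:
    return np.geomspace(0.03, 0.3, 20)


@dataclass
class EmbeddingConfig:
    """Embedding and radius-grid settings for the correlation integral.

    ``r_grid`` is in units of the series' standard deviation; the default
    spans 0.03–0.3 with 20 log-spaced points so that the conventional
    radius 0.2 lies inside the probed range.
    """

    d: int = 6
    tau: int = 1
    metric: str = "euclidean"
    r_grid: np.ndarray = field(default_factory=_default_r_grid)

    def __post_init__(self) -> None:
        if int(self.d) != self.d or self.d < 1:
            raise ValidationError(f"d must be a positive integer, got {self.d}")
        if int(self.tau) != self.tau or self.tau < 1:
            raise ValidationError(f"tau must be a positive integer, got {self.tau}")
        if self.metric not in METRICS:
            raise ValidationError(f"metric must be one of {METRICS}, got {self.metric!r}")
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        if self.r_grid.ndim != 1 or self.r_grid.size < 1:
            raise ValidationError("r_grid must be a non-empty 1-D array")
        if np.any(self.r_grid <= 0) or np.any(np.diff(self.r_grid) <= 0):
            raise ValidationError("r_grid must be strictly increasing and positive")


@dataclass
class CorrelationIntegralCurve:
    """C_d(r) over a radius grid for one embedding dimension."""

    r_values: np.ndarray        # absolute radii (signal units)
    r_relative: np.ndarray      # the same radii in units of the series SD
    c_values: np.ndarray        # C_d(r) in [0, 1], nondecreasing
    d: int
    tau: int
    metric: str
    n_vectors: int              # N = n - (d-1) tau
    series_sd: float


@dataclass
class CorrDimResult:
    """Slope estimate of log C_d(r) vs log r."""

    nu: float
    fit_r_range: tuple[float, float]  # absolute radii entering the fit
    fit_r2: float                     # R^2 of the log-log linear fit
    n_valid_points: int               # radii with C_d(r) > 0 used


def delay_embed(series: np.ndarray, d: int, tau: int = 1) -> np.ndarray:
    """Delay-embed a series into vectors ``(x_i, x_{i+tau}, ..., x_{i+(d-1)tau})``.

    Returns an ``(n - (d-1) tau, d)`` array; ``d = 1`` is the identity
    embedding (each point its own vector).
    """
    x = np.ascontiguousarray(series, dtype=float)
    if x.ndim != 1:
        raise ValidationError("series must be one-dimensional")
    if int(d) != d or d < 1 or int(tau) != tau or tau < 1:
        raise ValidationError(f"d and tau must be positive integers, got d={d}, tau={tau}")
    d, tau = int(d), int(tau)
    min_len = (d - 1) * tau + 1
    if x.size < min_len:
        raise ValidationError(
            f"series of length {x.size} too short for d={d}, tau={tau}; "
            f"need at least {min_len} points"
        )
    window = (d - 1) * tau + 1
    return np.ascontiguousarray(np.lib.stride_tricks.sliding_window_view(x, window)[:, ::tau])


# ---------------------------------------------------------------------------
# exact pair counting
#
# Blocked kernels: distances for a block of column indices are buffered,
# then thresholded against every radius.  The inner accumulation order
# matches a naive loop (no fastmath), so counts agree bit-for-bit with a
# plain double-loop evaluation of the same expression.

_BLOCK = 512


@nb.njit(cache=True)
def _count_pairs_euclidean(X: np.ndarray, r_sorted: np.ndarray) -> np.ndarray:
    N, d = X.shape
    K = r_sorted.shape[0]
    out = np.zeros(K, np.int64)
    buf = np.empty(_BLOCK, np.float64)
    for i in range(N):
        j0 = i + 1
        while j0 < N:
            m = min(_BLOCK, N - j0)
            for jj in range(m):
                j = j0 + jj
                s = 0.0
                for k in range(d):
                    t = X[i, k] - X[j, k]
                    s += t * t
                buf[jj] = math.sqrt(s)
            for kk in range(K):
                rk = r_sorted[kk]
                c = 0
                for jj in range(m):
                    c += buf[jj] <= rk
                out[kk] += c
            j0 += m
    return out


@nb.njit(cache=True)
def _count_pairs_chebyshev(X: np.ndarray, r_sorted: np.ndarray) -> np.ndarray:
    N, d = X.shape
    K = r_sorted.shape[0]
    out = np.zeros(K, np.int64)
    buf = np.empty(_BLOCK, np.float64)
    for i in range(N):
        j0 = i + 1
        while j0 < N:
            m = min(_BLOCK, N - j0)
            for jj in range(m):
                j = j0 + jj
                s = 0.0
                for k in range(d):
                    t = abs(X[i, k] - X[j, k])
                    if t > s:
                        s = t
                buf[jj] = s
            for kk in range(K):
                rk = r_sorted[kk]
                c = 0
                for jj in range(m):
                    c += buf[jj] <= rk
                out[kk] += c
            j0 += m
    return out


def _count_pairs(X: np.ndarray, radii: np.ndarray, metric: str) -> np.ndarray:
    X = np.ascontiguousarray(X, dtype=float)
    radii = np.ascontiguousarray(radii, dtype=float)
    if metric == "euclidean":
        return _count_pairs_euclidean(X, radii)
    if metric == "chebyshev":
        return _count_pairs_chebyshev(X, radii)
    raise ValidationError(f"metric must be one of {METRICS}, got {metric!r}")


def correlation_sum(embedded: np.ndarray, r: float, metric: str = "euclidean") -> float:
    """Fraction of unordered vector pairs within distance ``r``.

    Self-matches are excluded; pairs at distance exactly ``r`` count as
    neighbors.
    """
    X = np.asarray(embedded, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    N = X.shape[0]
    if N < 2:
        raise ValidationError(f"need at least 2 vectors, got {N}")
    if not r > 0:
        raise ValidationError(f"r must be positive, got {r}")
    count = int(_count_pairs(X, np.array([float(r)]), metric)[0])
    return 2.0 * count / (N * (N - 1))


def correlation_integral_curve(
    series: np.ndarray, config: EmbeddingConfig | None = None
) -> CorrelationIntegralCurve:
    """Evaluate C_d(r) on the configured radius grid.

    The relative grid is scaled by the series' sample standard deviation
    into absolute radii; a zero-variance series is rejected because the
    scaling is undefined.
    """
    if config is None:
        config = EmbeddingConfig()
    x = np.asarray(series, dtype=float)
    sd = float(x.std(ddof=1))
    if not sd > 0:
        raise ValidationError("zero-variance series: radius scaling is undefined")
    X = delay_embed(x, config.d, config.tau)
    N = X.shape[0]
    if N < 2:
        raise ValidationError("series too short: fewer than 2 embedded vectors")
    r_abs = config.r_grid * sd
    counts = _count_pairs(X, r_abs, config.metric)
    c = 2.0 * counts / (N * (N - 1))
    return CorrelationIntegralCurve(
        r_values=r_abs,
        r_relative=config.r_grid.copy(),
        c_values=c,
        d=config.d,
        tau=config.tau,
        metric=config.metric,
        n_vectors=N,
        series_sd=sd,
    )


def estimate_correlation_dimension(curve: CorrelationIntegralCurve) -> CorrDimResult:
    """Ordinary least-squares slope of log C_d(r) against log r.

    Radii with C_d(r) = 0 (no neighbor pairs) carry no information at
    that scale and are excluded from the fit; at least 3 positive radii
    are required.
    """
    mask = curve.c_values > 0
    n_valid = int(mask.sum())
    if n_valid < 3:
        raise ValidationError(
            f"only {n_valid} radii have C_d(r) > 0; widen the radius range "
            "or use a longer series"
        )
    log_r = np.log(curve.r_values[mask])
    log_c = np.log(curve.c_values[mask])
    fit = stats.linregress(log_r, log_c)
    return CorrDimResult(
        nu=float(fit.slope),
        fit_r_range=(float(curve.r_values[mask][0]), float(curve.r_values[mask][-1])),
        fit_r2=float(fit.rvalue) ** 2,
        n_valid_points=n_valid,
    )


def sample_entropy(
    series: np.ndarray, d: int = 2, r: float = 0.2, metric: str = "chebyshev"
) -> float:
    """Sample entropy ``ln(C_d(r) / C_{d+1}(r))`` at relative radius ``r``.

    ``r`` is in units of the series' standard deviation.  Templates of
    length ``d`` and ``d + 1`` are counted over the same ``n - d``
    starting positions, so the ratio is in (0, 1] and the entropy
    nonnegative.  Returns NaN when either correlation sum is zero (no
    matches at this radius).
    """
    x = np.asarray(series, dtype=float)
    if not r > 0:
        raise ValidationError(f"r must be positive, got {r}")
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        return 0.0  # perfectly regular: every template matches at any radius
    r_abs = r * sd
    X_d = delay_embed(x, d, 1)[:-1]  # same template count at both lengths
    X_d1 = delay_embed(x, d + 1, 1)
    c_d = correlation_sum(X_d, r_abs, metric)
    c_d1 = correlation_sum(X_d1, r_abs, metric)
    if c_d == 0.0 or c_d1 == 0.0:
        return float("nan")
    return float(np.log(c_d / c_d1))
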