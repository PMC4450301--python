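"""Rescaled-range (R/S) Hurst-exponent estimation.

The Hurst exponent ``H`` of a fractal record quantifies its long-range
memory: ``H > 0.5`` persistent (a deflection tends to be followed by a
deflection of the same sign), ``H < 0.5`` antipersistent, and ``H = 0.5``
an uncorrelated random process.  The classical estimator regresses
``log(R/S)`` — the range of the mean-adjusted cumulative sum of a segment
divided by that segment's standard deviation, averaged over non-overlapping
segments — against the log of the segment length.

The raw R/S statistic is biased upward for short segments.  By default the
estimate is therefore corrected with the Anis–Lloyd expected value of R/S
under the null of an uncorrelated process (with the finite-sample
``(n − 1/2)/n`` factor): the corrected estimate is ``0.5`` plus the slope
of ``log(R/S) − log(E[R/S])`` against log segment length.  The uncorrected
ordinary-least-squares slope is available with ``corrected=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .exceptions import DegenerateSeriesError, DomainError, SeriesLengthError
from .signal import TimeSeries

__all__ = [
    "HurstEstimate",
    "HurstTrajectory",
    "rs_hurst",
    "sliding_hurst",
    "reflect_h",
    "trend_direction",
    "expected_rescaled_range",
]

_MIN_WINDOW_FLOOR = 8


@dataclass(frozen=True)
class HurstEstimate:
    """Result of one R/S regression.

    ``H`` is clamped to [0, 1]; ``raw_slope`` keeps the unclamped
    regression value.  ``slope_stderr`` is the ordinary-least-squares
    standard error of the fitted slope.
    """

    H: float
    raw_slope: float
    n_scales: int
    slope_stderr: float
    window_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.H <= 1.0:
            raise DomainError("clamped H must lie in [0, 1]")
        if self.n_scales < 3:
            raise DomainError("need at least 3 scales for a meaningful fit")


@dataclass(frozen=True)
class HurstTrajectory:
    """Time-indexed Hurst estimates from a sliding window.

    ``times`` are the trailing-edge timestamps of each window position,
    strictly increasing; ``H_values`` are clamped to [0, 1].
    """

    times: np.ndarray
    H_values: np.ndarray
    window_length: int

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        h = np.asarray(self.H_values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "H_values", h)
        if t.shape != h.shape:
            raise DomainError("times and H_values must have equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise DomainError("times must be strictly increasing")
        if h.size and (h.min() < 0.0 or h.max() > 1.0):
            raise DomainError("H values must lie in [0, 1]")

    def __len__(self) -> int:
        return self.times.size


def expected_rescaled_range(w: int) -> float:
    """Anis–Lloyd expected R/S of an uncorrelated segment of length ``w``,
    with the finite-sample (w − 1/2)/w correction."""
    if w < 2:
        raise DomainError("segment length must be >= 2")
    i = np.arange(1, w)
    tail = float(np.sum(np.sqrt((w - i) / i)))
    if w <= 340:
        front = float(np.exp(gammaln((w - 1) / 2.0) - gammaln(w / 2.0))) / np.sqrt(np.pi)
    else:
        front = 1.0 / np.sqrt(w * np.pi / 2.0)
    return (w - 0.5) / w * front * tail


def _as_array(series: TimeSeries | np.ndarray) -> np.ndarray:
    if isinstance(series, TimeSeries):
        return series.values
    return np.asarray(series, dtype=float)


def _rs_statistic(x: np.ndarray, w: int) -> float:
    """Mean R/S over non-overlapping segments of length ``w``; NaN when
    every segment is constant."""
    n = x.size
    m = n // w
    segs = x[: m * w].reshape(m, w)
    dev = segs - segs.mean(axis=1, keepdims=True)
    walk = np.cumsum(dev, axis=1)
    rng = walk.max(axis=1) - walk.min(axis=1)
    std = segs.std(axis=1)
    ok = std > 0
    if not ok.any():
        return float("nan")
    return float(np.mean(rng[ok] / std[ok]))


def rs_hurst(
    series: TimeSeries | np.ndarray,
    min_window: int = 16,
    max_window: int | None = None,
    n_scales: int = 10,
    corrected: bool = True,
) -> HurstEstimate:
    """Estimate the Hurst exponent of a record by rescaled-range analysis.

    Parameters
    ----------
    series
        The record, treated directly as the fluctuation series whose
        cumulative sum is ranged.
    min_window, max_window
        Smallest and largest segment lengths; ``max_window`` defaults to
        half the record length.  Segment lengths are spaced geometrically.
    n_scales
        Number of segment lengths requested (duplicates after rounding are
        merged; at least 3 must survive).
    corrected
        Apply the Anis–Lloyd expected-R/S bias correction (default).

    Returns
    -------
    HurstEstimate
        The (clamped) estimate together with the raw regression slope,
        its standard error and the segment lengths used.
    """
    x = _as_array(series)
    n = x.size
    if min_window < _MIN_WINDOW_FLOOR:
        raise DomainError(f"min_window must be >= {_MIN_WINDOW_FLOOR}")
    if n < 2 * min_window:
        raise SeriesLengthError(
            f"series of length {n} too short for min_window {min_window}"
        )
    if max_window is None:
        max_window = n // 2
    if not min_window < max_window <= n:
        raise DomainError("require min_window < max_window <= series length")
    if np.ptp(x) == 0.0:
        raise DegenerateSeriesError("constant series has undefined R/S")

    sizes = np.unique(
        np.round(
            np.exp(np.linspace(np.log(min_window), np.log(max_window), n_scales))
        ).astype(int)
    )
    log_w: list[float] = []
    log_rs: list[float] = []
    used: list[int] = []
    for w in sizes:
        rs = _rs_statistic(x, int(w))
        if not np.isfinite(rs) or rs <= 0:
            continue
        if corrected:
            rs /= expected_rescaled_range(int(w))
        log_w.append(np.log2(w))
        log_rs.append(np.log2(rs))
        used.append(int(w))
    if len(used) < 3:
        raise DegenerateSeriesError(
            "fewer than 3 usable scales (too many zero-variance segments)"
        )

    lw = np.asarray(log_w)
    lr = np.asarray(log_rs)
    design = np.vstack([lw, np.ones_like(lw)]).T
    coef, res, *_ = np.linalg.lstsq(design, lr, rcond=None)
    slope = float(coef[0])
    k = len(used)
    if k > 2 and res.size:
        s2 = float(res[0]) / (k - 2)
        sxx = float(np.sum((lw - lw.mean()) ** 2))
        stderr = float(np.sqrt(s2 / sxx))
    else:
        stderr = 0.0
    raw = slope + 0.5 if corrected else slope
    return HurstEstimate(
        H=float(np.clip(raw, 0.0, 1.0)),
        raw_slope=raw,
        n_scales=k,
        slope_stderr=stderr,
        window_sizes=tuple(used),
    )


def sliding_hurst(
    series: TimeSeries,
    window_length: int,
    step: int = 1,
    min_window: int = 16,
    n_scales: int = 8,
    corrected: bool = True,
) -> HurstTrajectory:
    """Track the Hurst exponent in sliding windows over a record.

    One estimate is produced per window position, timestamped at the
    window's trailing (most recent) sample.  A window in which R/S is
    degenerate (constant data) carries the previous window's value
    forward, or 0.5 at the first position.
    """
    n = len(series)
    if window_length > n:
        raise SeriesLengthError("window_length exceeds series length")
    if window_length < 2 * min_window:
        raise SeriesLengthError(
            f"window_length must be >= {2 * min_window} for R/S at "
            f"min_window={min_window}"
        )
    if step < 1:
        raise DomainError("step must be >= 1")
    if np.ptp(series.values) == 0.0:
        raise DegenerateSeriesError("constant series has undefined R/S")
    starts = range(0, n - window_length + 1, step)
    times = []
    hs = []
    prev = 0.5
    for s in starts:
        seg = series.values[s : s + window_length]
        try:
            est = rs_hurst(
                seg,
                min_window=min_window,
                max_window=window_length // 2,
                n_scales=n_scales,
                corrected=corrected,
            )
            prev = est.H
        except DegenerateSeriesError:
            pass
        hs.append(prev)
        times.append(series.t0 + (s + window_length - 1) / series.sampling_rate)
    return HurstTrajectory(
        times=np.asarray(times), H_values=np.asarray(hs), window_length=window_length
    )


def reflect_h(H: float) -> float:
    """Fold ``H`` into the reference span [0.5, 1].

    A process with exponent ``H < 0.5`` carries the same magnitude of
    fluctuation as its mirror with ``H' = 1 − H``; magnitude computations
    run in the persistent half-interval.
    """
    if not 0.0 <= H <= 1.0:
        raise DomainError("H must lie in [0, 1]")
    return H if H >= 0.5 else 1.0 - H


def trend_direction(
    H: float,
    previous_trend: int,
    rng: np.random.Generator | None = None,
) -> int:
    """Direction of the next deflection given ``H`` and the previous trend.

    Persistent (``H > 0.5``): the previous trend continues.  Antipersistent
    (``H < 0.5``): it reverses.  At exactly ``H = 0.5`` the process carries
    no correlation, so a fair coin decides; pass a seeded ``rng`` for
    reproducibility (an unseeded default generator is used otherwise).
    """
    if not 0.0 <= H <= 1.0:
        raise DomainError("H must lie in [0, 1]")
    if previous_trend not in (+1, -1):
        raise DomainError("previous_trend must be +1 or -1")
    if H > 0.5:
        return previous_trend
    if H < 0.5:
        return -previous_trend
    if rng is None:
        rng = np.random.default_rng()
    return +1 if rng.random() < 0.5 else -1
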