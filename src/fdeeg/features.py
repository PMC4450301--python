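"""Evoked-response feature extraction and real-vs-predicted comparison.

The response to a stimulus is read from the post-stimulus record as a
sequence of qualifying local extrema: deflections whose absolute voltage
reaches the response band (5–10 μV in magnitude; larger deflections also
qualify).  The response starts at the first qualifying peak (P), its
duration is the span to the last peak of the response, and the peak-to-peak
voltage is the max-minus-min over that span.  When no negative extremum
qualifies, the response is taken to terminate at the deepest local minimum
after the last qualifying peak — the negative rebound (N) at which the
record returns to rest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import PairingError, ShapeError
from .hurst import HurstTrajectory, sliding_hurst
from .signal import TimeSeries
from .synth import TrialSet

__all__ = [
    "ResponseFeatures",
    "ComparisonRow",
    "detect_response",
    "grand_average",
    "average_features",
    "compare",
    "hurst_overlay",
]


@dataclass(frozen=True)
class ResponseFeatures:
    """Features of one evoked response; all ``None`` when no response
    qualifies."""

    initiation_ms: float | None
    duration_s: float | None
    peak_to_peak_uV: float | None
    p_time_s: float | None
    n_time_s: float | None

    @property
    def detected(self) -> bool:
        return self.initiation_ms is not None

    @staticmethod
    def none() -> "ResponseFeatures":
        return ResponseFeatures(None, None, None, None, None)


@dataclass(frozen=True)
class ComparisonRow:
    label: str
    real: ResponseFeatures
    predicted: ResponseFeatures


def _local_extrema(v: np.ndarray) -> list[tuple[int, int]]:
    """(index, sign) of strict local extrema: +1 maxima, −1 minima."""
    d = np.diff(v)
    out = []
    for i in range(1, v.size - 1):
        if d[i - 1] > 0 > d[i]:
            out.append((i, +1))
        elif d[i - 1] < 0 < d[i]:
            out.append((i, -1))
    return out


def detect_response(
    series: TimeSeries,
    pos_band: tuple[float, float] = (5.0, 10.0),
    neg_band: tuple[float, float] = (-10.0, -5.0),
    baseline_correct: bool = False,
) -> ResponseFeatures:
    """Extract initiation latency, duration and peak-to-peak voltage.

    Bands are read on the absolute voltage axis by default (the record is
    assumed already referenced); ``baseline_correct=True`` subtracts the
    value at stimulus onset first.  Returns the no-response sentinel, not
    an exception, when nothing qualifies.
    """
    post = series.post_stimulus()
    v = post.values.copy()
    if baseline_correct:
        v -= v[0]
    t = post.times
    onset = series.stimulus_onset

    extrema = _local_extrema(v)
    qualifying = [
        (i, s) for i, s in extrema if v[i] >= pos_band[0] or v[i] <= neg_band[1]
    ]
    if not qualifying:
        return ResponseFeatures.none()

    p_idx = qualifying[0][0]
    last_idx = qualifying[-1][0]
    if not any(s < 0 for _, s in qualifying):
        # no negative extremum reached the band: the response terminates at
        # the negative rebound — the deepest local minimum after the last
        # qualifying peak
        minima_after = [i for i, s in extrema if s < 0 and i > last_idx]
        if minima_after:
            last_idx = min(minima_after, key=lambda i: v[i])

    p_time = float(t[p_idx])
    n_time = float(t[last_idx])
    window = v[p_idx : last_idx + 1]
    return ResponseFeatures(
        initiation_ms=(p_time - onset) * 1000.0,
        duration_s=n_time - p_time,
        peak_to_peak_uV=float(window.max() - window.min()),
        p_time_s=p_time,
        n_time_s=n_time,
    )


def grand_average(trials: TrialSet | Sequence[TimeSeries]) -> TimeSeries:
    """Pointwise mean of stimulus-aligned trials.

    Suppresses the background (≈1/√n) relative to the stimulus-locked
    response; sampling metadata of the first trial is preserved.
    """
    seq = trials.trials if isinstance(trials, TrialSet) else tuple(trials)
    if len(seq) == 0:
        raise ShapeError("need at least one trial")
    first = seq[0]
    for tr in seq[1:]:
        if len(tr) != len(first) or tr.sampling_rate != first.sampling_rate:
            raise ShapeError("trials must share length and sampling rate")
    mean = np.mean([tr.values for tr in seq], axis=0)
    return first.with_values(mean)


def average_features(rows: Sequence[ResponseFeatures]) -> ResponseFeatures:
    """Arithmetic mean of each feature over detected rows."""
    det = [r for r in rows if r.detected]
    if not det:
        return ResponseFeatures.none()

    def m(attr: str) -> float:
        return float(np.mean([getattr(r, attr) for r in det]))

    return ResponseFeatures(
        m("initiation_ms"),
        m("duration_s"),
        m("peak_to_peak_uV"),
        m("p_time_s"),
        m("n_time_s"),
    )


def compare(
    real: Sequence[TrialSet] | TrialSet,
    predicted: Sequence[TrialSet] | TrialSet,
    **detect_kwargs,
) -> list[ComparisonRow]:
    """Per-subject real-vs-predicted feature table plus an Average row.

    Features are measured on the grand average of each trial set; the
    final row carries the arithmetic mean over subjects.
    """
    if isinstance(real, TrialSet):
        real = [real]
    if isinstance(predicted, TrialSet):
        predicted = [predicted]
    if len(real) != len(predicted):
        raise PairingError(
            f"{len(real)} real sets vs {len(predicted)} predicted sets"
        )
    rows = []
    for k, (r, p) in enumerate(zip(real, predicted), start=1):
        label = r.subject_label or str(k)
        rows.append(
            ComparisonRow(
                label,
                detect_response(grand_average(r), **detect_kwargs),
                detect_response(grand_average(p), **detect_kwargs),
            )
        )
    rows.append(
        ComparisonRow(
            "Average",
            average_features([r.real for r in rows]),
            average_features([r.predicted for r in rows]),
        )
    )
    return rows


def hurst_overlay(
    real: TimeSeries,
    predicted: TimeSeries,
    window: int,
    **kwargs,
) -> tuple[HurstTrajectory, HurstTrajectory]:
    """Sliding Hurst trajectories of a real record and its prediction,
    computed with identical settings for side-by-side plotting."""
    return (
        sliding_hurst(real, window, **kwargs),
        sliding_hurst(predicted, window, **kwargs),
    )
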