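"""Signal file formats and preprocessing.

Two interchange formats are supported: plain text with one voltage per
line (sampling metadata supplied by the caller) and CSV with ``time_s``
and ``value_uV`` columns (rate inferred from the time column, checked
uniform to 1 ppm).  Preprocessing mirrors standard evoked-potential
practice: a zero-phase Butterworth bandpass and optional discrete-wavelet
shrinkage denoising.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pywt
from scipy.signal import butter, filtfilt

from .exceptions import DomainError, FormatError, ParseError, SeriesLengthError
from .hurst import HurstTrajectory
from .signal import TimeSeries

__all__ = [
    "read_signal",
    "write_signal",
    "write_trajectory",
    "bandpass",
    "wavelet_denoise",
]


def read_signal(
    path: str | Path,
    format: str | None = None,
    sampling_rate: float | None = None,
    t0: float = 0.0,
    stimulus_onset: float | None = None,
) -> TimeSeries:
    """Load a voltage record from ``.txt`` (one value per line) or ``.csv``
    (columns ``time_s``, ``value_uV``).

    For text files the sampling rate must be supplied; for CSV it is
    inferred from the time column, which must be uniform to 1 ppm.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "txt":
        if sampling_rate is None:
            raise DomainError("sampling_rate is required for txt input")
        values = []
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                s = line.strip()
                if not s:
                    continue
                try:
                    values.append(float(s))
                except ValueError as exc:
                    raise ParseError(f"{path}:{ln}: non-numeric value {s!r}") from exc
        if not values:
            raise ParseError(f"{path}: empty file")
        return TimeSeries(np.asarray(values), sampling_rate, t0, stimulus_onset)
    if fmt == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        for col in ("time_s", "value_uV"):
            if col not in df.columns:
                raise FormatError(f"{path}: missing column {col!r}")
        if len(df) < 2:
            raise ParseError(f"{path}: need at least 2 rows")
        t = df["time_s"].to_numpy(dtype=float)
        steps = np.diff(t)
        if steps.min() <= 0 or (steps.max() - steps.min()) > 1e-6 * steps.mean():
            raise FormatError(f"{path}: non-uniform timebase")
        rate = 1.0 / steps.mean()
        return TimeSeries(
            df["value_uV"].to_numpy(dtype=float), rate, float(t[0]), stimulus_onset
        )
    raise DomainError(f"unknown format {fmt!r}")


def write_signal(series: TimeSeries, path: str | Path, format: str | None = None) -> None:
    """Write a record as ``.txt`` (values only) or ``.csv`` (time + value)."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "txt":
        np.savetxt(path, series.values, fmt="%.17g")
    elif fmt == "csv":
        pd.DataFrame(
            {"time_s": series.times, "value_uV": series.values}
        ).to_csv(path, index=False, float_format="%.17g")
    else:
        raise DomainError(f"unknown format {fmt!r}")


def write_trajectory(traj: HurstTrajectory, path: str | Path) -> None:
    """Hurst trajectory as CSV with columns ``time_s``, ``H``."""
    pd.DataFrame({"time_s": traj.times, "H": traj.H_values}).to_csv(
        Path(path), index=False, float_format="%.17g"
    )


def bandpass(
    series: TimeSeries, low: float, high: float, order: int = 4
) -> TimeSeries:
    """Zero-phase Butterworth bandpass (forward-backward filtering).

    ``low = 0`` degrades gracefully to a pure lowpass.  Band edges must
    satisfy ``0 <= low < high < rate/2``.
    """
    nyq = series.sampling_rate / 2.0
    if not 0.0 <= low < high < nyq:
        raise DomainError(f"band [{low}, {high}] invalid for Nyquist {nyq}")
    if low == 0.0:
        b, a = butter(order, high / nyq, btype="low")
    else:
        b, a = butter(order, [low / nyq, high / nyq], btype="band")
    filtered = filtfilt(b, a, series.values, padtype="even")
    return series.with_values(filtered)


def wavelet_denoise(
    series: TimeSeries,
    wavelet: str = "db4",
    level: int = 4,
    threshold_mode: str = "soft",
) -> TimeSeries:
    """Discrete-wavelet shrinkage with the universal threshold.

    Detail coefficients at every level are thresholded at
    ``σ · sqrt(2 ln n)`` with ``σ`` the median-absolute-deviation noise
    estimate from the finest level.  An orthogonal (periodization)
    transform is used, so shrinkage can only reduce signal energy.
    """
    n = len(series)
    if n < 64:
        raise SeriesLengthError("need at least 64 samples for denoising")
    coeffs = pywt.wavedec(series.values, wavelet, level=level, mode="periodization")
    detail_fine = coeffs[-1]
    sigma = float(np.median(np.abs(detail_fine))) / 0.6745
    thr = sigma * np.sqrt(2.0 * np.log(n))
    if thr > 0:
        coeffs = [coeffs[0]] + [
            pywt.threshold(c, thr, mode=threshold_mode) for c in coeffs[1:]
        ]
    rec = pywt.waverec(coeffs, wavelet, mode="periodization")[:n]
    return series.with_values(rec)
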