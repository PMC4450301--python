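"""Uniformly sampled voltage traces.

:class:`TimeSeries` is the substrate every other module operates on: a
single-channel record in microvolts with a sampling rate and, when the
record contains an evoked trial, the time at which the stimulus was
applied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import DomainError, SeriesLengthError

__all__ = ["TimeSeries"]


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled single-channel voltage record.

    Parameters
    ----------
    values
        Sample values in microvolts, in temporal order.
    sampling_rate
        Samples per second, > 0.
    t0
        Time of the first sample in seconds (default 0).
    stimulus_onset
        Time in seconds at which the external stimulus was applied, or
        ``None`` for records without a stimulus marker.  Must fall inside
        the record when present.
    """

    values: np.ndarray
    sampling_rate: float
    t0: float = 0.0
    stimulus_onset: float | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 1:
            raise SeriesLengthError("values must be a non-empty 1-D array")
        if not self.sampling_rate > 0:
            raise DomainError("sampling_rate must be > 0")
        if self.stimulus_onset is not None:
            end = self.t0 + (vals.size - 1) / self.sampling_rate
            # allow half-sample slack so an onset on the last sample survives
            # floating-point construction of the time axis
            tol = 0.5 / self.sampling_rate
            if not (self.t0 - tol <= self.stimulus_onset <= end + tol):
                raise DomainError(
                    f"stimulus_onset {self.stimulus_onset} outside record "
                    f"[{self.t0}, {end}]"
                )

    def __len__(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def duration(self) -> float:
        """Span from first to last sample, seconds."""
        return (len(self) - 1) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.sampling_rate

    def index_at(self, t: float) -> int:
        """Index of the sample nearest to time ``t``."""
        i = int(round((t - self.t0) * self.sampling_rate))
        if not 0 <= i < len(self):
            raise DomainError(f"time {t} outside record")
        return i

    def value_at(self, t: float) -> float:
        return float(self.values[self.index_at(t)])

    @property
    def onset_index(self) -> int:
        if self.stimulus_onset is None:
            raise DomainError("series has no stimulus_onset")
        return self.index_at(self.stimulus_onset)

    def pre_stimulus(self) -> "TimeSeries":
        """Samples strictly before the stimulus onset."""
        i = self.onset_index
        if i < 1:
            raise SeriesLengthError("no pre-stimulus samples")
        return TimeSeries(self.values[:i], self.sampling_rate, self.t0, None)

    def post_stimulus(self) -> "TimeSeries":
        """Samples from the stimulus onset (inclusive) to the end."""
        i = self.onset_index
        return TimeSeries(
            self.values[i:],
            self.sampling_rate,
            self.t0 + i / self.sampling_rate,
            self.stimulus_onset,
        )

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        """Copy of this record with the same metadata and new samples."""
        if np.asarray(values).shape != self.values.shape:
            raise SeriesLengthError("replacement values must match length")
        return replace(self, values=np.asarray(values, dtype=float))
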