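"""Seedable synthetic EEG trials.

Real evoked-potential recordings are modelled here by their two statistical
ingredients: a fractal background — exact-covariance fractional Gaussian
noise (fGn) of prescribed Hurst exponent, generated by circulant embedding
— and a stimulus-locked evoked template (a positive peak followed by a
negative rebound) injected into the post-stimulus half of the trial.  The
default geometry is the standard checker-reversal protocol: 1 s before and
1 s after the stimulus at 256 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError, SeriesLengthError
from .signal import TimeSeries

__all__ = [
    "EvokedTemplate",
    "TrialSpec",
    "TrialSet",
    "simulate_fgn",
    "fgn_autocovariance",
    "make_trial",
    "make_session",
]


@dataclass(frozen=True)
class EvokedTemplate:
    """Stimulus-locked response shape: positive peak P then negative
    rebound N, each a Gaussian bump of common width.

    Latencies are seconds after the stimulus; amplitudes in microvolts.
    Defaults follow a typical visual evoked response (P at 118 ms, +9 μV;
    N at 170 ms, −4.97 μV).
    """

    p_latency: float = 0.118
    p_amplitude: float = 9.0
    n_latency: float = 0.170
    n_amplitude: float = -4.97
    width: float = 0.015

    def __post_init__(self) -> None:
        if not self.p_latency < self.n_latency:
            raise DomainError("P must precede N")
        if not (self.p_amplitude > 0 > self.n_amplitude):
            raise DomainError("require p_amplitude > 0 > n_amplitude")
        if not self.width > 0:
            raise DomainError("width must be > 0")

    def waveform(self, t_post: np.ndarray) -> np.ndarray:
        """Template sampled at times ``t_post`` (seconds post-stimulus)."""
        w2 = 2.0 * self.width**2
        return self.p_amplitude * np.exp(
            -((t_post - self.p_latency) ** 2) / w2
        ) + self.n_amplitude * np.exp(-((t_post - self.n_latency) ** 2) / w2)


@dataclass(frozen=True)
class TrialSpec:
    """Recipe for one synthetic trial.

    ``background_H`` defaults to 0.9, the strongly persistent regime
    typical of occipital EEG; ``background_scale`` is the background RMS
    in microvolts (default 2 μV, so ±5 μV response thresholds separate
    signal from background).
    """

    sampling_rate: float = 256.0
    pre_s: float = 1.0
    post_s: float = 1.0
    background_H: float = 0.9
    background_scale: float = 2.0
    evoked: EvokedTemplate | None = field(default_factory=EvokedTemplate)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, dur in (("pre_s", self.pre_s), ("post_s", self.post_s)):
            n = dur * self.sampling_rate
            if abs(n - round(n)) > 1e-9:
                raise DomainError(f"{name} × sampling_rate must be an integer")
        if not 0.0 < self.background_H < 1.0:
            raise DomainError("background_H must lie in (0, 1)")

    @property
    def n_pre(self) -> int:
        return int(round(self.pre_s * self.sampling_rate))

    @property
    def n_post(self) -> int:
        return int(round(self.post_s * self.sampling_rate))


@dataclass(frozen=True)
class TrialSet:
    """A session of stimulus-aligned trials from one subject."""

    trials: tuple[TimeSeries, ...]
    subject_label: str = ""

    def __post_init__(self) -> None:
        if len(self.trials) == 0:
            raise DomainError("TrialSet needs at least one trial")
        first = self.trials[0]
        for tr in self.trials[1:]:
            if (
                len(tr) != len(first)
                or tr.sampling_rate != first.sampling_rate
                or tr.stimulus_onset != first.stimulus_onset
            ):
                raise DomainError("all trials must share length, rate and onset")

    def __len__(self) -> int:
        return len(self.trials)


def fgn_autocovariance(k: np.ndarray, H: float, scale: float = 1.0) -> np.ndarray:
    """Autocovariance of unit-step fGn at integer lags ``k``."""
    k = np.abs(np.asarray(k, dtype=float))
    return (
        scale**2
        * 0.5
        * ((k + 1) ** (2 * H) - 2 * k ** (2 * H) + np.abs(k - 1) ** (2 * H))
    )


def _fgn_values(n: int, H: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance fGn by Davies–Harte circulant embedding, with a
    covariance-factorization fallback for a non-positive embedding."""
    if n == 2:
        # embedding ring degenerates; draw from the 2x2 covariance directly
        cov = fgn_autocovariance(np.array([[0, 1], [1, 0]]), H)
        return np.linalg.cholesky(cov) @ rng.standard_normal(2)
    g = fgn_autocovariance(np.arange(n), H)
    row = np.concatenate([g, g[-2:0:-1]])
    m = row.size
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8 * lam.max():
        if n > 4096:
            raise DomainError(
                "circulant embedding not positive semidefinite for this H/n"
            )
        idx = np.arange(n)
        cov = fgn_autocovariance(np.abs(idx[:, None] - idx[None, :]), H)
        return np.linalg.cholesky(cov + 1e-12 * np.eye(n)) @ rng.standard_normal(n)
    lam = np.clip(lam, 0.0, None)
    half = m // 2
    w = np.empty(m, dtype=complex)
    w[0] = np.sqrt(lam[0]) * rng.standard_normal()
    w[half] = np.sqrt(lam[half]) * rng.standard_normal()
    a = rng.standard_normal(half - 1)
    b = rng.standard_normal(half - 1)
    w[1:half] = np.sqrt(lam[1:half] / 2.0) * (a + 1j * b)
    w[half + 1 :] = np.conj(w[1:half][::-1])
    x = np.fft.fft(w) / np.sqrt(m)
    return x.real[:n]


def simulate_fgn(
    n: int,
    H: float,
    scale: float = 1.0,
    seed: int | None = None,
    sampling_rate: float = 256.0,
) -> TimeSeries:
    """Exact-covariance fractional Gaussian noise as a :class:`TimeSeries`.

    Deterministic under ``seed``; ``scale`` is the standard deviation in
    microvolts.
    """
    if n < 2:
        raise SeriesLengthError("need at least 2 samples")
    if not 0.0 < H < 1.0:
        raise DomainError("H must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    return TimeSeries(scale * _fgn_values(n, H, rng), sampling_rate)


def make_trial(spec: TrialSpec, seed: int | None = None) -> TimeSeries:
    """One synthetic trial: fGn background plus the evoked template.

    The stimulus is applied at ``t = pre_s``; the template, when present,
    is added to the post-stimulus segment only.
    """
    if seed is None:
        seed = spec.seed
    n = spec.n_pre + spec.n_post
    rng = np.random.default_rng(seed)
    if spec.background_scale > 0:
        vals = spec.background_scale * _fgn_values(n, spec.background_H, rng)
    else:
        vals = np.zeros(n)
    if spec.evoked is not None:
        t_post = np.arange(spec.n_post) / spec.sampling_rate
        vals = vals.copy()
        vals[spec.n_pre :] += spec.evoked.waveform(t_post)
    return TimeSeries(
        vals, spec.sampling_rate, t0=0.0, stimulus_onset=spec.pre_s
    )


def make_session(
    spec: TrialSpec, n_trials: int, subject_label: str = ""
) -> TrialSet:
    """Independent trials with per-trial seeds spawned from the master seed."""
    if n_trials < 1:
        raise DomainError("n_trials must be >= 1")
    children = np.random.SeedSequence(spec.seed).spawn(n_trials)
    trials = tuple(
        make_trial(spec, seed=int(c.generate_state(1)[0] % (2**31)))
        for c in children
    )
    return TrialSet(trials, subject_label)
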