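"""Fractional-integral response of the brain to an external stimulus.

The voltage record ``V(t)`` responds to an external influence — the flux
``φ(t)``, modelling the stimulus — through a Riemann–Liouville fractional
integral of order ``H`` with the weakly singular kernel ``(t − ξ)^{H−1}``::

    V(t) = V0 + C^{2H−1} D_eff^{−H} · (1/Γ(H)) ∫0^t φ(ξ) (t − ξ)^{H−1} dξ

Substituting the relaxation-time relation ``C = (D_eff/τ)^{1/2}`` turns the
prefactor into ``τ^{1/2−H} D_eff^{−1/2}`` (the default "derived" variant; a
"literal" ``τ^{1/2−H} D_eff^{−1}`` variant is kept for comparison).

The integral is evaluated by product integration: the flux is taken
piecewise linear between its samples while the kernel moments are
integrated exactly on each sub-interval, so the integrable singularity at
``ξ → t`` never meets a quadrature node.

The per-moment prediction loop couples this magnitude model to the Hurst
machinery: at each output time the current Hurst estimate (policy-
dependent) is reflected into [0.5, 1] to parameterize magnitude, the
effective diffusivity is refreshed, and the trend rule decides the sign of
the next deflection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gamma

from .diffusivity import TissueParams, effective_diffusivity
from .exceptions import DomainError, ExtrapolationError, FdeegError
from .hurst import (
    HurstTrajectory,
    reflect_h,
    rs_hurst,
    trend_direction,
)
from .signal import TimeSeries

__all__ = [
    "StimulusPulse",
    "FluxSeries",
    "ModelConfig",
    "ResponsePrediction",
    "gaussian_flux",
    "pulse_train_flux",
    "sample_flux",
    "frac_integral",
    "fractional_response",
    "growth_exponent",
    "predict_signal",
]


@dataclass(frozen=True)
class StimulusPulse:
    """Gaussian flux pulse modelling a single external stimulus.

    ``phi0`` is the peak flux (V·m/s), ``t_star`` the time of the peak and
    ``sigma`` the width parameter, both in seconds.  Defaults are the
    reference visual-stimulus parameterization (peak flux 1 V·m/s at
    2 ms with 1 ms width).
    """

    phi0: float = 1.0
    t_star: float = 0.002
    sigma: float = 0.001

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise DomainError("sigma must be > 0")


def gaussian_flux(t, pulse: StimulusPulse, conventional: bool = False):
    """Flux of a Gaussian pulse at time(s) ``t``.

    The default exponent is ``−(t − t*)² / σ²`` — the model's stated pulse
    form, in which σ is a width parameter rather than a standard
    deviation.  ``conventional=True`` selects the usual ``2σ²``
    denominator instead.
    """
    t_arr = np.asarray(t, dtype=float)
    denom = 2.0 * pulse.sigma**2 if conventional else pulse.sigma**2
    out = pulse.phi0 * np.exp(-((t_arr - pulse.t_star) ** 2) / denom)
    return float(out) if np.isscalar(t) else out


def pulse_train_flux(t, pulses: Sequence[StimulusPulse], conventional: bool = False):
    """Superposed flux of several concurrent stimuli."""
    if len(pulses) == 0:
        raise DomainError("pulse train must contain at least one pulse")
    out = sum(gaussian_flux(np.asarray(t, dtype=float), p, conventional) for p in pulses)
    return float(out) if np.isscalar(t) else out


@dataclass(frozen=True)
class FluxSeries:
    """Sampled flux history; the model clock starts at the stimulus."""

    times: np.ndarray
    flux: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.flux, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "flux", f)
        if t.shape != f.shape or t.ndim != 1 or t.size < 2:
            raise DomainError("times and flux must be equal-length 1-D, size >= 2")
        if t[0] != 0.0:
            raise DomainError("flux history must start at t = 0")
        if not np.all(np.diff(t) > 0):
            raise DomainError("times must be strictly increasing")


def sample_flux(
    pulses: StimulusPulse | Sequence[StimulusPulse],
    duration: float,
    dt: float,
    conventional: bool = False,
) -> FluxSeries:
    """Sample a pulse (train) on a uniform grid covering [0, duration]."""
    if isinstance(pulses, StimulusPulse):
        pulses = [pulses]
    n = int(np.ceil(duration / dt))
    t = np.arange(n + 1) * dt
    return FluxSeries(t, pulse_train_flux(t, pulses, conventional))


def frac_integral(flux: FluxSeries, H: float, t: float) -> float:
    """Riemann–Liouville fractional integral of the flux at time ``t``.

    Computes ``(1/Γ(H)) ∫0^t φ(ξ) (t − ξ)^{H−1} dξ`` by product
    integration: on each sub-interval the flux is linear between its two
    samples and the kernel moments

    ``M0 = ∫ (t − ξ)^{H−1} dξ = (b^H − a^H)/H`` and
    ``M1 = ∫ ξ (t − ξ)^{H−1} dξ = t·M0 − (b^{H+1} − a^{H+1})/(H+1)``

    (with ``a = t − ξ_hi``, ``b = t − ξ_lo``) are exact, so the weak
    singularity at ``ξ = t`` is integrated analytically.
    """
    if not 0.0 < H <= 1.0:
        raise DomainError("H must lie in (0, 1]")
    tt = flux.times
    if t < 0 or t > tt[-1] + 1e-12 * max(1.0, tt[-1]):
        raise ExtrapolationError(f"t={t} outside flux support [0, {tt[-1]}]")
    t = min(t, float(tt[-1]))
    if t == 0.0:
        return 0.0

    k = int(np.searchsorted(tt, t, side="left"))
    # sub-interval endpoints, last one cut at t
    lo = tt[:k].copy()
    hi = np.minimum(tt[1 : k + 1], t)
    f_lo = flux.flux[:k]
    f_hi = np.where(
        tt[1 : k + 1] <= t,
        flux.flux[1 : k + 1],
        np.interp(t, tt, flux.flux),
    )
    width = hi - lo
    keep = width > 0
    lo, hi, f_lo, f_hi, width = lo[keep], hi[keep], f_lo[keep], f_hi[keep], width[keep]

    a = t - hi  # smaller kernel argument (0 on the final interval)
    b = t - lo
    m0 = (np.power(b, H) - np.power(a, H)) / H
    m1 = t * m0 - (np.power(b, H + 1.0) - np.power(a, H + 1.0)) / (H + 1.0)
    slope = (f_hi - f_lo) / width
    total = float(np.sum(f_lo * m0 + slope * (m1 - lo * m0)))
    return total / float(gamma(H))


def fractional_response(
    flux: FluxSeries,
    H: float,
    D_eff: float,
    tau: float,
    V0: float,
    t: float,
    variant: str = "derived",
    flux_to_uv: float = 1.0,
) -> float:
    """Voltage at time ``t`` driven by the flux history.

    ``variant="derived"`` uses the prefactor ``τ^{1/2−H} D_eff^{−1/2}``
    obtained by substituting ``C = (D_eff/τ)^{1/2}`` into the solution's
    ``C^{2H−1} D_eff^{−H}``; ``variant="literal"`` uses
    ``τ^{1/2−H} / D_eff``.  ``flux_to_uv`` is the explicit unit bridge
    from flux voltage units to microvolts.
    """
    if not D_eff > 0:
        raise DomainError("D_eff must be > 0")
    if not tau > 0:
        raise DomainError("tau must be > 0")
    if variant == "derived":
        pref = tau ** (0.5 - H) / np.sqrt(D_eff)
    elif variant == "literal":
        pref = tau ** (0.5 - H) / D_eff
    else:
        raise DomainError(f"unknown variant {variant!r}")
    return V0 + flux_to_uv * pref * frac_integral(flux, H, t)


def growth_exponent(H: float, t_grid: np.ndarray | None = None) -> float:
    """Power-law growth exponent of the response under constant unit flux.

    Fits the slope of ``log(V − V0)`` against ``log t`` on a log-spaced
    grid; for constant flux the integral is ``t^H / Γ(H+1)`` exactly, so
    the fitted slope equals ``H`` to round-off.
    """
    if t_grid is None:
        t_grid = np.logspace(-2, 1, 16)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size < 8:
        raise DomainError("need at least 8 grid points")
    t_max = float(t_grid.max())
    support = np.linspace(0.0, t_max, 257)
    flux = FluxSeries(support, np.ones_like(support))
    v = np.array([frac_integral(flux, H, t) for t in t_grid])
    slope = np.polyfit(np.log(t_grid), np.log(v), 1)[0]
    return float(slope)


@dataclass(frozen=True)
class ModelConfig:
    """Everything the per-moment prediction loop needs.

    ``H_policy`` selects where the running Hurst exponent comes from:
    ``"fixed"`` (use ``fixed_H`` throughout), ``"prestim"`` (the estimate
    from the full pre-stimulus record, held constant), or ``"trailing"``
    (re-estimated each step over the trailing ``window_length`` samples of
    the concatenated pre-stimulus + predicted record; the default,
    free-running convention).
    """

    params: TissueParams = field(default_factory=TissueParams)
    pulses: tuple[StimulusPulse, ...] = (StimulusPulse(),)
    V0: float = 0.0
    eta_label: str = ""
    H_policy: str = "trailing"
    fixed_H: float | None = None
    dt: float = 1.0 / 256.0
    window_length: int | None = None
    flux_to_uv: float = 1.0
    variant: str = "derived"
    conventional_pulse: bool = False
    reflect: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise DomainError("dt must be > 0")
        if not np.isfinite(self.V0):
            raise DomainError("V0 must be finite")
        if self.H_policy not in ("fixed", "prestim", "trailing"):
            raise DomainError(f"unknown H_policy {self.H_policy!r}")
        if self.H_policy == "fixed" and self.fixed_H is None:
            raise DomainError("H_policy='fixed' requires fixed_H")


@dataclass(frozen=True)
class ResponsePrediction:
    """Predicted record plus the per-moment H and D_eff trajectories."""

    series: TimeSeries
    H_trajectory: HurstTrajectory
    D_eff_trajectory: np.ndarray  # m²/s, one value per predicted step

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.series.values)):
            raise FdeegError("predicted values must be finite (boundedness)")


def predict_signal(
    prestim: TimeSeries,
    config: ModelConfig,
    duration: float,
) -> ResponsePrediction:
    """Run the per-moment prediction loop for ``duration`` seconds.

    At each step ``t_k = k·dt`` after the stimulus: (1) the running Hurst
    exponent ``H_k`` is obtained per ``H_policy`` (the first estimate
    always comes from the full pre-stimulus record); (2) its reflection
    into [0.5, 1] parameterizes magnitude; (3) ``D_eff`` is refreshed from
    the diffusivity law at ``t_k``; (4) the frozen-coefficient magnitude
    model ``M_k = M(t_k; H_k, D_eff,k)`` (current coefficients applied to
    the whole flux history) is evaluated, and the magnitude increment is
    ``ΔM_k = M_k − M_{k−1}``; (5) the model's proposed trend ``sign(ΔM_k)``
    is passed through the trend rule at the *unreflected* ``H_k`` —
    persistent keeps it, antipersistent reverses it — and the signed
    magnitude increment is applied.  Under a persistent ``H`` the
    increments telescope, so the output equals the direct model evaluation
    exactly.
    """
    if duration <= 0:
        raise DomainError("duration must be > 0")
    n_steps = int(round(duration / config.dt))
    if n_steps < 1:
        raise DomainError("duration shorter than one step")
    rng = np.random.default_rng(config.seed)

    window = config.window_length or len(prestim)
    h0 = rs_hurst(prestim).H
    # the flux grid must resolve the pulse width, not just the output step
    flux_dt = min(config.dt, min(p.sigma for p in config.pulses) / 8.0)
    flux = sample_flux(
        config.pulses, n_steps * config.dt, flux_dt, config.conventional_pulse
    )

    record = list(prestim.values)  # grows with predictions (trailing policy)
    values = [config.V0]
    h_list = []
    d_list = []
    t_list = []
    prev_m = config.V0

    for k in range(1, n_steps + 1):
        t_k = k * config.dt
        if config.H_policy == "fixed":
            h_k = float(config.fixed_H)  # type: ignore[arg-type]
        elif config.H_policy == "prestim":
            h_k = h0
        else:
            if k == 1:
                h_k = h0
            else:
                tail = np.asarray(record[-window:])
                try:
                    h_k = rs_hurst(tail).H
                except (ValueError, FdeegError):
                    h_k = h_list[-1] if h_list else h0
        h_mag = reflect_h(h_k) if config.reflect else h_k
        d_k = effective_diffusivity(t_k, h_mag, config.params, reflect=False)
        if d_k <= 0:
            # z = 0 or underflow: no diffusive transport yet, hold the level
            values.append(values[-1])
            record.append(values[-1])
            h_list.append(h_k)
            d_list.append(d_k)
            t_list.append(t_k)
            continue
        m_curr = fractional_response(
            flux, h_mag, d_k, config.params.tau, config.V0, t_k,
            config.variant, config.flux_to_uv,
        )
        delta = m_curr - prev_m
        proposed = +1 if delta >= 0 else -1
        direction = trend_direction(h_k, proposed, rng)
        v_k = values[-1] + direction * abs(delta)
        if not np.isfinite(v_k):
            raise FdeegError("non-finite value in prediction loop")
        values.append(v_k)
        record.append(v_k)
        h_list.append(h_k)
        d_list.append(d_k)
        t_list.append(t_k)
        prev_m = m_curr

    onset = prestim.t0 + len(prestim) / prestim.sampling_rate
    series = TimeSeries(
        np.asarray(values),
        sampling_rate=1.0 / config.dt,
        t0=onset,
        stimulus_onset=onset,
    )
    traj = HurstTrajectory(
        times=onset + np.asarray(t_list),
        H_values=np.clip(np.asarray(h_list), 0.0, 1.0),
        window_length=window,
    )
    return ResponsePrediction(series, traj, np.asarray(d_list))
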