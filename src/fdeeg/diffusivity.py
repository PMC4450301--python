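"""Effective diffusivity of neural tissue from the phase-lagging relation.

Equating the phase-lagging model of the action potential with the
fractional-diffusion description of the same record yields a closed-form
law for the ratio of the effective (time-dependent) diffusivity ``D_eff``
to the constant tissue diffusivity ``D`` in terms of the dimensionless
time ``z = t / 2τ`` and the Hurst exponent ``H``::

    D_eff / D = [ 2^{1−H} Γ(H) z^{1−H} I0(z) e^{−z} ]²

where ``I0`` is the zero-order modified Bessel function of the first kind.
The product ``I0(z)·e^{−z}`` is evaluated directly in exponentially scaled
form (``scipy.special.i0e``) so the law remains finite at large ``z``.

Large-``z`` behaviour follows from ``I0(z) ~ e^z / sqrt(2πz)``::

    D_eff / D  →  2^{1−2H} Γ(H)² / π · z^{1−2H}

which tends to 1 for ``H = 1/2`` (classical diffusion) and to 0 for
``1/2 < H ≤ 1``.  The unsquared bracket is available for comparison via
``squared=False`` but is inconsistent with these limits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gamma, i0e

from .exceptions import DomainError

__all__ = [
    "TissueParams",
    "DiffusivityCurve",
    "dimensionless_diffusivity",
    "asymptotic_ratio",
    "effective_diffusivity",
    "diffusivity_curve",
    "propagation_speed",
]

#: Default relaxation time in seconds.  The model is undefined without τ;
#: this default is of the same order as the stimulus width and should be
#: reviewed for any real dataset (the CLI logs the value used on every run).
DEFAULT_TAU = 1e-3


@dataclass(frozen=True)
class TissueParams:
    """Constant physical properties of the neural tissue.

    Parameters
    ----------
    D
        Tissue diffusion coefficient, m²/s (> 0).  Governs how strongly
        the tissue dampens an electrical impulse travelling over the nerve.
    tau
        Relaxation time, seconds (> 0): the finite lag between a stimulus
        and the response, tied to the impulse propagation speed ``C`` by
        ``τ = D_eff / C²``.
    """

    D: float = 6.5e-4
    tau: float = DEFAULT_TAU

    def __post_init__(self) -> None:
        if not self.D > 0:
            raise DomainError("D must be > 0")
        if not self.tau > 0:
            raise DomainError("tau must be > 0")


@dataclass(frozen=True)
class DiffusivityCurve:
    """Sampled D_eff/D ratio curve for one Hurst exponent."""

    z_values: np.ndarray
    ratio_values: np.ndarray
    H: float

    def __post_init__(self) -> None:
        z = np.asarray(self.z_values, dtype=float)
        r = np.asarray(self.ratio_values, dtype=float)
        object.__setattr__(self, "z_values", z)
        object.__setattr__(self, "ratio_values", r)
        if z.shape != r.shape:
            raise DomainError("z_values and ratio_values must align")
        if z.size > 1 and not np.all(np.diff(z) > 0):
            raise DomainError("z_values must be increasing")
        if r.size and r.min() < 0:
            raise DomainError("ratio values must be >= 0")


def _check_h(H: float) -> None:
    if not 0.0 < H <= 1.0:
        raise DomainError("H must lie in (0, 1] (Gamma pole at 0)")


def dimensionless_diffusivity(z, H: float, squared: bool = True):
    """Ratio D_eff/D at dimensionless time ``z = t/2τ``.

    Vectorized over ``z``.  ``squared`` selects the default squared-bracket
    reading, which is the one consistent with the law's large-``z`` limits.
    """
    _check_h(H)
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr < 0):
        raise DomainError("z must be >= 0")
    # 0^0 := 1 covers the H = 1 endpoint at z = 0
    bracket = 2.0 ** (1.0 - H) * gamma(H) * np.power(z_arr, 1.0 - H) * i0e(z_arr)
    out = bracket**2 if squared else bracket
    return float(out) if np.isscalar(z) else out


def asymptotic_ratio(z, H: float):
    """Large-``z`` power law of the ratio: ``2^{1−2H} Γ(H)²/π · z^{1−2H}``."""
    _check_h(H)
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr <= 0):
        raise DomainError("z must be > 0 for the asymptotic form")
    out = 2.0 ** (1.0 - 2.0 * H) * gamma(H) ** 2 / np.pi * np.power(z_arr, 1.0 - 2.0 * H)
    return float(out) if np.isscalar(z) else out


def effective_diffusivity(
    t: float,
    H: float,
    params: TissueParams,
    reflect: bool = True,
) -> float:
    """Effective diffusivity ``D_eff(t)`` in m²/s.

    ``H`` below 0.5 is folded into the reference span [0.5, 1] by default
    (``H' = 1 − H`` carries the same fluctuation magnitude); pass
    ``reflect=False`` to evaluate the law at the given ``H`` directly.
    """
    if t < 0:
        raise DomainError("t must be >= 0")
    if reflect:
        from .hurst import reflect_h

        H = reflect_h(H)
    z = t / (2.0 * params.tau)
    return params.D * dimensionless_diffusivity(z, H)


def diffusivity_curve(z_values, H: float) -> DiffusivityCurve:
    """Evaluate the ratio law on a grid of dimensionless times."""
    z = np.asarray(z_values, dtype=float)
    return DiffusivityCurve(z, dimensionless_diffusivity(z, H), H)


def propagation_speed(D_eff: float, tau: float) -> float:
    """Impulse propagation speed ``C = sqrt(D_eff / τ)`` in m/s."""
    if D_eff < 0:
        raise DomainError("D_eff must be >= 0")
    if not tau > 0:
        raise DomainError("tau must be > 0")
    return float(np.sqrt(D_eff / tau))
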