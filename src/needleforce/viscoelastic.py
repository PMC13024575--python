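"""Linear viscoelastic stress-strain law used for renal tissue.

The rate-dependent law implemented here is

    sigma(t) = E * eps(t) + eta * d(eps)/dt

i.e. an elastic term in parallel with a viscous term. Note that although
this additive form is often introduced alongside a spring-dashpot-in-series
sketch, the equation as written is algebraically the parallel
(Kelvin-Voigt) arrangement; it is implemented exactly as stated, with no
series ODE substituted. The strain rate is computed by central differences
at interior samples and one-sided differences at the ends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MaxwellParams", "StrainHistory", "stress_response",
           "ramp_stress_closed_form"]


@dataclass(frozen=True)
class MaxwellParams:
    """Elastic modulus E (stress units) and viscosity eta (stress * s)."""

    E: float
    eta: float

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError(f"E must be > 0, got {self.E}")
        if not self.eta >= 0:
            raise ValueError(f"eta must be >= 0, got {self.eta}")


@dataclass
class StrainHistory:
    """Sampled strain trajectory eps(t) on a strictly increasing time grid."""

    t: np.ndarray
    eps: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.eps = np.asarray(self.eps, dtype=float)
        if self.t.size != self.eps.size:
            raise ValueError("t and eps must have equal length")
        if self.t.size < 2:
            raise ValueError("strain history needs at least 2 samples")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("time samples must be strictly increasing")


def stress_response(h: StrainHistory, m: MaxwellParams) -> np.ndarray:
    """Stress sigma_i = E*eps_i + eta*(deps/dt)_i along a strain history.

    The strain rate uses ``numpy.gradient``: second-order central
    differences at interior points, first-order one-sided at the two ends,
    so interior accuracy is O(dt^2) on smooth strains.
    """
    rate = np.gradient(h.eps, h.t)
    return m.E * h.eps + m.eta * rate


def ramp_stress_closed_form(t, rate: float, m: MaxwellParams):
    """Exact stress under a constant-rate ramp eps(t) = rate * t.

    Closed-form oracle for :func:`stress_response`:
    sigma(t) = E*rate*t + eta*rate.
    """
    t = np.asarray(t, dtype=float)
    out = m.E * rate * t + m.eta * rate
    return out if out.ndim else float(out)
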