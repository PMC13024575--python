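"""Closed-form tri-component puncture force model.

The axial force on a needle advancing into soft tissue is decomposed as

    f_needle(z) = f_cutting(z) + f_stiffness(z) + f_friction(z)

with depth z measured along the insertion axis (mm):

* cutting   — energy spent fracturing tissue at the tip; either a
  saturating exponential ``f_max * (1 - exp(-lam * z))`` or, in the stable
  cutting phase, a constant ``Gamma * w0``;
* stiffness — elastic restoring force of compressed tissue,
  ``k0 * exp(alpha*z) * z * sin(theta)`` with theta the puncture angle
  (90 deg = perpendicular);
* friction  — modified-Coulomb shaft resistance, the integral of the
  stiffness-derived normal stress along the inserted length, which has the
  closed form ``mu0*k0*sin(theta) * (exp(alpha*d)*(alpha*d - 1) + 1)/alpha**2``.

All component functions accept scalar or array depths and return matching
shapes. Depths must be non-negative; angles must lie in (0, 90] degrees.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import integrate

from .curve import ForceCurve
from .params import DomainError, TissueParams, validate_angle

__all__ = [
    "cutting_force_saturating",
    "cutting_force_constant",
    "stiffness_force",
    "friction_force_closed",
    "friction_force_quadrature",
    "total_force",
    "force_profile",
    "ForceDecomposition",
    "ALPHA_SWITCH",
]

# Below this alpha the friction closed form is replaced by its removable
# alpha -> 0 limit mu0*k0*sin(theta)*d^2/2 to avoid catastrophic cancellation.
ALPHA_SWITCH = 1e-6


def _check_depth(z):
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise DomainError("depth must be non-negative")
    return z


def cutting_force_saturating(z, p: TissueParams):
    """Saturating cutting force f_max * (1 - exp(-lam * z)) in N.

    Rises linearly (~ f_max*lam*z) near the surface and approaches the
    tissue rupture-force limit f_max at depth.
    """
    z = _check_depth(z)
    out = p.f_max * (-np.expm1(-p.lam * z))
    return out if out.ndim else float(out)


def cutting_force_constant(p: TissueParams):
    """Constant stable-phase cutting force Gamma * w0 (N), depth independent."""
    if p.gamma_w0 is None:
        raise DomainError(
            "constant cutting model requires gamma_w0 on TissueParams")
    return float(p.gamma_w0)


def stiffness_force(z, p: TissueParams, theta_deg: float = 90.0):
    """Elastic stiffness force k0 * exp(alpha*z) * z * sin(theta) in N."""
    z = _check_depth(z)
    validate_angle(theta_deg)
    s = np.sin(np.deg2rad(theta_deg))
    out = p.k0 * np.exp(p.alpha * z) * z * s
    return out if out.ndim else float(out)


def friction_force_closed(d, p: TissueParams, theta_deg: float = 90.0):
    """Closed-form modified-Coulomb shaft friction at insertion depth d (N).

    Analytic integral of mu0*k0*sin(theta)*z*exp(alpha*z) over [0, d].
    For alpha below ``ALPHA_SWITCH`` the removable-singularity limit
    mu0*k0*sin(theta)*d^2/2 is used.
    """
    d = _check_depth(d)
    validate_angle(theta_deg)
    s = np.sin(np.deg2rad(theta_deg))
    pref = p.mu0 * p.k0 * s
    if p.alpha < ALPHA_SWITCH:
        out = pref * d * d / 2.0
    else:
        a = p.alpha
        out = pref * (np.exp(a * d) * (a * d - 1.0) + 1.0) / (a * a)
    return out if np.ndim(out) else float(out)


def friction_force_quadrature(d, p: TissueParams, theta_deg: float = 90.0):
    """Shaft friction by adaptive quadrature of the Coulomb integrand.

    Independent numerical oracle for :func:`friction_force_closed`:
    integrates mu0*k0*sin(theta)*z*exp(alpha*z) over [0, d] with
    ``scipy.integrate.quad``.
    """
    d_arr = _check_depth(d)
    validate_angle(theta_deg)
    s = np.sin(np.deg2rad(theta_deg))
    pref = p.mu0 * p.k0 * s

    def one(dd: float) -> float:
        if dd == 0.0:
            return 0.0
        val, err = integrate.quad(
            lambda z: z * np.exp(p.alpha * z), 0.0, dd,
            epsabs=1e-14, epsrel=1e-12, limit=200)
        if not np.isfinite(val) or err > max(1e-10, 1e-8 * abs(val)):
            raise ArithmeticError(
                f"friction quadrature failed at d={dd}: value={val}, "
                f"abserr={err}")
        return pref * val

    if d_arr.ndim:
        return np.array([one(float(x)) for x in d_arr])
    return one(float(d_arr))


class ForceDecomposition(NamedTuple):
    """Total puncture force and its three components (N)."""

    total: object
    cutting: object
    stiffness: object
    friction: object


def total_force(z, p: TissueParams, theta_deg: float = 90.0,
                cutting_mode: str = "saturating") -> ForceDecomposition:
    """Total puncture force at depth z with its decomposition.

    cutting_mode selects the saturating exponential model (default) or the
    constant stable-phase model (requires ``gamma_w0``).
    """
    z = _check_depth(z)
    if cutting_mode == "saturating":
        fc = cutting_force_saturating(z, p)
    elif cutting_mode == "constant":
        fc = cutting_force_constant(p)
        fc = np.broadcast_to(fc, z.shape).copy() if z.ndim else fc
    else:
        raise DomainError(f"unknown cutting_mode {cutting_mode!r}")
    fs = stiffness_force(z, p, theta_deg)
    ff = friction_force_closed(z, p, theta_deg)
    return ForceDecomposition(fc + fs + ff, fc, fs, ff)


def force_profile(grid, p: TissueParams, theta_deg: float = 90.0,
                  cutting_mode: str = "saturating",
                  speed: float = 1.0) -> ForceCurve:
    """Evaluate the total force on a sorted depth grid and wrap as a curve.

    ``speed`` (mm/s) only sets the implied time axis t = depth/speed of the
    returned :class:`ForceCurve`; the model itself is depth-driven.
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise DomainError("depth grid must be non-empty")
    if np.any(np.diff(grid) <= 0) and grid.size > 1:
        raise DomainError("depth grid must be sorted strictly increasing")
    if not speed > 0:
        raise DomainError("speed must be > 0")
    dec = total_force(grid, p, theta_deg, cutting_mode)
    meta = {
        "kind": "analytic_profile",
        "tissue": p.label,
        "theta_deg": theta_deg,
        "cutting_mode": cutting_mode,
        "speed_mm_s": speed,
        **{f"param_{k}": v for k, v in p.as_dict().items()},
    }
    return ForceCurve(t=grid / speed, depth=grid, force=np.asarray(dec.total),
                      meta=meta)
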