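"""Nonlinear least-squares identification of tissue parameters.

Model parameters (f_max, lam, k0, alpha, and optionally mu0) are
identified from insertion-phase force-depth samples by minimizing the sum
of squared residuals between the analytic tri-component model and the
observations — equivalently the RMSE. The optimizer is a trust-region
variant of Levenberg-Marquardt (``scipy.optimize.least_squares`` with the
``trf`` method) so simple box bounds are handled smoothly. Only the
insertion phase is fitted: the model carries no retraction equation.

By default mu0 is held fixed (0.2): at fixed alpha, mu0 and k0 enter the
friction term only through their product, so freeing both is weakly
identified; the near-collinearity is surfaced through the condition number
of the Jacobian when a user frees both anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from . import force_model
from .curve import ForceCurve
from .evaluation import r_squared as _r2
from .params import TissueParams

__all__ = ["FitConfig", "FitResult", "residuals", "fit_model",
           "recovery_report", "PARAM_NAMES"]

PARAM_NAMES = ("f_max", "lam", "k0", "alpha", "mu0")
DEFAULT_BOUNDS = (1e-4, 100.0)


@dataclass
class FitConfig:
    """Optimizer settings for :func:`fit_model`.

    ``fixed`` names parameters held at their init value (default: mu0).
    ``multi_start`` > 1 adds seeded log-uniform restarts around the init,
    useful on noisy data with a poor starting point.
    """

    init: Optional[TissueParams] = None
    bounds: dict = field(default_factory=dict)  # name -> (lo, hi)
    max_iter: int = 500
    cost_tol: float = 1e-10
    step_tol: float = 1e-10
    grad_tol: float = 1e-10
    fixed: frozenset = frozenset({"mu0"})
    multi_start: int = 1
    cutting_mode: str = "saturating"

    def bound(self, name: str):
        return self.bounds.get(name, DEFAULT_BOUNDS)


@dataclass
class FitResult:
    """Identified parameters with goodness-of-fit and diagnostics."""

    params: TissueParams
    rmse: float
    r_squared: float
    n_iter: int
    converged: bool
    residual_sd: float
    covariance: Optional[np.ndarray]  # approximate, from the Jacobian
    free_names: tuple
    cost: float
    jacobian_cond: float
    message: str = ""

    def stderr(self) -> Optional[dict]:
        """Approximate standard errors of the free parameters, if available."""
        if self.covariance is None:
            return None
        se = np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))
        return dict(zip(self.free_names, se))


def _insertion_samples(curve: ForceCurve):
    ins = curve.insertion()
    if len(ins) == 0:
        raise ValueError("curve has no insertion-phase samples")
    return ins.depth, ins.force


def _assemble(free_names, x, base: TissueParams) -> TissueParams:
    vals = base.as_dict()
    vals.pop("gamma_w0", None)
    vals.update({n: float(v) for n, v in zip(free_names, x)})
    return TissueParams(**vals, gamma_w0=base.gamma_w0, label=base.label)


def residuals(params: TissueParams, curve: ForceCurve,
              theta_deg: float = 90.0,
              cutting_mode: str = "saturating") -> np.ndarray:
    """Model-minus-observed force at every insertion sample."""
    depth, force = _insertion_samples(curve)
    model = np.asarray(force_model.total_force(
        depth, params, theta_deg, cutting_mode).total)
    return model - force


def _heuristic_init(depth: np.ndarray, force: np.ndarray,
                    mu0: float) -> TissueParams:
    """Data-driven starting point when the user supplies none.

    f_max starts at 80% of the observed peak; lam at 3/max_depth (cutting
    saturated by roughly a third of the stroke); k0 and alpha from a
    log-linear fit of the late-depth force gradient, which the exponential
    stiffness term dominates.
    """
    f_max = max(0.8 * float(force.max()), 1e-3)
    lam = 3.0 / float(depth.max())
    k0, alpha = 0.05, 0.1
    late = depth >= 0.5 * depth.max()
    if late.sum() >= 5:
        g = np.gradient(force[late], depth[late])
        pos = g > 0
        if pos.sum() >= 3:
            slope, intercept = np.polyfit(depth[late][pos],
                                          np.log(g[pos]), 1)
            alpha = float(np.clip(slope, 1e-3, 2.0))
            # late gradient ~ k0*exp(alpha z)*(1 + alpha z + mu0 z);
            # anchor k0 at the median late depth
            zm = float(np.median(depth[late][pos]))
            gm = float(np.exp(intercept + slope * zm))
            k0 = float(np.clip(
                gm / ((1.0 + alpha * zm + mu0 * zm) * np.exp(alpha * zm)),
                1e-3, 10.0))
    return TissueParams(f_max=f_max, lam=lam, k0=k0, alpha=alpha, mu0=mu0)


def fit_model(curve: ForceCurve, theta_deg: float = 90.0,
              cfg: Optional[FitConfig] = None, seed=None) -> FitResult:
    """Identify tissue parameters from one (or a pooled) force curve.

    Deterministic for a given curve, config and seed; the seed only feeds
    the optional multi-start jitter. Non-convergence returns the best
    iterate with ``converged=False``; a singular Jacobian leaves the
    covariance unavailable (None).
    """
    cfg = cfg or FitConfig()
    depth, force = _insertion_samples(curve)
    if depth.size < 10:
        raise ValueError(f"need >= 10 insertion samples, got {depth.size}")

    base = cfg.init or _heuristic_init(depth, force,
                                       mu0=(cfg.init.mu0 if cfg.init else 0.2))
    free_names = tuple(n for n in PARAM_NAMES if n not in cfg.fixed)
    if not free_names:
        raise ValueError("at least one parameter must be free")
    x0 = np.array([getattr(base, n) for n in free_names], dtype=float)
    lo = np.array([cfg.bound(n)[0] for n in free_names])
    hi = np.array([cfg.bound(n)[1] for n in free_names])
    x0 = np.clip(x0, lo, hi)

    def fun(x):
        p = _assemble(free_names, x, base)
        return np.asarray(force_model.total_force(
            depth, p, theta_deg, cfg.cutting_mode).total) - force

    starts = [x0]
    if cfg.multi_start > 1:
        rng = np.random.default_rng(seed)
        for _ in range(cfg.multi_start - 1):
            jitter = np.exp(rng.uniform(np.log(0.5), np.log(2.0),
                                        size=x0.size))
            starts.append(np.clip(x0 * jitter, lo, hi))

    best = None
    for s in starts:
        res = least_squares(fun, s, bounds=(lo, hi), method="trf",
                            ftol=cfg.cost_tol, xtol=cfg.step_tol,
                            gtol=cfg.grad_tol, max_nfev=cfg.max_iter * 10)
        if best is None or res.cost < best.cost:
            best = res

    x = best.x
    p = _assemble(free_names, x, base)
    r = best.fun
    n, k = r.size, x.size
    rmse_val = float(np.sqrt(np.mean(r ** 2)))
    resid_sd = float(np.sqrt(np.sum(r ** 2) / max(n - k, 1)))
    J = best.jac
    # column-normalized condition number: scale-invariant, so it measures
    # parameter collinearity rather than unit disparities
    norms = np.linalg.norm(J, axis=0)
    norms[norms == 0.0] = 1.0
    try:
        cond = float(np.linalg.cond(J / norms))
    except np.linalg.LinAlgError:  # pragma: no cover
        cond = float("inf")
    cov = None
    jtj = J.T @ J
    if np.all(np.isfinite(jtj)):
        try:
            cov = resid_sd ** 2 * np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            cov = None
    return FitResult(
        params=p, rmse=rmse_val, r_squared=_r2(force, force + r),
        n_iter=int(best.nfev), converged=bool(best.status > 0),
        residual_sd=resid_sd, covariance=cov, free_names=free_names,
        cost=float(best.cost), jacobian_cond=cond, message=str(best.message))


def recovery_report(true_params: TissueParams, fits) -> "pd.DataFrame":
    """Per-parameter recovery summary over repeated fits.

    One row per free parameter: truth, mean estimate, bias, median and
    90%-quantile absolute relative error, and the coverage of approximate
    95% normal confidence intervals built from the Jacobian covariance.
    """
    import pandas as pd

    fits = list(fits)
    if not fits:
        raise ValueError("need at least one fit")
    free = fits[0].free_names
    rows = []
    for j, name in enumerate(free):
        truth = float(getattr(true_params, name))
        ests = np.array([getattr(f.params, name) for f in fits])
        rel = np.abs(ests - truth) / abs(truth)
        cover = []
        for f in fits:
            se = f.stderr()
            if se is not None and se[name] > 0:
                cover.append(abs(getattr(f.params, name) - truth)
                             <= 1.96 * se[name])
        rows.append({
            "param": name, "truth": truth, "mean_est": float(ests.mean()),
            "bias": float(ests.mean() - truth),
            "median_abs_rel_err": float(np.median(rel)),
            "q90_abs_rel_err": float(np.quantile(rel, 0.9)),
            "ci95_coverage": float(np.mean(cover)) if cover else float("nan"),
        })
    return pd.DataFrame(rows)
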