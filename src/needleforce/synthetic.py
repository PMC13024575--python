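"""Synthetic puncture-trial generator.

The measured porcine liver / renal force curves behind the validation study
are not publicly deposited, so this module generates trials with the same
statistical structure instead: the analytic tri-component force model
drives the noiseless trajectory, additive i.i.d. Gaussian measurement
noise (default sd 0.02 N, roughly 1-2% of liver peak forces) emulates
sensor fluctuation, a full speed x angle factorial with 5 repeats per
condition mirrors the experimental design, and a three-layer renal profile
(cortex: slow linear rise; medulla: steep rise; calyx: slow,
friction-dominated rise) reproduces the layered force-gradient signature.

What is deliberately *not* emulated: tissue anisotropy/heterogeneity
within a layer, stick-slip friction, rupture events, or the empirical
inverse angle trend caused by longer capsule paths at shallow angles (the
analytic model scales as sin(theta) and the generator follows the model).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.special import expit

from . import force_model
from .curve import PHASE_INSERTION, PHASE_RETRACTION, ForceCurve
from .params import (DomainError, InsertionProtocol, LayerProfile,
                     LayerSegment, TissueParams)
from .perturbation import PerturbationSpec, apply_perturbation
from .viscoelastic import MaxwellParams, StrainHistory, stress_response

__all__ = ["TrialSpec", "generate_insertion_curve", "generate_layered_curve",
           "add_retraction_phase", "generate_experiment", "ExperimentDataset",
           "renal_three_layer", "DEFAULT_NOISE_SD", "DEFAULT_SPEEDS",
           "DEFAULT_ANGLES", "DEFAULT_REPS"]

DEFAULT_NOISE_SD = 0.02  # N
DEFAULT_SPEEDS = (0.5, 1.5, 2.5)  # mm/s
DEFAULT_ANGLES = (15.0, 30.0, 45.0)  # degrees
DEFAULT_REPS = 5


def renal_three_layer(transition_width: float = 0.5) -> LayerProfile:
    """Default three-layer renal fixture: cortex / medulla / calyx.

    Depth extents (0-10 / 10-25 / 25-40 mm) and per-layer parameters are
    package conventions chosen to reproduce the slow / steep / slow
    gradient signature of a renal puncture: the medulla is stiffest
    (largest k0, alpha), the calyx softest and friction-dominated.
    """
    cortex = TissueParams(f_max=0.50, lam=0.25, k0=0.015, alpha=0.06,
                          mu0=0.2, label="renal_cortex")
    medulla = TissueParams(f_max=0.90, lam=0.50, k0=0.020, alpha=0.12,
                           mu0=0.2, label="renal_medulla")
    calyx = TissueParams(f_max=0.20, lam=0.30, k0=0.004, alpha=0.05,
                         mu0=0.3, label="renal_calyx")
    return LayerProfile(segments=(
        LayerSegment(0.0, 10.0, cortex, "cortex"),
        LayerSegment(10.0, 25.0, medulla, "medulla"),
        LayerSegment(25.0, 40.0, calyx, "calyx"),
    ), transition_width=transition_width)


@dataclass
class TrialSpec:
    """Everything needed to synthesize one puncture trial."""

    protocol: InsertionProtocol
    tissue: Union[TissueParams, LayerProfile]
    noise_sd: float = DEFAULT_NOISE_SD
    sample_rate: float = 10.0  # Hz
    seed: Optional[int] = None
    perturbation: Optional[PerturbationSpec] = None
    perturbation_coupling: float = 0.1  # N/mm
    cutting_mode: str = "saturating"
    speed_rate_multiplier: float = 1.0  # optional speed-effect emulation
    maxwell: Optional[MaxwellParams] = None
    maxwell_coupling: float = 0.0  # N per stress unit; rate correction, off

    def __post_init__(self) -> None:
        if not self.noise_sd >= 0:
            raise DomainError("noise_sd must be >= 0")
        if not self.sample_rate > 0:
            raise DomainError("sample_rate must be > 0")


def _time_grid(duration: float, rate: float) -> np.ndarray:
    n = int(np.floor(duration * rate + 1e-9)) + 1
    return np.arange(n) / rate


def _noiseless_force(spec: TrialSpec, depth: np.ndarray) -> np.ndarray:
    if isinstance(spec.tissue, LayerProfile):
        base = _layered_force(spec.tissue, depth, spec.protocol.angle_deg,
                              spec.cutting_mode)
    else:
        base = np.asarray(force_model.total_force(
            depth, spec.tissue, spec.protocol.angle_deg,
            spec.cutting_mode).total)
    base = base * spec.speed_rate_multiplier
    if spec.maxwell is not None and spec.maxwell_coupling != 0.0:
        # optional additive rate-dependent correction: strain proxied by
        # normalized depth so the viscous term reflects insertion speed
        t = depth / spec.protocol.speed
        eps = depth / spec.protocol.max_depth
        sigma = stress_response(StrainHistory(t, eps), spec.maxwell)
        base = base + spec.maxwell_coupling * sigma
    return base


def _layered_force(profile: LayerProfile, depth: np.ndarray,
                   theta_deg: float, cutting_mode: str) -> np.ndarray:
    """Piecewise model evaluation with carried-over force and blending.

    Each segment's cutting/stiffness/friction terms accumulate from its own
    entry depth on top of the force reached at the end of the previous
    segment; adjacent segments are blended with a logistic weight over
    ``transition_width`` so the slope change is smooth. Both branches of a
    blend equal the carried force at the boundary, so the noiseless curve
    is continuous regardless of width.
    """
    depth = np.asarray(depth, dtype=float)
    if np.any(depth > profile.total_depth + 1e-9):
        raise DomainError(
            f"depth {depth.max():.3f} mm exceeds the layer profile extent "
            f"{profile.total_depth} mm")

    def seg_force(seg: LayerSegment, offset: float, z: np.ndarray):
        local = np.clip(z - seg.start, 0.0, None)
        return offset + np.asarray(force_model.total_force(
            local, seg.params, theta_deg, cutting_mode).total)

    segs = profile.segments
    offsets = [0.0]
    for seg in segs[:-1]:
        offsets.append(float(seg_force(seg, offsets[-1],
                                       np.asarray([seg.end]))[0]))

    out = seg_force(segs[0], offsets[0], depth)
    scale = max(profile.transition_width / 8.0, 1e-12)
    for seg, off in zip(segs[1:], offsets[1:]):
        w = expit((depth - seg.start) / scale)
        out = (1.0 - w) * out + w * seg_force(seg, off, depth)
    return out


def generate_insertion_curve(spec: TrialSpec) -> ForceCurve:
    """Synthesize one insertion-phase trial.

    depth(t) = speed * t up to max_depth; force is the analytic model plus
    seeded Gaussian noise (and the optional lateral-perturbation ripple).
    With noise_sd = 0 and no perturbation the curve equals the analytic
    profile exactly.
    """
    proto = spec.protocol
    max_depth = proto.max_depth
    if isinstance(spec.tissue, LayerProfile):
        max_depth = min(max_depth, spec.tissue.total_depth)
    duration = max_depth / proto.speed
    t = _time_grid(duration, spec.sample_rate)
    depth = proto.speed * t
    force = _noiseless_force(spec, depth)

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        force = force + rng.normal(0.0, spec.noise_sd, size=force.shape)

    tissue_label = (spec.tissue.segments[0].params.label + "_layered"
                    if isinstance(spec.tissue, LayerProfile)
                    else spec.tissue.label)
    curve = ForceCurve(
        t=t, depth=depth, force=force,
        phase=np.full(t.shape, PHASE_INSERTION, dtype=object),
        meta={"kind": "synthetic_insertion", "tissue": tissue_label,
              "speed_mm_s": proto.speed, "angle_deg": proto.angle_deg,
              "max_depth_mm": max_depth, "noise_sd_N": spec.noise_sd,
              "sample_rate_hz": spec.sample_rate, "seed": spec.seed})
    if spec.perturbation is not None:
        curve = apply_perturbation(curve, spec.perturbation,
                                   spec.perturbation_coupling, seed=spec.seed)
    return curve


def generate_layered_curve(spec: TrialSpec) -> ForceCurve:
    """Synthesize a multi-layer trial; requires a LayerProfile tissue."""
    if not isinstance(spec.tissue, LayerProfile):
        raise DomainError("generate_layered_curve requires a LayerProfile")
    curve = generate_insertion_curve(spec)
    curve.meta["layer_labels"] = "|".join(
        s.label for s in spec.tissue.segments)
    curve.meta["layer_boundaries_mm"] = "|".join(
        repr(float(b)) for b in spec.tissue.boundaries)
    return curve


def add_retraction_phase(curve: ForceCurve, retraction_speed: float = None,
                         decay_rate: float = None) -> ForceCurve:
    """Append a retraction segment with exponentially decaying force.

    Depth runs back to 0 at ``retraction_speed`` (default: the insertion
    speed implied by the curve) while force decays from the final insertion
    value toward 0 at ``decay_rate`` (1/s; default chosen so the force
    falls to 5% of the peak by the end of the retraction). Force stays
    non-negative and the combined peak is the last insertion sample.
    """
    if not np.all(curve.phase == PHASE_INSERTION):
        raise ValueError("curve must be insertion-only")
    n = len(curve)
    if n < 2:
        raise ValueError("curve too short")
    dt = float(curve.t[1] - curve.t[0])
    max_depth = float(curve.depth[-1])
    if retraction_speed is None:
        retraction_speed = max_depth / float(curve.t[-1])
    if not retraction_speed > 0:
        raise ValueError("retraction_speed must be > 0")
    duration = max_depth / retraction_speed
    if decay_rate is None:
        decay_rate = np.log(20.0) / duration  # 5% of peak by end
    m = int(np.floor(duration / dt + 1e-9))
    tau = (np.arange(1, m + 1)) * dt
    t_r = curve.t[-1] + tau
    depth_r = np.clip(max_depth - retraction_speed * tau, 0.0, None)
    f_end = float(curve.force[-1])
    force_r = np.maximum(f_end * np.exp(-decay_rate * tau), 0.0)
    return ForceCurve(
        t=np.concatenate([curve.t, t_r]),
        depth=np.concatenate([curve.depth, depth_r]),
        force=np.concatenate([curve.force, force_r]),
        phase=np.concatenate([curve.phase,
                              np.full(m, PHASE_RETRACTION, dtype=object)]),
        meta={**curve.meta, "retraction_speed_mm_s": retraction_speed,
              "retraction_decay_rate_s": decay_rate})


def derive_trial_seed(master_seed: int, speed: float, angle: float,
                      rep: int) -> int:
    """Deterministic per-trial seed from the master seed and condition."""
    key = f"{master_seed}:{speed!r}:{angle!r}:{rep}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


@dataclass
class ExperimentDataset:
    """Full-factorial collection of synthetic trials."""

    curves: dict  # (speed, angle, rep) -> ForceCurve
    summary: pd.DataFrame  # per-trial peak forces and seeds
    master_seed: int
    tissue_label: str = ""

    def get(self, speed: float, angle: float, rep: int) -> ForceCurve:
        return self.curves[(speed, angle, rep)]

    def __len__(self) -> int:
        return len(self.curves)


def generate_experiment(speeds=DEFAULT_SPEEDS, angles=(90.0,),
                        reps: int = DEFAULT_REPS,
                        tissue: Union[TissueParams, LayerProfile] = None,
                        noise_sd: float = DEFAULT_NOISE_SD,
                        sample_rate: float = 10.0, max_depth: float = 40.0,
                        seed: int = 0,
                        with_retraction: bool = False) -> ExperimentDataset:
    """Generate one curve per (speed x angle x rep) cell.

    Per-trial seeds are derived from the master seed by hashing the
    condition, so regenerating with the same master seed reproduces every
    curve bit-identically while trials stay mutually independent. The
    summary table records the peak force of each trial, the response used
    by the downstream ANOVA/Tukey analysis.
    """
    from .evaluation import peak_force

    speeds, angles = list(speeds), list(angles)
    if not speeds or not angles or reps < 1:
        raise ValueError("need >= 1 level per factor and reps >= 1")
    if tissue is None:
        from .params import LIVER
        tissue = LIVER
    curves = {}
    rows = []
    for speed in speeds:
        for angle in angles:
            for rep in range(reps):
                trial_seed = derive_trial_seed(seed, speed, angle, rep)
                spec = TrialSpec(
                    protocol=InsertionProtocol(speed=speed, angle_deg=angle,
                                               max_depth=max_depth),
                    tissue=tissue, noise_sd=noise_sd,
                    sample_rate=sample_rate, seed=trial_seed)
                curve = generate_insertion_curve(spec)
                if with_retraction:
                    curve = add_retraction_phase(curve)
                curves[(speed, angle, rep)] = curve
                pf, pt, pd_ = peak_force(curve)
                rows.append({"speed_mm_s": speed, "angle_deg": angle,
                             "rep": rep, "seed": trial_seed,
                             "peak_force_N": pf, "peak_time_s": pt,
                             "peak_depth_mm": pd_})
    label = (tissue.segments[0].params.label + "_layered"
             if isinstance(tissue, LayerProfile) else tissue.label)
    return ExperimentDataset(curves=curves, summary=pd.DataFrame(rows),
                             master_seed=seed, tissue_label=label)
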