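"""Goodness-of-fit metrics, unified weighted error, and layer segmentation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .curve import ForceCurve

__all__ = ["MetricSet", "rmse", "r_squared", "max_error", "metric_set",
           "unified_error", "peak_force", "segment_curve",
           "SegmentationResult"]


@dataclass(frozen=True)
class MetricSet:
    """RMSE (N), coefficient of determination, max absolute error (N)."""

    rmse: float
    r_squared: float
    max_error: float
    n: int


def _pair(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"array length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("arrays must be non-empty")
    return a, b


def rmse(a, b) -> float:
    """Root mean square error sqrt(mean((a - b)^2))."""
    a, b = _pair(a, b)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def r_squared(obs, pred) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot about the observed mean."""
    obs, pred = _pair(obs, pred)
    if obs.size < 2:
        raise ValueError("r_squared needs at least 2 samples")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("r_squared undefined for constant observations")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def max_error(a, b) -> float:
    """Maximum absolute pointwise deviation max|a_i - b_i|."""
    a, b = _pair(a, b)
    return float(np.max(np.abs(a - b)))


def metric_set(obs, pred) -> MetricSet:
    """All three agreement metrics between observed and predicted forces."""
    obs, pred = _pair(obs, pred)
    return MetricSet(rmse=rmse(obs, pred), r_squared=r_squared(obs, pred),
                     max_error=max_error(obs, pred), n=int(obs.size))


def unified_error(metrics: pd.DataFrame,
                  weights: Optional[dict] = None) -> pd.Series:
    """Standardized, weighted aggregate error per condition (larger = worse).

    Each metric column is z-scored across conditions (population sd); the
    R^2 column is sign-flipped first so that larger always means worse;
    the z-scores are then combined by a weighted mean with weights
    normalized to sum to one (equal by default). A metric with zero
    variance across conditions contributes zero z-scores (with a warning).
    """
    cols = ["rmse", "r_squared", "max_error"]
    missing = [c for c in cols if c not in metrics.columns]
    if missing:
        raise ValueError(f"metrics table missing columns: {missing}")
    if len(metrics) < 2:
        raise ValueError("unified_error needs >= 2 conditions to standardize")
    if weights is None:
        weights = {c: 1.0 for c in cols}
    w = np.array([float(weights.get(c, 0.0)) for c in cols])
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative and not all zero")
    w = w / w.sum()

    z = np.zeros((len(metrics), len(cols)))
    for j, c in enumerate(cols):
        vals = metrics[c].to_numpy(dtype=float)
        if c == "r_squared":
            vals = -vals  # larger R^2 = better; flip so larger = worse
        sd = vals.std()  # population sd
        if sd == 0.0:
            warnings.warn(f"metric {c!r} has zero variance across conditions; "
                          "its z-scores are set to 0", UserWarning)
            continue
        z[:, j] = (vals - vals.mean()) / sd
    return pd.Series(z @ w, index=metrics.index, name="unified_error")


def peak_force(curve: ForceCurve):
    """Maximum force sample with its time and depth; ties -> earliest time."""
    if len(curve) == 0:
        raise ValueError("curve is empty")
    i = int(np.argmax(curve.force))  # argmax returns the first maximum
    return float(curve.force[i]), float(curve.t[i]), float(curve.depth[i])


@dataclass
class SegmentationResult:
    """Layer boundaries recovered from slope changes of a force-depth curve."""

    boundaries: list  # interior boundary depths (mm), sorted
    labels: list  # one label per segment
    gradients: list  # mean force-depth gradient per segment (N/mm)
    low_contrast: bool  # True when no well-separated slope break exists


def segment_curve(curve: ForceCurve, n_segments: int = 3,
                  window: int = 9,
                  labels: Optional[Sequence[str]] = None,
                  contrast_threshold: float = 5.0) -> SegmentationResult:
    """Split an insertion force-depth curve at its strongest slope changes.

    The force is smoothed with a centred moving average (``window``
    samples), its depth-gradient is formed, and the ``n_segments - 1``
    largest well-separated peaks of the absolute gradient change (curvature)
    mark the layer boundaries — the mechanical signature of a transition
    between tissue layers of different density. Mean force gradients per
    recovered segment are reported. When the curvature shows no peak
    standing clear of the background (ratio below ``contrast_threshold``),
    the result is flagged ``low_contrast`` (e.g. a homogeneous tissue).
    """
    ins = curve.insertion()
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    if len(ins) < max(4 * window, 2 * n_segments + 2):
        raise ValueError(
            f"curve too short ({len(ins)} samples) for window {window}")
    depth = ins.depth
    force = ins.force

    f_s = uniform_filter1d(force, size=window, mode="nearest")
    grad = np.gradient(f_s, depth)
    curv = np.abs(np.gradient(grad, depth))
    n = len(ins)
    edge = max(window, 2)  # candidates stay clear of the curve ends

    min_sep = max(window, n // (4 * n_segments))
    peaks, _ = signal.find_peaks(curv, distance=min_sep)
    peaks = peaks[(peaks >= edge) & (peaks < n - edge)]
    order = np.argsort(curv[peaks])[::-1] if peaks.size else np.array([], int)
    chosen = sorted(peaks[order[: n_segments - 1]].tolist())

    low_contrast = len(chosen) < n_segments - 1
    if low_contrast:
        # no (enough) interior slope breaks: fall back to the largest
        # interior curvature samples, keeping separation, and flag it
        taken = list(chosen)
        for i in np.argsort(curv)[::-1]:
            i = int(i)
            if len(taken) >= n_segments - 1:
                break
            if edge <= i < n - edge and all(abs(i - j) >= min_sep
                                            for j in taken):
                taken.append(i)
        chosen = sorted(taken)
    else:
        # a genuine layer transition is a *localized* curvature spike: it
        # must stand clear of both the global background and the local
        # curvature a couple of windows away (a smoothly growing
        # exponential fails the second check)
        baseline = float(np.median(curv[edge:n - edge]))
        for i in chosen:
            side = [curv[j] for j in (i - 2 * window, i + 2 * window)
                    if edge <= j < n - edge]
            local_bg = max(side) if side else baseline
            if (baseline > 0 and curv[i] < contrast_threshold * baseline) \
                    or (local_bg > 0 and curv[i] < 2.0 * local_bg):
                low_contrast = True

    # refine each peak to the local curvature centroid: box smoothing turns
    # a sharp slope break into a plateau whose argmax can sit at its edge,
    # while the centroid stays at the break itself
    refined = []
    for i in chosen:
        lo, hi = max(i - window, 0), min(i + window + 1, n)
        w_loc = curv[lo:hi] - curv[lo:hi].min()
        tot = float(w_loc.sum())
        z = float(np.sum(w_loc * depth[lo:hi]) / tot) if tot > 0 \
            else float(depth[i])
        refined.append(int(np.argmin(np.abs(depth - z))))
    chosen = sorted(set(refined))

    boundaries = [float(depth[i]) for i in chosen]
    cut_idx = [0] + chosen + [len(ins) - 1]
    gradients = []
    for a, b in zip(cut_idx[:-1], cut_idx[1:]):
        span = depth[b] - depth[a]
        gradients.append(float((force[b] - force[a]) / span) if span > 0
                         else float("nan"))
    if labels is None:
        labels = [f"segment_{i + 1}" for i in range(len(gradients))]
    return SegmentationResult(boundaries=boundaries, labels=list(labels),
                              gradients=gradients, low_contrast=low_contrast)
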