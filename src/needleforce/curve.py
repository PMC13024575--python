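"""The sampled force-curve container shared by the whole pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PHASE_INSERTION = "insertion"
PHASE_RETRACTION = "retraction"


@dataclass
class ForceCurve:
    """A sampled (time, depth, force) puncture trajectory.

    Attributes
    ----------
    t : ndarray
        Sample times (s), strictly increasing.
    depth : ndarray
        Needle-tip depth (mm) at each sample.
    force : ndarray
        Axial puncture force (N), finite everywhere.
    phase : ndarray of str
        Per-sample label, ``"insertion"`` or ``"retraction"``.
    meta : dict
        Provenance record (tissue, speed, angle, seed, units, ...).
    """

    t: np.ndarray
    depth: np.ndarray
    force: np.ndarray
    phase: np.ndarray = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.phase is None:
            self.phase = np.full(self.t.shape, PHASE_INSERTION, dtype=object)
        else:
            self.phase = np.asarray(self.phase, dtype=object)
        n = self.t.size
        if not (self.depth.size == n and self.force.size == n
                and self.phase.size == n):
            raise ValueError("t, depth, force and phase must have equal length")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time samples must be strictly increasing")
        if not np.all(np.isfinite(self.force)):
            raise ValueError("force samples must be finite")

    def __len__(self) -> int:
        return self.t.size

    @property
    def insertion_mask(self) -> np.ndarray:
        return self.phase == PHASE_INSERTION

    def insertion(self) -> "ForceCurve":
        """Return the insertion-phase sub-curve (metadata shared)."""
        m = self.insertion_mask
        return ForceCurve(self.t[m], self.depth[m], self.force[m],
                          self.phase[m], dict(self.meta))

    def copy(self) -> "ForceCurve":
        return ForceCurve(self.t.copy(), self.depth.copy(), self.force.copy(),
                          self.phase.copy(), dict(self.meta))

    def allclose(self, other: "ForceCurve", atol: float = 0.0,
                 rtol: float = 0.0) -> bool:
        return (len(self) == len(other)
                and np.allclose(self.t, other.t, atol=atol, rtol=rtol)
                and np.allclose(self.depth, other.depth, atol=atol, rtol=rtol)
                and np.allclose(self.force, other.force, atol=atol, rtol=rtol)
                and bool(np.all(self.phase == other.phase)))
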