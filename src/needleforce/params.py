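"""Domain parameter types for needle-tissue puncture modelling.

Unit conventions, used consistently across the package: lengths and depths
in millimetres, forces in newtons, times in seconds, angles in degrees at
every public interface (converted to radians only inside trigonometric
calls), stiffness in N/mm, rates in mm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence


class DomainError(ValueError):
    """An input violates the physical domain of the model."""


@dataclass(frozen=True)
class TissueParams:
    """Constants of the analytical puncture-force model for one tissue.

    Parameters
    ----------
    f_max : float
        Saturation limit of the cutting force (N).
    lam : float
        Rate at which the cutting force approaches saturation (mm^-1).
    k0 : float
        Initial tissue stiffness (N/mm).
    alpha : float
        Exponential stiffness-growth coefficient (mm^-1).
    mu0 : float
        Needle-tissue Coulomb friction coefficient (dimensionless).
    gamma_w0 : float, optional
        Constant cutting force Gamma*w0 (N) for the stable-phase
        constant-cutting model; None when only the saturating model is used.
    label : str
        Free-text tissue name carried into curve metadata.
    """

    f_max: float
    lam: float
    k0: float
    alpha: float
    mu0: float = 0.2
    gamma_w0: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        if not self.f_max > 0:
            raise DomainError(f"f_max must be > 0, got {self.f_max}")
        if not self.lam > 0:
            raise DomainError(f"lam must be > 0, got {self.lam}")
        if not self.k0 > 0:
            raise DomainError(f"k0 must be > 0, got {self.k0}")
        if not self.alpha >= 0:
            raise DomainError(f"alpha must be >= 0, got {self.alpha}")
        if not self.mu0 >= 0:
            raise DomainError(f"mu0 must be >= 0, got {self.mu0}")
        if self.gamma_w0 is not None and not self.gamma_w0 >= 0:
            raise DomainError(f"gamma_w0 must be >= 0, got {self.gamma_w0}")

    def with_values(self, **kwargs) -> "TissueParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def as_dict(self) -> dict:
        d = {
            "f_max": self.f_max,
            "lam": self.lam,
            "k0": self.k0,
            "alpha": self.alpha,
            "mu0": self.mu0,
        }
        if self.gamma_w0 is not None:
            d["gamma_w0"] = self.gamma_w0
        return d


# Identified parameters for porcine tissues (0.5 mm/s quasi-static fits).
LIVER = TissueParams(f_max=1.68, lam=0.12, k0=0.05, alpha=0.21,
                     mu0=0.2, label="porcine_liver")
RENAL = TissueParams(f_max=1.12, lam=0.15, k0=0.08, alpha=0.25,
                     mu0=0.2, label="porcine_renal")

PRESETS = {"liver": LIVER, "renal": RENAL}


@dataclass(frozen=True)
class NeedleSpec:
    """Needle geometry.

    The shaft radius cancels out of the simplified friction integral (the
    normal stress is expressed per unit contact area before being projected
    back onto the shaft), so it does not enter force evaluation; it is kept
    for provenance and for geometry-aware extensions.
    """

    radius: float = 0.6  # mm; 1.2 mm diameter = 18 G
    bevel: str = "bevel"

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise DomainError(f"needle radius must be > 0, got {self.radius}")


@dataclass(frozen=True)
class InsertionProtocol:
    """Kinematics of one puncture trial.

    angle_deg is the inclination between the needle shaft and the tissue
    surface; 90 degrees is perpendicular insertion. Values above 90 are
    rejected rather than reflected.
    """

    speed: float  # mm/s
    angle_deg: float = 90.0
    max_depth: float = 40.0  # mm
    retraction_speed: Optional[float] = None  # mm/s

    def __post_init__(self) -> None:
        if not self.speed > 0:
            raise DomainError(f"speed must be > 0, got {self.speed}")
        validate_angle(self.angle_deg)
        if not self.max_depth > 0:
            raise DomainError(f"max_depth must be > 0, got {self.max_depth}")
        if self.retraction_speed is not None and not self.retraction_speed > 0:
            raise DomainError("retraction_speed must be > 0 when given")


def validate_angle(angle_deg: float) -> float:
    """Validate a puncture angle in (0, 90] degrees and return it."""
    if not (0.0 < angle_deg <= 90.0):
        raise DomainError(
            f"puncture angle must lie in (0, 90] degrees, got {angle_deg}")
    return angle_deg


@dataclass(frozen=True)
class LayerSegment:
    """One depth-bounded tissue layer of a multi-layer organ."""

    start: float  # mm
    end: float  # mm
    params: TissueParams
    label: str = ""

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise DomainError(
                f"segment end {self.end} must exceed start {self.start}")


@dataclass(frozen=True)
class LayerProfile:
    """Ordered, contiguous stack of tissue layers starting at depth 0."""

    segments: tuple
    transition_width: float = 0.5  # mm, logistic blending span

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        if len(segs) < 1:
            raise DomainError("LayerProfile needs at least one segment")
        if abs(segs[0].start) > 1e-12:
            raise DomainError("first segment must start at depth 0")
        for a, b in zip(segs[:-1], segs[1:]):
            if abs(a.end - b.start) > 1e-9:
                raise DomainError(
                    f"segments must be contiguous: {a.end} != {b.start}")
        if not self.transition_width >= 0:
            raise DomainError("transition_width must be >= 0")

    @property
    def total_depth(self) -> float:
        return self.segments[-1].end

    @property
    def boundaries(self) -> Sequence[float]:
        """Interior layer boundaries (mm), one fewer than segments."""
        return [s.end for s in self.segments[:-1]]
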