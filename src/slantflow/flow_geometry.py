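"""Generative model of the first-order optic flow produced by a slanted plane.

A planar surface at slant ``sigma`` (tilt fixed at 90 deg, i.e. slanted about
the horizontal axis) viewed by an observer translating laterally while
fixating the surface centre undergoes a relative rotation ``omega`` about the
vertical axis.  To first order the image velocity field inside a small patch
around fixation is

    v(beta) = omega * (1 + beta * tan(sigma)),

where ``beta`` is the angular elevation of a feature.  Its gradient over
elevation is the deformation component of the flow,

    def = omega * tan(sigma),

which is the single retinal quantity the slant estimators consume.  All
angles are radians internally; degrees appear only at I/O boundaries, and
slant is carried as its tangent (the response scale used throughout).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HALF_PATCH_RAD",
    "SurfaceSpec",
    "ViewingCondition",
    "FlowSample",
    "HeadTrajectory",
    "DefProfile",
    "relative_rotation_rate",
    "def_rate",
    "local_velocity",
    "sweep_rotation_deg",
    "def_profile",
    "max_def",
]

#: Half-width of the image patch (rad) over which the first-order expansion
#: of the velocity field is treated as valid (~4 deg, half an 8 deg patch).
HALF_PATCH_RAD = 0.07


@dataclass(frozen=True)
class SurfaceSpec:
    """A planar stimulus surface.

    Parameters
    ----------
    slant_deg:
        Slant of the surface in degrees, in ``[0, 90)``.  Slant is the angle
        between the surface normal and the line of sight.
    kind:
        ``"virtual"`` (rendered dot display) or ``"physical"`` (real surface).
    """

    slant_deg: float
    kind: str = "virtual"
    tilt_deg: float = field(default=90.0, init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.slant_deg < 90.0:
            raise ValueError(f"slant_deg must be in [0, 90), got {self.slant_deg}")
        if self.kind not in ("virtual", "physical"):
            raise ValueError(f"kind must be 'virtual' or 'physical', got {self.kind!r}")

    @property
    def slant_tan(self) -> float:
        """Tangent of the slant angle (the internal slant scale)."""
        return math.tan(math.radians(self.slant_deg))

    @classmethod
    def from_tan(cls, slant_tan: float, kind: str = "virtual") -> "SurfaceSpec":
        if slant_tan < 0:
            raise ValueError("slant_tan must be non-negative")
        return cls(math.degrees(math.atan(slant_tan)), kind=kind)


#: Peak lateral head velocity (mm/s) for each velocity regime.
PEAK_VELOCITY_MM_S = {"normal": 285.6, "slow": 57.7}

#: Viewing distance (mm) for virtual and physical surfaces.
VIEWING_DISTANCE_MM = {"virtual": 860.0, "physical": 760.0}


@dataclass(frozen=True)
class ViewingCondition:
    """Viewing distance, velocity regime, and active/passive mode.

    ``label`` is one of the three experimental conditions: active viewing of a
    virtual surface (AVV), passive viewing of a virtual surface (PVV), or
    active viewing of a physical surface (AVP).
    """

    distance_mm: float
    peak_velocity_mm_s: float
    regime: str  # "normal" | "slow"
    mode: str  # "active" | "passive"
    label: str  # "AVV" | "PVV" | "AVP"

    def __post_init__(self) -> None:
        if self.distance_mm <= 0:
            raise ValueError("distance_mm must be positive")
        if self.peak_velocity_mm_s <= 0:
            raise ValueError("peak_velocity_mm_s must be positive")
        if self.regime not in ("normal", "slow"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.label not in ("AVV", "PVV", "AVP"):
            raise ValueError(f"unknown condition label {self.label!r}")
        expected_mode = "passive" if self.label == "PVV" else "active"
        if self.mode != expected_mode:
            raise ValueError(f"label {self.label} implies mode {expected_mode!r}, got {self.mode!r}")

    @classmethod
    def from_label(cls, label: str, regime: str = "normal") -> "ViewingCondition":
        """Build the canonical condition for a label and velocity regime."""
        kind = "physical" if label == "AVP" else "virtual"
        return cls(
            distance_mm=VIEWING_DISTANCE_MM[kind],
            peak_velocity_mm_s=PEAK_VELOCITY_MM_S[regime],
            regime=regime,
            mode="passive" if label == "PVV" else "active",
            label=label,
        )


@dataclass(frozen=True)
class FlowSample:
    """One local sample of the first-order velocity field."""

    beta_rad: float
    velocity_rad_s: float

    def __post_init__(self) -> None:
        if abs(self.beta_rad) > HALF_PATCH_RAD:
            raise ValueError(
                f"|beta_rad|={abs(self.beta_rad):.4f} outside the linearization patch "
                f"(max {HALF_PATCH_RAD})"
            )


@dataclass(frozen=True)
class HeadTrajectory:
    """Sampled lateral head position and velocity over time."""

    t_s: np.ndarray
    x_mm: np.ndarray
    v_mm_s: np.ndarray
    peak_velocity_mm_s: float
    amplitude_mm: float
    n_half_cycles: int

    def __post_init__(self) -> None:
        t = np.asarray(self.t_s, dtype=float)
        if t.size == 0:
            raise ValueError("empty trajectory")
        if not (len(t) == len(self.x_mm) == len(self.v_mm_s)):
            raise ValueError("t_s, x_mm, v_mm_s must have equal lengths")
        if np.any(np.diff(t) <= 0):
            raise ValueError("t_s must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0])


@dataclass(frozen=True)
class DefProfile:
    """Instantaneous def as a function of time, with cycle bookkeeping.

    ``cycle_boundaries`` holds the indices of the velocity zero-crossings; a
    complete def cycle spans two consecutive crossings of the same sign
    change (one full back-and-forth period).
    """

    t_s: np.ndarray
    def_rad_s: np.ndarray
    cycle_boundaries: np.ndarray

    def __post_init__(self) -> None:
        if len(self.t_s) != len(self.def_rad_s):
            raise ValueError("t_s and def_rad_s must have equal lengths")
        if len(self.t_s) == 0:
            raise ValueError("empty profile")
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("t_s must be strictly increasing")
        cb = np.asarray(self.cycle_boundaries)
        if cb.size and (np.any(np.diff(cb) <= 0) or cb.min() < 0 or cb.max() >= len(self.t_s)):
            raise ValueError("cycle_boundaries must be sorted indices within range")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (t_s, def_rad_s, cycle_id); partial cycles get id -1."""
        cycle_id = np.full(len(self.t_s), -1, dtype=int)
        cb = np.asarray(self.cycle_boundaries)
        for k in range(0, len(cb) - 2, 2):
            cycle_id[cb[k] : cb[k + 2] + 1] = k // 2
        return pd.DataFrame({"t_s": self.t_s, "def_rad_s": self.def_rad_s, "cycle_id": cycle_id})


def relative_rotation_rate(
    head_velocity_mm_s: float, distance_mm: float, object_rotation_rad_s: float = 0.0
) -> float:
    """Relative observer/surface rotation rate (rad/s) under fixation.

    A lateral head translation at velocity ``v`` while fixating a point at
    distance ``d`` rotates the line of sight at ``v/d``; an independently
    rotating object adds its own rate.  For the stationary surfaces modelled
    here the object term is zero.
    """
    if distance_mm <= 0:
        raise ValueError("distance_mm must be positive")
    return object_rotation_rad_s + head_velocity_mm_s / distance_mm


def def_rate(slant_tan: float, omega_rad_s: float) -> float:
    """Deformation (def) component of the flow: ``omega * tan(slant)`` (rad/s)."""
    return omega_rad_s * slant_tan


def local_velocity(beta_rad: float, slant_tan: float, omega_rad_s: float) -> float:
    """First-order image angular velocity at elevation ``beta_rad``.

    ``v(beta) = omega * (1 + beta * tan(slant))``; its elevation gradient is
    :func:`def_rate`.  Valid only inside the linearization patch.
    """
    if abs(beta_rad) > HALF_PATCH_RAD:
        raise ValueError(
            f"|beta_rad|={abs(beta_rad):.4f} outside the linearization patch (max {HALF_PATCH_RAD})"
        )
    return omega_rad_s * (1.0 + beta_rad * slant_tan)


def sweep_rotation_deg(total_lateral_shift_mm: float, distance_mm: float) -> float:
    """Relative surface rotation (deg) swept by the full lateral head excursion."""
    if distance_mm <= 0:
        raise ValueError("distance_mm must be positive")
    if total_lateral_shift_mm < 0:
        raise ValueError("total_lateral_shift_mm must be non-negative")
    return math.degrees(math.atan(total_lateral_shift_mm / distance_mm))


def _zero_crossings(v: np.ndarray) -> np.ndarray:
    """Indices marking sign changes of v (first index of the new sign)."""
    s = np.sign(v)
    # carry the previous sign through exact zeros so a touch-and-go is not a crossing
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    return np.flatnonzero(np.diff(s) != 0) + 1


def def_profile(
    trajectory: HeadTrajectory, surface: SurfaceSpec, condition: ViewingCondition
) -> DefProfile:
    """Instantaneous signed def produced by a head trajectory.

    ``def(t) = (v(t)/d) * tan(slant)``: the instantaneous egocentric rotation
    rate times the slant tangent.  Sign alternates with the direction of the
    back-and-forth motion.
    """
    v = np.asarray(trajectory.v_mm_s, dtype=float)
    if v.size == 0:
        raise ValueError("empty trajectory")
    d = (v / condition.distance_mm) * surface.slant_tan
    return DefProfile(
        t_s=np.asarray(trajectory.t_s, dtype=float),
        def_rad_s=d,
        cycle_boundaries=_zero_crossings(v),
    )


def max_def(profile: DefProfile) -> float:
    """Per-trial def summary: mean over complete cycles of the peak |def|.

    A cycle runs between consecutive velocity zero-crossings of the same sign
    change (one full period); the trailing partial cycle is dropped.  A
    profile with no zero-crossings at all (unidirectional motion) is treated
    as a single cycle.
    """
    mag = np.abs(np.asarray(profile.def_rad_s, dtype=float))
    cb = np.asarray(profile.cycle_boundaries)
    if cb.size == 0:
        return float(mag.max())
    if cb.size < 3:
        raise ValueError("no complete def cycle in profile")
    peaks = []
    for k in range(0, cb.size - 2, 2):
        peaks.append(mag[cb[k] : cb[k + 2] + 1].max())
    return float(np.mean(peaks))
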