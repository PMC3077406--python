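"""Synthetic psychophysics data with the statistical structure the analysis assumes.

This module stands in for the behavioural experiment: it generates lateral
head trajectories, pinhole dot-display projections, per-trial maximum def
values, and noisy slant judgments for the three conditions — active viewing
of a virtual surface (AVV), passive viewing of a virtual surface (PVV, a
replay of the AVV optic flow), and active viewing of a physical surface
(AVP).

Study conditions emulated by default: planar surfaces slanted 20-80 deg
(virtual, 860 mm viewing distance) or 10-50 deg (physical, 760 mm), tilt
fixed at 90 deg; back-and-forth lateral head translation with 50 mm maximum
lateral shift at peak velocity 285.6 ("normal") or 57.7 ("slow") mm/s;
5 repetitions x 5 slants per virtual block, 4 x 4 per physical block;
responses generated as ``k*sqrt(def)`` plus Gaussian noise with residual SD
0.218 on the slant-tangent scale, with condition slopes
k = {PVV: 1.04, AVV: 1.88, AVP: 2.41}.

The head trajectory is an idealized sinusoid (the experiment's kinematics
were human-generated); amplitude 25 mm gives the 50 mm peak-to-peak shift
and a closed-form peak def.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .flow_geometry import (
    PEAK_VELOCITY_MM_S,
    VIEWING_DISTANCE_MM,
    HeadTrajectory,
    SurfaceSpec,
    ViewingCondition,
    def_profile,
    max_def,
)

__all__ = [
    "ConditionSpec",
    "DotFrame",
    "DotDisplay",
    "make_trajectory",
    "velocity_band_check",
    "project_dots",
    "project_sequence",
    "angular_positions",
    "generate_trials",
    "simulate_responses",
    "DEFAULT_K_BY_CONDITION",
    "DEFAULT_NOISE_SD_TAN",
]

#: Regression slopes of response_tan on sqrt(def) used to synthesize judgments.
DEFAULT_K_BY_CONDITION: Dict[str, float] = {"PVV": 1.04, "AVV": 1.88, "AVP": 2.41}
#: Residual SD of judgments on the slant-tangent scale.
DEFAULT_NOISE_SD_TAN = 0.218

#: Acoustic-feedback bands on mean |head velocity| (mm/s), centre +/- halfwidth.
VELOCITY_BANDS = {"normal": (83.0, 40.0), "slow": (20.0, 10.0)}

_CONDITION_DEFAULTS = {
    "AVV": {"slants": (20.0, 35.0, 50.0, 65.0, 80.0), "distance": 860.0, "reps": 5},
    "PVV": {"slants": (20.0, 35.0, 50.0, 65.0, 80.0), "distance": 860.0, "reps": 5},
    "AVP": {"slants": (10.0, 20.0, 40.0, 50.0), "distance": 760.0, "reps": 4},
}


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental block: condition label, slants, distance, repetitions.

    ``regime`` may be fixed (``"normal"``/``"slow"``) or ``None`` for
    between-subject assignment at generation time.
    """

    label: str
    slant_deg_set: Sequence[float] = None  # type: ignore[assignment]
    distance_mm: float = None  # type: ignore[assignment]
    repetitions: int = None  # type: ignore[assignment]
    regime: Optional[str] = None

    def __post_init__(self) -> None:
        if self.label not in _CONDITION_DEFAULTS:
            raise ValueError(f"unknown condition label {self.label!r}")
        d = _CONDITION_DEFAULTS[self.label]
        if self.slant_deg_set is None:
            object.__setattr__(self, "slant_deg_set", d["slants"])
        if self.distance_mm is None:
            object.__setattr__(self, "distance_mm", d["distance"])
        if self.repetitions is None:
            object.__setattr__(self, "repetitions", d["reps"])
        if self.regime is not None and self.regime not in ("normal", "slow"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.distance_mm <= 0 or self.repetitions < 1:
            raise ValueError("invalid condition spec")

    @property
    def surface_kind(self) -> str:
        return "physical" if self.label == "AVP" else "virtual"


def make_trajectory(
    peak_velocity_mm_s: float,
    amplitude_mm: float = 25.0,
    n_half_cycles: int = 11,
    sample_rate_hz: float = 1000.0,
) -> HeadTrajectory:
    """Sinusoidal back-and-forth lateral head translation.

    ``x(t) = A sin(2 pi t / T)`` with period ``T = 2 pi A / v_peak``,
    truncated after ``n_half_cycles`` half-periods.  With the defaults
    (A = 25 mm, 11 half-cycles, i.e. 5.5 back-and-forth translations at peak
    285.6 mm/s) the duration is about 3.0 s.
    """
    if min(peak_velocity_mm_s, amplitude_mm, sample_rate_hz) <= 0:
        raise ValueError("trajectory parameters must be positive")
    if n_half_cycles < 2:
        raise ValueError("n_half_cycles must be >= 2")
    period_s = 2.0 * math.pi * amplitude_mm / peak_velocity_mm_s
    if sample_rate_hz * period_s / 2.0 < 20:
        raise ValueError(
            f"sample rate {sample_rate_hz} Hz gives fewer than 20 samples per half-cycle"
        )
    duration = n_half_cycles * period_s / 2.0
    t = np.arange(0.0, duration + 0.5 / sample_rate_hz, 1.0 / sample_rate_hz)
    w = 2.0 * math.pi / period_s
    return HeadTrajectory(
        t_s=t,
        x_mm=amplitude_mm * np.sin(w * t),
        v_mm_s=peak_velocity_mm_s * np.cos(w * t),
        peak_velocity_mm_s=peak_velocity_mm_s,
        amplitude_mm=amplitude_mm,
        n_half_cycles=n_half_cycles,
    )


def velocity_band_check(trajectory: HeadTrajectory, regime: str) -> bool:
    """Mirror of the experiment's acoustic feedback on mean |head velocity|.

    Advisory: the experiment's bands refer to human kinematics and are not
    jointly consistent with the peak velocities under a pure sinusoid.
    """
    if regime not in VELOCITY_BANDS:
        raise ValueError(f"unknown regime {regime!r}")
    centre, half = VELOCITY_BANDS[regime]
    mean_speed = float(np.mean(np.abs(trajectory.v_mm_s)))
    return abs(mean_speed - centre) <= half


# ---------------------------------------------------------------------------
# dot displays (exact pinhole projection; oracle for the linearized flow)


@dataclass(frozen=True)
class DotFrame:
    """One projected frame: dot image positions (mm on screen) and eye position."""

    image_xy_mm: np.ndarray  # (n_dots, 2)
    eye_position_mm: np.ndarray  # (3,)
    distance_mm: float
    t_s: float = 0.0


@dataclass(frozen=True)
class DotDisplay:
    """A sequence of projected frames of the same physical dots."""

    frames: Sequence[DotFrame]
    surface: SurfaceSpec

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValueError("display must contain at least one frame")


def _surface_points(
    surface: SurfaceSpec, distance_mm: float, n_dots: int, seed, aperture_mm: float
) -> np.ndarray:
    """Random dots on the surface plane, seen inside the aperture from the
    central eye position (the origin).

    The plane passes through the fixation point (0, 0, d) and is rotated by
    the slant about the horizontal (x) axis — tilt 90 deg — so depth varies
    with elevation.  Dots are drawn uniformly in the image (texture cues
    removed) and back-projected onto the plane.
    """
    rng = np.random.default_rng(seed)
    half = aperture_mm / 2.0
    img = rng.uniform(-half, half, size=(n_dots, 2))
    d = distance_mm
    tan_s = surface.slant_tan
    # ray t*(ix, iy, d) meets the plane at t = 1 / (1 - (iy/d) tan_s)
    denom = 1.0 - (img[:, 1] / d) * tan_s
    if np.any(denom <= 0):
        raise ValueError("aperture extends past the plane's horizon for this slant")
    t = 1.0 / denom
    return np.column_stack([t * img[:, 0], t * img[:, 1], t * d])


def project_dots(
    surface: SurfaceSpec,
    eye_position_mm: Sequence[float],
    n_dots: int = 100,
    seed: int = 0,
    distance_mm: Optional[float] = None,
    aperture_mm: float = 70.0,
) -> DotFrame:
    """Perspective pinhole projection of the surface dots through the eye.

    The screen is the plane ``z = distance_mm``; the eye is at
    ``eye_position_mm`` relative to the central viewing position (the
    origin).  The same ``seed`` always yields the same physical dots, so
    frames rendered for different eye positions depict one rigid surface.
    """
    if n_dots < 1:
        raise ValueError("n_dots must be >= 1")
    d = float(distance_mm if distance_mm is not None else VIEWING_DISTANCE_MM[surface.kind])
    eye = np.asarray(eye_position_mm, dtype=float)
    if eye.shape != (3,):
        raise ValueError("eye_position_mm must be a 3-vector")
    pts = _surface_points(surface, d, n_dots, seed, aperture_mm)
    rel_z = pts[:, 2] - eye[2]
    if np.any(rel_z <= 0):
        raise ValueError("surface point behind the eye")
    scale = (d - eye[2]) / rel_z
    img = eye[None, :2] + (pts[:, :2] - eye[None, :2]) * scale[:, None]
    return DotFrame(image_xy_mm=img, eye_position_mm=eye, distance_mm=d)


def project_sequence(
    surface: SurfaceSpec,
    eye_positions_mm: np.ndarray,
    t_s: np.ndarray,
    n_dots: int = 100,
    seed: int = 0,
    distance_mm: Optional[float] = None,
    aperture_mm: float = 70.0,
) -> DotDisplay:
    """Render the same dots from a sequence of eye positions."""
    frames = [
        DotFrame(
            image_xy_mm=project_dots(
                surface, e, n_dots, seed, distance_mm, aperture_mm
            ).image_xy_mm,
            eye_position_mm=np.asarray(e, dtype=float),
            distance_mm=float(
                distance_mm if distance_mm is not None else VIEWING_DISTANCE_MM[surface.kind]
            ),
            t_s=float(t),
        )
        for e, t in zip(eye_positions_mm, t_s)
    ]
    return DotDisplay(frames=frames, surface=surface)


def angular_positions(frame: DotFrame) -> np.ndarray:
    """Dot directions (azimuth, elevation in rad) relative to the gaze line.

    The gaze is assumed fixated on the surface centre (0, 0, d), mirroring
    the experiment's removal of the common translation component of the
    flow.
    """
    eye = frame.eye_position_mm
    dz = frame.distance_mm - eye[2]
    gaze = (np.array([0.0, 0.0]) - eye[:2]) / dz
    dirs = (frame.image_xy_mm - eye[None, :2]) / dz
    return np.arctan(dirs) - np.arctan(gaze)[None, :]


# ---------------------------------------------------------------------------
# trial tables


def _def_max_lookup(spec: ConditionSpec, regime: str, sample_rate_hz: float = 1000.0):
    """Per-slant maximum def for one block, via the full flow pipeline."""
    traj = make_trajectory(PEAK_VELOCITY_MM_S[regime], sample_rate_hz=sample_rate_hz)
    cond = ViewingCondition.from_label(spec.label, regime)
    out = {}
    for slant in spec.slant_deg_set:
        surface = SurfaceSpec(slant, kind=spec.surface_kind)
        out[slant] = max_def(def_profile(traj, surface, cond))
    return out


def generate_trials(
    spec: ConditionSpec,
    n_subjects: int = 34,
    regime_assignment: Optional[Sequence[str]] = None,
    seed: int = 0,
    replay_from: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Trial table (without responses) for one condition block.

    Each subject gets the full crossing of slants x repetitions in a
    randomized order, with ``def_max`` computed through the flow-geometry
    pipeline from the subject's velocity regime.  Regimes are assigned
    between subjects (half "normal", half "slow", shuffled) unless
    ``regime_assignment`` or ``spec.regime`` fixes them.  ``replay_from``
    reuses another block's def values verbatim (the passive condition
    replays the active block's optic flow), only relabelling the condition.
    """
    rng = np.random.default_rng(seed)
    if replay_from is not None:
        df = replay_from.copy()
        df["condition"] = spec.label
        parts = [
            g.sample(frac=1.0, random_state=int(rng.integers(2**31)))
            for _, g in df.groupby("subject_id", sort=False)
        ]
        return pd.concat(parts, ignore_index=True)

    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if regime_assignment is None:
        if spec.regime is not None:
            regimes = [spec.regime] * n_subjects
        else:
            half = n_subjects // 2
            regimes = ["normal"] * (n_subjects - half) + ["slow"] * half
            rng.shuffle(regimes)
    else:
        regimes = list(regime_assignment)
        if len(regimes) != n_subjects:
            raise ValueError("regime_assignment length must equal n_subjects")

    lookups = {r: _def_max_lookup(spec, r) for r in sorted(set(regimes))}
    rows = []
    for subj in range(n_subjects):
        regime = regimes[subj]
        cells = [
            (slant, rep)
            for slant in spec.slant_deg_set
            for rep in range(spec.repetitions)
        ]
        order = rng.permutation(len(cells))
        for idx in order:
            slant, rep = cells[idx]
            rows.append(
                (
                    subj,
                    spec.label,
                    regime,
                    slant,
                    math.tan(math.radians(slant)),
                    lookups[regime][slant],
                    rep,
                    seed,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "condition",
            "regime",
            "slant_sim_deg",
            "slant_sim_tan",
            "def_max",
            "repetition",
            "seed",
        ],
    )


def simulate_responses(
    trials: pd.DataFrame,
    k_by_condition: Optional[Dict[str, float]] = None,
    noise_sd_tan: float = DEFAULT_NOISE_SD_TAN,
    seed: int = 0,
    subject_k_jitter_sd: float = 0.0,
) -> pd.DataFrame:
    """Attach noisy slant judgments: ``response_tan = max(0, k*sqrt(def) + eps)``.

    ``k`` is looked up per condition; ``eps`` is Gaussian with SD
    ``noise_sd_tan`` on the tangent scale.  ``subject_k_jitter_sd`` > 0
    multiplies each subject's k by a lognormal factor (for mixed-effects
    style recovery tests).  Responses are floored at 0 (judgments are
    magnitudes in [0, 90] deg); no ceiling is applied on the tangent scale.
    """
    if noise_sd_tan < 0:
        raise ValueError("noise_sd_tan must be non-negative")
    kmap = DEFAULT_K_BY_CONDITION if k_by_condition is None else k_by_condition
    unknown = set(trials["condition"].unique()) - set(kmap)
    if unknown:
        raise ValueError(f"no k for condition(s): {sorted(unknown)}")
    if any(v <= 0 for v in kmap.values()):
        raise ValueError("all k values must be positive")

    rng = np.random.default_rng(seed)
    df = trials.copy()
    k = df["condition"].map(kmap).to_numpy(dtype=float)
    if subject_k_jitter_sd > 0:
        subjects = df["subject_id"].unique()
        factors = dict(
            zip(subjects, np.exp(rng.normal(0.0, subject_k_jitter_sd, len(subjects))))
        )
        k = k * df["subject_id"].map(factors).to_numpy(dtype=float)
    mu = k * np.sqrt(df["def_max"].to_numpy(dtype=float))
    eps = rng.normal(0.0, noise_sd_tan, len(df)) if noise_sd_tan > 0 else 0.0
    df["response_tan"] = np.maximum(0.0, mu + eps)
    return df
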