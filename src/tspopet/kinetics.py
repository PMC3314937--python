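"""Time-activity curve simulation under the one-tissue compartment model.

Given predicted kinetic parameters, a plasma/whole-blood input function and a
frame schedule, this module generates noiseless framed TACs for total tissue

    C_T(t)  = (1 - V_B) K1 exp(-k2 t / (1 + BP_ND)) (*) C_P(t) + V_B C_B(t)

and for the non-displaceable compartment (the BP_ND = 0 special case), then
removes/applies radioactive decay and adds frame-variance scaled Gaussian
noise on the non-decay-corrected data, mimicking ROI-level counting noise.

All convolutions and frame averages are exact (closed-form exponential
algebra); no numerical quadrature is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._expsum import ExpSum
from .ligands import BindingClass, Isotope
from .prediction import KineticParameters

__all__ = [
    "InputFunction",
    "synth_input",
    "FrameSchedule",
    "default_schedule",
    "TimeActivityCurve",
    "NoiseModel",
    "total_tissue_tac",
    "nd_tissue_tac",
    "apply_decay",
    "add_noise",
]

#: Default tri-exponential input coefficients (A1, lam1, A2, lam2, A3, lam3):
#: bolus peak near 0.35 min, cleared to well under 1% of peak by 90 min.
#: Activity units are arbitrary — BP_ND is a ratio of two distribution
#: volumes sharing the same input, so the absolute scale cancels.
DEFAULT_INPUT_PARAMS = (800.0, -4.0, 40.0, -0.5, 25.0, -0.05)


@dataclass(frozen=True)
class InputFunction:
    """Tri-exponential arterial input with a linear-rise bolus:

        C_P(t) = (A1 t - A2 - A3) e^{lam1 t} + A2 e^{lam2 t} + A3 e^{lam3 t}

    which is zero at t = 0 by construction.  Whole blood is modelled as a
    scalar multiple of plasma (``blood_scale``), absent a metabolite model.
    """

    a1: float = DEFAULT_INPUT_PARAMS[0]
    lam1: float = DEFAULT_INPUT_PARAMS[1]
    a2: float = DEFAULT_INPUT_PARAMS[2]
    lam2: float = DEFAULT_INPUT_PARAMS[3]
    a3: float = DEFAULT_INPUT_PARAMS[4]
    lam3: float = DEFAULT_INPUT_PARAMS[5]
    blood_scale: float = 1.0

    @property
    def plasma_expsum(self) -> ExpSum:
        return ExpSum.from_terms(
            [
                (-(self.a2 + self.a3), self.a1, self.lam1),
                (self.a2, 0.0, self.lam2),
                (self.a3, 0.0, self.lam3),
            ]
        )

    @property
    def blood_expsum(self) -> ExpSum:
        return self.plasma_expsum.scale(self.blood_scale)

    def plasma(self, t):
        return self.plasma_expsum(t)

    def whole_blood(self, t):
        return self.blood_expsum(t)


def synth_input(params=None, blood_scale: float = 1.0, duration: float = 90.0) -> InputFunction:
    """Build an input function, rejecting parameterizations that go negative
    anywhere on [0, duration] (checked on a dense grid)."""
    if params is None:
        params = DEFAULT_INPUT_PARAMS
    fn = InputFunction(*params, blood_scale=blood_scale)
    t = np.linspace(0.0, duration, 2001)
    if np.any(fn.plasma(t) < -1e-9 * max(1.0, np.max(np.abs(fn.plasma(t))))):
        raise ValueError("input-function parameters give a negative curve on "
                         f"[0, {duration}]")
    return fn


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, strictly increasing acquisition frames (minutes)."""

    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self):
        starts = np.asarray(self.starts, dtype=float)
        ends = np.asarray(self.ends, dtype=float)
        if starts.shape != ends.shape or starts.ndim != 1 or starts.size == 0:
            raise ValueError("starts and ends must be matching 1-D arrays")
        if np.any(ends <= starts):
            raise ValueError("every frame must have positive duration")
        if np.any(np.abs(starts[1:] - ends[:-1]) > 1e-9):
            raise ValueError("frames must be contiguous and non-overlapping")
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)

    @property
    def durations(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.starts + self.ends)

    @property
    def n_frames(self) -> int:
        return self.starts.size

    @classmethod
    def from_durations(cls, durations_min) -> "FrameSchedule":
        d = np.asarray(durations_min, dtype=float)
        edges = np.concatenate([[0.0], np.cumsum(d)])
        return cls(edges[:-1], edges[1:])


def default_schedule(duration: float = 90.0) -> FrameSchedule:
    """Typical dynamic PET framing: 6x10 s, 4x60 s, 4x120 s, 3x300 s, then
    600 s frames (a trailing shorter frame tops up to the requested duration)."""
    durations = [10 / 60] * 6 + [1.0] * 4 + [2.0] * 4 + [5.0] * 3
    t = sum(durations)
    while duration - t >= 10.0 - 1e-9:
        durations.append(10.0)
        t += 10.0
    if duration - t > 1e-9:
        durations.append(duration - t)
    return FrameSchedule.from_durations(durations)


@dataclass(frozen=True)
class TimeActivityCurve:
    """Framed mean activity values with their decay-correction state."""

    schedule: FrameSchedule
    values: np.ndarray
    isotope: Isotope
    decay_corrected: bool = True

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.schedule.n_frames,):
            raise ValueError("values must have one entry per frame")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class NoiseModel:
    """Zero-mean Gaussian frame noise with variance
    ``scale^2 * (non-decay-corrected activity) / (frame duration)``."""

    scale: float

    def __post_init__(self):
        if self.scale < 0:
            raise ValueError("noise scale must be >= 0")

    def frame_sd(self, tac: TimeActivityCurve) -> np.ndarray:
        if tac.decay_corrected:
            raise ValueError("noise model applies to non-decay-corrected TACs")
        var = self.scale**2 * np.clip(tac.values, 0.0, None) / tac.schedule.durations
        return np.sqrt(var)


def _tissue_curve(k1: float, k2_app: float, input_fn: InputFunction,
                  v_b: float) -> ExpSum:
    conv = input_fn.plasma_expsum.convolve_exp(k2_app).scale((1.0 - v_b) * k1)
    return conv + input_fn.blood_expsum.scale(v_b)


def total_tissue_tac(
    kp: KineticParameters,
    cls: BindingClass,
    input_fn: InputFunction,
    v_b: float,
    schedule: FrameSchedule,
    isotope: Isotope,
) -> TimeActivityCurve:
    """Noiseless framed total-tissue TAC for one binding class.

    Specific binding slows the apparent efflux to k2 / (1 + BP_ND); frame
    values are exact time-averages of the continuous curve.
    """
    k2_app = kp.k2 / (1.0 + kp.bp_nd[cls])
    curve = _tissue_curve(kp.k1, k2_app, input_fn, v_b)
    values = curve.frame_means(schedule.starts, schedule.ends)
    return TimeActivityCurve(schedule, values, isotope, decay_corrected=True)


def nd_tissue_tac(
    kp: KineticParameters,
    input_fn: InputFunction,
    v_b: float,
    schedule: FrameSchedule,
    isotope: Isotope,
) -> TimeActivityCurve:
    """Noiseless framed non-displaceable TAC (BP_ND = 0 curve)."""
    curve = _tissue_curve(kp.k1, kp.k2, input_fn, v_b)
    values = curve.frame_means(schedule.starts, schedule.ends)
    return TimeActivityCurve(schedule, values, isotope, decay_corrected=True)


def decay_factors(schedule: FrameSchedule, isotope: Isotope) -> np.ndarray:
    """Per-frame decay factor exp(-ln2 * t_mid / half_life) (midpoint rule)."""
    return np.exp2(-schedule.midpoints / isotope.half_life)


def apply_decay(tac: TimeActivityCurve, direction: str) -> TimeActivityCurve:
    """Move between decay-corrected and raw (non-decay-corrected) activity.

    ``uncorrect`` multiplies by the per-frame decay factor, ``correct``
    divides; the two are exact inverses.
    """
    factors = decay_factors(tac.schedule, tac.isotope)
    if direction == "uncorrect":
        if not tac.decay_corrected:
            raise ValueError("TAC is already non-decay-corrected")
        return replace(tac, values=tac.values * factors, decay_corrected=False)
    if direction == "correct":
        if tac.decay_corrected:
            raise ValueError("TAC is already decay-corrected")
        return replace(tac, values=tac.values / factors, decay_corrected=True)
    raise ValueError(f"direction must be 'uncorrect' or 'correct', got {direction!r}")


def add_noise(
    tac: TimeActivityCurve,
    model: NoiseModel,
    rng: np.random.Generator | int,
) -> TimeActivityCurve:
    """Add one realization of frame noise to a non-decay-corrected TAC.

    Negative noisy frame values are allowed (as in real ROI data).
    """
    if tac.decay_corrected:
        raise ValueError("noise must be added to non-decay-corrected data")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sd = model.frame_sd(tac)
    return replace(tac, values=tac.values + rng.normal(0.0, 1.0, sd.shape) * sd)
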