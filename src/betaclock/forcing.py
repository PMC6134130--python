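"""Zeitgeber signals: the feeding schedule and the SCN-driven neural cue.

Zeitgeber time (ZT) convention: ZT0 = lights on, ZT12 = lights off, 24 h
period.  Nocturnal rodents eat during the dark phase, so normal feeding (NF)
places the food window at ZT12-ZT24; daytime feeding (DF) shifts it by 12 h
into the light phase.  The SCN cue models rhythmic neural activity peaking
during the light phase; crucially it never shifts with the feeding schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "ZeitgeberSchedule",
    "ForcingBundle",
    "food_drive",
    "food_intake_rhs",
    "scn_cue",
    "SCN_PEAK_ZT",
]

#: phase (ZT hours) at which the SCN neural-activity cue peaks
SCN_PEAK_ZT = 6.0

#: steepness (1/h) of the smoothed edges of the feeding window
FOOD_EDGE_STEEPNESS = 4.0


@dataclass(frozen=True)
class ZeitgeberSchedule:
    """Light-dark convention plus the feeding window.

    ``food_shift`` is the displacement of the whole feeding window:
    0 = NF (nighttime feeding), +12 = DF (daytime feeding).  All phases are
    interpreted modulo 24 h.
    """

    period: float = 24.0
    lights_on: float = 0.0
    lights_off: float = 12.0
    food_onset: float = 12.0
    food_duration: float = 12.0
    food_shift: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.food_duration < 24.0):
            raise ValueError(f"food_duration must be in (0, 24), got {self.food_duration}")
        if self.period != 24.0:
            raise ValueError("only the 24 h day is supported")

    def shifted(self, delta: float) -> "ZeitgeberSchedule":
        """Schedule with the feeding window displaced by ``delta`` hours."""
        return ZeitgeberSchedule(
            period=self.period,
            lights_on=self.lights_on,
            lights_off=self.lights_off,
            food_onset=self.food_onset,
            food_duration=self.food_duration,
            food_shift=self.food_shift + delta,
        )

    @property
    def window_center(self) -> float:
        return (self.food_onset + self.food_shift + 0.5 * self.food_duration) % 24.0


def _circ_dist(t: np.ndarray | float, center: float) -> np.ndarray | float:
    """Circular distance (h) between time-of-day t and a phase center."""
    d = np.mod(np.asarray(t, dtype=float) - center, 24.0)
    return np.minimum(d, 24.0 - d)


def food_drive(t: np.ndarray | float, schedule: ZeitgeberSchedule) -> np.ndarray | float:
    """Smooth square-ish feeding drive: ~1 inside the food window, ~0 outside.

    A logistic edge of steepness ``FOOD_EDGE_STEEPNESS`` smooths the window
    boundaries so the ODE right-hand side stays differentiable.  Shifting the
    schedule by delta maps the drive exactly onto its time-shifted copy.
    """
    half = 0.5 * schedule.food_duration
    d = _circ_dist(t, schedule.window_center)
    out = 1.0 / (1.0 + np.exp(-FOOD_EDGE_STEEPNESS * (half - d)))
    if np.isscalar(t):
        return float(out)
    return out


def food_intake_rhs(
    t: float,
    food_state: np.ndarray,
    schedule: ZeitgeberSchedule,
    params,
) -> np.ndarray:
    """Two-variable relaxation cascade converting the feeding drive into the
    food-intake signal entering the glucose equation.

    drive -> fast activator F1 -> slower output F2; F2 is the signal.
    """
    f1, f2 = food_state
    drive = food_drive(t, schedule)
    df1 = params.k_f1 * drive - params.d_f1 * f1
    df2 = params.k_f2 * f1 - params.d_f2 * f2
    return np.array([df1, df2])


def scn_cue(
    t: np.ndarray | float,
    cneur: float,
    schedule: ZeitgeberSchedule | None = None,
    peak: float = SCN_PEAK_ZT,
) -> np.ndarray | float:
    """SCN-driven neural cue: clipped-cosine pulse scaled by cneur.

    The waveform is max(0, cos)^4, a smooth unimodal pulse centred on
    ``peak`` (a light-phase hour), reflecting the daytime peak of SCN
    neuronal firing.  The cue is independent of the feeding schedule (it
    tracks the light-dark cycle only); cneur = 0 removes it entirely.
    """
    if cneur < 0:
        raise ValueError(f"cneur must be >= 0, got {cneur}")
    c = np.cos(2.0 * np.pi * (np.asarray(t, dtype=float) - peak) / 24.0)
    w = np.where(c > 0.0, c, 0.0) ** 4
    out = cneur * w
    if np.isscalar(t):
        return float(out)
    return out


def scn_mean(cneur: float) -> float:
    """Temporal mean of the SCN cue over one day (the ablation level).

    Mean of max(0, cos)^4 over a full period is 3/16.
    """
    return cneur * 3.0 / 16.0


@dataclass
class ForcingBundle:
    """The two zeitgeber signals evaluated as functions of time.

    ``food_signal(t)`` is the food-intake rate (the output F2 of the
    two-ODE subsystem on its entrained cycle, or any callable supplied by the
    caller); ``scn_signal(t)`` is the neural cue entering Rev-Erb
    transcription.  ``scn_constant`` replaces the SCN rhythm by a constant
    (the "no central clock" ablation).
    """

    schedule: ZeitgeberSchedule = field(default_factory=ZeitgeberSchedule)
    cneur: float = 0.0
    food_signal: Callable[[float], float] | None = None
    scn_constant: float | None = None
    scn_peak: float = SCN_PEAK_ZT
    exo_transcription_override: float | None = None

    def scn(self, t):
        if self.scn_constant is not None:
            if np.isscalar(t):
                return self.scn_constant
            return np.full_like(np.asarray(t, dtype=float), self.scn_constant)
        return scn_cue(t, self.cneur, self.schedule, peak=self.scn_peak)

    def food(self, t):
        if self.food_signal is None:
            raise ValueError("no food signal attached to this bundle")
        return self.food_signal(t)
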