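"""Peak phases, amplitudes, circular phase shifts and the differential-shift
statistic comparing feeding conditions.

Phases are reported in ZT hours in [0, 24).  A shift between two conditions
is the minimal circular distance in [0, 12] plus a direction tag
("advance", "delay", or "antiphase" when the two directions are
indistinguishable at exactly 12 h).  The differential shift between the
positive (Bmal1) and negative (Per) clock arms is the signed circular
phase difference Bmal1 - Per under normal feeding minus the same difference
under shifted feeding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import STATE_NAMES
from .simulate import Trajectory

__all__ = [
    "PhaseReport",
    "peak_phase",
    "circular_shift",
    "signed_circular_difference",
    "differential_shift",
    "amplitude_change",
    "phase_report",
]

#: amplitude below which a peak phase is considered undefined
FLAT_TOL = 1e-9


class UndefinedPhaseError(ValueError):
    """Signal has no usable peak (amplitude below ``FLAT_TOL``)."""


def _quadratic_refine(t: np.ndarray, x: np.ndarray, i: int) -> float:
    """Vertex of the parabola through the three samples bracketing index i."""
    if i == 0 or i == len(t) - 1:
        return float(t[i])
    y0, y1, y2 = x[i - 1], x[i], x[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(t[i])
    delta = 0.5 * (y0 - y2) / denom
    return float(t[i] + delta * (t[i + 1] - t[i]))


def peak_phase(traj_or_times, variable_or_values=None, *, variable: str | None = None) -> float:
    """Peak phase (ZT h in [0, 24)) of one variable over one entrained cycle.

    Accepts either ``peak_phase(trajectory, "per_mRNA")`` or raw arrays
    ``peak_phase(times, values)``.  The grid argmax is refined by quadratic
    interpolation through the three bracketing samples.
    """
    if isinstance(traj_or_times, Trajectory):
        traj = traj_or_times
        name = variable if variable is not None else variable_or_values
        t = traj.times
        x = traj[name]
    else:
        t = np.asarray(traj_or_times, dtype=float)
        x = np.asarray(variable_or_values, dtype=float)
    if x.max() - x.min() < FLAT_TOL:
        raise UndefinedPhaseError("signal is flat; peak phase undefined")
    # drop the duplicated endpoint of a closed cycle for the argmax,
    # but keep wrap-around neighbours for the parabola
    n = len(t) - 1 if np.isclose((t[-1] - t[0]) % 24.0, 0.0, atol=1e-9) else len(t)
    i = int(np.argmax(x[:n]))
    if 0 < i < len(t) - 1:
        ph = _quadratic_refine(t, x, i)
    else:
        # wrap neighbours around the cycle
        tm = np.array([t[(i - 1) % n], t[i], t[(i + 1) % n]])
        xm = np.array([x[(i - 1) % n], x[i], x[(i + 1) % n]])
        tm = np.unwrap(tm, period=24.0) if False else tm
        # build a consistent local time axis
        step = t[1] - t[0]
        tloc = np.array([t[i] - step, t[i], t[i] + step])
        ph = _quadratic_refine(tloc, xm, 1)
    return float(ph % 24.0)


def signed_circular_difference(phase_a: float, phase_b: float) -> float:
    """Representative of (phase_b - phase_a) mod 24 in the interval (-12, 12]."""
    d = (phase_b - phase_a) % 24.0
    if d > 12.0:
        d -= 24.0
    return float(d)


def circular_shift(phase_a: float, phase_b: float) -> tuple[float, str]:
    """Minimal circular distance in [0, 12] h plus a direction tag.

    ``delay`` means phase_b lags phase_a (positive representative),
    ``advance`` the opposite; exactly 12 h is direction-ambiguous and tagged
    ``antiphase``.
    """
    d = signed_circular_difference(phase_a, phase_b)
    mag = abs(d)
    if np.isclose(mag, 12.0, atol=1e-12):
        return 12.0, "antiphase"
    return mag, ("delay" if d > 0 else ("advance" if d < 0 else "none"))


def amplitude_change(traj_a: Trajectory, traj_b: Trajectory, variable: str) -> float:
    """Peak-to-trough amplitude ratio (condition b over condition a)."""
    amp_a = traj_a.amplitude(variable)
    if amp_a <= FLAT_TOL:
        raise UndefinedPhaseError(f"zero amplitude for {variable!r} in condition a")
    return traj_b.amplitude(variable) / amp_a


@dataclass
class PhaseReport:
    """Per-variable peak phase and amplitude of one entrained condition,
    optionally paired with a second condition to give circular shifts."""

    condition: str
    peak_phases: dict[str, float]
    amplitudes: dict[str, float]
    shifts: dict[str, tuple[float, str]] = field(default_factory=dict)
    other_condition: str | None = None

    def phase(self, variable: str) -> float:
        return self.peak_phases[variable]

    def shift(self, variable: str) -> float:
        return self.shifts[variable][0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for var, ph in self.peak_phases.items():
            shift, direction = self.shifts.get(var, (np.nan, ""))
            rows.append(
                {
                    "variable": var,
                    "condition": self.condition,
                    "peak_phase_h": ph,
                    "amplitude": self.amplitudes[var],
                    "shift_h": shift,
                    "direction": direction,
                }
            )
        return pd.DataFrame(rows)


def phase_report(
    traj: Trajectory,
    other: Trajectory | None = None,
    *,
    variables: tuple[str, ...] | None = None,
    condition: str = "NF",
    other_condition: str = "DF",
) -> PhaseReport:
    """Build a :class:`PhaseReport` for one trajectory, with between-condition
    circular shifts when a second trajectory is given.

    Variables whose cycle is flat (e.g. ablated signals) are skipped.
    """
    variables = variables if variables is not None else STATE_NAMES
    phases: dict[str, float] = {}
    amps: dict[str, float] = {}
    shifts: dict[str, tuple[float, str]] = {}
    for var in variables:
        try:
            phases[var] = peak_phase(traj, var)
        except UndefinedPhaseError:
            continue
        amps[var] = traj.amplitude(var)
        if other is not None:
            try:
                other_ph = peak_phase(other, var)
            except UndefinedPhaseError:
                continue
            shifts[var] = circular_shift(phases[var], other_ph)
    return PhaseReport(
        condition=condition,
        peak_phases=phases,
        amplitudes=amps,
        shifts=shifts,
        other_condition=None if other is None else other_condition,
    )


def differential_shift(
    report_nf: PhaseReport,
    report_df: PhaseReport,
    gene_pos: str = "bmal1_mRNA",
    gene_neg: str = "per_mRNA",
) -> float:
    """Signed change of the Bmal1-Per circular phase difference between
    conditions: (Bmal1 - Per) under NF minus (Bmal1 - Per) under DF, each
    taken as the representative in (-12, 12], and the result itself reduced
    to (-12, 12]."""
    d_nf = signed_circular_difference(report_nf.phase(gene_neg), report_nf.phase(gene_pos))
    d_df = signed_circular_difference(report_df.phase(gene_neg), report_df.phase(gene_pos))
    return signed_circular_difference(d_df, d_nf)
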