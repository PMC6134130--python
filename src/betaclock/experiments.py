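"""In-silico experimental program: feeding-schedule inversion, SCN-strength
scan, small feeding shifts, one-at-a-time parameter sensitivity, network
architecture ablations, and re-entrainment (adaptation) timing.

Architectures:

* ``physiological`` -- local clock entrained by both the SCN cue and food.
* ``no_central_clock`` -- the SCN rhythm is replaced by its temporal mean;
  food coupling intact.  Mimics complete uncoupling from the central clock.
* ``no_clock`` -- the circadian transcription of the exocytosis factor is
  replaced by its mean value, disconnecting the clock from secretion (the
  clock itself keeps running).

Ablation means are computed over the entrained physiological NF cycle and
cached per parameter set.
"""

from __future__ import annotations

from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .forcing import ZeitgeberSchedule
from .metabolic import (
    anticipation_index,
    coincidence_index,
    decompose_secretion,
    syndrome_report,
)
from .model import CLOCK_MRNAS, hill_activation, hill_repression
from .params import ModelParameters, PARAM_NAMES
from .phase import differential_shift, phase_report
from .simulate import Trajectory, run_to_limit_cycle

__all__ = [
    "Architecture",
    "ablation_means",
    "run_condition",
    "inversion_experiment",
    "cneur_scan",
    "small_shift_scan",
    "parameter_sensitivity",
    "adaptation_time",
    "DEFAULT_CNEUR_GRID",
]

Architecture = Literal["physiological", "no_central_clock", "no_clock"]

#: SCN-strength grid used for the published scan (step 0.05, 0 -> 1.55)
DEFAULT_CNEUR_GRID = np.round(np.arange(0.0, 1.5501, 0.05), 4)

_ABLATION_CACHE: dict[bytes, dict[str, float]] = {}


def ablation_means(
    params: ModelParameters,
    schedule: ZeitgeberSchedule | None = None,
    **sim_kw,
) -> dict[str, float]:
    """Temporal means used by the ablated architectures.

    ``scn_mean`` is the cycle average of the SCN cue; ``exo_transcription``
    is the cycle average of the clock-driven Exo transcription rate, both
    over the entrained physiological NF cycle.
    """
    sched = schedule if schedule is not None else ZeitgeberSchedule()
    key = params.to_vector().tobytes() + bytes(f"{sched}", "utf8")
    if key in _ABLATION_CACHE:
        return _ABLATION_CACHE[key]
    from .forcing import scn_cue

    traj = run_to_limit_cycle(params, sched, **sim_kw)
    t = traj.times
    scn = np.asarray(scn_cue(t, params.cneur))
    gate = hill_activation(traj["BMAL1_prot"], params.K_bmal_exo, params.n_bmal_exo) * (
        hill_repression(traj["percry_complex"], params.K_cplx_exo, params.n_cplx_exo)
    )
    exo_tx = params.v_exo * np.asarray(gate)
    span = t[-1] - t[0]
    out = {
        "scn_mean": float(np.trapezoid(scn, t) / span),
        "exo_transcription": float(np.trapezoid(exo_tx, t) / span),
    }
    _ABLATION_CACHE[key] = out
    return out


def _overrides(params: ModelParameters, architecture: Architecture, **sim_kw):
    if architecture == "physiological":
        return {}
    means = ablation_means(params, **sim_kw)
    if architecture == "no_central_clock":
        return {"scn_constant": means["scn_mean"]}
    if architecture == "no_clock":
        return {"exo_override": means["exo_transcription"]}
    raise ValueError(f"unknown architecture {architecture!r}")


def run_condition(
    params: ModelParameters,
    architecture: Architecture = "physiological",
    food_shift: float = 0.0,
    *,
    schedule: ZeitgeberSchedule | None = None,
    **sim_kw,
) -> Trajectory:
    """Entrain the model under one architecture and feeding shift.

    Non-entrainment is reported via ``Trajectory.converged``; it is not an
    exception because scan grids legitimately contain unlocked points.
    """
    base = schedule if schedule is not None else ZeitgeberSchedule()
    sched = base.shifted(food_shift)
    kw = dict(sim_kw)
    kw.update(_overrides(params, architecture, **sim_kw))
    traj = run_to_limit_cycle(params, sched, **kw)
    traj.condition = f"{architecture}:shift{food_shift:+g}"
    return traj


def inversion_experiment(
    params: ModelParameters,
    architecture: Architecture = "physiological",
    **sim_kw,
) -> dict:
    """NF vs DF (12 h feeding inversion) under one architecture.

    Returns the two trajectories, the paired phase report, the
    Bmal1-Per differential shift, and the metabolic summary.
    """
    nf = run_condition(params, architecture, 0.0, **sim_kw)
    df = run_condition(params, architecture, 12.0, **sim_kw)
    rep_nf = phase_report(nf, df, condition="NF")
    rep_df = phase_report(df, condition="DF")
    summary: dict = {
        "architecture": architecture,
        "entrained": bool(nf.converged and df.converged),
        "phase_report": rep_nf,
        "trajectories": {"NF": nf, "DF": df},
    }
    if not summary["entrained"]:
        return summary
    summary["differential_shift_h"] = differential_shift(rep_nf, rep_df)
    summary.update(syndrome_report(nf, df))
    summary["coincidence_NF"] = coincidence_index(decompose_secretion(nf, params))
    summary["coincidence_DF"] = coincidence_index(decompose_secretion(df, params))
    ant_nf = anticipation_index(nf)
    ant_df = anticipation_index(df)
    summary["anticipation_NF"] = ant_nf.anticipation_index
    summary["anticipation_DF"] = ant_df.anticipation_index
    summary["rupture_NF"] = ant_nf.rupture_detected
    summary["rupture_DF"] = ant_df.rupture_detected
    return summary


def cneur_scan(
    params: ModelParameters,
    grid: Iterable[float] | None = None,
    **sim_kw,
) -> pd.DataFrame:
    """Phase shifts of Per and Bmal1 under feeding inversion as a function of
    the SCN-cue strength cneur.

    Non-entrained grid points are flagged (``entrained = False``) and carry
    NaN shifts.  The scan reproduces the signature tug-of-war: Per follows
    food (~12 h shift throughout) while Bmal1 shifts progressively less as
    the SCN cue strengthens.
    """
    grid = DEFAULT_CNEUR_GRID if grid is None else np.asarray(list(grid), dtype=float)
    rows = []
    for c in grid:
        p = params.replace(cneur=float(c))
        nf = run_condition(p, "physiological", 0.0, **sim_kw)
        df = run_condition(p, "physiological", 12.0, **sim_kw)
        ok = bool(nf.converged and df.converged)
        row = {"cneur": float(c), "entrained": ok,
               "shift_per": np.nan, "shift_bmal1": np.nan,
               "differential_shift": np.nan}
        if ok:
            rep_nf = phase_report(nf, df, condition="NF")
            rep_df = phase_report(df, condition="DF")
            row["shift_per"] = rep_nf.shift("per_mRNA")
            row["shift_bmal1"] = rep_nf.shift("bmal1_mRNA")
            row["differential_shift"] = differential_shift(rep_nf, rep_df)
        rows.append(row)
    return pd.DataFrame(rows)


def small_shift_scan(
    params: ModelParameters,
    shifts: Iterable[float] = (-4, -2, -1, 0, 1, 2, 4),
    **sim_kw,
) -> pd.DataFrame:
    """Effect of small feeding-schedule displacements Delta on clock phase
    relationships and on insulin amplitude (ratio vs Delta = 0)."""
    ref = run_condition(params, "physiological", 0.0, **sim_kw)
    rep_ref = phase_report(ref, condition="NF")
    rows = []
    for delta in shifts:
        if abs(delta) > 12:
            raise ValueError("|shift| must be <= 12 h")
        tr = run_condition(params, "physiological", float(delta), **sim_kw)
        ok = bool(tr.converged and ref.converged)
        row = {"shift_h": float(delta), "entrained": ok,
               "differential_shift": np.nan, "insulin_amplitude_ratio": np.nan}
        if ok:
            rep = phase_report(tr, condition=f"shift{delta:+g}")
            row["differential_shift"] = differential_shift(rep_ref, rep)
            row["insulin_amplitude_ratio"] = (
                tr.amplitude("insulin") / ref.amplitude("insulin")
            )
        rows.append(row)
    return pd.DataFrame(rows)


def parameter_sensitivity(
    params: ModelParameters,
    param_names: Iterable[str],
    fold_range: tuple[float, float] = (0.5, 2.0),
    n_points: int = 9,
    **sim_kw,
) -> pd.DataFrame:
    """One-at-a-time scan checking where the differential-phase-shift
    property (shift(Per) > shift(Bmal1)) survives parameter variation."""
    factors = np.geomspace(fold_range[0], fold_range[1], n_points)
    rows = []
    for name in param_names:
        if name not in PARAM_NAMES:
            raise KeyError(f"unknown parameter {name!r}")
        base_val = getattr(params, name)
        for f in factors:
            p = params.replace(**{name: base_val * float(f)})
            nf = run_condition(p, "physiological", 0.0, **sim_kw)
            df = run_condition(p, "physiological", 12.0, **sim_kw)
            ok = bool(nf.converged and df.converged)
            row = {"parameter": name, "factor": float(f),
                   "value": base_val * float(f), "entrained": ok,
                   "shift_per": np.nan, "shift_bmal1": np.nan,
                   "property_holds": False}
            if ok:
                rep = phase_report(nf, df)
                row["shift_per"] = rep.shift("per_mRNA")
                row["shift_bmal1"] = rep.shift("bmal1_mRNA")
                row["property_holds"] = bool(row["shift_per"] > row["shift_bmal1"])
            rows.append(row)
    return pd.DataFrame(rows)


def adaptation_time(
    params: ModelParameters,
    architecture: Architecture = "physiological",
    *,
    shift_to: float = 12.0,
    max_cycles: int = 100,
    tol: float = 1e-3,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> dict:
    """Cycles needed to re-entrain after switching the feeding schedule.

    The model is first entrained under NF, the feeding window is then
    displaced by ``shift_to`` hours, and cycles after the switch are
    compared against the final (converged) post-switch cycle using the
    amplitude-normalized sup distance.  Returned counts are the number of
    full cycles that elapse before the matching cycle: 0 means the first
    post-switch cycle is already on the new limit cycle (e.g. a null
    switch).  ``cycles_metabolic`` restricts the comparison to glucose,
    insulin and the exocytosis factor, which adapt immediately when
    secretion is disconnected from the clock.
    """
    from .model import STATE_NAMES
    from .simulate import _cycle_distance, _forcing_array, _solve

    base = ZeitgeberSchedule()
    kw = _overrides(params, architecture, rtol=rtol, atol=atol)
    # settle well below the matching tolerance: the consecutive-cycle test
    # underestimates distance to the attractor when transients decay slowly
    settle_tol = tol / 20.0
    nf = run_to_limit_cycle(params, base, tol=settle_tol, max_cycles=400,
                            rtol=rtol, atol=atol, **kw)
    if not nf.converged:
        raise RuntimeError("model did not entrain under NF; cannot switch")

    pv = params.to_vector()
    farr = _forcing_array(
        base.shifted(shift_to),
        kw.get("scn_constant"),
        kw.get("exo_override"),
        None,
        scn_peak=params.scn_peak,
    )
    y = np.concatenate([nf.states[-1], nf.food_states[-1]])
    coarse = np.linspace(0.0, 24.0, 97)
    cycles = []
    for k in range(max_cycles):
        t0 = 24.0 * k
        sol = _solve(pv, farr, t0, t0 + 24.0, y, t0 + coarse, rtol, atol)
        cycles.append(sol.y.T)
        y = cycles[-1][-1].copy()
        if k >= 1 and _cycle_distance(cycles[-2], cycles[-1]) < settle_tol:
            break
    ref = cycles[-1]
    settled = len(cycles) >= 2 and _cycle_distance(cycles[-2], cycles[-1]) < settle_tol

    met_idx = [STATE_NAMES.index(v) for v in ("glucose", "insulin", "exo_mRNA", "EXO_prot")]

    def first_match(idx: list[int] | None) -> int | float:
        if not settled:
            return float("inf")
        for k, cyc in enumerate(cycles):
            a = ref if idx is None else ref[:, idx]
            b = cyc if idx is None else cyc[:, idx]
            if _cycle_distance(a, b) < tol:
                return k
        return float("inf")

    return {
        "architecture": architecture,
        "shift_h": shift_to,
        "converged": settled,
        "cycles_all": first_match(None),
        "cycles_metabolic": first_match(met_idx),
    }
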