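"""Integration layer: solver contracts, convergence, symmetry, determinism."""

import numpy as np
import pytest

from betaclock.forcing import ZeitgeberSchedule
from betaclock.model import N_STATE, STATE_NAMES
from betaclock.params import ModelParameters
from betaclock.simulate import (
    DEFAULT_INIT,
    _full_rhs,
    _full_rhs_py,
    _forcing_array,
    integrate,
    run_to_limit_cycle,
)


class TestFusedRhsConsistency:
    def test_fused_rhs_matches_reference_modules(self, ref_params, rng):
        """The (optionally compiled) fused 15-equation RHS agrees with the
        public model_core + food-subsystem right-hand sides."""
        from betaclock.forcing import ForcingBundle, food_intake_rhs, scn_cue
        from betaclock.model import rhs as model_rhs

        sched = ZeitgeberSchedule()
        pv = ref_params.to_vector()
        farr = _forcing_array(sched, None, None, None)
        for _ in range(10):
            t = float(rng.uniform(0.0, 48.0))
            y = rng.uniform(0.05, 2.0, N_STATE + 2)
            fused = _full_rhs(t, y, pv, farr)
            assert np.allclose(fused, _full_rhs_py(t, y, pv, farr), atol=1e-14)
            cues = ForcingBundle(
                schedule=sched,
                cneur=ref_params.cneur,
                food_signal=lambda _t: y[14],
            )
            ref = model_rhs(t, y[:N_STATE], ref_params, cues)
            assert np.allclose(fused[:N_STATE], ref, rtol=1e-10, atol=1e-12)
            food = food_intake_rhs(t, y[N_STATE:], sched, ref_params)
            assert np.allclose(fused[N_STATE:], food, rtol=1e-8, atol=1e-10)


class TestIntegrate:
    def test_decoupled_insulin_closed_form(self):
        """With constant gates (glucose and EXO pinned at fixed points),
        insulin follows the analytic relaxation
        (k_i c / d_i)(1 - exp(-d_i t))."""
        from betaclock.model import f_exo, f_glu

        p = ModelParameters(k_ins_glu=1e-12)
        sched = ZeitgeberSchedule()
        exo_tx = 0.8  # constant Exo transcription (clockless override)
        me_ss = exo_tx / p.d_exo_m
        pe_ss = p.k_exo * me_ss / p.d_exo_p
        g_ss = p.g_base / p.d_glu
        init = np.full(N_STATE + 2, DEFAULT_INIT)
        init[STATE_NAMES.index("glucose")] = g_ss
        init[STATE_NAMES.index("insulin")] = 0.0
        init[STATE_NAMES.index("exo_mRNA")] = me_ss
        init[STATE_NAMES.index("EXO_prot")] = pe_ss
        init[N_STATE:] = 0.0  # food subsystem off
        traj = integrate(
            p, sched, (0.0, 48.0), init, food_constant=0.0, exo_override=exo_tx
        )
        c = f_glu(g_ss, p) * f_exo(pe_ss, p)
        expected = (p.k_i * c / p.d_i) * (1.0 - np.exp(-p.d_i * traj.times))
        assert np.allclose(traj["insulin"], expected, atol=1e-6)

    def test_translation_symmetry(self, ref_params):
        """Shifting both zeitgebers and the start time by the same delta
        yields the identical trajectory, time-shifted."""
        sched = ZeitgeberSchedule()
        init = np.full(N_STATE + 2, 0.3)
        for delta in (6.0, 12.0):
            a = integrate(ref_params, sched, (0.0, 72.0), init)
            b = integrate(
                ref_params, sched, (delta, 72.0 + delta), init,
                forcing_offset=delta,
            )
            assert np.allclose(a.states, b.states, atol=1e-6)

    def test_tolerance_refinement(self, ref_params):
        """Halving rtol changes the 72 h state by < 1e-5 relative."""
        sched = ZeitgeberSchedule()
        a = integrate(ref_params, sched, (0.0, 72.0), rtol=1e-8, atol=1e-10)
        b = integrate(ref_params, sched, (0.0, 72.0), rtol=5e-9, atol=1e-10)
        scale = np.abs(a.states[-1]) + 1e-6
        assert np.max(np.abs(a.states[-1] - b.states[-1]) / scale) < 1e-5

    def test_non_negativity(self, ref_params):
        traj = integrate(ref_params, ZeitgeberSchedule(), (0.0, 500.0), grid_step=0.25)
        assert traj.states.min() > -1e-9

    def test_too_short_span_rejected(self, ref_params):
        with pytest.raises(ValueError):
            integrate(ref_params, ZeitgeberSchedule(), (0.0, 10.0))


class TestRunToLimitCycle:
    def test_reference_entrains_to_24h(self, nf_traj):
        assert nf_traj.converged
        assert nf_traj.times[0] == 0.0
        assert nf_traj.times[-1] == pytest.approx(24.0)
        # per-variable periodicity of the closed cycle
        for i in range(N_STATE):
            x = nf_traj.states[:, i]
            amp = x.max() - x.min()
            if amp > 1e-9:
                assert abs(x[-1] - x[0]) / amp < 1e-3

    def test_idempotent_restart(self, ref_params, nf_traj):
        """Restarting from the converged cycle endpoint reconverges fast."""
        init = np.concatenate([nf_traj.states[-1], nf_traj.food_states[-1]])
        again = run_to_limit_cycle(ref_params, ZeitgeberSchedule(), init=init)
        assert again.converged
        assert again.n_transient_cycles <= 2

    def test_determinism(self, ref_params):
        a = run_to_limit_cycle(ref_params, ZeitgeberSchedule(), max_cycles=40)
        b = run_to_limit_cycle(ref_params, ZeitgeberSchedule(), max_cycles=40)
        assert np.array_equal(a.states, b.states)

    def test_constant_cues_reported_not_entrained(self, ref_params):
        """With both zeitgebers frozen the clock free-runs at its own period,
        so the 24 h cycle map must not report convergence."""
        from betaclock.forcing import scn_mean

        traj = run_to_limit_cycle(
            ref_params,
            ZeitgeberSchedule(),
            max_cycles=40,
            scn_constant=scn_mean(ref_params.cneur),
            food_constant=0.5,
        )
        assert not traj.converged

    def test_free_running_clock_oscillates(self, ref_params):
        """With both zeitgebers frozen at their means the clock is still a
        self-sustained oscillator with a circadian (20-28 h) period."""
        from scipy.signal import find_peaks

        from betaclock.forcing import scn_mean

        traj = integrate(
            ref_params,
            ZeitgeberSchedule(),
            (0.0, 700.0),
            grid_step=0.1,
            scn_constant=scn_mean(ref_params.cneur),
            food_constant=0.5,
            rtol=1e-7,
        )
        t, x = traj.times, traj["per_mRNA"]
        sel = t > 350.0  # discard transient
        x = x[sel]
        amp = x.max() - x.min()
        assert amp > 1e-3 * max(abs(x.mean()), 1e-6), "oscillation died out"
        peaks, _ = find_peaks(x, prominence=0.2 * amp)
        periods = np.diff(t[sel][peaks])
        assert 20.0 <= periods.mean() <= 28.0

    def test_entrained_period_is_24h(self, nf_traj):
        """Zero-crossing analysis of the mean-subtracted cycle: crossing
        pairs one cycle apart differ by 24 h within 0.05 h."""
        t = nf_traj.times
        for var in ("per_mRNA", "bmal1_mRNA", "insulin"):
            x = nf_traj[var] - nf_traj[var].mean()
            up = np.where((x[:-1] < 0) & (x[1:] >= 0))[0]
            assert len(up) == 1  # exactly one upward crossing per 24 h cycle
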