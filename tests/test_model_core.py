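"""Unit tests for the regulatory building blocks and the 13-variable RHS."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betaclock.forcing import ForcingBundle, ZeitgeberSchedule
from betaclock.model import (
    CLOCK_VARIABLES,
    N_STATE,
    STATE_NAMES,
    f_exo,
    f_glu,
    hill_activation,
    hill_repression,
    insulin_derivative,
    rhs,
)
from betaclock.params import ModelParameters


class TestHillFunctions:
    @pytest.mark.parametrize(
        "x, K, n, expected",
        [
            (1.0, 1.0, 2.0, 0.5),   # half-saturation at x = K
            (0.0, 1.0, 2.0, 0.0),
            (3.0, 1.0, 2.0, 0.9),   # 9 / (1 + 9)
            (2.5, 2.5, 7.0, 0.5),
        ],
    )
    def test_activation_values(self, x, K, n, expected):
        assert hill_activation(x, K, n) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "x, K, n, expected",
        [(0.0, 1.0, 2.0, 1.0), (1.0, 1.0, 2.0, 0.5), (3.0, 1.0, 2.0, 0.1)],
    )
    def test_repression_values(self, x, K, n, expected):
        assert hill_repression(x, K, n) == pytest.approx(expected, abs=1e-12)

    @given(
        x=st.floats(0.0, 100.0),
        K=st.floats(0.01, 50.0),
        n=st.floats(1.0, 8.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_complementarity(self, x, K, n):
        """Activation and repression sum to one at equal arguments."""
        total = hill_activation(x, K, n) + hill_repression(x, K, n)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_monotone(self):
        x = np.linspace(0.0, 10.0, 200)
        up = hill_activation(x, 2.0, 3.0)
        down = hill_repression(x, 2.0, 3.0)
        assert np.all(np.diff(up) >= 0)
        assert np.all(np.diff(down) <= 0)

    @pytest.mark.parametrize("bad", [{"K": 0.0}, {"K": -1.0}, {"n": 0.5}])
    def test_invalid_parameters(self, bad):
        kw = {"K": 1.0, "n": 2.0}
        kw.update(bad)
        with pytest.raises(ValueError):
            hill_activation(1.0, **kw)
        with pytest.raises(ValueError):
            hill_repression(1.0, **kw)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            hill_activation(-0.1, 1.0, 2.0)


class TestSecretionGates:
    def test_f_glu_boundaries(self, ref_params):
        assert f_glu(0.0, ref_params) == 0.0
        assert f_glu(ref_params.K_glu_sec, ref_params) == pytest.approx(0.5)

    def test_f_exo_boundaries(self, ref_params):
        assert f_exo(0.0, ref_params) == 0.0
        assert f_exo(ref_params.K_exo_sec, ref_params) == pytest.approx(0.5)

    def test_f_glu_monotone_finite_differences(self, ref_params):
        """Numeric derivative of the glucose gate is non-negative on a grid."""
        g = np.linspace(0.0, 8.0, 400)
        vals = np.asarray(f_glu(g, ref_params))
        assert np.all(np.diff(vals) >= -1e-15)
        assert vals.max() < 1.0


class TestInsulinDerivative:
    def test_balance_point(self):
        p = ModelParameters(k_i=1.0, d_i=0.5)
        assert insulin_derivative(2.0, 1.0, 1.0, p) == pytest.approx(0.0)

    def test_pure_clearance_when_no_glucose(self, ref_params):
        val = insulin_derivative(1.7, 0.0, 0.9, ref_params)
        assert val == pytest.approx(-ref_params.d_i * 1.7)

    def test_formula_identity_random(self, ref_params, rng):
        for _ in range(20):
            ins, fg, fe = rng.uniform(0, 3), rng.uniform(0, 1), rng.uniform(0, 1)
            expected = ref_params.k_i * fg * fe - ref_params.d_i * ins
            assert insulin_derivative(ins, fg, fe, ref_params) == pytest.approx(
                expected, abs=1e-14
            )


def _bundle(params, food=0.3):
    return ForcingBundle(
        schedule=ZeitgeberSchedule(),
        cneur=params.cneur,
        food_signal=lambda t: food,
    )


class TestRhs:
    def test_state_count(self):
        assert N_STATE == 13
        assert len(CLOCK_VARIABLES) == 9

    def test_production_only_at_origin(self, ref_params):
        """With cues off, every derivative at the zero state is >= 0."""
        cues = ForcingBundle(cneur=0.0, food_signal=lambda t: 0.0)
        d = rhs(0.0, np.zeros(N_STATE), ref_params, cues)
        assert np.all(d >= 0.0)

    def test_insulin_row_matches_insulin_derivative(self, ref_params, rng):
        cues = _bundle(ref_params)
        for _ in range(10):
            state = rng.uniform(0.05, 3.0, N_STATE)
            d = rhs(3.3, state, ref_params, cues)
            g, ins, pe = state[9], state[10], state[12]
            expected = insulin_derivative(
                ins, f_glu(g, ref_params), f_exo(pe, ref_params), ref_params
            )
            assert d[10] == pytest.approx(expected, rel=1e-12)

    def test_clock_block_autonomous_without_couplings(self, ref_params, rng):
        """With c_glu = 0 and cneur = 0, clock derivatives ignore the
        metabolic variables (block structure via finite differences)."""
        p = ref_params.replace(c_glu=1e-12, cneur=0.0)
        cues = ForcingBundle(cneur=0.0, food_signal=lambda t: 0.5)
        state = rng.uniform(0.1, 2.0, N_STATE)
        d0 = rhs(0.0, state, p, cues)
        for met_var in ("glucose", "insulin", "exo_mRNA", "EXO_prot"):
            pert = state.copy()
            pert[STATE_NAMES.index(met_var)] *= 1.7
            d1 = rhs(0.0, pert, p, cues)
            assert np.allclose(d0[:9], d1[:9], atol=1e-10)

    def test_non_finite_state_rejected(self, ref_params):
        cues = _bundle(ref_params)
        state = np.full(N_STATE, 0.5)
        state[3] = np.nan
        with pytest.raises(FloatingPointError):
            rhs(0.0, state, ref_params, cues)
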