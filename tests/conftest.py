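"""Shared fixtures.

Entrained limit-cycle trajectories are expensive (tens of forced cycles of
a 15-equation stiff system), so the reference NF/DF runs and the
architecture variants are computed once per session and shared.
"""

from __future__ import annotations

import numpy as np
import pytest

from betaclock.experiments import run_condition
from betaclock.forcing import ZeitgeberSchedule
from betaclock.params import ModelParameters, reference_params


@pytest.fixture(scope="session")
def ref_params() -> ModelParameters:
    return reference_params()


@pytest.fixture(scope="session")
def nf_schedule() -> ZeitgeberSchedule:
    return ZeitgeberSchedule()


@pytest.fixture(scope="session")
def df_schedule() -> ZeitgeberSchedule:
    return ZeitgeberSchedule().shifted(12.0)


@pytest.fixture(scope="session")
def nf_traj(ref_params):
    traj = run_condition(ref_params, "physiological", 0.0)
    assert traj.converged
    return traj


@pytest.fixture(scope="session")
def df_traj(ref_params):
    traj = run_condition(ref_params, "physiological", 12.0)
    assert traj.converged
    return traj


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def synthetic_nf_table(ref_params):
    from betaclock.synth import NoiseSpec, generate_pseudo_experiment

    return generate_pseudo_experiment(
        ref_params, noise=NoiseSpec(cv=0.05, replicates=3, seed=7)
    )
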